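"""Readers, writers and the canonical in-memory coordinate model.

All coordinates are held internally as 0-based half-open intervals; single
base positions are 0-based indices of the base itself.  Every external
dialect is converted at the I/O boundary:

* FASTA — no coordinates.
* GTF — 1-based inclusive.
* BED12 — native 0-based half-open.
* RepeatMasker ``.out`` — 1-based inclusive.
* FusionMap-style fusion tables — 1-based positions.

Breakpoint semantics (important, and easy to get wrong): ``break1`` is the
*last transcribed base* of the gene-1 portion of the fusion transcript and
``break2`` is the *first transcribed base* of the gene-2 portion.  The fusion
point therefore lies between ``break1`` and ``break2`` in transcript space.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "reverse_complement",
    "GenomeSequence",
    "GeneModel",
    "Breakpoint",
    "FusionRecord",
    "RepeatFeature",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_fusionmap_table",
    "write_fusionmap_table",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_ct_table",
    "write_ct_table",
    "build_gene_index",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case ACGTN string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """A genome held in memory as upper-case ACGTN strings per chromosome.

    The accessor works in the internal convention (0-based half-open).
    Requesting strand ``-`` returns the reverse complement of the ``+``
    sequence over the same interval.  Out-of-bounds requests raise rather
    than silently truncating.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome contains no chromosomes")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            s = _VALID_BASES.sub("N", seq.upper())
            self._seqs[name] = s

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return len(self._seqs[chrom])

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        self._check_chrom(chrom)
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        n = len(self._seqs[chrom])
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} (length {n})"
            )
        s = self._seqs[chrom][start:end]
        return reverse_complement(s) if strand == "-" else s

    def set_slice(self, chrom: str, start: int, end: int, replacement: str,
                  strand: str = "+") -> None:
        """Overwrite an interval in place (used by the synthetic generators).

        ``replacement`` is given in ``strand`` orientation and must have the
        interval's length.
        """
        self._check_chrom(chrom)
        if len(replacement) != end - start:
            raise ValueError("replacement length does not match interval")
        if strand == "-":
            replacement = reverse_complement(replacement)
        repl = _VALID_BASES.sub("N", replacement.upper())
        s = self._seqs[chrom]
        if not (0 <= start <= end <= len(s)):
            raise ValueError("interval out of bounds")
        self._seqs[chrom] = s[:start] + repl + s[end:]


@dataclass(frozen=True)
class Breakpoint:
    """A single genomic base with its transcribed strand (internal 0-based)."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 0:
            raise ValueError("position must be non-negative (internal 0-based)")


@dataclass
class GeneModel:
    """A transcript: ordered exons, strand, and an optional CDS span.

    ``exons`` are genomic half-open intervals in *transcription order*: for a
    minus-strand transcript ``exons[0]`` has the largest genomic coordinates.
    ``cds_start``/``cds_end`` are a genomic half-open span (or None when
    non-coding); both endpoints must fall inside exons.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s}, {e}) in {self.transcript_id}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"exons of {self.transcript_id} not in transcription order"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if self.cds_start >= self.cds_end:
                raise ValueError("empty CDS span")
            for pos in (self.cds_start, self.cds_end - 1):
                if self.genomic_to_transcript(pos) is None:
                    raise ValueError(
                        f"CDS endpoint {pos} of {self.transcript_id} is not exonic"
                    )

    # -- coordinate helpers -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole transcript."""
        starts, ends = zip(*self.exons)
        return min(starts), max(ends)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def transcript_to_genomic(self, t: int) -> int:
        """Genomic position of transcript base ``t`` (0-based)."""
        if t < 0:
            raise ValueError("negative transcript coordinate")
        cum = 0
        for s, e in self.exons:
            length = e - s
            if t < cum + length:
                off = t - cum
                return s + off if self.strand == "+" else e - 1 - off
            cum += length
        raise ValueError(f"transcript coordinate {t} beyond transcript length {cum}")

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Transcript coordinate of a genomic base, or None if intronic."""
        cum = 0
        for s, e in self.exons:
            if s <= pos < e:
                off = pos - s if self.strand == "+" else e - 1 - pos
                return cum + off
            cum += e - s
        return None

    def cds_transcript_interval(self) -> tuple[int, int] | None:
        """Inclusive (first, last) transcript coordinates of coding bases."""
        if self.cds_start is None:
            return None
        if self.strand == "+":
            first, last = self.cds_start, self.cds_end - 1
        else:
            first, last = self.cds_end - 1, self.cds_start
        c0 = self.genomic_to_transcript(first)
        c1 = self.genomic_to_transcript(last)
        assert c0 is not None and c1 is not None
        return c0, c1

    def three_prime_exon_ends(self) -> set[int]:
        """Genomic positions of the last (3', transcription order) base of each exon."""
        return {e - 1 if self.strand == "+" else s for s, e in self.exons}

    def five_prime_exon_starts(self) -> set[int]:
        """Genomic positions of the first (5', transcription order) base of each exon."""
        return {s if self.strand == "+" else e - 1 for s, e in self.exons}

    def transcript_sequence(self, genome: GenomeSequence) -> str:
        return "".join(
            genome.sequence(self.chrom, s, e, self.strand) for s, e in self.exons
        )

    def coding_sequence(self, genome: GenomeSequence) -> str:
        interval = self.cds_transcript_interval()
        if interval is None:
            return ""
        c0, c1 = interval
        return self.transcript_sequence(genome)[c0:c1 + 1]


@dataclass
class FusionRecord:
    """One fusion call with its two parental breakpoints.

    ``break1`` is the last transcribed base of the gene-1 portion and
    ``break2`` the first transcribed base of the gene-2 portion (FusionMap's
    convention).  Pre-computed classification strings from the caller's
    upstream tool are retained verbatim when present.
    """

    fusion_id: str
    gene1_id: str
    gene2_id: str
    break1: Breakpoint
    break2: Breakpoint
    read_count: int = 0
    dataset: str | None = None
    splice_pattern_class: str | None = None
    frame_shift_class: str | None = None
    on_exon_boundary: str | None = None

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


@dataclass(frozen=True)
class RepeatFeature:
    """A RepeatMasker annotation interval (internal half-open coordinates)."""

    chrom: str
    start: int
    end: int
    repeat_name: str
    repeat_class_family: str
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("repeat start > end")
        if not self.repeat_class_family:
            raise ValueError("repeat class/family must be non-empty")

    @property
    def family(self) -> str:
        """Family key: the text before '/', or the whole string when no '/'."""
        return self.repeat_class_family.split("/")[0]


def build_gene_index(models: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    """Group transcripts by gene_id for the classifiers."""
    index: dict[str, list[GeneModel]] = {}
    for m in models:
        index.setdefault(m.gene_id, []).append(m)
    return index


# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path: str | Path) -> GenomeSequence:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA header {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


def write_genome_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(c, 0, genome.length(c))), id=c, description="")
        for c in genome.chrom_names
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene models (GTF / BED12)


def read_gene_models(path: str | Path, dialect: str) -> list[GeneModel]:
    """Read transcript models from a GTF or BED12 file.

    Both dialects are converted to the internal convention: 0-based half-open
    intervals, exons in transcription order.
    """
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'gtf' or 'bed12'")


def _read_gtf(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta[tid] = (gid, feat.seqid, feat.strand)
        # GTF is 1-based inclusive
        interval = (feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(interval)
    models = []
    for tid, (gid, chrom, strand) in meta.items():
        if tid not in exons:
            raise ValueError(f"transcript {tid} has zero exons")
        ex = sorted(exons[tid])
        if strand == "-":
            ex = ex[::-1]
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        models.append(GeneModel(gid, tid, chrom, strand, ex, cds_start, cds_end))
    return models


def _read_bed12(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise ValueError("BED12 requires 12 columns")
    models = []
    for row in df.itertuples(index=False):
        chrom, chrom_start = row[0], int(row[1])
        name, strand = str(row[3]), str(row[5])
        thick_start, thick_end = int(row[6]), int(row[7])
        block_count = int(row[9])
        if block_count == 0:
            raise ValueError(f"transcript {name} has zero exons")
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        starts = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        if len(sizes) != block_count or len(starts) != block_count:
            raise ValueError(f"blockCount mismatch for {name}")
        ex = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
        if strand == "-":
            ex = ex[::-1]
        cds_start = thick_start if thick_start < thick_end else None
        cds_end = thick_end if thick_start < thick_end else None
        models.append(GeneModel(name, name, chrom, strand, ex, cds_start, cds_end))
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path, dialect: str) -> None:
    if dialect == "gtf":
        _write_gtf(models, path)
    elif dialect == "bed12":
        _write_bed12(models, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'gtf' or 'bed12'")


def _write_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\tfusionloci\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                # Emit per-exon CDS chunks clipped to the CDS span.
                for s, e in sorted(m.exons):
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{m.chrom}\tfusionloci\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
                        )


def _write_bed12(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            ex = sorted(m.exons)
            start, end = ex[0][0], ex[-1][1]
            thick_start = m.cds_start if m.is_coding else start
            thick_end = m.cds_end if m.is_coding else start
            sizes = ",".join(str(e - s) for s, e in ex)
            starts = ",".join(str(s - start) for s, _ in ex)
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.transcript_id}\t0\t{m.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(ex)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# FusionMap-style fusion tables

DEFAULT_FUSION_COLUMNS: dict[str, str] = {
    "fusion_id": "FusionID",
    "chrom1": "Chromosome1",
    "pos1": "Position1",
    "strand1": "Strand1",
    "chrom2": "Chromosome2",
    "pos2": "Position2",
    "strand2": "Strand2",
    "gene1": "KnownGene1",
    "gene2": "KnownGene2",
    "read_count": "SeedCount",
    "splice_pattern_class": "SplicePatternClass",
    "frame_shift_class": "FrameShiftClass",
    "on_exon_boundary": "OnExonBoundary",
    "dataset": "Dataset",
}

_MANDATORY_FUSION_FIELDS = (
    "fusion_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
    "gene1", "gene2", "read_count",
)


def read_fusionmap_table(path: str | Path,
                         column_map: Mapping[str, str] | None = None) -> list[FusionRecord]:
    """Read a FusionMap-style tab-delimited fusion table.

    Positions are 1-based in the file and converted to internal 0-based.
    ``column_map`` maps internal field names to file column names; the
    defaults follow FusionMap's own headers.  Pre-computed classification
    columns are retained when present and left unset otherwise.
    """
    cols = dict(DEFAULT_FUSION_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    for fieldname in _MANDATORY_FUSION_FIELDS:
        if cols[fieldname] not in df.columns:
            raise ValueError(f"missing mandatory column {cols[fieldname]!r}")

    def opt(row, fieldname):
        col = cols[fieldname]
        if col not in df.columns:
            return None
        val = getattr(row, col.replace(" ", "_"), None)
        if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
            return None
        return str(val)

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        d = dict(zip(df.columns, row))
        records.append(FusionRecord(
            fusion_id=str(d[cols["fusion_id"]]),
            gene1_id=str(d[cols["gene1"]]),
            gene2_id=str(d[cols["gene2"]]),
            break1=Breakpoint(str(d[cols["chrom1"]]), int(d[cols["pos1"]]) - 1,
                              str(d[cols["strand1"]])),
            break2=Breakpoint(str(d[cols["chrom2"]]), int(d[cols["pos2"]]) - 1,
                              str(d[cols["strand2"]])),
            read_count=int(d[cols["read_count"]]),
            dataset=_cell(d, cols.get("dataset")),
            splice_pattern_class=_cell(d, cols.get("splice_pattern_class")),
            frame_shift_class=_cell(d, cols.get("frame_shift_class")),
            on_exon_boundary=_cell(d, cols.get("on_exon_boundary")),
        ))
    return records


def _cell(rowdict, col):
    if col is None or col not in rowdict:
        return None
    val = rowdict[col]
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
        return None
    return str(val)


def write_fusionmap_table(records: Sequence[FusionRecord], path: str | Path,
                          column_map: Mapping[str, str] | None = None) -> None:
    cols = dict(DEFAULT_FUSION_COLUMNS)
    if column_map:
        cols.update(column_map)
    rows = []
    for r in records:
        rows.append({
            cols["fusion_id"]: r.fusion_id,
            cols["chrom1"]: r.break1.chrom,
            cols["pos1"]: r.break1.pos + 1,
            cols["strand1"]: r.break1.strand,
            cols["chrom2"]: r.break2.chrom,
            cols["pos2"]: r.break2.pos + 1,
            cols["strand2"]: r.break2.strand,
            cols["gene1"]: r.gene1_id,
            cols["gene2"]: r.gene2_id,
            cols["read_count"]: r.read_count,
            cols["dataset"]: r.dataset if r.dataset is not None else "",
            cols["splice_pattern_class"]: r.splice_pattern_class or "",
            cols["frame_shift_class"]: r.frame_shift_class or "",
            cols["on_exon_boundary"]: r.on_exon_boundary or "",
        })
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query              matching"
    "  repeat         position in repeat\n"
    "score  div. del. ins.  sequence  begin  end          (left)     repeat"
    "  class/family   begin  end    (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Read the whitespace-aligned RepeatMasker ``.out`` dialect.

    The three header lines are skipped; coordinates (1-based inclusive) are
    converted to internal.  A strand column of ``C`` (complement) maps to
    ``-``.
    """
    features = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            raise ValueError(f"malformed RepeatMasker row at line {lineno}")
        try:
            chrom = parts[4]
            begin, end = int(parts[5]), int(parts[6])
            strand = "-" if parts[8] in ("C", "-") else "+"
            name, class_family = parts[9], parts[10]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed RepeatMasker row at line {lineno}") from exc
        features.append(RepeatFeature(chrom, begin - 1, end, name, class_family, strand))
    return features


def write_repeatmasker_out(features: Sequence[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, f in enumerate(features, start=1):
            strand = "C" if f.strand == "-" else "+"
            fh.write(
                f"  239 10.0  0.0  0.0  {f.chrom}  {f.start + 1}  {f.end}  (0)  "
                f"{strand}  {f.repeat_name}  {f.repeat_class_family}  1  "
                f"{f.end - f.start}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# qPCR Ct tables (CSV)

CT_COLUMNS = ["sample_id", "condition", "target", "replicate", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: sample_id, condition, target, replicate, ct."""
    df = pd.read_csv(str(path))
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    df = df[CT_COLUMNS].copy()
    df["ct"] = df["ct"].astype(float)
    if not ((df["ct"] > 0) & df["ct"].notna() & (df["ct"] < float("inf"))).all():
        raise ValueError("Ct values must be finite and positive")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CT_COLUMNS].to_csv(str(path), index=False)
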