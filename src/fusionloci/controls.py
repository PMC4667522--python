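"""Random non-fusion splice-site controls and junction matching.

The control set mirrors the study design: consecutive-exon splice junctions
sampled uniformly at random from annotated multi-exon transcripts.  Each
control site carries a donor position (3' end of exon i) and an acceptor
position (5' start of exon i+1), so it can flow through the same flank
extraction and overlap machinery as a fusion.

Junction matching compares fusion junction coordinates against the junction
set of an external transcript assembly, optionally with a positional
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import Breakpoint, FusionRecord, GeneModel

__all__ = [
    "ControlSite",
    "JunctionKey",
    "sample_control_sites",
    "enumerate_junctions",
    "match_fusions",
    "dataset_overlap",
    "read_control_sites",
    "write_control_sites",
]


@dataclass(frozen=True)
class ControlSite:
    """One consecutive-exon splice junction of one transcript."""

    site_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    seed: int | None = None

    @property
    def break1(self) -> Breakpoint:
        return Breakpoint(self.chrom, self.donor_pos, self.strand)

    @property
    def break2(self) -> Breakpoint:
        return Breakpoint(self.chrom, self.acceptor_pos, self.strand)


@dataclass(frozen=True)
class JunctionKey:
    """A comparable two-sided junction coordinate key.

    The two (chrom, pos) pairs are stored in lexicographic order so keys
    built from either side ordering compare equal.  Strands ride along but
    do not participate in equality unless requested by the matcher.
    """

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str | None = None
    strand2: str | None = None

    @classmethod
    def make(cls, chrom1, pos1, chrom2, pos2, strand1=None, strand2=None):
        if (chrom1, pos1) <= (chrom2, pos2):
            return cls(chrom1, pos1, chrom2, pos2, strand1, strand2)
        return cls(chrom2, pos2, chrom1, pos1, strand2, strand1)

    @property
    def coords(self) -> tuple:
        return (self.chrom1, self.pos1, self.chrom2, self.pos2)


def _internal_junctions(model: GeneModel) -> list[tuple[int, int]]:
    """(donor, acceptor) genomic positions for each consecutive exon pair."""
    out = []
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        donor = e1 - 1 if model.strand == "+" else s1
        acceptor = s2 if model.strand == "+" else e2 - 1
        out.append((donor, acceptor))
    return out


def sample_control_sites(models: Sequence[GeneModel], n: int, seed: int,
                         replace: bool = False) -> list[ControlSite]:
    """Uniformly sample ``n`` consecutive-exon junctions from the annotation.

    Sampling is without replacement (reproducible from ``seed``); asking for
    more junctions than exist raises unless ``replace`` is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = []
    for m in sorted(models, key=lambda m: m.transcript_id):
        for i, (donor, acceptor) in enumerate(_internal_junctions(m)):
            pool.append((m, i, donor, acceptor))
    if not pool:
        raise ValueError("annotation contains no multi-exon transcript")
    if n > len(pool) and not replace:
        raise ValueError(
            f"requested {n} control sites but only {len(pool)} junctions exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=replace)
    sites = []
    for rank, k in enumerate(idx):
        m, i, donor, acceptor = pool[k]
        sites.append(ControlSite(
            site_id=f"ctrl{rank + 1}",
            gene_id=m.gene_id,
            transcript_id=m.transcript_id,
            chrom=m.chrom,
            strand=m.strand,
            donor_pos=donor,
            acceptor_pos=acceptor,
            seed=seed,
        ))
    return sites


def enumerate_junctions(transcripts: Iterable[GeneModel],
                        with_strand: bool = True) -> set[JunctionKey]:
    """One de-duplicated key per consecutive exon pair per transcript."""
    keys = set()
    for m in transcripts:
        for donor, acceptor in _internal_junctions(m):
            strands = (m.strand, m.strand) if with_strand else (None, None)
            keys.add(JunctionKey.make(m.chrom, donor, m.chrom, acceptor, *strands))
    return keys


def match_fusions(fusions: Sequence[FusionRecord],
                  junction_keys: Iterable[JunctionKey],
                  tolerance: int = 0,
                  require_strand: bool = False,
                  ) -> tuple[dict[str, list[JunctionKey]], int]:
    """Match fusion junctions against an external junction key set.

    A fusion matches a key when, after the canonical side ordering, both
    chromosomes agree and both positions agree within ``tolerance``.  By
    default both sides must hit the same key (i.e. the same external
    transcript junction) and strand is ignored.  Returns per-fusion match
    lists and the number of fusions with at least one match.
    """
    keys = list(junction_keys)
    coord_index = {}
    for k in keys:
        coord_index.setdefault(k.coords, []).append(k)
    matches: dict[str, list[JunctionKey]] = {}
    for f in fusions:
        fkey = JunctionKey.make(
            f.break1.chrom, f.break1.pos, f.break2.chrom, f.break2.pos,
            f.break1.strand, f.break2.strand,
        )
        found: list[JunctionKey] = []
        if tolerance == 0:
            found = list(coord_index.get(fkey.coords, []))
        else:
            for k in keys:
                if (k.chrom1 == fkey.chrom1 and k.chrom2 == fkey.chrom2
                        and abs(k.pos1 - fkey.pos1) <= tolerance
                        and abs(k.pos2 - fkey.pos2) <= tolerance):
                    found.append(k)
        if require_strand:
            found = [
                k for k in found
                if (k.strand1, k.strand2) == (fkey.strand1, fkey.strand2)
            ]
        matches[f.fusion_id] = found
    n_matched = sum(1 for v in matches.values() if v)
    return matches, n_matched


def dataset_overlap(fusions: Sequence[FusionRecord]) -> dict[str, int]:
    """Counts of fusions per provenance tag combination.

    A fusion's ``dataset`` field may list several comma-separated tags; the
    tally groups by the sorted tag set, which is the information behind
    dataset-overlap (Venn-style) figures.
    """
    counts: dict[str, int] = {}
    for f in fusions:
        tags = "&".join(sorted(t.strip() for t in (f.dataset or "unknown").split(",")))
        counts[tags] = counts.get(tags, 0) + 1
    return counts


# -- on-disk form of control sites (1-based positions) ----------------------

CONTROL_COLUMNS = ["site_id", "gene_id", "transcript_id", "chrom", "strand",
                   "donor_pos", "acceptor_pos"]


def write_control_sites(sites: Sequence[ControlSite], path: str | Path) -> None:
    rows = [{
        "site_id": s.site_id, "gene_id": s.gene_id,
        "transcript_id": s.transcript_id, "chrom": s.chrom, "strand": s.strand,
        "donor_pos": s.donor_pos + 1, "acceptor_pos": s.acceptor_pos + 1,
    } for s in sites]
    pd.DataFrame(rows, columns=CONTROL_COLUMNS).to_csv(str(path), sep="\t", index=False)


def read_control_sites(path: str | Path) -> list[ControlSite]:
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    missing = [c for c in CONTROL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"control table missing columns: {missing}")
    return [
        ControlSite(
            site_id=str(r.site_id), gene_id=str(r.gene_id),
            transcript_id=str(r.transcript_id), chrom=str(r.chrom),
            strand=str(r.strand), donor_pos=int(r.donor_pos) - 1,
            acceptor_pos=int(r.acceptor_pos) - 1,
        )
        for r in df.itertuples(index=False)
    ]
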