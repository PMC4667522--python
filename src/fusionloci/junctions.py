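"""Classification of fusion junctions.

Four independent classifications are made per fusion call:

* splice pattern — the donor/acceptor dinucleotides read from the genome
  immediately outside the two breakpoint bases, on each parental gene's
  strand; the named classes are GT-AG (canonical), GC-AG, AT-AC, CT-AC and
  CT-GC, everything else is ``other``;
* exon boundary — whether each breakpoint coincides with an annotated exon
  border (3' exon end for gene 1, 5' exon start for gene 2);
* reading frame — the codon phase (0/1/2) of the breakpoint base within each
  parental CDS, rendered as the field's "p1→p2" notation with an absent phase
  left empty; the frame is maintained when phase2 == (phase1 + 1) mod 3;
* category — read-through (adjacent parental genes), intrachromosomal
  non-adjacent, or interchromosomal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genomic_io import (
    Breakpoint,
    FusionRecord,
    GeneModel,
    GenomeSequence,
    build_gene_index,
)

__all__ = [
    "SplicePatternClass",
    "ExonBoundaryClass",
    "FrameShiftClass",
    "FusionCategory",
    "AnnotatedFusion",
    "CohortSummary",
    "SPLICE_CLASS_LABELS",
    "classify_splice_pattern",
    "classify_exon_boundary",
    "classify_frame",
    "classify_category",
    "annotate_cohort",
    "summarize_cohort",
    "filter_same_chrom_sense",
]

SPLICE_CLASS_LABELS = ("GT-AG", "GC-AG", "AT-AC", "CT-AC", "CT-GC")
ARROW = "→"


@dataclass(frozen=True)
class SplicePatternClass:
    donor_dinucleotide: str
    acceptor_dinucleotide: str

    @property
    def label(self) -> str:
        cand = f"{self.donor_dinucleotide}-{self.acceptor_dinucleotide}"
        return cand if cand in SPLICE_CLASS_LABELS else "other"

    @property
    def is_canonical(self) -> bool:
        return self.label == "GT-AG"


@dataclass(frozen=True)
class ExonBoundaryClass:
    gene1_on_boundary: bool
    gene2_on_boundary: bool
    matched_transcript1: str | None = None
    matched_transcript2: str | None = None

    @property
    def label(self) -> str:
        if self.gene1_on_boundary and self.gene2_on_boundary:
            return "both"
        if self.gene1_on_boundary:
            return "gene1_only"
        if self.gene2_on_boundary:
            return "gene2_only"
        return "neither"


@dataclass(frozen=True)
class FrameShiftClass:
    phase1: int | None
    phase2: int | None
    matched_transcript1: str | None = None
    matched_transcript2: str | None = None

    @property
    def label(self) -> str:
        p1 = "" if self.phase1 is None else str(self.phase1)
        p2 = "" if self.phase2 is None else str(self.phase2)
        return f"{p1}{ARROW}{p2}"

    @property
    def frame_status(self) -> str:
        if self.phase1 is None or self.phase2 is None:
            return "not_applicable"
        return "in_frame" if self.phase2 == (self.phase1 + 1) % 3 else "frameshift"


@dataclass(frozen=True)
class FusionCategory:
    label: str  # read_through | intrachromosomal_non_adjacent | interchromosomal
    sense_antisense: bool


@dataclass
class AnnotatedFusion:
    record: FusionRecord
    splice: SplicePatternClass
    boundary: ExonBoundaryClass
    frame: FrameShiftClass
    category: FusionCategory


def classify_splice_pattern(fusion: FusionRecord, genome: GenomeSequence) -> SplicePatternClass:
    """Donor/acceptor dinucleotides flanking the two breakpoint bases.

    The donor is the two bases immediately 3' of break1 on gene 1's strand;
    the acceptor the two bases immediately 5' of break2 on gene 2's strand.
    When a breakpoint coincides with an annotated splice site these are the
    intron's terminal dinucleotides.
    """
    donor = _dinuc_after(fusion.break1, genome)
    acceptor = _dinuc_before(fusion.break2, genome)
    return SplicePatternClass(donor, acceptor)


def _dinuc_after(bp: Breakpoint, genome: GenomeSequence) -> str:
    n = genome.length(bp.chrom)
    if bp.strand == "+":
        if bp.pos + 3 > n:
            raise ValueError(f"breakpoint {bp} within 2 bases of contig end")
        return genome.sequence(bp.chrom, bp.pos + 1, bp.pos + 3, "+")
    if bp.pos - 2 < 0:
        raise ValueError(f"breakpoint {bp} within 2 bases of contig end")
    return genome.sequence(bp.chrom, bp.pos - 2, bp.pos, "-")


def _dinuc_before(bp: Breakpoint, genome: GenomeSequence) -> str:
    n = genome.length(bp.chrom)
    if bp.strand == "+":
        if bp.pos - 2 < 0:
            raise ValueError(f"breakpoint {bp} within 2 bases of contig end")
        return genome.sequence(bp.chrom, bp.pos - 2, bp.pos, "+")
    if bp.pos + 3 > n:
        raise ValueError(f"breakpoint {bp} within 2 bases of contig end")
    return genome.sequence(bp.chrom, bp.pos + 1, bp.pos + 3, "-")


def _resolve(gene_id: str, index: Mapping[str, list[GeneModel]]) -> list[GeneModel]:
    if gene_id not in index:
        raise KeyError(f"unknown gene id {gene_id!r}")
    return index[gene_id]


def classify_exon_boundary(fusion: FusionRecord,
                           models: Iterable[GeneModel] | Mapping[str, list[GeneModel]],
                           ) -> ExonBoundaryClass:
    """Does each breakpoint sit exactly on an annotated exon border?

    A match on any transcript of the gene counts; the matched transcript id
    is recorded.
    """
    index = models if isinstance(models, Mapping) else build_gene_index(models)
    t1 = t2 = None
    for m in _resolve(fusion.gene1_id, index):
        if fusion.break1.pos in m.three_prime_exon_ends() and fusion.break1.chrom == m.chrom:
            t1 = m.transcript_id
            break
    for m in _resolve(fusion.gene2_id, index):
        if fusion.break2.pos in m.five_prime_exon_starts() and fusion.break2.chrom == m.chrom:
            t2 = m.transcript_id
            break
    return ExonBoundaryClass(t1 is not None, t2 is not None, t1, t2)


def _phase_at(bp: Breakpoint, transcripts: Sequence[GeneModel]) -> tuple[int | None, str | None]:
    for m in transcripts:
        if m.chrom != bp.chrom or not m.is_coding:
            continue
        t = m.genomic_to_transcript(bp.pos)
        if t is None:
            continue
        interval = m.cds_transcript_interval()
        c0, c1 = interval
        if c0 <= t <= c1:
            return (t - c0) % 3, m.transcript_id
    return None, None


def classify_frame(fusion: FusionRecord,
                   models: Iterable[GeneModel] | Mapping[str, list[GeneModel]],
                   ) -> FrameShiftClass:
    """Codon phase of the breakpoint base in each parental CDS.

    The phase is the 0-based position of the base within its codon, i.e. the
    number of coding bases from the CDS start up to and including the break
    base, minus one, mod 3.  Absent when the base is outside the CDS (UTR or
    intron) or the gene is non-coding.
    """
    index = models if isinstance(models, Mapping) else build_gene_index(models)
    p1, t1 = _phase_at(fusion.break1, _resolve(fusion.gene1_id, index))
    p2, t2 = _phase_at(fusion.break2, _resolve(fusion.gene2_id, index))
    return FrameShiftClass(p1, p2, t1, t2)


def classify_category(fusion: FusionRecord,
                      models: Iterable[GeneModel] | Mapping[str, list[GeneModel]],
                      ) -> FusionCategory:
    """Read-through vs intrachromosomal non-adjacent vs interchromosomal.

    Two same-chromosome parental genes are adjacent (read-through) when no
    third annotated gene lies entirely within the gap between their spans;
    overlapping parental spans also count as adjacent.  Strand plays no role
    in adjacency; the sense-antisense flag compares the fusion record's two
    break strands.
    """
    index = models if isinstance(models, Mapping) else build_gene_index(models)
    g1 = _resolve(fusion.gene1_id, index)
    g2 = _resolve(fusion.gene2_id, index)

    def gene_span(transcripts):
        starts, ends = zip(*(t.span for t in transcripts))
        return transcripts[0].chrom, min(starts), max(ends)

    chrom1, s1, e1 = gene_span(g1)
    chrom2, s2, e2 = gene_span(g2)
    sense_antisense = (chrom1 == chrom2
                       and fusion.break1.strand != fusion.break2.strand)
    if chrom1 != chrom2:
        return FusionCategory("interchromosomal", False)
    if e1 > s2 and e2 > s1:  # overlapping spans
        return FusionCategory("read_through", sense_antisense)
    gap_start, gap_end = (e1, s2) if e1 <= s2 else (e2, s1)
    for gid, transcripts in index.items():
        if gid in (fusion.gene1_id, fusion.gene2_id):
            continue
        c, s, e = gene_span(transcripts)
        if c == chrom1 and gap_start <= s and e <= gap_end:
            return FusionCategory("intrachromosomal_non_adjacent", sense_antisense)
    return FusionCategory("read_through", sense_antisense)


def annotate_cohort(fusions: Sequence[FusionRecord], genome: GenomeSequence,
                    models: Iterable[GeneModel]) -> list[AnnotatedFusion]:
    """Run all four classifiers over a cohort."""
    index = build_gene_index(models)
    out = []
    for f in fusions:
        out.append(AnnotatedFusion(
            record=f,
            splice=classify_splice_pattern(f, genome),
            boundary=classify_exon_boundary(f, index),
            frame=classify_frame(f, index),
            category=classify_category(f, index),
        ))
    return out


@dataclass
class CohortSummary:
    n: int
    splice_counts: dict[str, int]
    splice_mean_read_count: dict[str, float]
    boundary_counts: dict[str, int]
    frame_label_counts: dict[str, int]
    frame_status_counts: dict[str, int]
    in_frame_fraction_all: float
    """In-frame fraction over all fusions, not_applicable counted as frame-preserving."""
    in_frame_fraction_classifiable: float
    """In-frame fraction over fusions with both phases present."""
    category_counts: dict[str, int]
    sense_antisense_count: int
    splice_by_boundary: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "splice_counts": self.splice_counts,
            "splice_mean_read_count": self.splice_mean_read_count,
            "boundary_counts": self.boundary_counts,
            "frame_label_counts": self.frame_label_counts,
            "frame_status_counts": self.frame_status_counts,
            "in_frame_fraction_all": self.in_frame_fraction_all,
            "in_frame_fraction_classifiable": self.in_frame_fraction_classifiable,
            "category_counts": self.category_counts,
            "sense_antisense_count": self.sense_antisense_count,
            "splice_by_boundary": self.splice_by_boundary,
        }


def summarize_cohort(annotated: Sequence[AnnotatedFusion],
                     count_na_as_in_frame: bool = True) -> CohortSummary:
    """Cohort tallies: per-class counts, mean expression and frame fractions.

    Two in-frame fractions are reported because their denominators differ:
    one over the whole cohort (classes with an absent phase counted with the
    frame-preserving group by default, switchable via ``count_na_as_in_frame``)
    and one over fusions where both phases are present.
    """
    splice_counts: dict[str, int] = {}
    splice_read_sums: dict[str, int] = {}
    boundary_counts: dict[str, int] = {}
    frame_label_counts: dict[str, int] = {}
    frame_status_counts: dict[str, int] = {}
    category_counts: dict[str, int] = {}
    splice_by_boundary: dict[str, dict[str, int]] = {}
    sense_antisense = 0
    for a in annotated:
        sl = a.splice.label
        splice_counts[sl] = splice_counts.get(sl, 0) + 1
        splice_read_sums[sl] = splice_read_sums.get(sl, 0) + a.record.read_count
        bl = a.boundary.label
        boundary_counts[bl] = boundary_counts.get(bl, 0) + 1
        fl = a.frame.label
        frame_label_counts[fl] = frame_label_counts.get(fl, 0) + 1
        fs = a.frame.frame_status
        frame_status_counts[fs] = frame_status_counts.get(fs, 0) + 1
        cl = a.category.label
        category_counts[cl] = category_counts.get(cl, 0) + 1
        if a.category.sense_antisense:
            sense_antisense += 1
        splice_by_boundary.setdefault(sl, {})
        splice_by_boundary[sl][bl] = splice_by_boundary[sl].get(bl, 0) + 1

    n = len(annotated)
    in_frame = frame_status_counts.get("in_frame", 0)
    shift = frame_status_counts.get("frameshift", 0)
    na = frame_status_counts.get("not_applicable", 0)
    preserved = in_frame + (na if count_na_as_in_frame else 0)
    frac_all = preserved / n if n else 0.0
    classifiable = in_frame + shift
    frac_classifiable = in_frame / classifiable if classifiable else 0.0
    mean_reads = {
        k: splice_read_sums[k] / splice_counts[k] for k in splice_counts
    }
    return CohortSummary(
        n=n,
        splice_counts=splice_counts,
        splice_mean_read_count=mean_reads,
        boundary_counts=boundary_counts,
        frame_label_counts=frame_label_counts,
        frame_status_counts=frame_status_counts,
        in_frame_fraction_all=frac_all,
        in_frame_fraction_classifiable=frac_classifiable,
        category_counts=category_counts,
        sense_antisense_count=sense_antisense,
        splice_by_boundary=splice_by_boundary,
    )


def filter_same_chrom_sense(fusions: Sequence[FusionRecord]) -> list[FusionRecord]:
    """Keep fusions whose breakpoints share a chromosome and a strand.

    This is the subset used for the repeat-overlap analysis: same-chromosome
    fusions that are not sense-antisense.
    """
    return [
        f for f in fusions
        if f.break1.chrom == f.break2.chrom and f.break1.strand == f.break2.strand
    ]
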