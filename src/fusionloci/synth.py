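"""Seeded synthetic genomes, annotations, repeat tracks, fusion cohorts and
Ct tables with known planted truth.

The generator emulates the shape of a read-through-dominated fusion cohort:
multi-exon genes on both strands with valid CDS phases and configurable
intron boundary dinucleotides, planted adjacent-gene / distal / cross-
chromosome fusions with chosen splice-pattern, exon-boundary and codon-phase
labels, repeat intervals from six families, and qPCR Ct tables with known
fold changes.  Every stage is reproducible byte-for-byte from a single
integer seed, and each emitted record has a corresponding truth entry.

The defaults mirror the cohort composition the pipeline is documented
against: 185 fusions split 140 read-through / 30 same-chromosome
non-adjacent / 15 interchromosomal, 140 GT-AG junctions, a 95/66/24
both/one/neither exon-boundary split, a 140/25/20 in-frame/frameshift/
non-coding frame split, two sense-antisense fusions (leaving 168
same-chromosome same-strand fusions), and six repeat families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    Breakpoint,
    FusionRecord,
    GeneModel,
    GenomeSequence,
    RepeatFeature,
    reverse_complement,
)
from .hybridization import segment_interval

__all__ = [
    "GenomeConfig",
    "FusionPlantConfig",
    "ComplementPlantConfig",
    "CtConfig",
    "SyntheticBundle",
    "SPLICE_DINUCLEOTIDES",
    "generate_genome",
    "plant_fusions",
    "generate_ct_table",
    "generate_cohort",
]

SPLICE_DINUCLEOTIDES: dict[str, tuple[str, str]] = {
    "GT-AG": ("GT", "AG"),
    "GC-AG": ("GC", "AG"),
    "AT-AC": ("AT", "AC"),
    "CT-AC": ("CT", "AC"),
    "CT-GC": ("CT", "GC"),
    # A pairing-inert non-canonical junction; classifies as "other".
    "other": ("AA", "AA"),
}


@dataclass
class GenomeConfig:
    n_chromosomes: int = 6
    chrom_length: int = 220_000
    genes_per_chrom: int = 90
    exon_count_range: tuple[int, int] = (4, 6)
    exon_length_range: tuple[int, int] = (60, 120)
    intron_length_range: tuple[int, int] = (80, 160)
    intergenic_gap_range: tuple[int, int] = (400, 700)
    intron_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"GT-AG": 0.96, "GC-AG": 0.04}
    )
    strand_persistence: float = 0.8
    repeat_families: tuple[str, ...] = (
        "SINE/Alu", "LINE/L1", "LTR/ERV1", "DNA/TcMar-Tigger",
        "Simple_repeat", "Low_complexity",
    )
    repeats_per_family_per_chrom: int = 5
    repeat_length_range: tuple[int, int] = (150, 300)


@dataclass
class ComplementPlantConfig:
    """Plant reverse-complementary flank segments for the first n fusions.

    A run of the requested offsets in the gene-1 segment of ``combo`` is set
    to C (strand-oriented) and the matching gene-2 offsets to its reverse
    complement (G).  With ``mask_background`` the four flank windows are
    first reset to an inert A background, so the planted duplex is the
    unique maximum pairing and the positional-profile truth is unambiguous;
    affected fusions use the pairing-inert "other" splice dinucleotides.
    """

    n_fusions: int = 0
    offset_start: int = -30
    offset_end: int = -11  # inclusive
    combo: str = "up1-up2"
    mask_background: bool = True


@dataclass
class FusionPlantConfig:
    n_read_through: int = 140
    n_intrachromosomal_non_adjacent: int = 30
    n_interchromosomal: int = 15
    n_sense_antisense: int = 2  # carved out of the non-adjacent class
    splice_class_counts: Mapping[str, int] = field(default_factory=lambda: {
        "GT-AG": 140, "GC-AG": 15, "AT-AC": 7, "CT-AC": 8, "CT-GC": 6, "other": 9,
    })
    boundary_counts: Mapping[str, int] = field(default_factory=lambda: {
        "both": 95, "gene1_only": 33, "gene2_only": 33, "neither": 24,
    })
    frame_counts: Mapping[str, int] = field(default_factory=lambda: {
        "in_frame": 140, "frameshift": 25, "not_applicable": 20,
    })
    read_count_range: tuple[int, int] = (2, 60)
    datasets: tuple[str, ...] = ("cohortA", "cohortB", "LNCaP")
    flank_width: int = 100
    complement: ComplementPlantConfig | None = None

    @property
    def n_total(self) -> int:
        return (self.n_read_through + self.n_intrachromosomal_non_adjacent
                + self.n_interchromosomal)


@dataclass
class CtConfig:
    fold_changes: Mapping[str, float] = field(default_factory=lambda: {
        "FUSION_A": 2.5, "FUSION_B": 0.4, "FUSION_C": 1.0,
    })
    mock_condition: str = "mock"
    treated_condition: str = "treated"
    n_replicates: int = 3
    noise_sd: float = 0.2
    housekeeping: str = "18S"
    housekeeping_ct: float = 12.0
    base_ct: float = 24.0
    sample_id: str = "LNCaP"


@dataclass
class SyntheticBundle:
    genome: GenomeSequence
    genes: list[GeneModel]
    repeats: list[RepeatFeature]
    truth: dict


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_chrom(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def _write_oriented(ba: bytearray, start: int, end: int, letters: str, strand: str) -> None:
    if strand == "-":
        letters = reverse_complement(letters)
    ba[start:end] = letters.encode()


def _plant_intron_dinucs(ba: bytearray, exons_txn: list[tuple[int, int]],
                         strand: str, classes: Sequence[str]) -> None:
    """Write donor/acceptor dinucleotides for each intron (transcription order)."""
    for k, cls in enumerate(classes):
        donor, acceptor = SPLICE_DINUCLEOTIDES[cls]
        s1, e1 = exons_txn[k]
        s2, e2 = exons_txn[k + 1]
        if strand == "+":
            _write_oriented(ba, e1, e1 + 2, donor, "+")
            _write_oriented(ba, s2 - 2, s2, acceptor, "+")
        else:
            _write_oriented(ba, s1 - 2, s1, donor, "-")
            _write_oriented(ba, e2, e2 + 2, acceptor, "-")


def _tune_cds(model: GeneModel, c0: int, max_last: int | None = None) -> None:
    """Give the transcript a CDS starting at transcript coordinate ``c0``.

    The CDS length is the largest multiple of three that keeps the last
    coding base at or before ``max_last`` (default: four bases short of the
    transcript end).
    """
    limit = model.transcript_length - 4 if max_last is None else max_last
    n_codons = (limit - c0 + 1) // 3
    if n_codons < 2:
        raise ValueError("transcript too short for a CDS")
    c1 = c0 + 3 * n_codons - 1
    g_first = model.transcript_to_genomic(c0)
    g_last = model.transcript_to_genomic(c1)
    if model.strand == "+":
        model.cds_start, model.cds_end = g_first, g_last + 1
    else:
        model.cds_start, model.cds_end = g_last, g_first + 1


def generate_genome(config: GenomeConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate a genome with multi-exon genes, CDS phases and repeat track."""
    config = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    weights = dict(config.intron_class_weights)
    labels = list(weights)
    probs = np.array([weights[l] for l in labels], dtype=float)
    probs = probs / probs.sum()

    chrom_bytes: dict[str, bytearray] = {}
    genes: list[GeneModel] = []
    intron_truth: dict[str, list[str]] = {}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        ba = _random_chrom(rng, config.chrom_length)
        pos = 500
        strand = rng.choice(["+", "-"])
        for gi in range(config.genes_per_chrom):
            n_ex = int(rng.integers(config.exon_count_range[0],
                                    config.exon_count_range[1] + 1))
            ex_lens = rng.integers(config.exon_length_range[0],
                                   config.exon_length_range[1] + 1, size=n_ex)
            in_lens = rng.integers(config.intron_length_range[0],
                                   config.intron_length_range[1] + 1, size=n_ex - 1)
            span = int(ex_lens.sum() + in_lens.sum())
            if pos + span + 200 > config.chrom_length:
                raise ValueError(
                    f"infeasible config: genes overflow {chrom} "
                    f"(gene {gi + 1}/{config.genes_per_chrom})"
                )
            exons_genomic = []
            p = pos
            for k in range(n_ex):
                exons_genomic.append((p, p + int(ex_lens[k])))
                p += int(ex_lens[k])
                if k < n_ex - 1:
                    p += int(in_lens[k])
            if rng.random() >= config.strand_persistence:
                strand = "-" if strand == "+" else "+"
            exons_txn = exons_genomic if strand == "+" else exons_genomic[::-1]
            classes = [labels[i] for i in rng.choice(len(labels), size=n_ex - 1, p=probs)]
            _plant_intron_dinucs(ba, exons_txn, strand, classes)
            gene_id = f"{chrom}_g{gi + 1}"
            model = GeneModel(gene_id, f"{gene_id}_t1", chrom, strand, exons_txn)
            _tune_cds(model, 6)
            genes.append(model)
            intron_truth[model.transcript_id] = classes
            pos += span + int(rng.integers(config.intergenic_gap_range[0],
                                           config.intergenic_gap_range[1] + 1))
        chrom_bytes[chrom] = ba

    repeats: list[RepeatFeature] = []
    for chrom in chrom_bytes:
        for family in config.repeat_families:
            leaf = family.split("/")[-1]
            for ri in range(config.repeats_per_family_per_chrom):
                length = int(rng.integers(config.repeat_length_range[0],
                                          config.repeat_length_range[1] + 1))
                start = int(rng.integers(0, config.chrom_length - length))
                repeats.append(RepeatFeature(
                    chrom, start, start + length, f"{leaf}-{ri + 1}", family,
                    str(rng.choice(["+", "-"])),
                ))

    genome = GenomeSequence({c: ba.decode() for c, ba in chrom_bytes.items()})
    truth = {
        "seed": int(seed),
        "genome_config": asdict(config),
        "intron_classes": intron_truth,
        "repeats": [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "family": r.family, "class_family": r.repeat_class_family}
            for r in repeats
        ],
    }
    return SyntheticBundle(genome, genes, repeats, truth)


# ---------------------------------------------------------------------------
# Fusion planting


def _cumlens(model: GeneModel) -> list[int]:
    cum = [0]
    for s, e in model.exons:
        cum.append(cum[-1] + (e - s))
    return cum


def _intron_pos_after_exon(model: GeneModel, exon_idx: int, offset: int) -> int:
    """Genomic position ``offset`` bases into the intron after a txn exon."""
    s, e = model.exons[exon_idx]
    return e + offset if model.strand == "+" else s - 1 - offset


def _intron_pos_before_exon(model: GeneModel, exon_idx: int, offset: int) -> int:
    """Genomic position ``offset`` bases upstream (txn) of an exon start."""
    s, e = model.exons[exon_idx]
    return s - offset if model.strand == "+" else e - 1 + offset


def _place_break1(model: GeneModel, on_boundary: bool, phase: int | None) -> int:
    """Choose gene-1's break base and retune the CDS; returns genomic pos."""
    cum = _cumlens(model)
    if on_boundary and phase is not None:
        t1 = cum[2] - 1  # 3' end of the second exon
        _tune_cds(model, 6 + ((t1 - phase - 6) % 3))
        return model.transcript_to_genomic(t1)
    if on_boundary and phase is None:
        _tune_cds(model, cum[1] + 6)  # CDS starts in exon 2; break in 5' UTR
        return model.transcript_to_genomic(cum[1] - 1)
    if phase is not None:
        t1 = cum[2] - 6  # interior of exon 2
        _tune_cds(model, 6 + ((t1 - phase - 6) % 3))
        return model.transcript_to_genomic(t1)
    _tune_cds(model, 6)
    return _intron_pos_after_exon(model, 1, 9)  # 10 bases into intron 2


def _place_break2(model: GeneModel, on_boundary: bool, phase: int | None) -> int:
    """Choose gene-2's break base and retune the CDS; returns genomic pos."""
    cum = _cumlens(model)
    if on_boundary and phase is not None:
        t2 = cum[1]  # 5' start of the second exon
        _tune_cds(model, 6 + ((t2 - phase - 6) % 3))
        return model.transcript_to_genomic(t2)
    if on_boundary and phase is None:
        # CDS confined to the earlier exons; break at the last exon's start (3' UTR)
        t2 = cum[len(model.exons) - 1]
        _tune_cds(model, 6, max_last=t2 - 3)
        return model.transcript_to_genomic(t2)
    if phase is not None:
        t2 = cum[1] + 5  # interior of exon 2
        _tune_cds(model, 6 + ((t2 - phase - 6) % 3))
        return model.transcript_to_genomic(t2)
    _tune_cds(model, 6)
    return _intron_pos_before_exon(model, 1, 10)  # 10 bases into intron 1


def _plant_donor(genome: GenomeSequence, bp: Breakpoint, letters: str) -> None:
    if bp.strand == "+":
        genome.set_slice(bp.chrom, bp.pos + 1, bp.pos + 3, letters)
    else:
        genome.set_slice(bp.chrom, bp.pos - 2, bp.pos, letters, strand="-")


def _plant_acceptor(genome: GenomeSequence, bp: Breakpoint, letters: str) -> None:
    if bp.strand == "+":
        genome.set_slice(bp.chrom, bp.pos - 2, bp.pos, letters)
    else:
        genome.set_slice(bp.chrom, bp.pos + 1, bp.pos + 3, letters, strand="-")


def _offsets_to_genomic(bp: Breakpoint, slot: str, side: str, width: int,
                        d0: int, d1: int) -> tuple[int, int, str]:
    """Genomic interval of a contiguous signed-offset range within a flank."""
    start, end, orient = segment_interval(bp.pos, bp.strand, slot, side, width)
    if side == "up":
        i0, i1 = width + d0, width + d1
    else:
        i0, i1 = d0 - 1, d1 - 1
    if orient == "+":
        return start + i0, start + i1 + 1, orient
    return end - 1 - i1, end - i0, orient


class _PairPicker:
    """Allocate parental gene pairs from the sequential per-chromosome layout."""

    def __init__(self, genes: Sequence[GeneModel]):
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in genes:
            by_chrom.setdefault(m.chrom, []).append(m)
        for lst in by_chrom.values():
            lst.sort(key=lambda m: m.span[0])
        self.by_chrom = by_chrom
        self.chroms = sorted(by_chrom)
        self.ptr = {c: 0 for c in self.chroms}
        self.rot = 0

    def _chrom_sequence(self):
        n = len(self.chroms)
        for k in range(n):
            yield self.chroms[(self.rot + k) % n]

    def take_adjacent(self, equal_strand: bool = True) -> tuple[GeneModel, GeneModel]:
        for c in self._chrom_sequence():
            genes = self.by_chrom[c]
            i = self.ptr[c]
            while i + 1 < len(genes):
                if (genes[i].strand == genes[i + 1].strand) == equal_strand:
                    self.ptr[c] = i + 2
                    self.rot += 1
                    return genes[i], genes[i + 1]
                i += 1
        raise ValueError("infeasible config: ran out of adjacent gene pairs")

    def take_non_adjacent(self, equal_strand: bool = True) -> tuple[GeneModel, GeneModel]:
        for c in self._chrom_sequence():
            genes = self.by_chrom[c]
            i = self.ptr[c]
            while i + 2 < len(genes):
                if (genes[i].strand == genes[i + 2].strand) == equal_strand:
                    self.ptr[c] = i + 3
                    self.rot += 1
                    return genes[i], genes[i + 2]
                i += 1
        raise ValueError("infeasible config: ran out of non-adjacent gene pairs")

    def take_interchromosomal(self) -> tuple[GeneModel, GeneModel]:
        avail = [c for c in self.chroms if self.ptr[c] < len(self.by_chrom[c])]
        if len(avail) < 2:
            raise ValueError("infeasible config: ran out of cross-chromosome genes")
        c1 = avail[self.rot % len(avail)]
        c2 = next(c for c in avail if c != c1)
        self.rot += 1
        g1 = self.by_chrom[c1][self.ptr[c1]]
        g2 = self.by_chrom[c2][self.ptr[c2]]
        self.ptr[c1] += 1
        self.ptr[c2] += 1
        return g1, g2


def _expand_counts(counts: Mapping[str, int], expected_total: int, what: str) -> list[str]:
    out = []
    for label, n in counts.items():
        out.extend([label] * int(n))
    if len(out) != expected_total:
        raise ValueError(
            f"{what} counts sum to {len(out)}, expected {expected_total}"
        )
    return out


def plant_fusions(bundle: SyntheticBundle, config: FusionPlantConfig | None = None,
                  seed: int = 0) -> tuple[list[FusionRecord], dict]:
    """Plant a fusion cohort with known labels into a generated genome.

    Mutates the bundle in place: splice dinucleotides are written around the
    chosen breakpoints, parental CDS spans are retuned to realise the
    requested codon phases, and (optionally) reverse-complementary flank
    runs are planted.  Returns the fusion records (read-compatible with the
    FusionMap-style table reader/writer) and a truth dict keyed by fusion id.
    """
    config = config or FusionPlantConfig()
    rng = np.random.default_rng(seed)
    n = config.n_total
    if config.n_sense_antisense > config.n_intrachromosomal_non_adjacent:
        raise ValueError("sense-antisense fusions are carved from the non-adjacent class")

    categories = (
        ["read_through"] * config.n_read_through
        + ["intrachromosomal_non_adjacent"] * config.n_intrachromosomal_non_adjacent
        + ["interchromosomal"] * config.n_interchromosomal
    )
    antisense = (
        [False] * config.n_read_through
        + [True] * config.n_sense_antisense
        + [False] * (config.n_intrachromosomal_non_adjacent - config.n_sense_antisense)
        + [False] * config.n_interchromosomal
    )
    order = rng.permutation(n)
    categories = [categories[i] for i in order]
    antisense = [antisense[i] for i in order]
    base = _expand_counts(config.splice_class_counts, n, "splice class")
    splice_labels = [base[i] for i in rng.permutation(n)]
    base = _expand_counts(config.boundary_counts, n, "boundary")
    boundary_labels = [base[i] for i in rng.permutation(n)]
    base = _expand_counts(config.frame_counts, n, "frame")
    frame_kinds = [base[i] for i in rng.permutation(n)]

    picker = _PairPicker(bundle.genes)
    genome = bundle.genome
    comp = config.complement
    fusions: list[FusionRecord] = []
    truth: dict[str, dict] = {}
    for i in range(n):
        cat = categories[i]
        if cat == "read_through":
            g1, g2 = picker.take_adjacent(equal_strand=True)
        elif cat == "intrachromosomal_non_adjacent":
            g1, g2 = picker.take_non_adjacent(equal_strand=not antisense[i])
        else:
            g1, g2 = picker.take_interchromosomal()

        b_label = boundary_labels[i]
        on1 = b_label in ("both", "gene1_only")
        on2 = b_label in ("both", "gene2_only")
        kind = frame_kinds[i]
        if kind == "in_frame":
            p1 = int(rng.integers(0, 3))
            p2 = (p1 + 1) % 3
        elif kind == "frameshift":
            p1 = int(rng.integers(0, 3))
            p2 = int(rng.choice([p for p in range(3) if p != (p1 + 1) % 3]))
        elif kind == "not_applicable":
            which = int(rng.integers(0, 3))
            p1 = None if which in (0, 2) else int(rng.integers(0, 3))
            p2 = None if which in (1, 2) else int(rng.integers(0, 3))
        else:
            raise ValueError(f"unknown frame kind {kind!r}")

        pos1 = _place_break1(g1, on1, p1)
        pos2 = _place_break2(g2, on2, p2)
        bp1 = Breakpoint(g1.chrom, pos1, g1.strand)
        bp2 = Breakpoint(g2.chrom, pos2, g2.strand)

        planted_comp = comp is not None and i < comp.n_fusions
        s_label = "other" if planted_comp else splice_labels[i]
        donor, acceptor = SPLICE_DINUCLEOTIDES[s_label]

        comp_truth = None
        if planted_comp:
            a_name, b_name = comp.combo.split("-")
            width = config.flank_width
            if comp.mask_background:
                for bp, slot in ((bp1, "gene1"), (bp2, "gene2")):
                    for side in ("up", "down"):
                        s, e, orient = segment_interval(bp.pos, bp.strand, slot, side, width)
                        s, e = max(0, s), min(genome.length(bp.chrom), e)
                        genome.set_slice(bp.chrom, s, e, "A" * (e - s), strand=orient)
            run_len = comp.offset_end - comp.offset_start + 1
            for letters, bp, slot, side in (
                ("C" * run_len, bp1, "gene1", a_name.rstrip("12")),
                ("G" * run_len, bp2, "gene2", b_name.rstrip("12")),
            ):
                s, e, orient = _offsets_to_genomic(
                    bp, slot, side, width, comp.offset_start, comp.offset_end)
                genome.set_slice(bp.chrom, s, e, letters, strand=orient)
            comp_truth = {
                "combo": comp.combo,
                "offsets": list(range(comp.offset_start, comp.offset_end + 1)),
            }

        _plant_donor(genome, bp1, donor)
        _plant_acceptor(genome, bp2, acceptor)

        if p1 is None or p2 is None:
            frame_status = "not_applicable"
        elif p2 == (p1 + 1) % 3:
            frame_status = "in_frame"
        else:
            frame_status = "frameshift"

        fid = f"fus{i + 1}"
        fusions.append(FusionRecord(
            fusion_id=fid,
            gene1_id=g1.gene_id,
            gene2_id=g2.gene_id,
            break1=bp1,
            break2=bp2,
            read_count=int(rng.integers(config.read_count_range[0],
                                        config.read_count_range[1] + 1)),
            dataset=str(rng.choice(config.datasets)),
        ))
        truth[fid] = {
            "category": cat,
            "sense_antisense": bool(antisense[i]),
            "splice_label": s_label,
            "donor": donor,
            "acceptor": acceptor,
            "boundary_label": b_label,
            "phase1": p1,
            "phase2": p2,
            "frame_status": frame_status,
            "gene1": g1.gene_id,
            "gene2": g2.gene_id,
            "complement": comp_truth,
        }

    bundle.truth["fusions"] = truth
    bundle.truth["fusion_seed"] = int(seed)
    return fusions, truth


def generate_cohort(genome_config: GenomeConfig | None = None,
                    fusion_config: FusionPlantConfig | None = None,
                    seed: int = 0) -> tuple[SyntheticBundle, list[FusionRecord], dict]:
    """Genome + planted fusion cohort from one seed."""
    bundle = generate_genome(genome_config, seed)
    fusions, truth = plant_fusions(bundle, fusion_config, seed + 1)
    return bundle, fusions, truth


# ---------------------------------------------------------------------------
# Ct tables


def generate_ct_table(config: CtConfig | None = None,
                      seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Synthetic qPCR Ct table with known fold changes.

    Treated-condition target Cts are shifted by -log2(fold) relative to
    mock; Gaussian noise of ``noise_sd`` cycles is added to every
    measurement.  With zero noise the delta-delta-Ct recovery is exact.
    """
    config = config or CtConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for condition in (config.mock_condition, config.treated_condition):
        for rep in range(1, config.n_replicates + 1):
            rows.append({
                "sample_id": config.sample_id, "condition": condition,
                "target": config.housekeeping, "replicate": rep,
                "ct": config.housekeeping_ct + config.noise_sd * rng.standard_normal(),
            })
            for target, fold in config.fold_changes.items():
                shift = -np.log2(fold) if condition == config.treated_condition else 0.0
                rows.append({
                    "sample_id": config.sample_id, "condition": condition,
                    "target": target, "replicate": rep,
                    "ct": config.base_ct + shift + config.noise_sd * rng.standard_normal(),
                })
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "target",
                                     "replicate", "ct"])
    truth = {"seed": int(seed), "fold_changes": dict(config.fold_changes),
             "noise_sd": config.noise_sd}
    return df, truth
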