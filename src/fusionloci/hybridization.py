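"""Flanking-sequence co-hybridization analysis.

The workflow: take the four 100-nt strand-oriented genomic segments around a
fusion's two breakpoints (gene 1 up/downstream, gene 2 up/downstream), build
the four two-segment combinations joined by a 20-N spacer, predict a nested
base-pair structure over each combination, keep the pairs that join the two
segments (inter-molecular), profile them by signed distance from the fusion
point, and export hybridized stretches of at least eight nucleotides for
external motif discovery.

The built-in pairing engine is a maximum-base-pair Nussinov dynamic program
over a DNA Watson-Crick alphabet (A:T, G:C; G:T wobble optional) with a
deterministic traceback, so results are reproducible and checkable against
exhaustive enumeration.  Structures computed by an external folding tool can
be substituted through the dot-bracket adapter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .genomic_io import Breakpoint, FusionRecord, GenomeSequence

__all__ = [
    "FlankSet",
    "CombinationSequence",
    "DuplexPrediction",
    "PositionalProfile",
    "COMBO_IDS",
    "segment_interval",
    "extract_flanks",
    "build_combinations",
    "nussinov_pairs",
    "parse_dotbracket",
    "fold_pairs",
    "filter_intermolecular",
    "positional_profile",
    "extract_stretches",
    "write_stretches_fasta",
]

COMBO_IDS = ("up1-up2", "up1-down2", "down1-up2", "down1-down2")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class FlankSet:
    """The four strand-oriented flank segments of one fusion.

    Offsets are signed distances from the fusion point: upstream segments
    cover offsets -W..-1 (the -1 base abuts the junction), downstream
    segments +1..+W.  Segments shorter than ``width`` only occur at contig
    ends and are flagged.
    """

    fusion_id: str
    width: int
    up1: str
    down1: str
    up2: str
    down2: str
    intervals: dict[str, tuple[str, int, int]]
    truncated: dict[str, bool]

    def segment(self, name: str) -> str:
        return getattr(self, name)

    def offsets(self, name: str) -> tuple[int, ...]:
        length = len(self.segment(name))
        if name.startswith("up"):
            return tuple(range(-length, 0))
        return tuple(range(1, length + 1))


@dataclass
class CombinationSequence:
    """segA + 20 N + segB, with index spans and per-index junction offsets."""

    combo_id: str
    sequence: str
    segA_span: tuple[int, int]
    segB_span: tuple[int, int]
    segA_offsets: tuple[int, ...]
    segB_offsets: tuple[int, ...]
    width: int
    spacer: int = 20
    fusion_id: str = ""


@dataclass
class DuplexPrediction:
    """A nested base-pair set; after filtering, split into inter/intra pairs."""

    pairs: frozenset
    score: float
    inter_pairs: frozenset | None = None
    intra_pairs: frozenset | None = None


def segment_interval(pos: int, strand: str, slot: str, side: str,
                     width: int) -> tuple[int, int, str]:
    """Genomic half-open interval of one flank segment, plus read orientation.

    ``pos`` is the breakpoint base: the last transcribed base of the gene-1
    portion (slot ``gene1``) or the first transcribed base of the gene-2
    portion (slot ``gene2``).  The gene-1 upstream segment includes the break
    base; the gene-2 downstream segment includes it.  The returned strand is
    the orientation in which the interval is read to give the strand-oriented
    segment (far-upstream first for 'up', junction-proximal first for 'down').
    """
    if slot == "gene1":
        if side == "up":
            return (pos + 1 - width, pos + 1, "+") if strand == "+" else (pos, pos + width, "-")
        return (pos + 1, pos + 1 + width, "+") if strand == "+" else (pos - width, pos, "-")
    if slot == "gene2":
        if side == "up":
            return (pos - width, pos, "+") if strand == "+" else (pos + 1, pos + 1 + width, "-")
        return (pos, pos + width, "+") if strand == "+" else (pos + 1 - width, pos + 1, "-")
    raise ValueError(f"unknown gene slot {slot!r}")


def _read_segment(genome: GenomeSequence, bp: Breakpoint, slot: str, side: str,
                  width: int) -> tuple[str, tuple[str, int, int], bool]:
    if not (0 <= bp.pos < genome.length(bp.chrom)):
        raise ValueError(f"breakpoint {bp} is off-contig")
    start, end, orient = segment_interval(bp.pos, bp.strand, slot, side, width)
    cstart, cend = max(0, start), min(genome.length(bp.chrom), end)
    truncated = (cstart, cend) != (start, end)
    seq = genome.sequence(bp.chrom, cstart, cend, orient)
    return seq, (bp.chrom, cstart, cend), truncated


def extract_flanks(fusion, genome: GenomeSequence, width: int = 100) -> FlankSet:
    """The four width-nt flank segments, oriented along each gene's strand.

    ``fusion`` is any object with ``break1``/``break2`` breakpoints and an
    id — a fusion record or a control splice site.
    """
    owner = getattr(fusion, "fusion_id", None) or getattr(fusion, "site_id")
    segs, intervals, trunc = {}, {}, {}
    for name, (bp, slot, side) in {
        "up1": (fusion.break1, "gene1", "up"),
        "down1": (fusion.break1, "gene1", "down"),
        "up2": (fusion.break2, "gene2", "up"),
        "down2": (fusion.break2, "gene2", "down"),
    }.items():
        seq, interval, t = _read_segment(genome, bp, slot, side, width)
        segs[name], intervals[name], trunc[name] = seq, interval, t
    return FlankSet(owner, width, segs["up1"], segs["down1"],
                    segs["up2"], segs["down2"], intervals, trunc)


def build_combinations(flanks: FlankSet, spacer: int = 20) -> dict[str, CombinationSequence]:
    """The four two-segment concatenations, joined by ``spacer`` N bases."""
    combos = {}
    for combo_id in COMBO_IDS:
        a_name, b_name = combo_id.split("-")
        seg_a, seg_b = flanks.segment(a_name), flanks.segment(b_name)
        seq = seg_a + "N" * spacer + seg_b
        combos[combo_id] = CombinationSequence(
            combo_id=combo_id,
            sequence=seq,
            segA_span=(0, len(seg_a)),
            segB_span=(len(seg_a) + spacer, len(seq)),
            segA_offsets=flanks.offsets(a_name),
            segB_offsets=flanks.offsets(b_name),
            width=flanks.width,
            spacer=spacer,
            fusion_id=flanks.fusion_id,
        )
    return combos


# ---------------------------------------------------------------------------
# Built-in maximum-pairing engine


def _pair_matrix(wobble: bool) -> np.ndarray:
    pm = np.zeros((5, 5), dtype=np.bool_)
    for a, b in (("A", "T"), ("G", "C")):
        pm[_BASE_CODE[a], _BASE_CODE[b]] = pm[_BASE_CODE[b], _BASE_CODE[a]] = True
    if wobble:
        pm[_BASE_CODE["G"], _BASE_CODE["T"]] = pm[_BASE_CODE["T"], _BASE_CODE["G"]] = True
    return pm


@njit(cache=True)
def _nussinov_fill(codes, pair, min_loop):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pair[codes[i], codes[k]]:
                    cand = 1 + (m[i + 1, k - 1] if k - 1 > i else 0)
                    if k + 1 <= j:
                        cand += m[k + 1, j]
                    if cand > best:
                        best = cand
            m[i, j] = best
    return m


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def nussinov_pairs(seq: str, wobble: bool = False, min_loop: int = 3) -> frozenset:
    """Maximum-cardinality nested base-pair set via dynamic programming.

    The traceback is deterministic: at each interval, prefer leaving the
    left base unpaired, then pairing it with the interval's right end, then
    bifurcating at the smallest split point.  N never pairs.
    """
    n = len(seq)
    if n == 0:
        return frozenset()
    codes = _encode(seq)
    pm = _pair_matrix(wobble)
    m = _nussinov_fill(codes.astype(np.int64), pm, min_loop)
    pairs = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if m[i, j] == m[i + 1, j]:
            stack.append((i + 1, j))
            continue
        # Prefer pairing (i, j) itself, then the smallest split point k.
        found = False
        if pm[codes[i], codes[j]]:
            inner = m[i + 1, j - 1] if j - 1 > i else 0
            if m[i, j] == 1 + inner:
                pairs.add((i, j))
                stack.append((i + 1, j - 1))
                found = True
        if not found:
            for k in range(i + min_loop + 1, j):
                if not pm[codes[i], codes[k]]:
                    continue
                inner = m[i + 1, k - 1] if k - 1 > i else 0
                rest = m[k + 1, j]
                if m[i, j] == 1 + inner + rest:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    found = True
                    break
        assert found, "traceback failed to reproduce the DP optimum"
    return frozenset(pairs)


def parse_dotbracket(structure: str) -> frozenset:
    """Pairs encoded by a nested dot-bracket string (``(``, ``)``, ``.``)."""
    stack, pairs = [], set()
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)


def fold_pairs(seq: CombinationSequence | str, engine: str = "builtin",
               dotbracket: str | None = None, wobble: bool = False,
               min_loop: int = 3, energy: float | None = None) -> DuplexPrediction:
    """Predict a nested pair set over a combination sequence.

    ``engine='builtin'`` runs the maximum-pairing DP; ``engine='dotbracket'``
    ingests an externally produced structure string of the same length (the
    pass-through ``energy`` becomes the score).  Either way no spacer (N)
    base may appear in a pair.
    """
    sequence = seq.sequence if isinstance(seq, CombinationSequence) else seq
    if engine == "builtin":
        pairs = nussinov_pairs(sequence, wobble=wobble, min_loop=min_loop)
        return DuplexPrediction(pairs, float(len(pairs)))
    if engine == "dotbracket":
        if dotbracket is None:
            raise ValueError("dotbracket engine requires a structure string")
        if len(dotbracket) != len(sequence):
            raise ValueError(
                f"dot-bracket length {len(dotbracket)} != sequence length {len(sequence)}"
            )
        pairs = parse_dotbracket(dotbracket)
        for i, j in pairs:
            if sequence[i] == "N" or sequence[j] == "N":
                raise ValueError(f"pair ({i}, {j}) involves an N (spacer) base")
        score = float(len(pairs)) if energy is None else energy
        return DuplexPrediction(pairs, score)
    raise ValueError(f"unknown engine {engine!r}")


def filter_intermolecular(pred: DuplexPrediction,
                          seq: CombinationSequence) -> DuplexPrediction:
    """Split predicted pairs into inter-molecular (segA-segB) and intra pairs."""
    a0, a1 = seq.segA_span
    b0, b1 = seq.segB_span
    inter, intra = set(), set()
    for i, j in pred.pairs:
        if a0 <= i < a1 and b0 <= j < b1:
            inter.add((i, j))
        else:
            intra.add((i, j))
    return DuplexPrediction(pred.pairs, pred.score, frozenset(inter), frozenset(intra))


@dataclass
class PositionalProfile:
    """Per-combination positional counts of inter-molecular pairing.

    ``gene1_counts[combo][offset]`` is the number of fusions whose gene-1
    segment base at that signed offset from the fusion point participates in
    an inter-molecular pair (likewise ``gene2_counts`` for the partner
    segment).  ``mean_inter_pairs`` is the average number of inter-paired
    nucleotides (two per pair) per fusion.
    """

    width: int
    n_fusions: int
    gene1_counts: dict[str, dict[int, int]]
    gene2_counts: dict[str, dict[int, int]]
    mean_inter_pairs: dict[str, float]

    def to_frame(self):
        import pandas as pd

        rows = []
        for combo in COMBO_IDS:
            for track, counts in (("gene1", self.gene1_counts[combo]),
                                  ("gene2", self.gene2_counts[combo])):
                for off in sorted(counts):
                    rows.append({"combo": combo, "track": track,
                                 "offset": off, "count": counts[off]})
        return pd.DataFrame(rows, columns=["combo", "track", "offset", "count"])


def positional_profile(
    cohort: Sequence[Mapping[str, tuple[CombinationSequence, DuplexPrediction]]],
) -> PositionalProfile:
    """Aggregate inter-molecular pairing positions over a cohort.

    ``cohort`` holds, per fusion, a mapping from combo id to the combination
    sequence and its inter-filtered prediction.  All fusions must have been
    processed with one flank width.
    """
    widths = {combo.width for per_fusion in cohort for combo, _ in per_fusion.values()}
    if len(widths) > 1:
        raise ValueError(f"mixed flank widths in cohort: {sorted(widths)}")
    width = widths.pop() if widths else 0
    g1: dict[str, dict[int, int]] = {c: {} for c in COMBO_IDS}
    g2: dict[str, dict[int, int]] = {c: {} for c in COMBO_IDS}
    inter_nt_sums: dict[str, int] = {c: 0 for c in COMBO_IDS}
    for per_fusion in cohort:
        for combo_id, (combo, pred) in per_fusion.items():
            if pred.inter_pairs is None:
                raise ValueError("predictions must be inter-filtered first")
            a_hit, b_hit = set(), set()
            for i, j in pred.inter_pairs:
                a_hit.add(combo.segA_offsets[i - combo.segA_span[0]])
                b_hit.add(combo.segB_offsets[j - combo.segB_span[0]])
            for off in a_hit:
                g1[combo_id][off] = g1[combo_id].get(off, 0) + 1
            for off in b_hit:
                g2[combo_id][off] = g2[combo_id].get(off, 0) + 1
            inter_nt_sums[combo_id] += 2 * len(pred.inter_pairs)
    n = len(cohort)
    means = {c: (inter_nt_sums[c] / n if n else 0.0) for c in COMBO_IDS}
    return PositionalProfile(width, n, g1, g2, means)


def extract_stretches(pred: DuplexPrediction, seq: CombinationSequence,
                      min_len: int = 8) -> list[tuple[str, str]]:
    """Hybridized-stretch candidates for external motif discovery.

    Within each segment, maximal runs of consecutive inter-paired positions
    are concatenated into one candidate sequence per segment; candidates of
    at least ``min_len`` nt are returned as (segment label, sequence).
    """
    if pred.inter_pairs is None:
        raise ValueError("predictions must be inter-filtered first")
    out = []
    for label, span in (("gene1", seq.segA_span), ("gene2", seq.segB_span)):
        positions = sorted(
            p for pair in pred.inter_pairs for p in pair if span[0] <= p < span[1]
        )
        runs, current = [], []
        for p in positions:
            if current and p == current[-1] + 1:
                current.append(p)
            else:
                if current:
                    runs.append(current)
                current = [p]
        if current:
            runs.append(current)
        candidate = "".join(seq.sequence[r[0]:r[-1] + 1] for r in runs)
        if len(candidate) >= min_len:
            out.append((label, candidate))
    return out


def write_stretches_fasta(stretches: Iterable[tuple[str, str, str, str]],
                          path) -> None:
    """Write (fusion_id, combo_id, segment, sequence) records to FASTA."""
    with open(path, "w") as fh:
        for fusion_id, combo_id, segment, sequence in stretches:
            fh.write(f">{fusion_id}|{combo_id}|{segment}\n{sequence}\n")
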