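"""Repeat-family overlap with fusion-flanking windows versus random controls.

Each fusion (or control splice site) contributes four 100-nt genomic windows
(up/down x gene1/gene2).  A window counts as overlapped by a repeat family
when any feature of that family shares at least one base with it; counts are
reported both per window and de-duplicated per fusion, for the fusion and
control sources side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import FusionRecord, GenomeSequence, RepeatFeature
from .hybridization import segment_interval

__all__ = ["FlankWindow", "OverlapTally", "make_windows", "tally_overlaps",
           "compare_sources"]

SIDES = ("up", "down")
SLOTS = ("gene1", "gene2")


@dataclass(frozen=True)
class FlankWindow:
    chrom: str
    start: int
    end: int
    side: str
    gene_slot: str
    source: str
    owner_id: str
    truncated: bool = False


def make_windows(sites: Sequence, genome: GenomeSequence, width: int = 100,
                 source: str = "fusion") -> list[FlankWindow]:
    """Four genomic windows per fusion/control site.

    ``sites`` are objects exposing ``break1``/``break2`` breakpoints and an
    id (``fusion_id`` or ``site_id``).  Windows are plain genomic intervals;
    strand only determines which side is up- vs downstream, overlap itself is
    strand-agnostic.  Off-contig windows are truncated and flagged.
    """
    windows = []
    for site in sites:
        owner = getattr(site, "fusion_id", None) or getattr(site, "site_id")
        for slot, bp in (("gene1", site.break1), ("gene2", site.break2)):
            n = genome.length(bp.chrom)
            if not (0 <= bp.pos < n):
                raise ValueError(f"breakpoint {bp} is off-contig")
            for side in SIDES:
                start, end, _ = segment_interval(bp.pos, bp.strand, slot, side, width)
                cstart, cend = max(0, start), min(n, end)
                windows.append(FlankWindow(
                    bp.chrom, cstart, cend, side, slot, source, owner,
                    truncated=(cstart, cend) != (start, end),
                ))
    return windows


@dataclass
class OverlapTally:
    """Per-family overlap counts, stratified by source, gene slot and side."""

    families: tuple[str, ...]
    window_counts: dict[tuple[str, str, str, str], int]
    """(family, source, gene_slot, side) -> number of windows overlapped."""
    owner_counts: dict[tuple[str, str], int]
    """(family, source) -> number of distinct fusions/sites with any window hit."""
    n_windows: dict[tuple[str, str, str], int]
    """(source, gene_slot, side) -> windows in that stratum."""
    n_owners: dict[str, int]
    """source -> distinct fusions/sites."""

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(sorted(self.n_owners))


def tally_overlaps(windows: Sequence[FlankWindow],
                   repeats: Iterable[RepeatFeature],
                   min_overlap: int = 1) -> OverlapTally:
    """Count windows (and distinct fusions) overlapped per repeat family.

    Overlap means an intersection of at least ``min_overlap`` bases in the
    half-open internal convention.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[tuple[str, str], IntervalTree] = {}
    families = set()
    for r in repeats:
        families.add(r.family)
        if r.end > r.start:
            trees.setdefault((r.chrom, r.family), IntervalTree()).addi(r.start, r.end)

    window_counts: dict[tuple[str, str, str, str], int] = {}
    owner_hits: dict[tuple[str, str], set] = {}
    n_windows: dict[tuple[str, str, str], int] = {}
    owners: dict[str, set] = {}
    for w in windows:
        n_windows[(w.source, w.gene_slot, w.side)] = (
            n_windows.get((w.source, w.gene_slot, w.side), 0) + 1
        )
        owners.setdefault(w.source, set()).add(w.owner_id)
        for fam in families:
            tree = trees.get((w.chrom, fam))
            if tree is None:
                continue
            hit = any(
                min(iv.end, w.end) - max(iv.begin, w.start) >= min_overlap
                for iv in tree.overlap(w.start, w.end)
            )
            if hit:
                key = (fam, w.source, w.gene_slot, w.side)
                window_counts[key] = window_counts.get(key, 0) + 1
                owner_hits.setdefault((fam, w.source), set()).add(w.owner_id)

    return OverlapTally(
        families=tuple(sorted(families)),
        window_counts=window_counts,
        owner_counts={k: len(v) for k, v in owner_hits.items()},
        n_windows=n_windows,
        n_owners={src: len(ids) for src, ids in owners.items()},
    )


def compare_sources(tally: OverlapTally, level: str = "window") -> pd.DataFrame:
    """Side-by-side fusion vs control overlap table.

    ``level='window'`` reports per-(family, gene slot, side) window counts
    and fractions; ``level='fusion'`` reports per-family distinct-fusion
    counts.  Fractions against an empty stratum are reported as 0.
    """
    sources = tally.sources
    if not {"fusion", "control"} <= set(sources):
        raise ValueError(f"both sources required, found {sources}")

    def frac(num, den):
        return num / den if den else 0.0

    rows = []
    if level == "window":
        for fam in tally.families:
            for slot in SLOTS:
                for side in SIDES:
                    row = {"family": fam, "gene_slot": slot, "side": side}
                    for src in ("fusion", "control"):
                        n = tally.window_counts.get((fam, src, slot, side), 0)
                        total = tally.n_windows.get((src, slot, side), 0)
                        row[f"{src}_windows"] = n
                        row[f"{src}_fraction"] = frac(n, total)
                    rows.append(row)
        return pd.DataFrame(rows, columns=[
            "family", "gene_slot", "side",
            "fusion_windows", "fusion_fraction",
            "control_windows", "control_fraction",
        ])
    if level == "fusion":
        for fam in tally.families:
            row = {"family": fam}
            for src in ("fusion", "control"):
                n = tally.owner_counts.get((fam, src), 0)
                row[f"{src}_count"] = n
                row[f"{src}_fraction"] = frac(n, tally.n_owners.get(src, 0))
            rows.append(row)
        return pd.DataFrame(rows, columns=[
            "family", "fusion_count", "fusion_fraction",
            "control_count", "control_fraction",
        ])
    raise ValueError(f"unknown level {level!r}")
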