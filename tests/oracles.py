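"""Independent oracles used by the tests.

These deliberately avoid the library's classification and folding code
paths: the frame oracle works at the sequence level through translation,
the folding oracle enumerates every nested structure, and the overlap
oracle is a quadratic all-pairs scan.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Seq import Seq

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def translation_frame_status(fusion, gene_index, genome) -> str:
    """Frame status by translating the fused coding sequence.

    The gene-1 coding fragment up to and including the break base is
    concatenated with the gene-2 coding fragment from the break base to the
    CDS end; the fusion maintains the frame iff the translated chimera ends
    with gene 2's own downstream peptide.
    """
    g1 = gene_index[fusion.gene1_id][0]
    g2 = gene_index[fusion.gene2_id][0]
    t1 = g1.genomic_to_transcript(fusion.break1.pos)
    t2 = g2.genomic_to_transcript(fusion.break2.pos)
    if t1 is None or t2 is None:
        return "not_applicable"
    c1 = g1.cds_transcript_interval()
    c2 = g2.cds_transcript_interval()
    if c1 is None or c2 is None:
        return "not_applicable"
    if not (c1[0] <= t1 <= c1[1]) or not (c2[0] <= t2 <= c2[1]):
        return "not_applicable"
    cds1 = g1.coding_sequence(genome)
    cds2 = g2.coding_sequence(genome)
    frag1 = cds1[: t1 - c1[0] + 1]
    i2 = t2 - c2[0]
    fused = frag1 + cds2[i2:]
    fused = fused[: len(fused) // 3 * 3]
    pep_fused = str(Seq(fused).translate())
    first_full_codon = (i2 + 2) // 3
    pep2_tail = str(Seq(cds2[: len(cds2) // 3 * 3]).translate())[first_full_codon:]
    assert pep2_tail, "degenerate oracle input: no downstream peptide"
    return "in_frame" if pep_fused.endswith(pep2_tail) else "frameshift"


def max_pairs_by_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pair count by exhaustive recursion (small inputs only)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        options = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _WC:
                inner = best(i + 1, k - 1) if k - 1 > i else 0
                rest = best(k + 1, j) if k + 1 <= j else 0
                options.append(1 + inner + rest)
        return max(options)

    return best(0, len(seq) - 1) if seq else 0


def brute_force_overlap_tally(windows, repeats, min_overlap: int = 1):
    """All-pairs window x feature intersection, keyed like OverlapTally."""
    window_counts: dict = {}
    owner_hits: dict = {}
    for w in windows:
        families_hit = set()
        for r in repeats:
            if r.chrom != w.chrom:
                continue
            if min(r.end, w.end) - max(r.start, w.start) >= min_overlap:
                families_hit.add(r.family)
        for fam in families_hit:
            key = (fam, w.source, w.gene_slot, w.side)
            window_counts[key] = window_counts.get(key, 0) + 1
            owner_hits.setdefault((fam, w.source), set()).add(w.owner_id)
    return window_counts, {k: len(v) for k, v in owner_hits.items()}
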