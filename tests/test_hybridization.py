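import numpy as np
import pytest
from hypothesis import given, strategies as st

from fusionloci.genomic_io import (
    Breakpoint,
    FusionRecord,
    GenomeSequence,
    reverse_complement,
)
from fusionloci.hybridization import (
    CombinationSequence,
    build_combinations,
    extract_flanks,
    extract_stretches,
    filter_intermolecular,
    fold_pairs,
    nussinov_pairs,
    parse_dotbracket,
    positional_profile,
)

from oracles import max_pairs_by_enumeration


def fusion(pos1, s1, pos2, s2, chrom="c", fid="f"):
    return FusionRecord(fid, "g1", "g2", Breakpoint(chrom, pos1, s1),
                        Breakpoint(chrom, pos2, s2), 1)


def make_combo(seg_a, seg_b, spacer=20):
    seq = seg_a + "N" * spacer + seg_b
    return CombinationSequence(
        "up1-up2", seq, (0, len(seg_a)), (len(seg_a) + spacer, len(seq)),
        tuple(range(-len(seg_a), 0)), tuple(range(-len(seg_b), 0)),
        width=max(len(seg_a), len(seg_b)), spacer=spacer,
    )


@pytest.fixture(scope="module")
def random_genome():
    rng = np.random.default_rng(42)
    return GenomeSequence({"c": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])})


class TestExtractFlanks:
    def test_plus_strand_arithmetic(self, random_genome):
        # break at external position 150 = internal 149
        flanks = extract_flanks(fusion(149, "+", 1000, "+"), random_genome, width=100)
        assert flanks.up1 == random_genome.sequence("c", 50, 150)
        assert flanks.down1 == random_genome.sequence("c", 150, 250)
        assert flanks.up2 == random_genome.sequence("c", 900, 1000)
        assert flanks.down2 == random_genome.sequence("c", 1000, 1100)
        assert not any(flanks.truncated.values())

    def test_minus_strand_segments_are_revcomp(self, random_genome):
        g = random_genome
        flanks = extract_flanks(fusion(500, "-", 1000, "-"), g, width=100)
        assert flanks.up1 == reverse_complement(g.sequence("c", 500, 600))
        assert flanks.down1 == reverse_complement(g.sequence("c", 400, 500))
        assert flanks.up2 == reverse_complement(g.sequence("c", 1001, 1101))
        assert flanks.down2 == reverse_complement(g.sequence("c", 901, 1001))

    def test_contig_edge_truncates_with_flag(self, random_genome):
        flanks = extract_flanks(fusion(39, "+", 1000, "+"), random_genome, width=100)
        assert len(flanks.up1) == 40
        assert flanks.truncated["up1"]
        assert flanks.offsets("up1") == tuple(range(-40, 0))

    def test_off_contig_break_is_an_error(self, random_genome):
        with pytest.raises(ValueError, match="off-contig"):
            extract_flanks(fusion(5000, "+", 100, "+"), random_genome)

    def test_strand_consistency_of_upstream_segment(self, random_genome):
        """The upstream flank read on '-' equals the revcomp of the 3'-adjacent
        plus-strand genomic bases."""
        plus = extract_flanks(fusion(700, "+", 1000, "+"), random_genome, 50)
        minus = extract_flanks(fusion(700, "-", 1000, "+"), random_genome, 50)
        assert minus.up1 == reverse_complement(
            random_genome.sequence("c", 700, 750, "+"))
        assert plus.up1[-1] == random_genome.sequence("c", 700, 701)


class TestCombinations:
    def test_four_combos_with_spacer(self, random_genome):
        flanks = extract_flanks(fusion(500, "+", 1000, "+"), random_genome, 100)
        combos = build_combinations(flanks, spacer=20)
        assert set(combos) == {"up1-up2", "up1-down2", "down1-up2", "down1-down2"}
        combo = combos["up1-up2"]
        assert len(combo.sequence) == 220
        assert combo.sequence[100:120] == "N" * 20
        assert combo.segB_span[0] == 120


class TestFolding:
    def test_hairpin_stem(self):
        assert nussinov_pairs("GGGAAAACCC") == frozenset({(0, 9), (1, 8), (2, 7)})

    def test_no_complementary_letters(self):
        assert nussinov_pairs("AAAAAAA") == frozenset()

    def test_wobble_flag(self):
        seq = "GGGGGTTTTT"  # G:T only pairs when wobble is enabled
        assert nussinov_pairs(seq) == frozenset()
        assert len(nussinov_pairs(seq, wobble=True)) == 3

    def test_min_loop_respected(self):
        for i, j in nussinov_pairs("GAAACAAAGTTTCTTT"):
            assert j - i > 3

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(30):
            n = int(rng.integers(1, 15))
            seq = "".join(bases[rng.integers(0, 4, n)])
            assert len(nussinov_pairs(seq)) == max_pairs_by_enumeration(seq)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=40))
    def test_nested_and_n_free(self, seq):
        pairs = sorted(nussinov_pairs(seq))
        seen = set()
        for i, j in pairs:
            assert seq[i] != "N" and seq[j] != "N"
            assert i < j
            assert i not in seen and j not in seen
            seen.update((i, j))
        for (i, j), (k, l) in zip(pairs, pairs[1:]):
            # sorted pairs: either disjoint or nested, never crossing
            assert k > j or l < j

    def test_dotbracket_round_trip_and_errors(self):
        pairs = parse_dotbracket("((..)).((...))")
        assert pairs == frozenset({(0, 5), (1, 4), (7, 13), (8, 12)})
        with pytest.raises(ValueError, match="unbalanced"):
            parse_dotbracket("((.)")
        with pytest.raises(ValueError, match="unbalanced"):
            parse_dotbracket(".))")
        combo = make_combo("GGGG", "CCCC", spacer=5)
        with pytest.raises(ValueError, match="length"):
            fold_pairs(combo, engine="dotbracket", dotbracket="()")
        # a structure pairing into the spacer is rejected
        with pytest.raises(ValueError, match="spacer"):
            fold_pairs(combo, engine="dotbracket", dotbracket="(....)" + "." * 7)

    def test_dotbracket_engine_accepts_external_structure(self):
        combo = make_combo("GGGG", "CCCC", spacer=5)
        struct = "((((" + "....." + "))))"
        pred = fold_pairs(combo, engine="dotbracket", dotbracket=struct, energy=-7.5)
        assert len(pred.pairs) == 4
        assert pred.score == -7.5


class TestInterFilter:
    def test_partition_conserves_pairs(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            a = "".join(bases[rng.integers(0, 4, 40)])
            b = "".join(bases[rng.integers(0, 4, 40)])
            combo = make_combo(a, b)
            pred = filter_intermolecular(fold_pairs(combo), combo)
            assert pred.inter_pairs | pred.intra_pairs == pred.pairs
            assert not (pred.inter_pairs & pred.intra_pairs)
            a0, a1 = combo.segA_span
            b0, b1 = combo.segB_span
            for i, j in pred.inter_pairs:
                assert a0 <= i < a1 and b0 <= j < b1

    def test_revcomp_duplex_pairs_fully_intermolecular(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        for _ in range(5):
            a = "".join(bases[rng.integers(0, 4, 30)])
            combo = make_combo(a, reverse_complement(a))
            pred = filter_intermolecular(fold_pairs(combo), combo)
            # the spacer removes any minimum-loop loss: every base pairs
            assert len(pred.inter_pairs) == 30

    def test_revcomp_maximizes_inter_pairs_over_shuffles(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        wins = 0
        for _ in range(20):
            a = "".join(bases[rng.integers(0, 4, 15)])
            b0 = reverse_complement(a)
            combo = make_combo(a, b0)
            ref = len(filter_intermolecular(fold_pairs(combo), combo).inter_pairs)
            for _ in range(5):
                b = "".join(rng.permutation(list(b0)))
                shuffled = make_combo(a, b)
                got = len(filter_intermolecular(fold_pairs(shuffled), shuffled).inter_pairs)
                assert got <= ref
            wins += 1
        assert wins == 20


class TestProfileAndStretches:
    def _single_pair_cohort(self):
        combo = make_combo("A" * 10, "A" * 10, spacer=5)
        # one pair joining segA index 4 (offset -6) to segB index 0 (offset -10)
        struct = "...." + "(" + "." * 10 + ")" + "." * 9
        pred = filter_intermolecular(
            fold_pairs(combo, engine="dotbracket", dotbracket=struct), combo)
        return combo, pred

    def test_single_inter_pair_offsets(self):
        combo, pred = self._single_pair_cohort()
        profile = positional_profile([{"up1-up2": (combo, pred)}])
        assert profile.gene1_counts["up1-up2"] == {-6: 1}
        assert profile.gene2_counts["up1-up2"] == {-10: 1}
        assert profile.mean_inter_pairs["up1-up2"] == 2.0

    def test_empty_cohort_profile(self):
        profile = positional_profile([])
        assert profile.n_fusions == 0
        assert all(not c for c in profile.gene1_counts.values())

    def test_mixed_widths_error(self):
        c1, p1 = self._single_pair_cohort()
        c2 = make_combo("A" * 30, "A" * 30, spacer=5)
        p2 = filter_intermolecular(fold_pairs(c2), c2)
        with pytest.raises(ValueError, match="width"):
            positional_profile([{"up1-up2": (c1, p1)}, {"up1-up2": (c2, p2)}])

    @pytest.mark.parametrize("n_paired,expected_lengths", [
        (7, []),            # below the eight-nucleotide threshold
        (10, [10, 10]),     # one 10-nt run per segment
    ])
    def test_stretch_threshold(self, n_paired, expected_lengths):
        a = "G" * n_paired + "A" * (30 - n_paired)
        b = "A" * (30 - n_paired) + "C" * n_paired
        combo = make_combo(a, b)
        pred = filter_intermolecular(fold_pairs(combo), combo)
        assert len(pred.inter_pairs) == n_paired
        got = extract_stretches(pred, combo, min_len=8)
        assert sorted(len(s) for _, s in got) == sorted(expected_lengths)

    def test_runs_concatenated_per_segment(self):
        # runs of 5 and 4 inter-paired bases on each segment concatenate to 9
        # (the TT gap letters cannot extend the maximum pairing)
        a = "G" * 5 + "TT" + "G" * 4 + "A" * 19
        b = "A" * 19 + "C" * 4 + "TT" + "C" * 5
        combo = make_combo(a, b)
        pred = filter_intermolecular(fold_pairs(combo), combo)
        assert len(pred.inter_pairs) == 9
        got = extract_stretches(pred, combo, min_len=8)
        assert [(seg, len(s)) for seg, s in got] == [("gene1", 9), ("gene2", 9)]
        assert got[0][1] == "G" * 9
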