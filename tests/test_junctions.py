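import itertools

import pytest

from fusionloci.genomic_io import (
    Breakpoint,
    FusionRecord,
    GeneModel,
    GenomeSequence,
    build_gene_index,
    reverse_complement,
)
from fusionloci.junctions import (
    FrameShiftClass,
    annotate_cohort,
    classify_category,
    classify_exon_boundary,
    classify_frame,
    classify_splice_pattern,
    filter_same_chrom_sense,
    summarize_cohort,
)

from oracles import translation_frame_status


def fusion(chrom1, pos1, s1, chrom2, pos2, s2, g1="g1", g2="g2", fid="f", reads=1):
    return FusionRecord(fid, g1, g2, Breakpoint(chrom1, pos1, s1),
                        Breakpoint(chrom2, pos2, s2), reads)


class TestSplicePattern:
    def test_planted_gt_ag_is_canonical(self):
        #          break1=pos4      break2=pos20
        seq = "AAAAA" + "GT" + "AAAAAAAAAAA" + "AG" + "AAAAA"
        g = GenomeSequence({"c": seq})
        cls = classify_splice_pattern(fusion("c", 4, "+", "c", 20, "+"), g)
        assert (cls.donor_dinucleotide, cls.acceptor_dinucleotide) == ("GT", "AG")
        assert cls.label == "GT-AG" and cls.is_canonical

    def test_minus_strand_donor_read_as_revcomp(self):
        # plus-strand letters immediately left of the break base read "AC";
        # on the minus strand the donor is their reverse complement, "GT"
        seq = "AAAA" + "AC" + "A" * 14
        g = GenomeSequence({"c": seq})
        cls = classify_splice_pattern(fusion("c", 6, "-", "c", 15, "+"), g)
        assert cls.donor_dinucleotide == "GT"

    def test_n_region_never_matches(self):
        g = GenomeSequence({"c": "AAAANNAAAAAAAAAAAAANNAAAA"})
        cls = classify_splice_pattern(fusion("c", 3, "+", "c", 21, "+"), g)
        assert cls.label == "other" and not cls.is_canonical

    def test_contig_end_is_an_error(self):
        g = GenomeSequence({"c": "ACGTACGT"})
        with pytest.raises(ValueError, match="contig end"):
            classify_splice_pattern(fusion("c", 6, "+", "c", 3, "+"), g)

    def test_label_partition_is_exhaustive(self, small_cohort):
        bundle, fusions, _ = small_cohort
        labels = [classify_splice_pattern(f, bundle.genome).label for f in fusions]
        allowed = {"GT-AG", "GC-AG", "AT-AC", "CT-AC", "CT-GC", "other"}
        assert set(labels) <= allowed
        assert len(labels) == len(fusions)


class TestExonBoundary:
    def _models(self):
        g1 = GeneModel("g1", "g1_t", "c", "+", [(10, 20), (30, 40), (50, 60)])
        g2 = GeneModel("g2", "g2_t", "c", "+", [(100, 110), (120, 130)])
        return [g1, g2]

    def test_planted_boundaries_are_both(self):
        cls = classify_exon_boundary(fusion("c", 39, "+", "c", 120, "+"), self._models())
        assert cls.label == "both"

    def test_shift_into_intron_drops_gene1(self):
        cls = classify_exon_boundary(fusion("c", 40, "+", "c", 120, "+"), self._models())
        assert cls.label == "gene2_only"

    def test_unknown_gene_errors(self):
        with pytest.raises(KeyError, match="nope"):
            classify_exon_boundary(fusion("c", 39, "+", "c", 120, "+", g1="nope"),
                                   self._models())

    def test_matches_exhaustive_scan(self, small_cohort):
        bundle, fusions, _ = small_cohort
        index = build_gene_index(bundle.genes)
        for f in fusions:
            got = classify_exon_boundary(f, index)
            # brute-force scan over every exon coordinate of every transcript
            ends = set()
            starts = set()
            for m in index[f.gene1_id]:
                for s, e in m.exons:
                    ends.add(e - 1 if m.strand == "+" else s)
            for m in index[f.gene2_id]:
                for s, e in m.exons:
                    starts.add(s if m.strand == "+" else e - 1)
            assert got.gene1_on_boundary == (f.break1.pos in ends)
            assert got.gene2_on_boundary == (f.break2.pos in starts)


class TestFrame:
    def _coding_pair(self):
        # gene1: CDS starts at transcript coord 2; break base at coord 10 -> phase 2
        g1 = GeneModel("g1", "g1_t", "c", "+", [(0, 12), (20, 32)],
                       cds_start=2, cds_end=30)
        # gene2: CDS starts at coord 3; break at coord 3 -> phase 0
        g2 = GeneModel("g2", "g2_t", "c", "+", [(100, 112), (120, 132)],
                       cds_start=103, cds_end=130)
        return [g1, g2]

    def test_in_frame_two_to_zero(self):
        cls = classify_frame(fusion("c", 10, "+", "c", 103, "+"), self._coding_pair())
        assert (cls.phase1, cls.phase2) == (2, 0)
        assert cls.label == "2→0"
        assert cls.frame_status == "in_frame"

    def test_frameshift_one_to_one(self):
        cls = classify_frame(fusion("c", 9, "+", "c", 104, "+"), self._coding_pair())
        assert (cls.phase1, cls.phase2) == (1, 1)
        assert cls.label == "1→1"
        assert cls.frame_status == "frameshift"

    def test_utr_break_has_absent_phase(self):
        cls = classify_frame(fusion("c", 1, "+", "c", 103, "+"), self._coding_pair())
        assert cls.phase1 is None and cls.phase2 == 0
        assert cls.label == "→0"
        assert cls.frame_status == "not_applicable"

    def test_frame_rule_closure(self):
        # of the nine present-phase pairs exactly three maintain the frame
        in_frame = [
            (p1, p2) for p1, p2 in itertools.product(range(3), range(3))
            if FrameShiftClass(p1, p2).frame_status == "in_frame"
        ]
        assert sorted(in_frame) == [(0, 1), (1, 2), (2, 0)]

    def test_agrees_with_translation_oracle(self, small_cohort):
        bundle, fusions, _ = small_cohort
        index = build_gene_index(bundle.genes)
        checked = 0
        for f in fusions:
            got = classify_frame(f, index).frame_status
            assert got == translation_frame_status(f, index, bundle.genome)
            checked += 1
        assert checked == len(fusions)


class TestCategory:
    def _layout(self):
        a = GeneModel("a", "a_t", "c", "+", [(0, 50), (60, 100)])
        b = GeneModel("b", "b_t", "c", "+", [(200, 250), (260, 300)])
        mid = GeneModel("mid", "mid_t", "c", "-", [(160, 190), (110, 150)])
        other = GeneModel("other", "other_t", "chr9", "+", [(0, 40), (50, 90)])
        return [a, b, mid, other]

    def test_empty_gap_is_read_through(self):
        models = [m for m in self._layout() if m.gene_id in ("a", "b")]
        cat = classify_category(fusion("c", 99, "+", "c", 200, "+", "a", "b"), models)
        assert cat.label == "read_through"

    def test_interchromosomal(self):
        cat = classify_category(
            fusion("c", 99, "+", "chr9", 50, "+", "a", "other"), self._layout())
        assert cat.label == "interchromosomal"

    def test_contained_third_gene_breaks_adjacency(self):
        cat = classify_category(fusion("c", 99, "+", "c", 200, "+", "a", "b"),
                                self._layout())
        assert cat.label == "intrachromosomal_non_adjacent"

    def test_sense_antisense_flag_from_break_strands(self):
        models = [m for m in self._layout() if m.gene_id in ("a", "mid")]
        cat = classify_category(fusion("c", 99, "+", "c", 160, "-", "a", "mid"), models)
        assert cat.sense_antisense


class TestSummaryAndFilter:
    def test_mean_read_count_per_splice_class(self):
        g = GenomeSequence({"c": "AAAAA" + "GT" + "AAAAAAAAAAA" + "AG" + "AAAAA"})
        models = [GeneModel("g1", "t1", "c", "+", [(0, 5)]),
                  GeneModel("g2", "t2", "c", "+", [(20, 26)])]
        fusions = [fusion("c", 4, "+", "c", 20, "+", fid="f1", reads=2),
                   fusion("c", 4, "+", "c", 20, "+", fid="f2", reads=4)]
        summary = summarize_cohort(annotate_cohort(fusions, g, models))
        assert summary.splice_mean_read_count == {"GT-AG": 3.0}
        assert summary.boundary_counts == {"both": 2}

    def test_empty_cohort_is_not_an_error(self):
        summary = summarize_cohort([])
        assert summary.n == 0
        assert summary.in_frame_fraction_all == 0.0

    def test_planted_mix_recovered(self, small_cohort):
        bundle, fusions, truth = small_cohort
        summary = summarize_cohort(annotate_cohort(fusions, bundle.genome, bundle.genes))
        from collections import Counter
        want = Counter(t["splice_label"] for t in truth.values())
        assert summary.splice_counts == dict(want)
        assert summary.category_counts == dict(
            Counter(t["category"] for t in truth.values()))
        assert sum(summary.splice_counts.values()) == summary.n == len(fusions)

    @pytest.mark.parametrize("s1,s2,chrom2,kept", [
        ("+", "+", "c", True),
        ("-", "-", "c", True),
        ("+", "-", "c", False),
        ("+", "+", "chr9", False),
    ])
    def test_same_chrom_sense_filter(self, s1, s2, chrom2, kept):
        f = fusion("c", 10, s1, chrom2, 20, s2)
        assert (filter_same_chrom_sense([f]) == [f]) is kept
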