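import numpy as np
import pytest

from methentropy.entropy_core import segment_stats
from methentropy.genomic_annotation import (
    assign_quintiles,
    assign_segments,
    build_features,
    classify_level,
    common_segments,
    gene_body_stats,
    is_completely_unmethylated,
    pairwise_correlation,
    summarize_classes,
    tss_profile,
)
from methentropy.methylome_io import ExpressionRecord, GeneModel, GenomicInterval
from tests.conftest import make_segment


def seg_stats_at(start, counts=None, chrom="chr1"):
    positions = (start, start + 10, start + 20, start + 30)
    return segment_stats(make_segment(counts or {0b1111: 8, 0b0000: 8}, positions, chrom))


class TestBuildFeatures:
    def test_cgi_shores_and_shelves(self):
        fs = build_features([], cgis=[GenomicInterval("chr1", 5000, 6000)])
        assert [(i.start, i.end) for i in fs.intervals["cgi_shore"]] == [
            (3000, 5000),
            (6000, 8000),
        ]
        assert [(i.start, i.end) for i in fs.intervals["cgi_shelf"]] == [
            (1000, 3000),
            (8000, 10000),
        ]

    def test_shores_and_shelves_never_overlap_cgis(self):
        # two close CGIs: flanks must be clipped against both islands and shores
        cgis = [GenomicInterval("chr1", 5000, 6000), GenomicInterval("chr1", 7000, 7500)]
        fs = build_features([], cgis=cgis)
        for a in fs.intervals["cgi_shore"] + fs.intervals["cgi_shelf"]:
            for c in fs.intervals["cgi"]:
                assert not a.overlaps(c)
        for sh in fs.intervals["cgi_shelf"]:
            for so in fs.intervals["cgi_shore"]:
                assert not sh.overlaps(so)

    def test_plus_strand_promoter_is_1kb_upstream(self):
        fs = build_features([GeneModel("G", "chr1", "+", 10000, 12000)])
        (p,) = fs.intervals["promoter_1kb"]
        assert (p.start, p.end) == (9000, 10000)

    def test_minus_strand_promoter_reflects(self):
        fs = build_features([GeneModel("G", "chr1", "-", 10000, 12000)])
        (p,) = fs.intervals["promoter_1kb"]
        assert (p.start, p.end) == (12000, 13000)

    def test_promoter_split_by_one_bp_cgi_overlap(self):
        genes = [
            GeneModel("A", "chr1", "+", 10000, 12000),
            GeneModel("B", "chr1", "+", 30000, 32000),
        ]
        # CGI ends exactly where A's promoter starts + 1 bp inside
        fs = build_features(genes, cgis=[GenomicInterval("chr1", 8000, 9001)])
        assert [p.label for p in fs.intervals["cgi_promoter"]] == ["A"]
        assert [p.label for p in fs.intervals["non_cgi_promoter"]] == ["B"]

    def test_gene_structure_classes(self):
        g = GeneModel(
            "G",
            "chr1",
            "+",
            1000,
            5000,
            cds_start=1500,
            cds_end=4500,
            exon_starts=(1000, 3000),
            exon_ends=(2000, 5000),
        )
        fs = build_features([g])
        assert [(i.start, i.end) for i in fs.intervals["utr5"]] == [(1000, 1500)]
        assert [(i.start, i.end) for i in fs.intervals["utr3"]] == [(4500, 5000)]
        assert [(i.start, i.end) for i in fs.intervals["coding_exon"]] == [
            (1500, 2000),
            (3000, 4500),
        ]
        assert [(i.start, i.end) for i in fs.intervals["intron"]] == [(2000, 3000)]


class TestAssignSegments:
    def test_segment_joins_every_overlapping_class(self):
        fs = build_features(
            [GeneModel("G", "chr1", "+", 1000, 5000, exon_starts=(1000, 3000), exon_ends=(2000, 5000))],
            repeats=[GenomicInterval("chr1", 2500, 2600, ".", "SINE")],
        )
        s = seg_stats_at(2560)  # span [2560,2592): inside the intron and the SINE
        assigned = assign_segments([s], fs)
        assert s in assigned["intron"] and s in assigned["SINE"]

    def test_unassigned_bucket(self):
        fs = build_features([GeneModel("G", "chr1", "+", 1000, 5000)])
        s = seg_stats_at(100000)
        assert assign_segments([s], fs)["unassigned"] == [s]

    def test_boundary_spanning_segment_in_both_classes(self):
        g = GeneModel(
            "G", "chr1", "+", 1000, 5000, cds_start=1000, cds_end=5000,
            exon_starts=(1000, 3000), exon_ends=(2000, 5000),
        )
        fs = build_features([g])
        s = seg_stats_at(1990)  # span [1990,2022) crosses the exon/intron boundary
        assigned = assign_segments([s], fs)
        assert s in assigned["coding_exon"] and s in assigned["intron"]

    def test_summaries_count_assigned_segments(self):
        fs = build_features([GeneModel("G", "chr1", "+", 1000, 5000)])
        stats = [seg_stats_at(500), seg_stats_at(600)]
        summaries = {s.feature: s for s in summarize_classes(assign_segments(stats, fs))}
        assert summaries["promoter_1kb"].n_segments == 2


class TestClassifyLevel:
    @pytest.mark.parametrize(
        "level,expected",
        [
            (0.85, "hypermethylated"),
            (0.80, "intermediate"),  # strict inequality at the cutoffs
            (0.20, "intermediate"),
            (0.19, "hypomethylated"),
            (0.0, "hypomethylated"),
            (1.0, "hypermethylated"),
        ],
    )
    def test_boundaries(self, level, expected):
        assert classify_level(level) == expected

    def test_completely_unmethylated_subclass(self):
        assert is_completely_unmethylated(0.0)
        assert not is_completely_unmethylated(0.01)


class TestCommonSegments:
    def test_intersection_by_key(self):
        a = [seg_stats_at(100), seg_stats_at(200), seg_stats_at(300)]
        b = [seg_stats_at(200)]
        common = common_segments([a, b])
        assert list(common) == [("chr1", (200, 210, 220, 230))]

    def test_identical_samples_share_everything(self):
        a = [seg_stats_at(100), seg_stats_at(200)]
        assert len(common_segments([a, a])) == 2

    def test_disjoint_samples_share_nothing(self):
        assert common_segments([[seg_stats_at(100)], [seg_stats_at(500)]]) == {}


class TestPairwiseCorrelation:
    def make_common(self, levels_a, levels_b):
        common = {}
        for i, (la, lb) in enumerate(zip(levels_a, levels_b)):
            sa = seg_stats_at(100 * (i + 1))
            sb = seg_stats_at(100 * (i + 1))
            sa.level, sb.level = la, lb
            common[sa.key] = [sa, sb]
        return common

    def test_identical_vectors(self):
        common = self.make_common([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert pairwise_correlation(common) == pytest.approx(1.0)

    def test_negated_vectors(self):
        common = self.make_common([0.1, 0.5, 0.9], [0.9, 0.5, 0.1])
        assert pairwise_correlation(common) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = [0.1, 0.4, 0.35, 0.8]
        y = [0.2, 0.3, 0.6, 0.9]
        common = self.make_common(x, y)
        assert pairwise_correlation(common) == pytest.approx(float(np.corrcoef(x, y)[0, 1]))

    def test_too_few_segments(self):
        with pytest.raises(ValueError):
            pairwise_correlation(self.make_common([0.1], [0.2]))


class TestQuintiles:
    def test_five_distinct_genes_one_per_group(self):
        recs = [ExpressionRecord(f"G{i}", float(i)) for i in range(5)]
        q = assign_quintiles(recs)
        assert q == {"G0": 1, "G1": 2, "G2": 3, "G3": 4, "G4": 5}

    def test_constant_values_stable_and_balanced(self):
        recs = [ExpressionRecord(f"G{i}", 1.0) for i in range(7)]
        q = assign_quintiles(recs)
        sizes = np.bincount(list(q.values()))[1:]
        assert sizes.max() - sizes.min() <= 1
        assert q["G0"] == 1  # stable tie order

    def test_zero_expression_ranks_lowest(self):
        recs = [ExpressionRecord("Z", 0.0)] + [
            ExpressionRecord(f"G{i}", float(i + 1)) for i in range(4)
        ]
        assert assign_quintiles(recs)["Z"] == 1


class TestTssProfile:
    GENES = [GeneModel("G", "chr1", "+", 10000, 12000)]
    EXPR = [ExpressionRecord("G", 5.0)]

    def test_segment_midpoint_binning(self):
        s = seg_stats_at(9834)  # midpoint 9850 -> offset -150 -> bin [-200,-100)
        _level, entropy, missing = tss_profile([s], self.GENES, self.EXPR)
        filled = entropy["[-200,-100)"].dropna()
        assert len(filled) == 1
        assert filled.iloc[0] == pytest.approx(s.entropy)
        assert missing == 0

    def test_minus_strand_reflection(self):
        genes = [GeneModel("G", "chr1", "-", 8000, 10000)]  # TSS at 10000
        s = seg_stats_at(10134)  # midpoint 10150, genomically right -> upstream
        _level, entropy, _ = tss_profile([s], genes, self.EXPR)
        filled = entropy["[-200,-100)"].dropna()
        assert len(filled) == 1

    def test_empty_bins_are_missing_not_zero(self):
        s = seg_stats_at(9834)
        _level, entropy, _ = tss_profile([s], self.GENES, self.EXPR)
        assert np.isnan(entropy["[100,200)"]).all()

    def test_genes_without_expression_counted(self):
        genes = self.GENES + [GeneModel("H", "chr1", "+", 50000, 51000)]
        *_rest, missing = tss_profile([], genes, self.EXPR)
        assert missing == 1

    def test_translation_invariance(self):
        shift = 1_000_000
        s1 = seg_stats_at(9834)
        s2 = seg_stats_at(9834 + shift)
        genes2 = [GeneModel("G", "chr1", "+", 10000 + shift, 12000 + shift)]
        a = tss_profile([s1], self.GENES, self.EXPR)[1]
        b = tss_profile([s2], genes2, self.EXPR)[1]
        assert a.fillna(-1).equals(b.fillna(-1))


class TestGeneBodyStats:
    def test_mean_of_member_segments(self):
        g = GeneModel("G", "chr1", "+", 10000, 12000)
        s1, s2 = seg_stats_at(9500), seg_stats_at(9600)
        s1.entropy, s2.entropy = 0.1, 0.3
        df = gene_body_stats([s1, s2], [g])
        assert df.loc[0, "mean_entropy"] == pytest.approx(0.2)
        assert df.loc[0, "n_segments"] == 2

    def test_gene_without_segments_absent(self):
        g = GeneModel("G", "chr1", "+", 10000, 12000)
        assert gene_body_stats([seg_stats_at(500000)], [g]).empty

    def test_boundary_overlap_inclusive(self):
        g = GeneModel("G", "chr1", "+", 10000, 12000)  # window [9000, 10200)
        s = seg_stats_at(10199 - 30)  # span [10169, 10201): 1 bp inside
        assert len(gene_body_stats([s], [g])) == 1
        s2 = seg_stats_at(10200)  # span starts exactly at window end
        assert gene_body_stats([s2], [g]).empty
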