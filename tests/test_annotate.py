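import math

import numpy as np
import pytest

from chromgraph.annotate import (
    AnchorFeature,
    bh_qvalues,
    enrichment_two_proportion,
    intersect_pairs,
    long_range_hits,
    promoter_connectivity,
    relative_connectivity,
)
from oracles import permutation_proportion_test
from test_interactions import make_call


def snp(chrom, pos, name="snp"):
    return AnchorFeature(chrom, pos, pos + 1, name, "gwas-snp")


def promoter(chrom, start, end, name="gene"):
    return AnchorFeature(chrom, start, end, name, "gene-promoter")


class TestIntersectPairs:
    def test_snp_promoter_pair(self):
        call = make_call("chrT", 1, 6, 0.5)  # [25000,50000) - [150000,175000)
        hits = intersect_pairs([call], [snp("chrT", 30_100)],
                               [promoter("chrT", 160_000, 161_000)])
        assert len(hits) == 1
        assert hits[0].orientation == "forward"

    def test_swapped_orientation(self):
        call = make_call("chrT", 1, 6, 0.5)
        hits = intersect_pairs([call], [promoter("chrT", 160_000, 161_000, "g")],
                               [snp("chrT", 30_100)])
        assert len(hits) == 1
        assert hits[0].orientation == "swapped"

    def test_same_bin_without_call_gives_no_hit(self):
        hits = intersect_pairs([], [snp("chrT", 100)], [promoter("chrT", 200, 300)])
        assert hits == []

    def test_features_on_other_chromosome_ignored(self):
        call = make_call("chrT", 1, 6, 0.5)
        hits = intersect_pairs([call], [snp("chrX", 30_100)],
                               [promoter("chrT", 160_000, 161_000)])
        assert hits == []

    def test_both_anchors_same_side_is_not_a_hit(self):
        call = make_call("chrT", 1, 6, 0.5)
        hits = intersect_pairs([call], [snp("chrT", 30_100), snp("chrT", 31_000)], [])
        assert hits == []

    def test_symmetric_under_swap(self):
        calls = [make_call("chrT", 1, 6, 0.5), make_call("chrT", 2, 9, 0.4)]
        left = [snp("chrT", 30_100), snp("chrT", 230_000)]
        right = [promoter("chrT", 160_000, 161_000)]
        fwd = intersect_pairs(calls, left, right)
        rev = intersect_pairs(calls, right, left)
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert a.interaction == b.interaction
            assert a.left_features == b.right_features
            assert a.right_features == b.left_features
            assert {a.orientation, b.orientation} == {"forward", "swapped"}


class TestLongRange:
    def test_filtering(self):
        near = intersect_pairs([make_call("chrT", 0, 16, 0.5)],
                               [snp("chrT", 10)], [promoter("chrT", 400_001, 400_100)])
        far = intersect_pairs([make_call("chrT", 0, 25, 0.5)],
                              [snp("chrT", 10)], [promoter("chrT", 625_001, 625_100)])
        hits = near + far
        kept = long_range_hits(hits, 500_000)
        assert kept == far  # 625000 - 0 > 500 kbp, 400000 is not
        assert long_range_hits([], 500_000) == []

    def test_subset_property(self):
        calls = [make_call("chrT", 0, j, 0.5) for j in (5, 21, 30)]
        hits = intersect_pairs(calls, [snp("chrT", 10)],
                               [promoter("chrT", 0, 800_000, "g")])
        kept = long_range_hits(hits)
        assert set(id(h) for h in kept) <= set(id(h) for h in hits)
        assert all(h.interaction.distance > 500_000 for h in kept)


class TestPromoterConnectivity:
    def test_counts_touching_calls(self):
        calls = [make_call("chrT", 1, 6, 0.5), make_call("chrT", 1, 9, 0.4),
                 make_call("chrT", 2, 6, 0.3)]
        counts = promoter_connectivity(calls, [promoter("chrT", 30_000, 31_000, "geneA")])
        assert counts == {"geneA": 2}

    def test_no_calls_gives_zero(self):
        counts = promoter_connectivity([], [promoter("chrT", 0, 100, "geneA")])
        assert counts == {"geneA": 0}

    def test_duplicate_gene_names_merged_with_warning(self, caplog):
        calls = [make_call("chrT", 1, 6, 0.5)]
        with caplog.at_level("WARNING"):
            counts = promoter_connectivity(
                calls,
                [promoter("chrT", 30_000, 31_000, "geneA"),
                 promoter("chrT", 30_500, 31_500, "geneA")],
            )
        assert counts == {"geneA": 1}
        assert "geneA" in caplog.text

    def test_relative_connectivity_mean_centering(self):
        rel = relative_connectivity({"ct1": {"g": 4}, "ct2": {"g": 2}})
        assert rel == {"ct1": {"g": 1.0}, "ct2": {"g": -1.0}}


class TestEnrichment:
    def test_hand_computed_z(self):
        # 30/100 vs 10/100: pooled p=0.2, se=sqrt(0.2*0.8*0.02), z=0.2/0.0565685...
        res = enrichment_two_proportion(30, 100, 10, 100)
        assert res.z == pytest.approx(0.2 / math.sqrt(0.2 * 0.8 * 0.02), abs=1e-12)
        assert res.z == pytest.approx(3.5355, abs=1e-3)
        assert res.p < 0.001
        assert res.enrichment == pytest.approx(3.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        z_ref, p_ref = proportions_ztest([30, 10], [100, 100])
        res = enrichment_two_proportion(30, 100, 10, 100)
        assert res.z == pytest.approx(z_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_equal_proportions(self):
        res = enrichment_two_proportion(10, 50, 20, 100)
        assert res.z == 0.0
        assert res.p == 1.0
        assert res.enrichment == 1.0

    def test_zero_null_fraction_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            res = enrichment_two_proportion(100, 100, 0, 100)
        assert not res.defined
        assert math.isnan(res.enrichment)

    def test_matches_permutation_null(self):
        res = enrichment_two_proportion(30, 100, 10, 100)
        p_perm = permutation_proportion_test(30, 100, 10, 100, n_perm=10_000, seed=1)
        assert abs(res.p - p_perm) < 0.02

    def test_matches_permutation_moderate_counts(self):
        res = enrichment_two_proportion(40, 200, 25, 190)
        p_perm = permutation_proportion_test(40, 200, 25, 190, n_perm=10_000, seed=2)
        assert abs(res.p - p_perm) < 0.02

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            enrichment_two_proportion(5, 0, 1, 10)
        with pytest.raises(ValueError):
            enrichment_two_proportion(11, 10, 1, 10)


class TestBH:
    def test_monotone_and_bounded(self):
        q = bh_qvalues([0.01, 0.04, 0.03, 0.9])
        assert all(0 <= x <= 1 for x in q)
        assert q[3] == pytest.approx(0.9)

    def test_single(self):
        assert bh_qvalues([0.2]) == [pytest.approx(0.2)]

    def test_empty(self):
        assert bh_qvalues([]) == []

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        pvals = [0.001, 0.02, 0.03, 0.5, 0.8]
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_qvalues(pvals), ref, atol=1e-12)
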