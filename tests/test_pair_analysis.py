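"""Pair enumeration, duplicate filtering, distance binning, rank-sum
comparison, GESS and correlations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tadfunc.pair_analysis import (
    GenePair,
    InsufficientDataError,
    InsufficientPairsError,
    DegenerateRangeError,
    bin_pairs_by_distance,
    compare_distributions,
    correlate_scores,
    enumerate_intra_pairs,
    filter_duplicates,
    gess,
    mutual_pathways,
    rebalance,
    sample_baseline_pairs,
    sample_inter_pairs,
    significance_tier,
)


class TestEnumeration:
    def test_four_gene_domain_gives_six_pairs(self, toy_partition):
        # TAD 1 holds g1, g2, g3 -> C(3,2)=3; add none elsewhere
        pairs = enumerate_intra_pairs(toy_partition, "tad")
        tad1 = [p for p in pairs if {p.gene_a, p.gene_b} <= {"g1", "g2", "g3"}]
        assert len(tad1) == 3

    def test_single_gene_domain_gives_no_pairs(self, toy_partition):
        pairs = enumerate_intra_pairs(toy_partition, "gap")
        assert pairs == []  # g7 is alone in the gap

    def test_matches_brute_force_double_loop(self, toy_partition):
        pairs = {p.key for p in enumerate_intra_pairs(toy_partition, "tad")}
        expected = set()
        genes = toy_partition.assigned_genes("tad")
        for a, b in itertools.combinations(sorted(genes), 2):
            if toy_partition.domain_of(a) == toy_partition.domain_of(b):
                expected.add((a, b))
        assert pairs == expected

    def test_intra_inter_disjoint_and_exhaustive(self, toy_partition):
        """Intra pairs plus all eligible inter pairs cover every pair of
        TAD-assigned genes exactly once."""
        genes = sorted(toy_partition.assigned_genes("tad"))
        intra = {p.key for p in enumerate_intra_pairs(toy_partition, "tad")}
        n_eligible = sum(
            1 for a, b in itertools.combinations(genes, 2)
            if toy_partition.domain_of(a) != toy_partition.domain_of(b)
        )
        rng = np.random.default_rng(0)
        inter = {
            p.key for p in sample_inter_pairs(toy_partition, "tad", n_eligible, rng)
        }
        assert intra & inter == set()
        assert intra | inter == {
            k for k in map(tuple, itertools.combinations(genes, 2))
        }

    def test_inter_pairs_verified_by_membership_oracle(self, toy_partition):
        rng = np.random.default_rng(1)
        for p in sample_inter_pairs(toy_partition, "tad", 5, rng):
            assert toy_partition.domain_of(p.gene_a) != toy_partition.domain_of(p.gene_b)

    def test_inter_sampling_deterministic(self, toy_partition):
        a = sample_inter_pairs(toy_partition, "tad", 5, np.random.default_rng(7))
        b = sample_inter_pairs(toy_partition, "tad", 5, np.random.default_rng(7))
        assert [p.key for p in a] == [p.key for p in b]

    def test_inter_zero_and_overflow(self, toy_partition):
        assert sample_inter_pairs(toy_partition, "tad", 0, np.random.default_rng(0)) == []
        with pytest.raises(InsufficientPairsError):
            sample_inter_pairs(toy_partition, "tad", 10_000, np.random.default_rng(0))

    def test_baseline_ignores_domains(self, toy_partition):
        pairs = sample_baseline_pairs(toy_partition, 10, np.random.default_rng(0))
        assert len({p.key for p in pairs}) == 10

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            GenePair("g", "g")


class TestDuplicateFilter:
    table = {("a", "b"): (95.0, 1e-5), ("a", "c"): (50.0, 1e-5),
             ("b", "c"): (90.0, 1e-5), ("a", "d"): (95.0, 0.5)}

    def _pairs(self):
        return [GenePair(*k) for k in [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("c", "d")]]

    def test_high_identity_low_evalue_removed(self):
        kept = {p.key for p in filter_duplicates(self._pairs(), self.table)}
        assert ("a", "b") not in kept

    def test_low_identity_kept(self):
        kept = {p.key for p in filter_duplicates(self._pairs(), self.table)}
        assert ("a", "c") in kept

    def test_boundary_identity_90_kept(self):
        """The rule is strictly greater than 90%."""
        kept = {p.key for p in filter_duplicates(self._pairs(), self.table)}
        assert ("b", "c") in kept

    def test_high_evalue_kept_and_absent_pairs_kept(self):
        kept = {p.key for p in filter_duplicates(self._pairs(), self.table)}
        assert ("a", "d") in kept and ("c", "d") in kept

    def test_rebalance_equalises(self):
        intra = [GenePair("a", f"x{i}") for i in range(10)]
        inter = [GenePair("b", f"y{i}") for i in range(4)]
        i2, j2 = rebalance(intra, inter, np.random.default_rng(0))
        assert len(i2) == len(j2) == 4


class TestBinning:
    def test_worked_bin_1(self):
        pairs = [GenePair("a", "b", 250_000)]
        assert 1 in bin_pairs_by_distance(pairs, 200_000)

    def test_zero_distance_bin_0(self):
        assert 0 in bin_pairs_by_distance([GenePair("a", "b", 0)], 200_000)

    def test_exact_boundary_goes_up(self):
        """Half-open bins: d == bin_size falls in bin 1."""
        assert 1 in bin_pairs_by_distance([GenePair("a", "b", 200_000)], 200_000)


class TestCompareDistributions:
    def test_identical_samples_p_near_one(self):
        x = [0.1, 0.5, 0.9, 0.3] * 5
        p, tier = compare_distributions(x, list(x))
        assert p > 0.9 and tier == "ns"

    def test_asymptotic_close_to_exact_oracle(self):
        """At small n without deep-tail separation the tie-corrected
        normal approximation agrees with the exact MWU enumeration."""
        rng = np.random.default_rng(3)
        x = list(rng.normal(0.0, 1.0, 8))
        y = list(rng.normal(0.8, 1.0, 8))
        p_asym, _ = compare_distributions(x, y)
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p_asym == pytest.approx(p_exact, rel=0.10)

    def test_tiers(self):
        assert significance_tier(0.0005) == "**"
        assert significance_tier(5e-5) == "***"
        assert significance_tier(0.01) == "*"
        assert significance_tier(0.2) == "ns"

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_distributions([], [1.0])


class TestGess:
    def test_equal_counts_score_one(self):
        assert gess(100, 100, 1000, 0) == 1.0

    def test_max_min_pair_scores_zero(self):
        assert gess(1000, 0, 1000, 0) == 0.0

    def test_worked_value(self):
        """ecA=255, ecB=63, max=1023, min=0 -> (10-|8-6|)/10 = 0.8."""
        assert gess(255, 63, 1023, 0) == pytest.approx(0.8)

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError):
            gess(5, 5, 5, 5)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(0, 1000), st.floats(0, 1000),
    )
    def test_symmetric_and_bounded(self, a, b):
        s = gess(a, b, 1000.0, 0.0)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(gess(b, a, 1000.0, 0.0))


class TestCorrelateScores:
    def test_perfect_linear_relation(self):
        sims = [0.3, 0.5, 0.7, 0.9]
        r, _ = correlate_scores(sims, [2 * s + 1 for s in sims], 0.2)
        assert r == pytest.approx(1.0)

    def test_threshold_removing_all_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlate_scores([0.1, 0.1, 0.1], [1, 2, 3], 0.2)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        sims = list(rng.uniform(0.3, 1.0, 10))
        ges = list(rng.uniform(0.0, 1.0, 10))
        r, _ = correlate_scores(sims, ges, 0.0)
        x, y = np.array(sims), np.array(ges)
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected)


class TestMutualPathways:
    pmap = {"P1": {"a", "b"}, "P2": {"a", "b", "c"}, "P3": {"b"}}

    def test_single_shared(self):
        assert mutual_pathways("a", "c", self.pmap) == ["P2"]

    def test_disjoint(self):
        assert mutual_pathways("c", "d", self.pmap) == []

    def test_multiple_shared_is_set_intersection(self):
        assert mutual_pathways("a", "b", self.pmap) == ["P1", "P2"]
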