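"""Tests for the nonparametric cohort statistics battery."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import d50track.stats as dstats
from d50track import (
    InvalidArgumentError,
    InvalidDesignError,
    categorical_homogeneity,
    compare_groups,
    normality_gate,
    phase_association,
    summarize,
)


class TestSummarize:
    def test_odd_length_exact(self):
        assert summarize([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_constant_vector(self):
        med, q25, q75 = summarize([7.0] * 10)
        assert med == q25 == q75 == 7.0

    def test_empty_absent(self):
        assert summarize([]) is None


def _kw_permutation_pvalue(groups):
    """Exact permutation null of the Kruskal-Wallis statistic.

    Enumerates every assignment of the pooled values to the group sizes and
    counts the fraction with H at least as large as observed.  Independent
    of the implementation under test.
    """
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def h_stat(parts):
        return sps.kruskal(*parts).statistic

    observed = h_stat(groups)
    n = len(pooled)
    idx = set(range(n))
    count = total = 0
    for first in itertools.combinations(range(n), sizes[0]):
        rest = sorted(idx - set(first))
        for second in itertools.combinations(rest, sizes[1]):
            third = sorted(set(rest) - set(second))
            parts = [pooled[list(first)], pooled[list(second)],
                     pooled[list(third)]]
            total += 1
            if h_stat(parts) >= observed - 1e-9:
                count += 1
    return count / total


class TestCompareGroups:
    def test_separated_strata_detected(self):
        # At n = 3 per stratum no rank-based pairwise test can reject an
        # adjacent pair after Bonferroni (the smallest attainable two-sided
        # rank p is 0.1), so the checkable separation signal is the omnibus
        # rejection plus the extreme pair.
        groups = {"a": [1, 2, 3], "b": [11, 12, 13], "c": [21, 22, 23]}
        res = compare_groups(groups)
        assert res.pvalue < 0.05
        assert ("a", "c") in res.significant_pairs()
        # every pairwise z points the right way
        z = res.pairwise.set_index(["group1", "group2"])["z"]
        assert z[("a", "b")] < 0 and z[("b", "c")] < 0 and z[("a", "c")] < 0
        # exact permutation oracle agrees the omnibus separation is real
        exact_p = _kw_permutation_pvalue(list(map(np.asarray, groups.values())))
        assert exact_p < 0.05
        assert exact_p == pytest.approx(6 / 1680, abs=1e-12)

    def test_shifted_stratum_only_its_pairs_significant(self):
        rng = np.random.default_rng(21)
        base = rng.normal(0, 1, 40)
        groups = {"u1": base, "u2": rng.normal(0, 1, 40),
                  "s": rng.normal(4, 1, 40)}
        res = compare_groups(groups)
        sig = set(map(frozenset, res.significant_pairs()))
        assert frozenset({"u1", "s"}) in sig
        assert frozenset({"u2", "s"}) in sig
        assert frozenset({"u1", "u2"}) not in sig

    def test_bonferroni_invariants(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 20) for i, k in enumerate("abc")}
        res = compare_groups(groups)
        assert np.all(res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-15)
        assert np.all(res.pairwise["p_adj"] <= 1.0)
        assert np.allclose(res.pairwise["p_adj"],
                           np.minimum(1.0, res.pairwise["p_raw"] * 3))

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.gamma(2, 2, 25) for k in "abc"}
        res1 = compare_groups(groups)
        res2 = compare_groups({k: np.exp(v / 5.0) for k, v in groups.items()})
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-12)

    def test_null_calibration(self):
        # identically distributed strata: rejection rate compatible with 5%
        rng = np.random.default_rng(11)
        rejections = sum(
            compare_groups({k: rng.normal(0, 1, 50) for k in "abc"}).pvalue
            < 0.05
            for _ in range(1000)
        )
        # binomial(1000, 0.05) central 99.9% region
        assert 27 <= rejections <= 75

    def test_dunn_z_matches_direct_computation(self):
        groups = {"a": [1.0, 4.0, 7.0], "b": [2.0, 5.0, 9.0],
                  "c": [12.0, 15.0, 20.0]}
        res = compare_groups(groups)
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        rbar = {"a": ranks[:3].mean(), "b": ranks[3:6].mean(),
                "c": ranks[6:].mean()}
        n = 9
        var = n * (n + 1) / 12.0  # no ties here
        row = res.pairwise.set_index(["group1", "group2"]).loc[("a", "c")]
        z_expect = (rbar["a"] - rbar["c"]) / np.sqrt(var * (2 / 3))
        assert row["z"] == pytest.approx(z_expect, rel=1e-12)

    def test_mannwhitney_posthoc_path(self):
        groups = {"a": [1, 2, 3, 4], "b": [10, 11, 12, 13], "c": [1, 2, 3, 5]}
        res = compare_groups(groups, posthoc="mannwhitney")
        assert res.n_comparisons == 3

    def test_degenerate_design(self):
        with pytest.raises(InvalidDesignError):
            compare_groups({"a": [1, 2, 3], "b": []})


class TestPhaseAssociation:
    def test_perfect_negative(self):
        rho, p = phase_association([30, 20, 10], [1, 2, 3])
        assert rho == pytest.approx(-1.0)

    def test_null_case(self):
        rng = np.random.default_rng(4)
        rho, p = phase_association(rng.normal(0, 1, 500),
                                   rng.integers(1, 4, 500))
        assert abs(rho) < 0.15

    def test_constant_side_absent(self):
        assert phase_association([5.0, 5.0, 5.0], [1, 2, 3]) is None

    def test_too_few_pairs(self):
        with pytest.raises(InvalidArgumentError):
            phase_association([1, 2], [1, 2])


class TestCategoricalHomogeneity:
    def test_2x2_matches_fisher_exact(self):
        table = [[8, 2], [1, 5]]
        res = categorical_homogeneity(table)
        assert res.method == "ffh-exact"
        _, p_fisher = sps.fisher_exact(table)
        assert res.pvalue == pytest.approx(p_fisher, rel=1e-9)

    def test_proportional_rows_p_one(self):
        res = categorical_homogeneity([[2, 4], [1, 2]], force_exact=True)
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_chi_square_path_matches_formula(self):
        table = np.array([[20, 30], [25, 15], [30, 20]])
        res = categorical_homogeneity(table)
        assert res.method == "chi-square"
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.pvalue == pytest.approx(sps.chi2.sf(chi2, 2), rel=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self, monkeypatch):
        table = [[5, 3, 2], [2, 6, 3], [3, 2, 7]]
        exact = categorical_homogeneity(table, force_exact=True)
        assert exact.method == "ffh-exact"
        monkeypatch.setattr(dstats, "_FFH_MAX_ENUM", 1)
        mc = categorical_homogeneity(table, force_exact=True)
        assert mc.method == "ffh-monte-carlo"
        assert mc.pvalue == pytest.approx(exact.pvalue, abs=4 * mc.mc_se + 1e-4)

    def test_degenerate_margin(self):
        with pytest.raises(InvalidDesignError):
            categorical_homogeneity([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(InvalidArgumentError):
            categorical_homogeneity([[1.5, 2], [3, 4]])


class TestNormalityGate:
    def test_normal_calibration(self):
        rng = np.random.default_rng(6)
        passes = sum(normality_gate(rng.normal(0, 1, 500))[1] > 0.05
                     for _ in range(100))
        assert passes >= 90

    def test_left_skew_detected(self):
        rng = np.random.default_rng(7)
        w, p = normality_gate(48.0 - rng.exponential(6.0, 200))
        assert p < 0.05

    def test_constant_and_range_errors(self):
        with pytest.raises(InvalidArgumentError):
            normality_gate([3.0] * 10)
        with pytest.raises(InvalidArgumentError):
            normality_gate([1.0, 2.0])
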