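"""Nonparametric tests against brute-force enumeration oracles."""

from itertools import combinations, permutations

import numpy as np
import pytest
from scipy import stats as sps

from tractprox.stats import (GroupSummary, mann_whitney,
                             normality_gated_comparison, spearman,
                             summarize_groups, wilcoxon_signed_rank)
import pandas as pd


# --- independent oracles (direct definitions, no rank shortcuts) ----------

def mw_oracle(a, b):
    """U and exact two-sided p by enumerating group assignments of the
    pooled values and counting discordant pairs directly."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(pooled)

    def u_of(group_a):
        rest = [pooled[i] for i in range(n) if i not in group_a]
        ga = [pooled[i] for i in group_a]
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in rest)

    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    mu = len(a) * len(b) / 2.0
    hits = total = 0
    for comb in combinations(range(n), len(a)):
        total += 1
        if abs(u_of(comb) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


def wilcoxon_oracle(d):
    """W+ and exact two-sided p by enumerating all sign patterns."""
    d = [x for x in d if x != 0]
    ranks = sps.rankdata([abs(x) for x in d])
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    n = len(d)
    mu = n * (n + 1) / 4.0
    hits = 0
    for bits in range(1 << n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return w_obs, hits / (1 << n)


def spearman_oracle(x, y):
    """rho and exact two-sided p over all permutations of y."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


class TestMannWhitney:
    def test_disjoint_pairs_exact(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "mann-whitney-exact"

    def test_identical_multisets_p_one(self):
        res = mann_whitney([1, 2, 5], [1, 2, 5])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 5))
        b = rng.normal(size=rng.integers(2, 5))
        res = mann_whitney(a, b)
        u, p = mw_oracle(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p)

    def test_exact_and_asymptotic_paths_agree_at_boundary(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=6), rng.normal(size=6)
        exact = mann_whitney(a, b)
        asym = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=True)
        assert exact.method == "mann-whitney-exact"
        assert abs(exact.p_value - asym.pvalue) < 0.02

    def test_large_samples_use_tie_corrected_normal_path(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 30).astype(float)  # heavy ties
        b = rng.integers(1, 5, 25).astype(float)
        res = mann_whitney(a, b)
        assert res.method == "mann-whitney-asymptotic"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxon:
    def test_five_positive_differences(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2 / 32)

    def test_balanced_pair_p_one(self):
        res = wilcoxon_signed_rank([1.0, 0.0], [0.0, 1.0])
        assert res.p_value == pytest.approx(1.0)

    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0
        assert res.extra["all_zero"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=rng.integers(3, 8))
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        w, p = wilcoxon_oracle(d)
        assert res.statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p)

    def test_zeros_dropped_from_n(self):
        res = wilcoxon_signed_rank([2, 3, 5, 5], [1, 1, 5, 5])
        assert res.n == (2,)

    def test_large_sample_approximation(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(1.0, 1.0, 40)
        post = rng.normal(0.0, 1.0, 40)
        res = wilcoxon_signed_rank(pre, post)
        assert res.method == "wilcoxon-asymptotic"
        ref = sps.wilcoxon(pre - post, zero_method="wilcox", correction=True,
                           method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 8, 3, 1])
        assert res.statistic == pytest.approx(-1.0)
        assert res.extra["rs_squared"] == pytest.approx(1.0)
        res2 = spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert res2.statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_equals_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        rho, p = spearman_oracle(x, y)
        assert res.statistic == pytest.approx(rho)
        assert res.p_value == pytest.approx(p)
        assert res.method == "spearman-exact"

    def test_large_sample_matches_scipy_t_approx(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_constant_sample_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.extra.get("zero_rank_variance")
        assert np.isnan(res.statistic)


class TestNormalityGate:
    def test_exponential_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        a, b = rng.exponential(size=40), rng.exponential(size=40)
        res = normality_gated_comparison(a, b)
        assert "mann-whitney" in res.method

    def test_gaussian_routes_to_welch_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=60), rng.normal(size=60)
        res = normality_gated_comparison(a, b)
        assert res.method == "welch-t"

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        res = normality_gated_comparison(a, a.copy())
        assert res.p_value > 0.99

    def test_null_p_values_roughly_uniform(self):
        # Kolmogorov check on the p distribution under the null
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            a, b = rng.normal(size=25), rng.normal(size=25)
            ps.append(normality_gated_comparison(a, b).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSummaries:
    def test_group_summary_order_statistics(self):
        s = GroupSummary.from_sample([3.0, 1.0, 2.0, 5.0, 4.0])
        assert s.min <= s.p25 <= s.p50 <= s.p75 <= s.max
        assert s.p50 == 3.0 and s.n == 5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        a = GroupSummary.from_sample(x)
        b = GroupSummary.from_sample(rng.permutation(x))
        for field in ("n", "mean", "min", "max", "sd", "p25", "p50", "p75"):
            assert getattr(a, field) == pytest.approx(getattr(b, field))

    def test_single_value_sd_flagged_nan(self):
        assert np.isnan(GroupSummary.from_sample([2.5]).sd)

    def _records(self, resp, non):
        rows = [dict(distance_mm=d, improvement_pct=10.0, responder=True,
                     included=True) for d in resp]
        rows += [dict(distance_mm=d, improvement_pct=-1.0, responder=False,
                      included=True) for d in non]
        return pd.DataFrame(rows)

    def test_report_medians_and_exact_test(self):
        rep = summarize_groups(self._records([1.0, 1.6, 2.0], [2.8, 3.0, 5.0]))
        assert rep["summaries"]["responders"].p50 == pytest.approx(1.6)
        assert rep["summaries"]["non_responders"].p50 == pytest.approx(3.0)
        mw = rep["tests"]["distance_mann_whitney"]
        u, p = mw_oracle([1.0, 1.6, 2.0], [2.8, 3.0, 5.0])
        assert mw.statistic == pytest.approx(u)
        assert mw.p_value == pytest.approx(p)

    def test_empty_class_flagged_not_fatal(self):
        rep = summarize_groups(self._records([1.0, 2.0, 3.0], []))
        assert "non_responders" not in rep["summaries"]
        assert any("empty class" in f for f in rep["flags"])
        assert "distance_mann_whitney" not in rep["tests"]
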