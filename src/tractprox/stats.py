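"""Nonparametric statistical battery and group summaries.

The tests mirror standard clinical-outcome reporting: Mann-Whitney for
independent group differences (exact enumeration when both samples
together hold at most 12 untied values, normal approximation with tie and
continuity corrections otherwise), the Wilcoxon signed-rank test for
paired pre/post comparisons (zero differences dropped, midranks of |d|,
exact sign enumeration up to 12 effective pairs), Spearman rank
correlation with Rs^2, and a normality-gated two-sample comparison that
routes to Welch's t test or Mann-Whitney depending on Shapiro-Wilk checks
at alpha = 0.05.  All p values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_N_MAX = 12
SPEARMAN_EXACT_N_MAX = 8


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    extra: dict = None

    def __post_init__(self) -> None:
        if self.extra is None:
            self.extra = {}
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p value outside [0, 1]")


@dataclass
class GroupSummary:
    n: int
    mean: float
    min: float
    max: float
    sd: float  # NaN when n < 2
    p25: float
    p50: float
    p75: float

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            raise ValueError("empty sample")
        # linear-interpolation (type-7) percentiles
        p25, p50, p75 = np.percentile(x, [25, 50, 75])
        sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
        return cls(n=int(x.size), mean=float(x.mean()), min=float(x.min()),
                   max=float(x.max()), sd=sd, p25=float(p25), p50=float(p50),
                   p75=float(p75))


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by enumeration of group assignments when n_a + n_b <= 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    ranks = _midranks(pooled)
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    if a.size + b.size <= EXACT_N_MAX and not ties:
        # enumerate every assignment of the pooled ranks to group A
        n = pooled.size
        mu = a.size * b.size / 2.0
        all_ranks = np.arange(1, n + 1)
        obs_dev = abs(u_a - mu)
        hits = total = 0
        for comb in combinations(range(n), a.size):
            u = all_ranks[list(comb)].sum() - a.size * (a.size + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return TestResult(statistic=float(u_a), p_value=hits / total,
                          method="mann-whitney-exact", n=(int(a.size), int(b.size)))
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="mann-whitney-asymptotic", n=(int(a.size), int(b.size)))


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original rule — this changes
    n and is recorded); |d| are midranked; exact p by enumeration of the
    2^n sign patterns when the effective n <= 12, else the normal
    approximation with continuity correction.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size == 0:
        raise ValueError("paired samples must be equal-length and non-empty")
    d = pre - post
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0,
                          method="wilcoxon-degenerate", n=(0,),
                          extra={"all_zero": True})
    ranks = _midranks(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= EXACT_N_MAX:
        mu = n * (n + 1) / 4.0
        obs_dev = abs(w_plus - mu)
        hits = 0
        for signs in range(1 << n):
            w = sum(ranks[i] for i in range(n) if signs >> i & 1)
            if abs(w - mu) >= obs_dev - 1e-12:
                hits += 1
        return TestResult(statistic=float(w_plus), p_value=hits / (1 << n),
                          method="wilcoxon-exact", n=(int(n),))
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method="approx")
    return TestResult(statistic=float(w_plus), p_value=float(res.pvalue),
                      method="wilcoxon-asymptotic", n=(int(n),))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with Rs^2.

    Rs is the Pearson correlation of midranks; p is exact (enumeration of
    rank permutations) for n <= 8, else the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          method="spearman-degenerate", n=(int(x.size),),
                          extra={"zero_rank_variance": True})
    rs = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= SPEARMAN_EXACT_N_MAX:
        obs = abs(rs)
        hits = total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                hits += 1
        p = hits / total
        method = "spearman-exact"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "spearman-t-approx"
    return TestResult(statistic=rs, p_value=p, method=method, n=(int(n),),
                      extra={"rs_squared": rs * rs})


def normality_gated_comparison(a, b) -> TestResult:
    """Welch's t test when both groups pass Shapiro-Wilk at alpha = 0.05,
    Mann-Whitney otherwise; the method label records the route."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    normal = (sps.shapiro(a).pvalue > 0.05) and (sps.shapiro(b).pvalue > 0.05)
    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          method="welch-t", n=(int(a.size), int(b.size)))
    out = mann_whitney(a, b)
    out.method = "mann-whitney (normality failed)"
    return out


# ---------------------------------------------------------------------------
# report assembly

def summarize_groups(records: pd.DataFrame, tremor_tests: dict | None = None):
    """Distance summaries per responder class plus the outcome statistics.

    ``records`` needs columns distance_mm, improvement_pct, responder,
    included.  Returns a dict with per-class ``GroupSummary`` rows, the
    responder-vs-non-responder Mann-Whitney on distance, the Spearman of
    improvement vs distance, and any pre-computed pre/post Wilcoxon
    results passed in ``tremor_tests``.
    """
    inc = records[records["included"]].copy()
    inc = inc[np.isfinite(inc["distance_mm"])]
    if inc.empty:
        raise ValueError("no included records with a measured distance")
    groups = {
        "responders": inc.loc[inc["responder"], "distance_mm"].to_numpy(),
        "non_responders": inc.loc[~inc["responder"], "distance_mm"].to_numpy(),
    }
    summaries = {}
    flags = []
    for name, vals in groups.items():
        if vals.size:
            summaries[name] = GroupSummary.from_sample(vals)
        else:
            flags.append(f"{name}: empty class, summary not computed")
    tests: dict = {}
    if all(v.size for v in groups.values()):
        tests["distance_mann_whitney"] = mann_whitney(
            groups["responders"], groups["non_responders"]
        )
    else:
        flags.append("distance_mann_whitney: not computed (empty class)")
    if inc.shape[0] >= 3:
        tests["improvement_vs_distance_spearman"] = spearman(
            inc["improvement_pct"].to_numpy(), inc["distance_mm"].to_numpy()
        )
    if tremor_tests:
        tests.update(tremor_tests)
    return {"summaries": summaries, "tests": tests, "flags": flags}


def render_report(report: dict) -> str:
    """Human-readable rendering of a summarize_groups result."""
    lines = ["Distance to tract border (mm) by responder class", ""]
    header = f"{'group':<15}{'n':>4}{'mean':>8}{'min':>7}{'max':>7}{'sd':>7}{'p25':>7}{'p50':>7}{'p75':>7}"
    lines.append(header)
    for name, s in report["summaries"].items():
        lines.append(
            f"{name:<15}{s.n:>4}{s.mean:>8.2f}{s.min:>7.2f}{s.max:>7.2f}"
            f"{s.sd:>7.2f}{s.p25:>7.2f}{s.p50:>7.2f}{s.p75:>7.2f}"
        )
    lines.append("")
    for name, t in report["tests"].items():
        extra = ""
        if "rs_squared" in t.extra:
            extra = f"  Rs^2={t.extra['rs_squared']:.3f}"
        lines.append(f"{name}: stat={t.statistic:.3f} p={t.p_value:.4g} [{t.method}]{extra}")
    for f in report["flags"]:
        lines.append(f"flag: {f}")
    return "\n".join(lines) + "\n"


def report_tables(report: dict):
    """TSV-ready DataFrames (summary table, test table)."""
    srows = [dict(group=k, **vars(s)) for k, s in report["summaries"].items()]
    trows = []
    for name, t in report["tests"].items():
        trows.append(dict(test=name, statistic=t.statistic, p_value=t.p_value,
                          method=t.method, n="/".join(str(v) for v in t.n),
                          **{k: v for k, v in t.extra.items()}))
    return pd.DataFrame(srows), pd.DataFrame(trows)
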