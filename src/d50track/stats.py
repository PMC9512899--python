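"""Nonparametric cohort statistics for pseudo-longitudinal analyses.

The analysis battery mirrors common clinical-neurophysiology practice for
left-skewed measurements: Shapiro-Wilk as the normality gate, medians with
interquartile ranges as the descriptive summary, Kruskal-Wallis with Dunn's
rank-based pairwise post-hoc tests under Bonferroni correction for group
comparisons, Spearman correlation for ordinal associations, and Pearson
chi-square or the Fisher-Freeman-Halton exact test for contingency tables.

All significance decisions default to alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .exceptions import InvalidArgumentError, InvalidDesignError

__all__ = [
    "ALPHA",
    "summarize",
    "compare_groups",
    "phase_association",
    "categorical_homogeneity",
    "normality_gate",
    "GroupComparisonResult",
    "ContingencyResult",
]

ALPHA = 0.05
#: Fixed seed of the Monte-Carlo fallback of the exact contingency test.
_FFH_MC_SEED = 20220926
_FFH_MC_TABLES = 100_000
#: Enumeration budget above which the exact path falls back to Monte Carlo.
_FFH_MAX_ENUM = 500_000


def summarize(values):
    """Median and interquartile range (25th-75th percentile).

    Uses linearly interpolated quantiles.  Returns ``None`` for an empty
    stratum (absent, per reporting convention).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return None
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q25), float(q75)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn-Bonferroni
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    """Omnibus and pairwise comparison of >= 2 strata."""

    test_name: str
    statistic: float
    pvalue: float
    group_summaries: dict        # stratum -> (median, q25, q75, n)
    pairwise: pd.DataFrame       # group1, group2, z, p_raw, p_adj
    n_comparisons: int

    def significant_pairs(self, alpha=ALPHA):
        sig = self.pairwise[self.pairwise["p_adj"] < alpha]
        return list(zip(sig["group1"], sig["group2"]))


def _dunn_pairwise(groups, labels):
    """Dunn's z tests on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum over tie groups of (t^3 - t); two-sided normal p-values.
    """
    pooled = np.concatenate(groups)
    n = np.array([len(g) for g in groups])
    big_n = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(n)
    mean_ranks = [ranks[s:e].mean() for s, e in zip(np.r_[0, bounds[:-1]], bounds)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = big_n * (big_n + 1) / 12.0 - tie_term / (12.0 * (big_n - 1))

    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group1": labels[i], "group2": labels[j],
                     "z": float(z), "p_raw": float(p)})
    return pd.DataFrame(rows)


def _mannwhitney_pairwise(groups, labels):
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        u, p = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
        rows.append({"group1": labels[i], "group2": labels[j],
                     "z": float(u), "p_raw": float(p)})
    return pd.DataFrame(rows)


def compare_groups(values_by_stratum, posthoc="dunn"):
    """Kruskal-Wallis omnibus test with Bonferroni-corrected pairwise tests.

    Parameters
    ----------
    values_by_stratum : mapping of stratum label -> array_like
        Empty strata are dropped; at least two non-empty strata required.
    posthoc : {"dunn", "mannwhitney"}
        Pairwise procedure.  Dunn's rank test on the pooled ranks matches
        the usual post-hoc attached to a Kruskal-Wallis omnibus; pairwise
        Mann-Whitney is offered as an alternative.

    Returns
    -------
    GroupComparisonResult
        Adjusted p-values are ``min(1, raw * n_comparisons)``.
    """
    labels, groups = [], []
    for lab, vals in values_by_stratum.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            labels.append(lab)
            groups.append(arr)
    if len(groups) < 2:
        raise InvalidDesignError("need >= 2 non-empty strata to compare")

    stat, pval = sps.kruskal(*groups)

    if posthoc == "dunn":
        pw = _dunn_pairwise(groups, labels)
    elif posthoc == "mannwhitney":
        pw = _mannwhitney_pairwise(groups, labels)
    else:
        raise InvalidArgumentError(f"unknown posthoc {posthoc!r}")
    k = len(pw)
    pw["p_adj"] = np.minimum(1.0, pw["p_raw"] * k)

    summaries = {lab: (*summarize(g), len(g)) for lab, g in zip(labels, groups)}
    return GroupComparisonResult(
        test_name=f"kruskal-wallis + {posthoc}-bonferroni",
        statistic=float(stat), pvalue=float(pval),
        group_summaries=summaries, pairwise=pw, n_comparisons=k,
    )


def phase_association(values, phase_codes):
    """Spearman rank correlation of a measurement with ordinal phase codes.

    Average ranks handle ties.  Returns ``(rho, p)``, or ``None`` when
    either side is constant (rho undefined, reported as absent).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(phase_codes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("paired 1-D samples required")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InvalidArgumentError("need n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    method: str            # "chi-square" | "ffh-exact" | "ffh-monte-carlo"
    pvalue: float
    statistic: float | None = None
    dof: int | None = None
    mc_se: float | None = None
    n_tables: int | None = field(default=None, repr=False)


def _log_table_prob(table, log_row_fact, log_col_fact, log_n_fact):
    # multivariate hypergeometric probability of a table with fixed margins
    return (log_row_fact + log_col_fact - log_n_fact
            - gammaln(np.asarray(table, dtype=float) + 1.0).sum())


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row, remaining_cols, current):
        if row == r - 1:
            yield current + [list(remaining_cols)]
            return
        target = row_sums[row]

        def fill(col, left, partial):
            if col == c - 1:
                if left <= remaining_cols[c - 1]:
                    yield partial + [left]
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                yield from fill(col + 1, left - v, partial + [v])

        for row_fill in fill(0, target, []):
            new_remaining = tuple(remaining_cols[j] - row_fill[j] for j in range(c))
            yield from rec(row + 1, new_remaining, current + [row_fill])

    yield from rec(0, tuple(col_sums), [])


def _count_enumeration(row_sums, col_sums, cap):
    """Cheap upper bound on the enumeration size (product of compositions)."""
    c = len(col_sums)
    est = 1.0
    for rs in row_sums[:-1]:
        # compositions of rs into c parts, ignoring column caps
        est *= math.comb(rs + c - 1, c - 1)
        if est > cap:
            return cap + 1
    return est


def categorical_homogeneity(table, force_exact=None, rng_seed=_FFH_MC_SEED):
    """Homogeneity test for an r x c contingency table of counts.

    Pearson chi-square is used when every expected count is >= 5; otherwise
    the Fisher-Freeman-Halton exact test (probability-ordering p-value under
    the multivariate hypergeometric null), computed by full enumeration for
    small tables and by seeded Monte Carlo (Patefield sampling of
    margin-conditioned tables) for large ones.  The path taken is recorded
    in ``method``.
    """
    tab = np.asarray(table)
    if tab.ndim != 2 or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = np.asarray(table, dtype=float)
        if np.any(tab < 0) or np.any(tab != np.round(tab)):
            raise InvalidArgumentError("table must hold non-negative integers")
        tab = tab.astype(int)
    row_sums = tab.sum(axis=1)
    col_sums = tab.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise InvalidDesignError("degenerate table: a margin contains zeros")

    chi2, _, dof, expected = sps.chi2_contingency(tab, correction=False)
    use_exact = force_exact if force_exact is not None else np.any(expected < 5)
    if not use_exact:
        p = float(sps.chi2.sf(chi2, dof))
        return ContingencyResult(method="chi-square", pvalue=p,
                                 statistic=float(chi2), dof=int(dof))

    n = int(tab.sum())
    log_row_fact = gammaln(row_sums + 1.0).sum()
    log_col_fact = gammaln(col_sums + 1.0).sum()
    log_n_fact = gammaln(n + 1.0)
    logp_obs = _log_table_prob(tab, log_row_fact, log_col_fact, log_n_fact)
    cutoff = logp_obs + 1e-7  # tolerate float noise in the ordering

    if _count_enumeration(list(row_sums), list(col_sums), _FFH_MAX_ENUM) <= _FFH_MAX_ENUM:
        total = 0.0
        count = 0
        for cand in _enumerate_tables(list(row_sums), list(col_sums)):
            count += 1
            lp = _log_table_prob(cand, log_row_fact, log_col_fact, log_n_fact)
            if lp <= cutoff:
                total += np.exp(lp)
        return ContingencyResult(method="ffh-exact", pvalue=float(min(total, 1.0)),
                                 n_tables=count)

    rng = np.random.default_rng(rng_seed)
    dist = sps.random_table(row_sums, col_sums)
    samples = dist.rvs(_FFH_MC_TABLES, method="patefield", random_state=rng)
    lps = np.array([
        _log_table_prob(s, log_row_fact, log_col_fact, log_n_fact)
        for s in samples
    ])
    hits = float(np.mean(lps <= cutoff))
    se = float(np.sqrt(hits * (1 - hits) / _FFH_MC_TABLES))
    return ContingencyResult(method="ffh-monte-carlo", pvalue=hits, mc_se=se,
                             n_tables=_FFH_MC_TABLES)


def normality_gate(values):
    """Shapiro-Wilk test documenting the (left-skewed) distribution shape.

    Returns ``(W, p)``.  Requires 3 <= n <= 5000 and non-constant data.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if not 3 <= arr.size <= 5000:
        raise InvalidArgumentError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {arr.size}")
    if np.all(arr == arr[0]):
        raise InvalidArgumentError("constant sample: W undefined")
    w, p = sps.shapiro(arr)
    return float(w), float(p)
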