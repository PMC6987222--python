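"""Cohort association statistics.

The battery used on the screening cohort and the expression cohorts:
Pearson chi-square on score-by-variable contingency tables, Mann-Whitney /
Wilcoxon rank-sum comparisons, the Kruskal-Wallis test with pairwise
rank-sum post-tests, Spearman rank correlation, positivity rates over the
ordinal 0-3 score, and the conventional significance-star annotation.

Small samples use exact enumeration (rank-sum with n1+n2 <= 10, Spearman
with n <= 9); larger samples use tie-corrected asymptotic approximations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_RANKSUM_MAX_N = 10
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    df: int | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1) and not math.isnan(self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = self.to_array()
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("grand total must be > 0")
        if len(self.row_labels) != arr.shape[0] or len(self.col_labels) != arr.shape[1]:
            raise ValueError("label lengths must match count dimensions")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @classmethod
    def from_array(
        cls,
        counts,
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=np.int64)
        rows = tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(arr.shape[0]))
        cols = tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(arr.shape[1]))
        return cls(rows, cols, tuple(tuple(int(v) for v in row) for row in arr))


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction).

    X2 = sum (O - E)^2 / E with expected counts from the row/column
    margins; df = (r-1)(c-1); upper-tail chi-square p.  No cell pooling is
    applied.  Zero row or column margins make the expectation degenerate
    and are rejected.
    """
    arr = table.to_array()
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(chi2), p_value=float(p), method="pearson-chi-square",
        n=int(arr.sum()), df=int(df),
    )


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a vs b using mid-ranks for ties."""
    n1 = len(a)
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates all C(n1+n2, n1) splits of the pooled sample; the p-value is
    the fraction of splits whose U deviates from the null mean n1*n2/2 at
    least as much as the observed U.  Handles ties naturally via mid-ranks.
    """
    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    mean_u = n1 * (n - n1) / 2
    obs_dev = abs(u_obs - mean_u)
    offset = n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mean_u) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) test.

    Uses full-enumeration exact inference when n1 + n2 <= 10, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    u = _rank_sum_u(a, b)
    if len(a) + len(b) <= EXACT_RANKSUM_MAX_N:
        p = _exact_rank_sum_p(a, b, u)
        method = "mann-whitney-exact"
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "mann-whitney-asymptotic"
    return TestResult(statistic=u, p_value=float(min(p, 1.0)), method=method,
                      n=len(a) + len(b))


def kruskal_wallis(*groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test (chi-square approximation)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical: H = 0 by definition, scipy raises instead
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis",
                          n=sum(map(len, arrays)), df=len(arrays) - 1)
    h, p = stats.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p), method="kruskal-wallis",
                      n=sum(map(len, arrays)), df=len(arrays) - 1)


def pairwise_wilcoxon(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise two-sided rank-sum tests between named groups.

    Returns one row per pair with the unadjusted p (as conventionally
    reported) alongside the Holm-adjusted p, labelled as such.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in combinations(names, 2):
        res = mann_whitney(groups[a], groups[b])
        rows.append({"group_a": a, "group_b": b, "u_statistic": res.statistic,
                     "p_unadjusted": res.p_value, "method": res.method})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_unadjusted"], method="holm")[1]
    out["adjustment"] = "holm"
    return out


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p over all n! permutations of one rank vector."""
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    hits = total = 0
    for perm in permutations(range(n)):
        rho = float(rx_c @ ry_c[list(perm)]) / denom
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation on mid-ranks.

    Exact permutation p for n <= 9, otherwise the t approximation.  A
    constant input leaves rho undefined; the result is NaN with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          method="spearman", n=len(x), note="constant input: rho undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if len(x) <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
        method = "spearman-exact"
    else:
        _, p = stats.spearmanr(x, y)
        method = "spearman-t-approx"
    return TestResult(statistic=rho, p_value=float(p), method=method, n=len(x))


def positivity_rate(scores) -> float:
    """Fraction of samples with score >= 1 (the NEAT1_2-positive rate)."""
    arr = np.asarray(scores)
    if arr.size == 0:
        raise ValueError("empty score vector")
    if not np.isin(arr, [0, 1, 2, 3]).all():
        raise ValueError("scores must be in {0, 1, 2, 3}")
    return float((arr >= 1).mean())


def star_annotation(p: float) -> str:
    """Significance stars: **** <= 1e-4, *** <= 1e-3, ** <= 0.01, * <= 0.05, else ns."""
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p <= cut:
            return stars
    return "ns"


def summarize_cohort(
    records: pd.DataFrame,
    variables: Sequence[str],
    score_col: str = "score",
) -> pd.DataFrame:
    """Variable-by-score association report (the machine twin of a
    clinicopathological characteristics table).

    For each variable, rows with a missing value for that variable are
    excluded (pairwise, never whole-cohort deletion), the variable x score
    contingency table is built over all score levels 0-3, and a Pearson
    chi-square is run.  Emits per-level counts with row percentages (1 dp)
    and the p-value (3 dp); single-level variables are skipped with a
    warning.
    """
    if records.empty:
        raise ValueError("empty cohort")
    score_levels = [0, 1, 2, 3]
    rows = []
    for var in variables:
        sub = records[[var, score_col]].dropna()
        levels = list(pd.unique(sub[var]))
        if len(levels) < 2:
            warnings.warn(f"variable {var!r} has a single level; skipped")
            continue
        ct = pd.crosstab(sub[var], sub[score_col]).reindex(
            index=levels, columns=score_levels, fill_value=0
        )
        table = ContingencyTable.from_array(
            ct.to_numpy(), [str(l) for l in levels], [str(s) for s in score_levels]
        )
        res = pearson_chi_square(table)
        for level in levels:
            counts = ct.loc[level]
            n_level = counts.sum()
            row = {"variable": var, "level": level, "n": int(n_level),
                   "chi2": round(res.statistic, 3), "df": res.df,
                   "p_value": round(res.p_value, 3)}
            for s in score_levels:
                row[f"score{s}_n"] = int(counts[s])
                row[f"score{s}_pct"] = round(100 * counts[s] / n_level, 1)
            rows.append(row)
    return pd.DataFrame(rows)
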