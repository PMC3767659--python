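"""Small-sample demographic comparisons: continuity-corrected chi-square,
rank-sum and Kruskal-Wallis tests, numerical sex ratios."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def yates_chi2(table) -> tuple[float, int, float]:
    """Chi-square test of a 2x2 table with Yates continuity correction.

    Statistic = sum over cells of (|O - E| - 0.5)^2 / E with the correction
    clamped so a cell term cannot go below zero; df = 1.  All margins must
    be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    chi2 = float((adj ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, 1, p


def _rank_sum_exact_p(ranks2: np.ndarray, n1: int, w2_obs: int) -> float:
    """Exact two-sided p for the rank sum via subset-sum DP on doubled ranks.

    ``ranks2`` are midranks times 2 (integers even with ties); counts the
    number of size-n1 subsets at each achievable doubled rank sum and
    returns 2 * min(P(W <= obs), P(W >= obs)) capped at 1.
    """
    total = int(ranks2.sum())
    # dp[k][s] = number of subsets of size k with doubled-rank sum s
    dp = [np.zeros(total + 1, dtype=float) for _ in range(n1 + 1)]
    dp[0][0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n1, len(dp) - 1), 0, -1):
            dp[k][r:] += dp[k - 1][: total + 1 - r]
    counts = dp[n1]
    n_total = counts.sum()
    p_le = counts[: w2_obs + 1].sum() / n_total
    p_ge = counts[w2_obs:].sum() / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(
    sample_a, sample_b, exact_threshold: int = 25
) -> tuple[float, float]:
    """Two-sample rank-sum test; W is the rank sum of the first sample.

    Midranks handle ties.  For combined n <= ``exact_threshold`` the p-value
    is exact (full enumeration of subset rank sums via dynamic programming);
    beyond that a normal approximation with tie correction is used, without
    continuity correction.  If every value is tied across both samples the
    p-value is 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    n1, n2 = a.size, b.size
    n = n1 + n2
    w = float(ranks[:n1].sum())
    if np.ptp(combined) == 0:
        return w, 1.0
    if n <= exact_threshold:
        ranks2 = np.round(ranks * 2).astype(int)
        w2 = int(round(w * 2))
        p = _rank_sum_exact_p(ranks2, n1, w2)
        return w, p
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (w - mu) / math.sqrt(var)
    return w, float(2 * stats.norm.sf(abs(z)))


def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(groups) - 1
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


# ---------------------------------------------------------------------------
# Nest censuses
# ---------------------------------------------------------------------------

CENSUS_COLUMNS = ("nest", "year", "queenright", "n_workers", "n_males", "n_alate_females")


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    for col in CENSUS_COLUMNS:
        if col not in census.columns:
            raise ValueError(f"census missing column {col!r}")
    counts = census[["n_workers", "n_males", "n_alate_females"]]
    if (counts < 0).any().any():
        raise ValueError("negative counts in census")
    return census


def numerical_sex_ratio(census: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-nest numerical sex ratio (females / all sexuals) plus QL/QR summary.

    Nests without adult sexuals are excluded (and absent from the per-nest
    frame).  The summary gives mean and standard error by queenright status.
    """
    census = validate_census(census)
    sexuals = census["n_males"] + census["n_alate_females"]
    kept = census[sexuals > 0].copy()
    kept["nsr"] = kept["n_alate_females"] / (kept["n_alate_females"] + kept["n_males"])
    summary = (
        kept.groupby("queenright")["nsr"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else float("nan"),
             n="count")
        .reset_index()
    )
    return kept[["nest", "year", "queenright", "nsr"]], summary


def sexuals_presence_table(census: pd.DataFrame) -> np.ndarray:
    """2x2 table (rows: queenless/queenright, cols: sexuals present/absent)."""
    census = validate_census(census)
    has_sex = (census["n_males"] + census["n_alate_females"]) > 0
    ql = ~census["queenright"].astype(bool)
    return np.array(
        [
            [int((ql & has_sex).sum()), int((ql & ~has_sex).sum())],
            [int((~ql & has_sex).sum()), int((~ql & ~has_sex).sum())],
        ]
    )
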