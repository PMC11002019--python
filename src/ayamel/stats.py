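"""Statistical toolkit for outcome analysis.

Exact contingency tests (Fisher 2x2 and its Freeman-Halton r x c
generalization, plus the chi-square test used for larger tables),
rank tests, Spearman correlation, Kaplan-Meier / log-rank survival
comparison and ROC AUC evaluation.

Conventions
-----------
* Two-sided Fisher P uses the probability-ordering definition: the sum of
  the probabilities of all margin-consistent tables whose hypergeometric
  probability does not exceed the observed one (relative tolerance 1e-7
  to absorb floating-point ties).
* Mann-Whitney U is exact (full enumeration of group assignments) when
  both groups have at most 8 observations, otherwise a tie-corrected
  normal approximation without continuity correction.
* The Kaplan-Meier median is the earliest time with S(t) <= 0.5, with no
  interpolation; it is NaN when the curve never reaches 0.5.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.special import gammaln
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact",
    "chi_square_test",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman_correlation",
    "survival_compare",
    "SurvivalComparison",
    "roc_auc",
]

#: relative tolerance when comparing table probabilities in exact tests
_PROB_RTOL = 1e-7


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise ValueError("contingency table entries must be non-negative integers")
        table = table.astype(np.int64)
    if table.sum() < 1:
        raise ValueError("contingency table grand total must be >= 1")
    return table.astype(np.int64)


def _log_table_prob(table: np.ndarray, logfact: np.ndarray) -> float:
    # log P(table | margins) = sum lg(row!) + sum lg(col!) - lg(n!) - sum lg(cell!)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    return (
        logfact[rows].sum()
        + logfact[cols].sum()
        - logfact[table.sum()]
        - logfact[table].sum()
    )


def _count_tables(rows: tuple[int, ...], cols: tuple[int, ...]) -> int:
    """Number of non-negative integer tables with the given margins."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, cols_left: tuple[int, ...]) -> int:
        if i == len(rows) - 1:
            return 1  # last row is forced
        total = 0
        # enumerate compositions of rows[i] bounded by cols_left
        def comp(j: int, rem: int, cl: tuple[int, ...], acc: int) -> int:
            if j == len(cl) - 1:
                if rem <= cl[j]:
                    new = cl[:j] + (cl[j] - rem,)
                    return rec(i + 1, new)
                return 0
            s = 0
            for v in range(min(rem, cl[j]) + 1):
                s += comp(j + 1, rem - v, cl[:j] + (cl[j] - v,) + cl[j + 1:], acc)
            return s

        total = comp(0, rows[i], cols_left, 0)
        return total

    return rec(0, cols)


def _freeman_halton(table: np.ndarray, mc_tables: int, seed: int) -> tuple[float, str]:
    rows = tuple(int(x) for x in table.sum(axis=1))
    cols = tuple(int(x) for x in table.sum(axis=0))
    n = int(table.sum())
    logfact = gammaln(np.arange(n + 1) + 1)
    obs = _log_table_prob(table, logfact)
    cutoff = obs + math.log1p(_PROB_RTOL)

    n_tables = _count_tables(rows, cols)
    if n_tables <= 2_000_000:
        r, c = table.shape
        total = 0.0

        def rec(i: int, cols_left: list[int], cells: list[list[int]]) -> None:
            nonlocal total
            if i == r - 1:
                last = cols_left
                t = np.array(cells + [last], dtype=np.int64)
                lp = _log_table_prob(t, logfact)
                if lp <= cutoff:
                    total += math.exp(lp)
                return

            def comp(j: int, rem: int, cl: list[int], rowcells: list[int]) -> None:
                if j == c - 1:
                    if rem <= cl[j]:
                        cl2 = list(cl)
                        cl2[j] -= rem
                        rec(i + 1, cl2, cells + [rowcells + [rem]])
                    return
                for v in range(min(rem, cl[j]) + 1):
                    cl2 = list(cl)
                    cl2[j] -= v
                    comp(j + 1, rem - v, cl2, rowcells + [v])

            comp(0, rows[i], cols_left, [])

        rec(0, list(cols), [])
        return min(total, 1.0), "enumeration"

    # Monte-Carlo fallback: Patefield sampling of margin-fixed tables
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(rows, cols)
    hits = 0
    done = 0
    chunk = 100_000
    while done < mc_tables:
        k = min(chunk, mc_tables - done)
        draws = sampler.rvs(size=k, random_state=rng).astype(np.int64)
        lps = (
            logfact[np.array(rows)].sum()
            + logfact[np.array(cols)].sum()
            - logfact[n]
            - logfact[draws].sum(axis=(1, 2))
        )
        hits += int(np.count_nonzero(lps <= cutoff))
        done += k
    return (hits + 1) / (mc_tables + 1), "monte-carlo"


def fisher_exact(table, *, mc_tables: int = 1_000_000, seed: int = 0) -> float:
    """Two-sided exact test of independence for an r x c contingency table.

    2x2 tables use the classical Fisher exact test; larger tables use the
    Freeman-Halton generalization by full enumeration of margin-consistent
    tables, falling back to seeded Monte-Carlo sampling (``mc_tables``
    tables) when the enumeration would exceed ~2e6 tables.

    A table with an all-zero row or column carries no evidence against
    independence; P = 1 is returned with a warning.
    """
    table = _validate_table(table)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        warnings.warn("contingency table has a zero margin; returning P = 1")
        return 1.0
    if table.shape == (2, 2):
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    p, method = _freeman_halton(table, mc_tables, seed)
    logger.debug("Freeman-Halton test computed by %s: P = %.6g", method, p)
    return float(p)


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns ``(statistic, p)``.  This is the conventional test for
    contingency tables with more than two rows or columns.
    """
    table = _validate_table(table)
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact by full enumeration of the C(n1+n2, n1) group assignments when
    both groups have <= 8 observations (valid under ties), otherwise a
    tie-corrected normal approximation.  Returns ``(U, p)`` with U the
    statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if max(n1, n2) <= 8:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        return u_obs, hits / total

    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(var)
    return u_obs, float(2.0 * sps.norm.sf(abs(z)))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square P (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical, no evidence of any kind
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation P.

    Zero variance in either variable leaves rho undefined; ``(nan, nan)``
    is returned with a warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("zero variance; Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves and the Mantel-Cox log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    chi2: float
    p_value: float


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit estimate; columns ``time`` and ``survival``."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.values, "survival": sf.iloc[:, 0].values})


def km_median(curve: pd.DataFrame) -> float:
    """Earliest time with S(t) <= 0.5; NaN if never reached."""
    hit = curve.loc[curve["survival"] <= 0.5, "time"]
    return float(hit.iloc[0]) if len(hit) else float("nan")


def survival_compare(times, events, groups, group_a, group_b) -> SurvivalComparison:
    """Compare two survival groups: KM curves, medians, log-rank chi2 and P.

    ``times`` are positive durations (months here), ``events`` binary event
    indicators, ``groups`` the per-subject group label.  Tied event times
    are handled with the standard hypergeometric variance at each distinct
    time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    masks = {g: groups == g for g in (group_a, group_b)}
    for g, m in masks.items():
        if not m.any():
            raise ValueError(f"group {g!r} is empty")

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for g, m in masks.items():
        curve = km_curve(times[m], events[m])
        curves[g] = curve
        medians[g] = km_median(curve)

    ma, mb = masks[group_a], masks[group_b]
    if events[ma].sum() == 0 and events[mb].sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        res = _lifelines_logrank(
            times[ma], times[mb],
            event_observed_A=events[ma], event_observed_B=events[mb],
        )
        chi2, p = float(res.test_statistic), float(res.p_value)
    return SurvivalComparison(curves=curves, medians=medians, chi2=chi2, p_value=p)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Area under the empirical ROC curve.

    AUC = (#{pos > neg} + 0.5 #{pos = neg}) / (n_pos * n_neg), computed
    through midranks; equals the trapezoidal area under the ROC curve and
    U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
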