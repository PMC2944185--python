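"""Shared statistical core: exact contingency tests, FDR control and survival.

Exact two-sided Fisher tests use the probability-mass criterion: the p-value
is the total probability of all tables (with the observed margins) whose
probability does not exceed that of the observed table.  A relative tolerance
guards the comparison against floating-point ordering artifacts in the tail.
Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "ContingencyTable",
    "SurvivalData",
    "KmCurve",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "bh_adjust",
    "hypergeometric_tail",
    "km_estimator",
    "logrank_test",
]

#: relative tolerance when comparing table probabilities in two-sided tests
REL_TOL = 1e-7


@dataclass
class ContingencyTable:
    """r x c nonnegative integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("contingency table counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("contingency table has zero grand total")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]


@dataclass
class SurvivalData:
    """Per-subject follow-up: time (months), event indicator and group label."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.group = np.asarray(self.group)
        if not (len(self.time) == len(self.event) == len(self.group)):
            raise ValueError("time, event and group must have equal length")
        if not np.isfinite(self.time).all():
            raise ValueError("survival times must be finite")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")


@dataclass
class KmCurve:
    """Product-limit estimate: S(t) just after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table.

    Returns ``(p_two_sided, odds_ratio)``; the odds ratio is the sample
    odds ratio ad/bc (``inf`` or ``nan`` when a margin degenerates).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    (a, b), (c, d) = t
    n = int(t.sum())
    if n == 0:
        raise ValueError("table has zero grand total")
    row1, col1 = a + b, a + c
    # X = count in cell (0,0) ~ Hypergeometric(n, col1, row1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + REL_TOL)].sum())
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return min(p, 1.0), odds


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])


def _enumerate_tables(row_rem, col_rem, lf, log_const, cells, out, row=0):
    """Recursively enumerate margin-consistent tables, collecting log-probs."""
    r = len(row_rem)
    if row == r - 1:
        # last row is determined by the column remainders
        if (col_rem < 0).any():
            return
        lp = log_const - sum(lf[v] for v in col_rem) - sum(cells)
        out.append(lp)
        return
    _fill_row(row_rem, col_rem, lf, log_const, cells, out, row, 0, row_rem[row])


def _fill_row(row_rem, col_rem, lf, log_const, cells, out, row, col, rem):
    c = len(col_rem)
    if col == c - 1:
        if rem > col_rem[col]:
            return
        col_rem2 = col_rem.copy()
        col_rem2[col] -= rem
        cells.append(lf[rem])
        _enumerate_tables(row_rem, col_rem2, lf, log_const, cells, out, row + 1)
        cells.pop()
        return
    for v in range(min(rem, col_rem[col]) + 1):
        col_rem2 = col_rem.copy()
        col_rem2[col] -= v
        cells.append(lf[v])
        _fill_row(row_rem, col_rem2, lf, log_const, cells, out, row, col + 1, rem - v)
        cells.pop()


def fisher_exact_rxc(table, max_total: int = 200) -> float:
    """Freeman-Halton exact test for an r x c table by full enumeration.

    The p-value is the total probability, under fixed margins, of all tables
    at most as probable as the observed one.  Enumeration is exhaustive, so
    the grand total is capped at ``max_total``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("expected a 2-dimensional table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    n = int(t.sum())
    if n == 0:
        raise ValueError("table has zero grand total")
    if n > max_total:
        raise ValueError(
            f"grand total {n} exceeds {max_total}; exhaustive enumeration "
            "is impractical (Monte Carlo estimation is out of scope)"
        )
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    lf = _log_factorials(n)
    log_const = (
        sum(lf[v] for v in row_sums) + sum(lf[v] for v in col_sums) - lf[n]
    )
    lp_obs = log_const - sum(lf[v] for v in t.ravel())

    out: list[float] = []
    _enumerate_tables(row_sums, col_sums.copy(), lf, log_const, [], out)
    lps = np.array(out)
    thr = lp_obs + math.log1p(REL_TOL)
    p = float(np.exp(lps[lps <= thr]).sum())
    return min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError("inconsistent hypergeometric arguments")
    if k > n:
        raise ValueError("k cannot exceed the number drawn")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def km_estimator(data: SurvivalData, group=None) -> KmCurve:
    """Kaplan-Meier product-limit curve for one group (or the pooled sample).

    Subjects censored at an event time are counted at risk at that time.  The
    median is the smallest observed time with S <= 0.5, ``None`` if the curve
    never reaches 0.5.
    """
    if group is None:
        mask = np.ones(len(data.time), dtype=bool)
    else:
        mask = data.group == group
    if mask.sum() == 0:
        raise ValueError(f"no subjects in group {group!r}")
    time, event = data.time[mask], data.event[mask]

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table
    is_event = tab["observed"].to_numpy() > 0
    times = tab.index.to_numpy(dtype=float)[is_event]
    at_risk = tab["at_risk"].to_numpy(dtype=float)[is_event]
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KmCurve(times, surv, at_risk, median)


def logrank_test(data: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square on 1 df, p-value)."""
    groups = np.unique(data.group)
    if len(groups) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(groups)}")
    m0, m1 = data.group == groups[0], data.group == groups[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("each group must contain at least one subject")
    if data.event.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = _ll_logrank(
        data.time[m0], data.time[m1],
        event_observed_A=data.event[m0], event_observed_B=data.event[m1],
    )
    return float(res.test_statistic), float(res.p_value)
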