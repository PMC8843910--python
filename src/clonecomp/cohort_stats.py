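"""First-principles cohort statistics: Fisher exact, Mann-Whitney U,
Kaplan-Meier, and the log-rank test.

These four procedures are reimplemented here rather than delegated so that
every convention is explicit and testable against independent references:

* Fisher exact (two-sided) sums hypergeometric point probabilities over all
  tables, with the observed margins, whose probability does not exceed that
  of the observed table — the probability-ordering convention used by the
  common clinical statistics packages.
* Mann-Whitney U uses midranks for ties; the two-sided p-value comes from
  exact enumeration for pooled n <= 12 and otherwise from the normal
  approximation with tie and continuity corrections.
* The Kaplan-Meier curve is the product-limit estimator with events
  processed before censorings at tied times; the median is the first event
  time at which the estimate drops to <= 0.5, or "not reached".
* The log-rank test is the standard one-degree-of-freedom statistic:
  observed-minus-expected events in one group summed over distinct event
  times, with the hypergeometric variance.

No multiple-testing correction is applied: per-variable p-values are
reported unadjusted.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import hypergeom as _hypergeom
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata

__all__ = [
    "ContingencyTable2x2",
    "SurvivalSample",
    "KMCurve",
    "NOT_REACHED",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "km_curve",
    "km_median",
    "logrank_test",
    "build_contingency",
]

#: Sentinel for a Kaplan-Meier median the curve never reaches.
NOT_REACHED = "not reached"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns are outcome levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SurvivalSample:
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be > 0, got {self.time}")


@dataclass(frozen=True)
class KMCurve:
    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.event_times) == len(self.survival) == len(self.at_risk)):
            raise ValueError("curve components must have equal length")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(self.survival, self.survival[1:])):
            raise ValueError("survival must be non-increasing")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by probability ordering.

    With margins fixed, the count in the (1,1) cell follows a
    hypergeometric distribution; the p-value sums the point probabilities
    of every table at least as extreme (probability <= observed, with a
    1e-7 relative tolerance for floating-point ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, table.total
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        warnings.warn("degenerate 2x2 table (zero margin): p = 1", stacklevel=2)
        return 1.0
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom.pmf(support, n, row1, col1)
    p_obs = _hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    if p >= 1.0 - 1e-9:
        return 1.0
    return p


def _mwu_exact_p(u_obs: float, ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided p by enumerating all assignments of pooled midranks."""
    n = len(ranks)
    base = n1 * (n1 + 1) / 2.0
    u_all = []
    for idx in itertools.combinations(range(n), n1):
        r1 = sum(ranks[i] for i in idx)
        u_all.append(r1 - base)
    u_all = np.asarray(u_all)
    n2 = n - n1
    mu = n1 * n2 / 2.0
    # two-sided: tables at least as far from the mean as observed
    dev = abs(u_obs - mu)
    p = float(np.mean(np.abs(u_all - mu) >= dev - 1e-9))
    return min(p, 1.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= 12:
        return float(u), _mwu_exact_p(u, ranks, n1)

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)  # continuity correction
    p = 2.0 * _norm.sf(max(z, 0.0))
    return float(u), float(min(p, 1.0))


def km_curve(samples: Sequence[SurvivalSample]) -> KMCurve:
    """Product-limit survival estimate.

    Censored observations tied with event times remain at risk at that
    time: events are processed first.
    """
    if not samples:
        raise ValueError("need at least one sample")
    times = np.array([s.time for s in samples])
    events = np.array([s.event for s in samples], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times, survival, at_risk = [], [], []
    s = 1.0
    n_total = len(times)
    i = 0
    while i < n_total:
        t = times[i]
        j = i
        d = 0
        while j < n_total and times[j] == t:
            d += int(events[j])
            j += 1
        n_at_risk = n_total - i
        if d > 0:
            s *= 1.0 - d / n_at_risk
            event_times.append(float(t))
            survival.append(s)
            at_risk.append(n_at_risk)
        i = j
    return KMCurve(tuple(event_times), tuple(survival), tuple(at_risk))


def km_median(curve: KMCurve) -> float | str:
    """Smallest event time with S(t) <= 0.5, or :data:`NOT_REACHED`."""
    for t, s in zip(curve.event_times, curve.survival):
        if s <= 0.5 + 1e-12:
            return t
    return NOT_REACHED


def logrank_test(group_a: Sequence[SurvivalSample],
                 group_b: Sequence[SurvivalSample]) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi-square, p-value)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    times = np.array([s.time for s in group_a] + [s.time for s in group_b])
    events = np.array([s.event for s in group_a] + [s.event for s in group_b],
                      dtype=bool)
    in_a = np.zeros(len(times), dtype=bool)
    in_a[:len(group_a)] = True
    if not events.any():
        raise ValueError("log-rank undefined with zero events")

    event_times = np.unique(times[events])
    sorted_all = np.sort(times)
    sorted_a = np.sort(times[in_a])
    n_at_risk = len(times) - np.searchsorted(sorted_all, event_times, side="left")
    na_at_risk = in_a.sum() - np.searchsorted(sorted_a, event_times, side="left")
    ev_all = np.sort(times[events])
    ev_a = np.sort(times[events & in_a])
    d = (np.searchsorted(ev_all, event_times, side="right")
         - np.searchsorted(ev_all, event_times, side="left"))
    d_a = (np.searchsorted(ev_a, event_times, side="right")
           - np.searchsorted(ev_a, event_times, side="left"))
    frac_a = na_at_risk / n_at_risk
    o_minus_e = float(np.sum(d_a - d * frac_a))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac_a * (1 - frac_a) * (n_at_risk - d) / (n_at_risk - 1)
    var = float(np.sum(v[n_at_risk > 1]))
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(_chi2.sf(chi2, df=1))
    return float(chi2), p


def build_contingency(patients: pd.DataFrame, group_field: str,
                      outcome_field: str) -> ContingencyTable2x2:
    """2x2 counts by (group, outcome) from a patient table.

    Rows with a missing value in either field are dropped (the count is
    reported via warning); patients whose CC class is undetermined must be
    excluded by the caller before tabulating.
    """
    sub = patients[[group_field, outcome_field]]
    n_missing = int(sub.isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} patient(s) with missing values",
                      stacklevel=2)
        sub = sub.dropna()
    if sub.empty:
        raise ValueError("no patients to tabulate")
    g_levels = sorted(sub[group_field].unique())
    o_levels = sorted(sub[outcome_field].unique())
    if len(g_levels) > 2 or len(o_levels) > 2:
        raise ValueError("both fields must be binary")
    counts = np.zeros((2, 2), dtype=int)
    for i, g in enumerate(g_levels):
        for j, o in enumerate(o_levels):
            counts[i, j] = int(((sub[group_field] == g)
                                & (sub[outcome_field] == o)).sum())
    return ContingencyTable2x2(int(counts[0, 0]), int(counts[0, 1]),
                               int(counts[1, 0]), int(counts[1, 1]))
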