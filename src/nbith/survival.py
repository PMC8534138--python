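"""Survival and frequency statistics: product-limit estimator, Mantel–Cox
log-rank test, Pearson chi-squared, and the quartile comparison of SCA
burden.

These are implemented from first principles (the estimators and test
statistics are written out, with scipy supplying only the chi-squared tail
probability) so that every quantity entering the heterogeneity–survival
analysis is auditable; established survival libraries serve as independent
cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "survival_at",
    "logrank",
    "logrank_from_arrays",
    "pearson_chi2",
    "sca_quartile_test",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Event-free and overall survival of one case.

    ``efs_event`` is relapse/progression/death; ``os_event`` is death.
    Times are months from diagnosis.
    """

    case_id: str
    efs_months: float
    efs_event: bool
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.efs_months < 0 or self.os_months < 0:
            raise ValueError(f"case {self.case_id}: negative survival time")

    def endpoint(self, which: str) -> tuple[float, bool]:
        if which == "efs":
            return self.efs_months, self.efs_event
        if which == "os":
            return self.os_months, self.os_event
        raise ValueError(f"endpoint must be 'efs' or 'os', got {which!r}")


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier step function: S(t) right-continuous, S(0) = 1."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # subjects at risk at each event time
    n_events: np.ndarray  # events at each event time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        if self.survival.size and not (
            0 <= self.survival.min() and self.survival.max() <= 1
        ):
            raise ValueError("survival probabilities must lie in [0, 1]")


def km_estimate(records: list[SurvivalRecord], endpoint: str = "os") -> KMCurve:
    """Product-limit estimator with right censoring.

    At tied times, events are processed before censorings (a subject
    censored at t is still at risk for an event at t).
    """
    if not records:
        raise ValueError("no survival records")
    pairs = [r.endpoint(endpoint) for r in records]
    return _km_from_arrays(
        np.array([t for t, _ in pairs], dtype=float),
        np.array([e for _, e in pairs], dtype=bool),
    )


def _km_from_arrays(times: np.ndarray, events: np.ndarray) -> KMCurve:
    if np.any(times < 0):
        raise ValueError("negative survival time")
    event_times = np.unique(times[events])
    n = len(times)
    s = 1.0
    surv, risk, nev = [], [], []
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / at_risk
        surv.append(s)
        risk.append(at_risk)
        nev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(risk),
        n_events=np.array(nev),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Step-function value S(t), right-continuous."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p_value: float | None  # None when no events in the pooled sample
    observed: tuple[float, float] = (0.0, 0.0)
    expected: tuple[float, float] = (0.0, 0.0)


def logrank(
    a: list[SurvivalRecord],
    b: list[SurvivalRecord],
    endpoint: str = "os",
) -> LogRankResult:
    """Mantel–Cox (unweighted) log-rank test between two groups."""
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    ta, ea = zip(*(r.endpoint(endpoint) for r in a))
    tb, eb = zip(*(r.endpoint(endpoint) for r in b))
    return logrank_from_arrays(
        np.array(ta, float), np.array(ea, bool), np.array(tb, float), np.array(eb, bool)
    )


def logrank_from_arrays(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> LogRankResult:
    """O - E over pooled event times with hypergeometric variance."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b]).astype(bool)
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])

    event_times = np.unique(times[events])
    if event_times.size == 0:
        warnings.warn("no events in pooled sample; log-rank p undefined",
                      stacklevel=2)
        return LogRankResult(0.0, 1, None)

    o_minus_e = 0.0
    var = 0.0
    obs_a = exp_a = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & (group == 0)).sum()
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        obs_a += d_a
        exp_a += e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    total_d = int(events.sum())
    if var == 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi2=float(chi2),
        df=1,
        p_value=p,
        observed=(obs_a, total_d - obs_a),
        expected=(exp_a, total_d - exp_a),
    )


def pearson_chi2(
    table: np.ndarray, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Zero marginal rows/columns are dropped with a warning.  The optional
    Yates continuity correction applies to 2x2 tables only.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("table must contain non-negative integers")

    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero marginal rows/columns", stacklevel=2)
        table = table[row_ok][:, col_ok]
        if table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError("table degenerate after dropping zero margins")

    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    resid = np.abs(table - expected)
    if continuity_correction and table.shape == (2, 2):
        resid = np.maximum(resid - 0.5, 0.0)
    statistic = float((resid**2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df=df))
    return statistic, df, p


def sca_quartile_test(
    cases: list[tuple[str, int]]
) -> tuple[float, int, float]:
    """Compare SCA-burden distributions between groups by quartile binning.

    Counts are binned at the cohort-wide empirical quartiles (values equal
    to a boundary go to the lower bin) and a Pearson chi-squared test is
    run on the group x quartile table.  With fewer than four distinct
    counts the binning degenerates to distinct-value bins (with a warning).
    """
    if not cases:
        raise ValueError("no cases")
    groups = sorted({g for g, _ in cases})
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.array([c for _, c in cases], dtype=float)

    distinct = np.unique(counts)
    if distinct.size < 4:
        warnings.warn(
            "fewer than 4 distinct counts; using distinct-value bins",
            stacklevel=2,
        )
        boundaries = distinct[:-1]
    else:
        boundaries = np.quantile(counts, [0.25, 0.5, 0.75])
        boundaries = np.unique(boundaries)

    def bin_of(x: float) -> int:
        # ties to the lower bin: bin = number of boundaries strictly below x
        return int(np.sum(boundaries < x))

    n_bins = len(boundaries) + 1
    table = np.zeros((len(groups), n_bins), dtype=int)
    for g, c in cases:
        table[groups.index(g), bin_of(c)] += 1
    return pearson_chi2(table)
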