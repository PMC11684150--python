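"""Kaplan–Meier estimation and two-sample survival tests.

Product-limit estimation, risk tables and restricted mean survival time are
delegated to lifelines; Greenwood variance and the Brookmeyer–Crowley-style
median confidence interval (inversion of the complementary-log-log pointwise
band) are computed from the risk table. Two-sample tests are the log-rank
(Mantel–Haenszel) test and the Gehan–Wilcoxon test with the Peto–Peto
approximation (weights equal to the left-continuous pooled KM estimate),
both as 1-df chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import survival_table_from_events
from scipy import stats


@dataclass
class KMEstimate:
    event_times: np.ndarray  # distinct observed times (events and censorings)
    survival: np.ndarray  # S(t) step values at event_times
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_variance: np.ndarray
    median: Optional[float]
    median_ci: tuple = (None, None)
    rmst: Optional[dict] = None  # {"value", "horizon", "ci"}
    n: int = 0

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step evaluation of S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out


@dataclass
class TestResult:
    method: str  # "LOGRANK" | "GEHAN_WILCOXON_PETO"
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0,1]")
        if self.statistic < 0:
            raise ValueError("statistic must be >= 0")


def km_estimate(durations, events, rmst_horizon=None, alpha: float = 0.05) -> KMEstimate:
    """Kaplan–Meier estimate with Greenwood variance, median (and CI), RMST.

    The median is the first time at which S(t) <= 0.5 (undefined if never
    reached); RMST integrates the KM step function to ``rmst_horizon``
    (default: largest observed time).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValueError("km_estimate requires at least one sample")

    kmf = KaplanMeierFitter()
    kmf.fit(durations, events, alpha=alpha)
    table = survival_table_from_events(durations, events)
    if 0.0 in table.index and table.loc[0.0, "removed"] == 0:
        table = table.drop(index=0.0)  # lifelines pads an empty t=0 row

    times = table.index.values.astype(float)
    d = table["observed"].values.astype(float)
    n_at_risk = table["at_risk"].values.astype(float)
    surv = np.asarray(kmf.survival_function_at_times(times), dtype=float)

    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    gw = surv ** 2 * np.cumsum(inc)

    median = float(kmf.median_survival_time_) if np.isfinite(kmf.median_survival_time_) else None
    median_ci = _median_ci(times, surv, gw, alpha)

    horizon = float(rmst_horizon) if rmst_horizon is not None else float(durations.max())
    rmst_val, rmst_var = _rmst_step(times, surv, d, n_at_risk, horizon)
    z = stats.norm.isf(alpha / 2.0)
    se = float(np.sqrt(max(rmst_var, 0.0)))
    rmst = {
        "value": float(rmst_val),
        "horizon": horizon,
        "ci": (float(rmst_val - z * se), float(rmst_val + z * se)),
    }

    return KMEstimate(
        event_times=times,
        survival=surv,
        at_risk=n_at_risk,
        events=d,
        greenwood_variance=gw,
        median=median,
        median_ci=median_ci,
        rmst=rmst,
        n=int(durations.size),
    )


def _rmst_step(times, surv, d, n_at_risk, tau):
    """Exact integral of the KM step function to tau, with the standard
    asymptotic variance (area-from-t-to-tau form of Greenwood)."""
    knots = np.concatenate([[0.0], times[times < tau], [tau]])
    steps = np.concatenate([[1.0], surv[times < tau]])
    area = float(np.sum(steps * np.diff(knots)))
    # variance: sum over event times t_i < tau of A(t_i)^2 d_i/(n_i (n_i-d_i))
    var = 0.0
    mask = (times < tau) & (d > 0)
    for t_i, d_i, n_i in zip(times[mask], d[mask], n_at_risk[mask]):
        k = np.concatenate([[t_i], times[(times > t_i) & (times < tau)], [tau]])
        s = np.concatenate([surv[times == t_i], surv[(times > t_i) & (times < tau)]])
        a_i = float(np.sum(s * np.diff(k)))
        if n_i > d_i:
            var += a_i ** 2 * d_i / (n_i * (n_i - d_i))
    return area, var


def _median_ci(times, surv, gw_var, alpha):
    """Invert the complementary-log-log pointwise band at S = 0.5."""
    z = stats.norm.isf(alpha / 2.0)
    lo = hi = None
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.log(-np.log(np.clip(surv, 1e-12, 1 - 1e-12)))
        se = np.sqrt(gw_var) / np.abs(np.clip(surv, 1e-12, None) * np.log(np.clip(surv, 1e-12, 1 - 1e-12)))
        upper = np.exp(-np.exp(logm - z * se))  # upper survival band
        lower = np.exp(-np.exp(logm + z * se))
    below = times[lower <= 0.5]
    lo = float(below[0]) if below.size else None
    below = times[upper <= 0.5]
    hi = float(below[0]) if below.size else None
    # lower band crosses first: it gives the lower confidence limit
    return (lo, hi)


def two_sample_test(durations_a, events_a, durations_b, events_b, method: str = "LOGRANK") -> TestResult:
    """Two-sample test between arms.

    ``method="LOGRANK"`` is the Mantel–Haenszel log-rank test (unit
    weights); ``method="GEHAN_WILCOXON_PETO"`` applies Peto–Peto weights
    (left-continuous pooled KM), the censoring-robust form of the
    Gehan–Wilcoxon test. If there are no events in either group the
    statistic is 0 and p = 1.
    """
    method = method.upper()
    if method not in ("LOGRANK", "GEHAN_WILCOXON_PETO"):
        raise ValueError("method must be 'LOGRANK' or 'GEHAN_WILCOXON_PETO'")
    durations_a = np.asarray(durations_a, dtype=float)
    durations_b = np.asarray(durations_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if durations_a.size == 0 or durations_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        return TestResult(method=method, statistic=0.0, df=1, p_value=1.0)

    weightings = None if method == "LOGRANK" else "peto"
    res = logrank_test(
        durations_a, durations_b, events_a, events_b, weightings=weightings
    )
    stat = float(res.test_statistic)
    if not np.isfinite(stat) or stat < 0:
        stat = 0.0
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(method=method, statistic=stat, df=1, p_value=p)


def km_to_frame(est: KMEstimate) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": est.event_times,
            "survival": est.survival,
            "at_risk": est.at_risk,
            "events": est.events,
            "greenwood_variance": est.greenwood_variance,
        }
    )


def plot_km_overlay(estimates: dict, ax=None, title: str = ""):
    """Step-plot several KM estimates (one per arm) on one axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for label, est in estimates.items():
        x = np.concatenate([[0.0], est.event_times])
        y = np.concatenate([[1.0], est.survival])
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel("weeks")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
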