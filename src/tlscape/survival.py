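"""Median-cutoff stratification, Kaplan–Meier curves, log-rank tests and
univariate Cox proportional-hazards fits.

Conventions, declared once: median ties go to the High group (value >=
median); at tied times events precede censorings (the standard product-limit
convention); Cox uses Efron tie handling with Wald p-values and
normal-approximation 95% confidence intervals. Estimation is delegated to
lifelines behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMCurve:
    """Product-limit survival curve. ``times`` are the sorted observed times
    (events and censorings), ``survival`` the step values after each time;
    S(0) = 1 is implicit."""

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "events": self.n_events, "censored": self.n_censored,
                             "survival": self.survival})


@dataclass
class CoxFit:
    covariate: str
    log_hr: float
    se: float
    hr: float
    ci95_lo: float
    ci95_hi: float
    p: float
    n: int
    n_events: int


def median_stratify(values) -> pd.Series:
    """Split samples at the median into ``Hi`` (value >= median, ties high)
    and ``Lo`` groups. ``values``: mapping or Series sample -> value."""
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if s.nunique() == 1:
        raise ValueError("all values identical: median stratification undefined")
    med = float(np.median(s.to_numpy()))
    return pd.Series(np.where(s.to_numpy() >= med, "Hi", "Lo"), index=s.index)


def _check_records(df: pd.DataFrame):
    if len(df) == 0:
        raise ValueError("no records")
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier product-limit estimate from a records frame with
    ``time_months`` and ``event`` columns."""
    _check_records(records)
    kmf = KaplanMeierFitter().fit(records["time_months"], records["event"])
    tbl = kmf.event_table.drop(index=0.0, errors="ignore")
    times = tbl.index.to_numpy(dtype=float)
    surv = np.array([kmf.predict(t) for t in times], dtype=float)
    return KMCurve(times=times,
                   at_risk=tbl["at_risk"].to_numpy(dtype=int),
                   n_events=tbl["observed"].to_numpy(dtype=int),
                   n_censored=tbl["censored"].to_numpy(dtype=int),
                   survival=surv)


def logrank_test(groups: list[pd.DataFrame]) -> dict:
    """K-sample log-rank test (observed − expected under the hypergeometric
    at each event time). Returns {"chi2", "df", "p"}."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    df = pd.concat(
        [g.assign(_group=i) for i, g in enumerate(groups)], ignore_index=True)
    _check_records(df)
    if df["event"].sum() == 0:
        raise ValueError("no events in any group: log-rank undefined")
    res = multivariate_logrank_test(df["time_months"], df["_group"], df["event"])
    return {"chi2": float(res.test_statistic), "df": len(groups) - 1,
            "p": float(res.p_value)}


def cox_univariate(records: pd.DataFrame, covariate: str) -> CoxFit:
    """Univariate Cox proportional-hazards fit (Efron ties, Newton solver).

    Raises on a constant covariate and on non-convergence / monotone
    partial likelihood (perfect separation).
    """
    _check_records(records)
    if covariate not in records.columns:
        raise ValueError(f"covariate {covariate!r} not in records")
    x = records[covariate].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant across records")
    df = records[["time_months", "event", covariate]]
    try:
        cph = CoxPHFitter().fit(df, duration_col="time_months", event_col="event")
    except ConvergenceError as e:
        raise ValueError(f"Cox fit failed to converge for {covariate!r}: {e}") from e
    log_hr = float(cph.params_[covariate])
    se = float(cph.standard_errors_[covariate])
    if not np.isfinite(log_hr) or not np.isfinite(se) or abs(log_hr) > 20 or se > 100:
        raise ValueError(
            f"monotone partial likelihood (perfect separation?) for {covariate!r}: "
            f"log HR {log_hr:.3g}, se {se:.3g}")
    return CoxFit(covariate=covariate, log_hr=log_hr, se=se,
                  hr=float(np.exp(log_hr)),
                  ci95_lo=float(np.exp(log_hr - 1.959963984540054 * se)),
                  ci95_hi=float(np.exp(log_hr + 1.959963984540054 * se)),
                  p=float(cph.summary.loc[covariate, "p"]),
                  n=int(len(df)), n_events=int(df["event"].sum()))
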