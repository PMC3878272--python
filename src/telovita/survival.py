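"""Left-truncated Kaplan-Meier estimation and the two-group logrank test.

Fish enter observation only at the truncation age (3 months by default:
pre-maturation mortality is unobservable), so every risk set excludes
individuals before their entry age: the risk set at time t is
``{records with entry < t <= exit}``.  At tied times deaths are processed
before censorings.  Pointwise confidence bands use the Greenwood variance
on the complementary log-log scale, which keeps them inside [0, 1];
the median and its confidence interval are read off the curve and its
bands at the first crossing of S = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import TelovitaError


@dataclass
class CohortRecord:
    """One fish's observation window: (entry, exit] and death indicator."""

    id: int
    sex: str
    entry_age: float
    exit_age: float
    event: bool

    def __post_init__(self):
        if not self.exit_age > self.entry_age >= 0:
            raise TelovitaError(
                f"record {self.id}: need exit > entry >= 0, got "
                f"({self.entry_age}, {self.exit_age})"
            )


def _as_arrays(records):
    """Accept a list of CohortRecord or a cohort DataFrame."""
    if isinstance(records, pd.DataFrame):
        entry = records["entry_age_months"].to_numpy(dtype=float)
        exit_ = records["exit_age_months"].to_numpy(dtype=float)
        event = records["event"].to_numpy(dtype=bool)
    else:
        entry = np.array([r.entry_age for r in records], dtype=float)
        exit_ = np.array([r.exit_age for r in records], dtype=float)
        event = np.array([r.event for r in records], dtype=bool)
    if entry.size == 0:
        raise TelovitaError("no records")
    if np.any(exit_ <= entry):
        raise TelovitaError("every record needs exit > entry")
    return entry, exit_, event


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit step function with Greenwood bands."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    anchor: float  # earliest entry age; S = 1 before the first event
    n_records: int

    def survival_at(self, t, band=None):
        """Step-function evaluation; ``band`` selects 'lower'/'upper' CI."""
        y = {None: self.survival, "lower": self.ci_lower, "upper": self.ci_upper}[band]
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:  # no events anywhere: S = 1
            out = np.ones_like(t)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, y[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def to_frame(self):
        return pd.DataFrame(
            {
                "time": self.times,
                "s": self.survival,
                "lo": self.ci_lower,
                "hi": self.ci_upper,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


@dataclass
class MedianEstimate:
    median: float
    ci_lower: float
    ci_upper: float
    defined: bool


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    n: int
    p_value: float


def _risk_and_events(entry, exit_, event, times):
    """At-risk counts just before each time and death counts at each time."""
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    # risk set at t: entry < t and exit >= t  (deaths at t still at risk)
    n_entered = np.searchsorted(entry_sorted, times, side="left")
    n_left = np.searchsorted(exit_sorted, times, side="left")
    at_risk = n_entered - n_left
    death_times = np.sort(exit_[event])
    d = np.searchsorted(death_times, times, side="right") - np.searchsorted(
        death_times, times, side="left"
    )
    return at_risk, d


def km_estimate(records, alpha=0.05):
    """Product-limit estimator with truncation-aware risk sets."""
    entry, exit_, event = _as_arrays(records)
    times = np.unique(exit_[event])
    anchor = float(entry.min())
    if times.size == 0:
        return SurvivalCurve(
            times=np.array([]), survival=np.array([]),
            ci_lower=np.array([]), ci_upper=np.array([]),
            at_risk=np.array([], dtype=int), n_events=np.array([], dtype=int),
            anchor=anchor, n_records=int(entry.size),
        )
    at_risk, d = _risk_and_events(entry, exit_, event, times)
    if np.any(at_risk <= 0):
        raise TelovitaError("empty risk set at an event time")
    frac = 1.0 - d / at_risk
    survival = np.cumprod(frac)

    # Greenwood on the log scale, transformed to log(-log S)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = np.cumsum(
            np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        )
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        log_s = np.log(survival)
        se_cll = np.sqrt(var_log) / np.abs(log_s)
        lower = survival ** np.exp(z * se_cll)
        upper = survival ** np.exp(-z * se_cll)
    zero = survival <= 0.0
    lower[zero] = 0.0
    upper[zero] = 0.0
    one = np.isclose(survival, 1.0)
    lower[one] = survival[one]
    upper[one] = survival[one]
    return SurvivalCurve(
        times=times, survival=survival, ci_lower=lower, ci_upper=upper,
        at_risk=at_risk.astype(int), n_events=d.astype(int),
        anchor=anchor, n_records=int(entry.size),
    )


def km_median(curve):
    """Smallest t with S(t) <= 0.5, with CI from the band crossings."""

    def first_crossing(y):
        idx = np.nonzero(y <= 0.5)[0]
        return float(curve.times[idx[0]]) if idx.size else np.nan

    if curve.times.size == 0:
        return MedianEstimate(np.nan, np.nan, np.nan, defined=False)
    med = first_crossing(curve.survival)
    # upper band crosses 0.5 latest -> upper confidence limit for the median
    lo = first_crossing(curve.ci_upper)
    hi = first_crossing(curve.ci_lower)
    if np.isnan(med):
        return MedianEstimate(np.nan, np.nan, np.nan, defined=False)
    return MedianEstimate(median=med, ci_lower=min(lo, hi), ci_upper=max(lo, hi),
                          defined=True)


def logrank_test(group_a, group_b):
    """Two-group logrank test with left-truncation-aware risk sets."""
    ea, xa, va = _as_arrays(group_a)
    eb, xb, vb = _as_arrays(group_b)
    if va.sum() + vb.sum() == 0:
        raise TelovitaError("logrank undefined: no events in either group")
    times = np.unique(np.concatenate([xa[va], xb[vb]]))
    na, da = _risk_and_events(ea, xa, va, times)
    nb, db = _risk_and_events(eb, xb, vb, times)
    n = na + nb
    d = da + db
    keep = n > 1
    na, nb, n, da, d = na[keep], nb[keep], n[keep], da[keep], d[keep]
    expected = d * na / n
    variance = d * (na / n) * (nb / n) * (n - d) / (n - 1)
    v = variance.sum()
    if v <= 0:
        raise TelovitaError("logrank undefined: zero variance")
    chi2 = float((da.sum() - expected.sum()) ** 2 / v)
    p = float(sps.chi2.sf(chi2, df=1))
    return LogrankResult(chi_square=chi2, df=1, n=int(ea.size + eb.size), p_value=p)
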