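"""Asymptotic exponential decay of mean TRF with age.

Model:  TRF(t) = plateau + (TRF0 - plateau) * exp(-lambda * t)

fitted per organ x sex by nonlinear least squares with a self-starting
rule: the plateau starts at the smallest observed TRF, TRF0 at the value
observed at the earliest age, and lambda at the slope of a log-linear
regression of (TRF - min TRF + eps) on age.  The rate-constant confidence
interval is the linearised (asymptotic) Wald interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitConvergenceError, TelovitaError


@dataclass
class OrganTelomerePanel:
    """Replicate (age, TRF) observations for one organ of one sex."""

    organ: str
    sex: str
    ages: np.ndarray  # months, one per replicate observation
    trf: np.ndarray  # bp

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.trf = np.asarray(self.trf, dtype=float)
        if self.ages.size != self.trf.size:
            raise TelovitaError("ages and trf must pair up")
        if np.any(self.ages <= 0) or np.any(self.trf <= 0):
            raise TelovitaError("ages and TRF values must be positive")
        if np.unique(self.ages).size < 3:
            raise TelovitaError("need >= 3 distinct ages to fit the decay model")

    @classmethod
    def from_frame(cls, frame, organ, sex):
        sub = frame[(frame["organ"] == organ) & (frame["sex"] == sex)]
        return cls(organ=organ, sex=sex, ages=sub["age"].to_numpy(),
                   trf=sub["trf_bp"].to_numpy())

    def summarize(self):
        """Per-age mean, SEM and n."""
        df = pd.DataFrame({"age": self.ages, "trf": self.trf})
        g = df.groupby("age")["trf"]
        return pd.DataFrame(
            {"mean": g.mean(), "sem": g.sem(), "n": g.size()}
        ).reset_index()


@dataclass
class DecayFit:
    trf0: float  # bp, extrapolated initial mean TRF
    plateau: float  # bp, horizontal asymptote
    lam: float  # per-month rate constant
    se_lam: float
    ci_lam: tuple
    r_squared: float  # against replicate observations
    r_squared_means: float  # against per-age means (figure convention)
    residuals: np.ndarray = field(repr=False)
    converged: bool = True
    organ: str = ""
    sex: str = ""

    def ci_lam_scaled(self, months_per_unit=12.0):
        """Rate CI rescaled to another time unit (default per-year)."""
        return tuple(v * months_per_unit for v in self.ci_lam)


def _model(t, trf0, plateau, lam):
    return plateau + (trf0 - plateau) * np.exp(-lam * t)


def _self_start(ages, trf):
    p_plateau = float(trf.min())
    p_trf0 = float(trf[np.argmin(ages)])
    shifted = trf - trf.min() + 1e-6
    slope = np.polyfit(ages, np.log(shifted), 1)[0]
    p_lam = max(-slope, 1e-3)
    return p_trf0, p_plateau, p_lam


def fit_decay(panel, weights=None, n_restarts=5, seed=0):
    """Fit the asymptotic decay model to an :class:`OrganTelomerePanel`.

    ``weights='inverse_sem2'`` performs inverse-variance weighting with the
    per-age SEM; the default is unweighted.  After ``n_restarts`` jittered
    restarts a :class:`FitConvergenceError` carrying the best partial fit
    is raised.
    """
    ages, trf = panel.ages, panel.trf
    sigma = None
    if weights == "inverse_sem2":
        summary = panel.summarize().set_index("age")
        sem = summary["sem"].reindex(ages).to_numpy()
        if np.any(~np.isfinite(sem)) or np.any(sem <= 0):
            raise TelovitaError("SEM weights unavailable (need >= 2 replicates per age)")
        sigma = sem
    p0 = _self_start(ages, trf)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else tuple(
            max(p * rng.uniform(0.6, 1.5), 1e-5) for p in p0
        )
        try:
            popt, pcov = curve_fit(
                _model, ages, trf, p0=start, sigma=sigma, maxfev=20000,
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 10.0]),
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((trf - _model(ages, *popt)) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitConvergenceError("decay fit failed after all restarts")
    popt, pcov, sse = best
    trf0, plateau, lam = (float(v) for v in popt)
    if lam < 0:  # mirror into the equivalent growing parameterisation check
        warnings.warn("fitted rate constant is negative (monotonicity violated)",
                      stacklevel=2)
    if plateau >= trf0:
        warnings.warn("fitted plateau >= TRF0 (monotonicity violated)", stacklevel=2)
    se_lam = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    ci = (lam - 1.959963984540054 * se_lam, lam + 1.959963984540054 * se_lam)
    resid = trf - _model(ages, *popt)
    sst = float(np.sum((trf - trf.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    means = panel.summarize()
    pred_means = _model(means["age"].to_numpy(), *popt)
    sse_m = float(np.sum((means["mean"].to_numpy() - pred_means) ** 2))
    sst_m = float(np.sum((means["mean"] - means["mean"].mean()) ** 2))
    r2_m = 1.0 - sse_m / sst_m if sst_m > 0 else np.nan
    return DecayFit(
        trf0=trf0, plateau=plateau, lam=lam, se_lam=se_lam, ci_lam=ci,
        r_squared=r2, r_squared_means=r2_m, residuals=resid,
        organ=panel.organ, sex=panel.sex,
    )


@dataclass
class RateComparison:
    ci_a: tuple
    ci_b: tuple
    overlap: bool
    difference: float  # lam_a - lam_b
    ci_difference: tuple

    @property
    def significantly_different(self):
        """CI-overlap criterion: disjoint rate CIs."""
        return not self.overlap


def compare_rates(fit_a, fit_b):
    """Compare two attrition rate constants by CI overlap and a Wald CI on
    their difference."""
    lo_a, hi_a = fit_a.ci_lam
    lo_b, hi_b = fit_b.ci_lam
    overlap = (lo_a <= hi_b) and (lo_b <= hi_a)
    diff = fit_a.lam - fit_b.lam
    se = float(np.hypot(fit_a.se_lam, fit_b.se_lam))
    z = 1.959963984540054
    return RateComparison(
        ci_a=(lo_a, hi_a), ci_b=(lo_b, hi_b), overlap=overlap,
        difference=diff, ci_difference=(diff - z * se, diff + z * se),
    )


def predict_trf(fit, age):
    """Modeled mean TRF at ``age`` months (monotone, -> plateau)."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise TelovitaError("age must be non-negative")
    out = _model(age, fit.trf0, fit.plateau, fit.lam)
    return out if out.ndim else float(out)
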