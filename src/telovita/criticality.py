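"""Critical hepatic telomere length from the survival-vs-TRF relation.

Age-group Kaplan-Meier survival probabilities are paired with the mean
liver TRF of fish sampled at the same ages (cross-sectional pooling: the
same fish cannot be followed, since TRF measurement is destructive).  An
ordinary least-squares line S = intercept + slope * TRF is fitted through
the pairs and extrapolated to S = 0; the TRF at that point,
L_crit = -intercept / slope, is the critical telomere length below which
organismal survival is predicted to vanish.  The extrapolation necessarily
leaves the observed TRF range, so a flag is always attached; uncertainty
comes from a nonparametric bootstrap that resamples fish and panel
replicates jointly and refits the whole chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidModelError, PairingError
from .survival import km_estimate

PAIRING_COLUMNS = ["age", "survival", "surv_lo", "surv_hi",
                   "mean_trf", "sem_trf", "n_replicates", "sex"]


def build_pairing(curve, panel, ages, sex="pooled"):
    """Pair S(age) from a KM curve with mean liver TRF(age) from a panel.

    ``panel`` holds replicate rows with columns (age, trf_bp) for one sex
    (liver only).  Ages missing from the panel raise a PairingError; ages
    at or before the curve's anchor (entry) age are excluded with a
    warning, since S is undefined there.
    """
    if "organ" in panel.columns:
        organs = set(panel["organ"].unique())
        if organs != {"liver"}:
            raise PairingError(f"pairing requires a liver panel, got {sorted(organs)}")
    ages = list(ages)
    missing = [a for a in ages if not (panel["age"] == a).any()]
    if missing:
        raise PairingError(f"ages missing from the TRF panel: {missing}")
    rows = []
    for age in ages:
        if age <= curve.anchor:
            warnings.warn(
                f"age {age} precedes the entry age {curve.anchor}; survival is "
                "undefined there and the age is excluded", stacklevel=2)
            continue
        reps = panel.loc[panel["age"] == age, "trf_bp"].to_numpy(dtype=float)
        rows.append((
            age,
            curve.survival_at(age),
            curve.survival_at(age, band="lower"),
            curve.survival_at(age, band="upper"),
            float(reps.mean()),
            float(reps.std(ddof=1) / np.sqrt(reps.size)) if reps.size > 1 else np.nan,
            int(reps.size),
            sex,
        ))
    return pd.DataFrame(rows, columns=PAIRING_COLUMNS)


@dataclass
class CriticalLengthModel:
    slope: float  # survival probability per bp (> 0 for a valid model)
    intercept: float
    l_critical: float  # bp, = -intercept / slope
    r_squared: float
    pairing: pd.DataFrame = field(repr=False)
    label: str = "pooled"
    ci_l_critical: tuple = (np.nan, np.nan)
    bootstrap_samples: np.ndarray = field(default=None, repr=False)
    flags: tuple = ()


def fit_critical(pairing, label="pooled"):
    """OLS of survival on mean TRF; extrapolate to zero survival."""
    if len(pairing) < 3:
        raise PairingError("need >= 3 (survival, TRF) pairs")
    x = pairing["mean_trf"].to_numpy(dtype=float)
    y = pairing["survival"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise PairingError("TRF values have zero spread")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise InvalidModelError(
            "fitted slope is not positive; survival does not rise with TRF and "
            "the zero-survival extrapolation is meaningless")
    pred = intercept + slope * x
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst if sst > 0 else np.nan
    l_crit = -intercept / slope
    flags = []
    if not (x.min() <= l_crit <= x.max()):
        flags.append("extrapolated_beyond_observed_range")
    return CriticalLengthModel(
        slope=float(slope), intercept=float(intercept), l_critical=float(l_crit),
        r_squared=r2, pairing=pairing, label=label, flags=tuple(flags),
    )


def predict_survival(model, trf):
    """Survival probability predicted at a TRF value, clamped to [0, 1]."""
    trf = np.asarray(trf, dtype=float)
    if np.any(trf < 0):
        raise InvalidModelError("TRF must be non-negative")
    out = np.clip(model.intercept + model.slope * trf, 0.0, 1.0)
    return out if out.ndim else float(out)


def _refit_once(cohort, liver_panel, ages, rng, per_sex_label):
    """One bootstrap replicate: resample fish within sex and panel replicates
    within (age, sex), then rerun KM -> pairing -> OLS."""
    parts = []
    for sex, grp in cohort.groupby("sex"):
        idx = rng.integers(0, len(grp), len(grp))
        parts.append(grp.iloc[idx])
    boot_cohort = pd.concat(parts, ignore_index=True)
    panel_parts = []
    for (_, _), grp in liver_panel.groupby(["age", "sex"]):
        idx = rng.integers(0, len(grp), len(grp))
        panel_parts.append(grp.iloc[idx])
    boot_panel = pd.concat(panel_parts, ignore_index=True)

    pairings = []
    sexes = (per_sex_label,) if per_sex_label in ("M", "F") else ("M", "F")
    for sex in sexes:
        curve = km_estimate(boot_cohort[boot_cohort["sex"] == sex])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairings.append(
                build_pairing(curve, boot_panel[boot_panel["sex"] == sex], ages, sex)
            )
    model = fit_critical(pd.concat(pairings, ignore_index=True))
    return model.l_critical


def bootstrap_critical(cohort, liver_panel, ages, n_boot=1000, rng=None,
                       label="pooled"):
    """Percentile bootstrap CI for L_crit over the whole estimation chain.

    ``label`` is 'pooled' for the fit through both sexes' pairings, or a
    sex code for a single-sex fit.  Replicates where the refitted slope is
    not positive are dropped (counted in the returned failure count).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    samples = []
    failures = 0
    for _ in range(n_boot):
        try:
            samples.append(_refit_once(cohort, liver_panel, ages, rng, label))
        except (InvalidModelError, PairingError, Exception):
            failures += 1
    samples = np.asarray(samples)
    if samples.size < max(20, n_boot // 10):
        raise InvalidModelError(
            f"bootstrap failed in {failures}/{n_boot} replicates; CI unreliable")
    ci = (float(np.percentile(samples, 2.5)), float(np.percentile(samples, 97.5)))
    return ci, samples


def critical_length_analysis(cohort, liver_panel, ages, n_boot=1000, rng=None):
    """Per-sex and pooled critical-length models with bootstrap CIs.

    ``cohort`` is a survival-record table (id, sex, entry_age_months,
    exit_age_months, event); ``liver_panel`` holds liver TRF replicates.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pairings = {}
    for sex in ("M", "F"):
        curve = km_estimate(cohort[cohort["sex"] == sex])
        pairings[sex] = build_pairing(
            curve, liver_panel[liver_panel["sex"] == sex], ages, sex)
    models = {}
    pooled_pairing = pd.concat(list(pairings.values()), ignore_index=True)
    for label, pairing in (("pooled", pooled_pairing),
                           ("M", pairings["M"]), ("F", pairings["F"])):
        model = fit_critical(pairing, label=label)
        ci, samples = bootstrap_critical(
            cohort, liver_panel, ages, n_boot=n_boot, rng=rng, label=label)
        model.ci_l_critical = ci
        model.bootstrap_samples = samples
        models[label] = model
    return models
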