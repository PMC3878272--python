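"""Seeded synthetic-data generator for the whole analysis chain.

The generator realises, fish by fish, the mechanistic model the downstream
analyses assume:

* each fish carries an initial mean TRF length per organ, a hepatic death
  threshold, and a private aging-rate multiplier shared by both organs;
* organ TRF follows the asymptotic decay
  ``TRF(t) = plateau + (TRF0 - plateau) * exp(-lambda * t)``;
* the fish dies when its liver TRF crosses its death threshold, or earlier
  by an independent exponential background hazard, whichever comes first;
* fish dying before the truncation age never enter the observable cohort
  (left truncation) and exits after the censoring age are right-censored.

Beyond the cohort itself the module fabricates every raw data product the
measurement modules consume: cross-sectional organ TRF panels drawn from
the cohort's survivors, copula-structured hormone/telomerase/TRF assay
panels, densitometric Southern-blot lane profiles with a ladder lane, and
qPCR amplification curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import HORMONES, PANEL_VARS, SEXES, SimConfig
from .errors import ConfigurationError
from .trfblot import LadderLane, LaneProfile

#: lambda-phage HindIII/EcoRI double-digest fragment sizes, bp
LAMBDA_HINDIII_ECORI = (
    21226, 5148, 4973, 4268, 3530, 2027, 1904, 1584, 1375, 947, 831, 564, 125,
)


@dataclass
class SyntheticIndividual:
    """One simulated fish with its latent aging parameters."""

    id: int
    sex: str
    trf0_liver: float  # bp, extrapolated age-0 liver TRF
    trf0_gill: float  # bp
    death_threshold: float  # bp, hepatic TRF at which the fish dies
    rate_factor: float  # private multiplier on the per-sex decay rates
    death_age: float  # months; true death time (threshold or background)
    telomeric_death: bool  # False if the background hazard struck first
    entry_age: float  # months; left-truncation age
    censored: bool  # True if still alive at the censoring age

    @property
    def exit_age(self):
        """Observed exit: death age, capped at the censoring age."""
        return self.death_age if not self.censored else self._censor_age

    _censor_age: float = np.nan


def trf_at(individual, organ, age, config):
    """Evaluate one fish's organ TRF trajectory at ``age`` months."""
    plateau = config.plateau[organ]
    trf0 = individual.trf0_liver if organ == "liver" else individual.trf0_gill
    lam = config.lam[organ][individual.sex] * individual.rate_factor
    return plateau + (trf0 - plateau) * np.exp(-lam * np.asarray(age, dtype=float))


def simulate_cohort(config: SimConfig):
    """Draw the observable cohort: fish alive past the truncation age.

    Returns a list of :class:`SyntheticIndividual`, deterministically
    reproducible from ``config.seed``.  Infeasible draws (threshold at or
    above the initial TRF, or at or below the plateau) are resampled up to
    ``config.max_resample`` times before a ConfigurationError is raised.
    """
    config.validate()
    rng = config.rng("cohort")
    plateau = config.plateau["liver"]
    individuals = []
    next_id = 0
    for sex in SEXES:
        n = config.n_per_sex
        trf0 = rng.normal(config.trf0_mean[sex], config.trf0_sd, n)
        theta = rng.normal(config.death_threshold_mean, config.death_threshold_sd, n)
        bad = (theta >= trf0) | (theta <= plateau) | (trf0 <= plateau)
        tries = 0
        while bad.any():
            tries += 1
            if tries > config.max_resample:
                raise ConfigurationError(
                    "could not draw a feasible (TRF0, death threshold) pair "
                    f"after {config.max_resample} retries; the threshold "
                    "distribution overlaps the TRF0 distribution or plateau"
                )
            k = int(bad.sum())
            trf0[bad] = rng.normal(config.trf0_mean[sex], config.trf0_sd, k)
            theta[bad] = rng.normal(
                config.death_threshold_mean, config.death_threshold_sd, k
            )
            bad = (theta >= trf0) | (theta <= plateau) | (trf0 <= plateau)

        trf0_gill = trf0 + rng.normal(0.0, config.trf0_gill_jitter_sd, n)
        rate = np.exp(rng.normal(0.0, config.lam_sigma, n))
        lam_i = config.lam["liver"][sex] * rate
        t_telomeric = np.log((trf0 - plateau) / (theta - plateau)) / lam_i
        hazard = config.hazard_for(sex)
        if hazard > 0:
            t_background = rng.exponential(1.0 / hazard, n)
        else:
            t_background = np.full(n, np.inf)
        death = np.minimum(t_telomeric, t_background)
        telomeric = t_telomeric <= t_background

        for i in range(n):
            if death[i] <= config.truncation_age:
                continue  # unobservable: died before entering the study
            ind = SyntheticIndividual(
                id=next_id + i,
                sex=sex,
                trf0_liver=float(trf0[i]),
                trf0_gill=float(trf0_gill[i]),
                death_threshold=float(theta[i]),
                rate_factor=float(rate[i]),
                death_age=float(death[i]),
                telomeric_death=bool(telomeric[i]),
                entry_age=config.truncation_age,
                censored=bool(death[i] > config.censor_age),
            )
            ind._censor_age = config.censor_age
            individuals.append(ind)
        next_id += n

    if config.censor_age < config.truncation_age or not individuals:
        warnings.warn(
            "observable cohort is empty (censoring before truncation, or all "
            "deaths pre-truncation)",
            stacklevel=2,
        )
    return individuals


def cohort_frame(individuals):
    """Tabulate a cohort as survival records (one row per fish)."""
    return pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "sex": [i.sex for i in individuals],
            "entry_age_months": [i.entry_age for i in individuals],
            "exit_age_months": [i.exit_age for i in individuals],
            "event": [int(not i.censored) for i in individuals],
        }
    )


def simulate_organ_panel(config, individuals, organs=("gill", "liver"), ages=None):
    """Cross-sectional TRF panels sampled destructively from survivors.

    At each sampling age, ``replicates * pool_size`` live fish per sex are
    drawn without replacement (with replacement, with a warning, if fewer
    remain); tissues of ``pool_size`` fish are pooled into one replicate
    (arithmetic or geometric mean TRF) and measured with lognormal blot
    noise.  Returns tidy rows (age, sex, organ, replicate, trf_bp).
    """
    rng = config.rng("organ_panel")
    ages = config.sampling_ages if ages is None else ages
    by_sex = {s: [i for i in individuals if i.sex == s] for s in SEXES}
    rows = []
    for age in ages:
        for sex in SEXES:
            alive = [i for i in by_sex[sex] if i.death_age > age]
            need = config.replicates * config.pool_size
            if not alive:
                warnings.warn(
                    f"no survivors at age {age} for sex {sex}; panel omitted",
                    stacklevel=2,
                )
                continue
            replace = len(alive) < need
            if replace:
                warnings.warn(
                    f"only {len(alive)} survivors at age {age} for sex {sex}; "
                    "sampling with replacement",
                    stacklevel=2,
                )
            chosen = rng.choice(len(alive), size=need, replace=replace)
            for organ in organs:
                trf = np.array(
                    [trf_at(alive[j], organ, age, config) for j in chosen]
                ).reshape(config.replicates, config.pool_size)
                if config.pooling == "arithmetic":
                    pooled = trf.mean(axis=1)
                else:
                    pooled = np.exp(np.log(trf).mean(axis=1))
                measured = pooled * np.exp(
                    rng.normal(0.0, config.trf_measurement_cv, config.replicates)
                )
                for r, val in enumerate(measured):
                    rows.append((age, sex, organ, r, float(val)))
    return pd.DataFrame(rows, columns=["age", "sex", "organ", "replicate", "trf_bp"])


def simulate_assay_panel(config, age, sex, organ, n_replicates=None, rng=None):
    """Draw an (E2, T, 11-KT, TA, TRF) panel with the configured rank
    correlation at one sampling age.

    A latent multivariate normal with correlation ``2 sin(pi rho_S / 6)``
    of the Spearman targets is mapped through monotone marginal transforms:
    lognormal hormones and telomerase activity centred on the sex-specific
    trajectory at ``age``, and a normal TRF marginal centred on the organ's
    mean decay curve.  Monotonicity preserves the ranks, so the empirical
    Spearman converges to the configured target as replicates grow.
    """
    if age not in config.sampling_ages:
        raise ConfigurationError(
            f"age {age} is not a sampling age {tuple(config.sampling_ages)}"
        )
    n = config.replicates if n_replicates is None else int(n_replicates)
    if rng is None:
        rng = config.rng(f"assay:{age}:{sex}:{organ}")
    corr = config.latent_correlation(sex, organ)  # raises if not PSD
    z = rng.multivariate_normal(np.zeros(len(PANEL_VARS)), corr, size=n, method="eigh")

    cols = {}
    for j, var in enumerate(PANEL_VARS):
        if var in HORMONES:
            med = config.hormone_curves[var][sex].level(age)
            cols[var] = med * np.exp(config.hormone_sigma * z[:, j])
        elif var == "ta":
            med = config.ta_curves[sex].level(age)
            cols["ta_rel"] = med * np.exp(config.ta_sigma * z[:, j])
        else:  # trf
            plateau = config.plateau[organ]
            mean_trf = plateau + (config.trf0_mean[sex] - plateau) * np.exp(
                -config.lam[organ][sex] * age
            )
            cols["trf_bp"] = mean_trf + config.assay_trf_sd * z[:, j]
    out = pd.DataFrame(cols)
    out.insert(0, "organ", organ)
    out.insert(0, "sex", sex)
    out.insert(0, "age", float(age))
    out.insert(3, "replicate", np.arange(n))
    return out[["age", "sex", "organ", "replicate", "e2", "t", "kt11", "ta_rel", "trf_bp"]]


@dataclass
class GelModel:
    """Affine log-size electrophoretic mobility: larger fragments migrate
    less.  position(size) = origin + slope * (log10(size_ref) - log10(size))."""

    origin_mm: float = 12.0  # migration of the largest reference fragment
    slope_mm_per_decade: float = 40.0
    size_ref: float = 21226.0

    def position(self, size_bp):
        size_bp = np.asarray(size_bp, dtype=float)
        return self.origin_mm + self.slope_mm_per_decade * (
            np.log10(self.size_ref) - np.log10(size_bp)
        )

    def size(self, position_mm):
        position_mm = np.asarray(position_mm, dtype=float)
        return 10.0 ** (
            np.log10(self.size_ref)
            - (position_mm - self.origin_mm) / self.slope_mm_per_decade
        )


def simulate_lane(
    true_mean_trf,
    smear_sd=0.18,
    ladder_sizes=LAMBDA_HINDIII_ECORI,
    gel: GelModel | None = None,
    seed=0,
    bin_width_mm=0.25,
    noise_cv=0.01,
):
    """Synthesise a densitometric TRF smear plus its ladder lane.

    The lane's optical density is a discretised lognormal fragment-number
    smear multiplied by fragment length (probe signal scales with telomere
    length), so the intensity-corrected mean ``sum(OD) / sum(OD/L)``
    recovers ``true_mean_trf`` up to discretisation and noise.

    Returns ``(LaneProfile, LadderLane, flags)`` where flags notes when the
    true value falls outside the ladder's calibration range.
    """
    if smear_sd <= 0:
        raise ConfigurationError("smear_sd must be positive")
    sizes = np.asarray(ladder_sizes, dtype=float)
    if not np.all(np.diff(sizes) < 0):
        raise ConfigurationError("ladder sizes must be strictly decreasing")
    gel = gel or GelModel()
    rng = np.random.default_rng(seed)

    flags = []
    if not (sizes.min() <= true_mean_trf <= sizes.max()):
        flags.append("outside_ladder_range")

    lo, hi = gel.position(sizes.max()), gel.position(sizes.min())
    positions = np.arange(lo, hi + bin_width_mm, bin_width_mm)
    log_len = np.log(gel.size(positions))
    # fragment-number density n(l) lognormal with molecule-weighted mean
    # E[n*L]/E[n] = exp(mu + sd^2/2) = true_mean_trf
    mu = np.log(true_mean_trf) - smear_sd**2 / 2.0
    log_density = -0.5 * ((log_len - mu) / smear_sd) ** 2
    log_od = log_density + log_len  # signal ~ number x length
    od = np.exp(log_od - log_od.max())  # normalised to peak 1, underflow-safe
    od = od * np.exp(rng.normal(0.0, noise_cv, od.size))
    profile = LaneProfile(positions=positions, od=od)
    ladder = LadderLane(sizes=sizes, positions=gel.position(sizes))
    return profile, ladder, flags


def simulate_amplification_curves(
    true_delta_cq,
    n_cycles=40,
    noise_sd=0.01,
    seed=0,
    n_replicates=3,
    f_max=1.0,
    reference_midpoint=20.0,
):
    """Triplicate sigmoid qPCR curves for a sample/reference pair.

    The early exponential phase doubles per cycle, so the threshold-crossing
    Cq difference between sample and reference equals ``true_delta_cq`` in
    the noise-free limit.  Returns tidy rows
    (sample, replicate, cycle, fluorescence).
    """
    if n_cycles < 40:
        raise ConfigurationError("protocol runs 40 cycles; n_cycles must be >= 40")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    rows = []
    for label, midpoint in (
        ("reference", reference_midpoint),
        ("sample", reference_midpoint + true_delta_cq),
    ):
        for rep in range(n_replicates):
            f = f_max / (1.0 + 2.0 ** (-(cycles - midpoint)))
            f = f * np.exp(rng.normal(0.0, noise_sd, f.size))
            for c, v in zip(cycles, f):
                rows.append((label, rep, int(c), float(v)))
    return pd.DataFrame(rows, columns=["sample", "replicate", "cycle", "fluorescence"])
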