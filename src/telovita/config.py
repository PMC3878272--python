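"""Study configuration for the synthetic medaka cohort generator.

The defaults encode the study conditions the analysis chain is calibrated
against: sex-specific median lifespans of 13.7 (males) and 14.6 (females)
months, initial liver terminal-restriction-fragment (TRF) lengths in the
12-17 kb range decaying toward a plateau, a hepatic death threshold of
3.8 kb, plasma sex-hormone trajectories peaking at 8 months, and the
sex- and organ-specific Spearman correlation structure linking hormones,
relative telomerase activity (TA) and TRF.

The per-sex liver decay rates are calibration constants: they were tuned
once (see ``scripts/calibrate_generator.py``) so that the left-truncated
Kaplan-Meier medians of the default cohort land on the target medians, and
then frozen here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError

SEXES = ("M", "F")
ORGANS = ("gill", "liver")
HORMONES = ("e2", "t", "kt11")
#: Variable order used by every 5x5 panel correlation matrix.
PANEL_VARS = ("e2", "t", "kt11", "ta", "trf")

#: Default cross-sectional sampling ages in months
#: (young, mature, senior, old, very old).
SAMPLING_AGES = (4.0, 8.0, 12.0, 15.0, 22.0)

#: Sparse Spearman targets per (sex, organ); keys are unordered variable
#: pairs. Entries absent here (and not on the hormone-hormone block) are 0.
SPEARMAN_TARGETS = {
    ("F", "gill"): {
        ("e2", "ta"): 0.31,
        ("e2", "trf"): 0.51,
        ("t", "trf"): 0.47,
        ("kt11", "trf"): 0.54,
    },
    ("F", "liver"): {
        ("e2", "ta"): 0.34,
        ("e2", "trf"): 0.68,
        ("t", "trf"): 0.60,
        ("kt11", "trf"): 0.71,
    },
    ("M", "gill"): {
        ("t", "ta"): 0.41,
        ("ta", "trf"): 0.62,
    },
    ("M", "liver"): {
        ("t", "trf"): 0.41,
        ("kt11", "trf"): 0.39,
    },
}


def spearman_to_linear(rho_s):
    """Convert a Spearman correlation to the latent Gaussian (Pearson)
    correlation that produces it: rho = 2 sin(pi * rho_s / 6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


@dataclass
class HormoneCurve:
    """Gamma-density-shaped mean trajectory, peaking at ``peak_age``.

    level(t) = baseline + peak_level * (t/m)^k * exp(-k (t - m)/m)

    with m = peak_age and k = shape.  The bracketed factor equals 1 at the
    peak and decays on both sides; larger ``shape`` gives a sharper peak
    and faster post-peak decline.  A near-flat profile is obtained with a
    small shape and peak_level comparable to baseline.
    """

    peak_age: float  # months
    peak_level: float  # concentration units above baseline at the peak
    baseline: float  # floor concentration
    shape: float = 3.0  # dimensionless sharpness, > 0

    def level(self, age):
        age = np.asarray(age, dtype=float)
        m, k = self.peak_age, self.shape
        g = np.where(
            age > 0, (age / m) ** k * np.exp(-k * (age - m) / m), 0.0
        )
        return self.baseline + self.peak_level * g


def _default_hormone_curves():
    # E2 peaks in females at 8 months and declines sharply ('menopause'-like);
    # the androgens peak in males at 8 months and decline gradually.  The
    # opposite sex carries a low, gently varying profile.
    return {
        "e2": {
            "F": HormoneCurve(peak_age=8.0, peak_level=40.0, baseline=5.0, shape=6.0),
            "M": HormoneCurve(peak_age=8.0, peak_level=1.5, baseline=2.5, shape=0.5),
        },
        "t": {
            "M": HormoneCurve(peak_age=8.0, peak_level=30.0, baseline=4.0, shape=4.0),
            "F": HormoneCurve(peak_age=8.0, peak_level=4.0, baseline=3.0, shape=0.5),
        },
        "kt11": {
            "M": HormoneCurve(peak_age=8.0, peak_level=25.0, baseline=3.0, shape=4.0),
            "F": HormoneCurve(peak_age=8.0, peak_level=1.0, baseline=1.0, shape=0.3),
        },
    }


def _default_ta_curves():
    # Female telomerase activity peaks in both organs at 8 months; male
    # activity is lower and flatter.
    return {
        "F": HormoneCurve(peak_age=8.0, peak_level=2.2, baseline=0.8, shape=3.0),
        "M": HormoneCurve(peak_age=8.0, peak_level=0.4, baseline=0.8, shape=1.0),
    }


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic cohort generator.

    Ages are in months and TRF lengths in bp throughout.
    """

    n_per_sex: int = 1500
    seed: int = 0
    truncation_age: float = 3.0  # fish enter observation at sexual maturation
    censor_age: float = 30.0  # administrative right-censoring age

    sampling_ages: tuple = SAMPLING_AGES

    # Initial (age 0, extrapolated) mean TRF per sex, bp
    trf0_mean: dict = field(default_factory=lambda: {"M": 12500.0, "F": 16500.0})
    trf0_sd: float = 2500.0
    #: gill TRF0 tracks the liver TRF0 of the same fish up to this jitter
    trf0_gill_jitter_sd: float = 400.0

    # Asymptotic decay: TRF(t) = plateau + (TRF0 - plateau) exp(-lambda t)
    plateau: dict = field(default_factory=lambda: {"gill": 5500.0, "liver": 2000.0})
    #: median per-month rate constant per organ per sex (calibrated, frozen)
    lam: dict = field(
        default_factory=lambda: {
            "liver": {"M": 0.0806, "F": 0.1416},
            "gill": {"M": 0.0403, "F": 0.0708},
        }
    )
    #: lognormal sigma of the per-individual rate multiplier, shared by both
    #: organs of one fish (a fast-aging fish is fast-aging everywhere)
    lam_sigma: float = 0.755

    # Hepatic death threshold distribution, bp
    death_threshold_mean: float = 3800.0
    death_threshold_sd: float = 300.0
    #: independent exponential background mortality, per month, per sex
    #: (male-biased: the female mid-life survival advantage exceeds what the
    #: telomere mechanism alone produces)
    background_hazard: dict = field(default_factory=lambda: {"M": 0.034, "F": 0.002})

    # Cross-sectional panel design
    replicates: int = 15  # pooled replicates per sex per age
    pool_size: int = 3  # fish per pooled replicate
    pooling: str = "arithmetic"  # or "geometric"
    trf_measurement_cv: float = 0.04  # lognormal blot measurement noise

    # Assay-panel marginals
    assay_trf_sd: float = 1200.0  # bp, normal marginal around the mean curve
    hormone_sigma: float = 0.4  # lognormal sigma of hormone marginals
    ta_sigma: float = 0.35  # lognormal sigma of the TA marginal

    hormone_curves: dict = field(default_factory=_default_hormone_curves)
    ta_curves: dict = field(default_factory=_default_ta_curves)

    # Rank-correlation structure (Spearman targets)
    spearman_targets: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in SPEARMAN_TARGETS.items()}
    )
    #: Spearman correlation among the three steroids (unreported; a single
    #: moderate value keeps every target matrix positive definite)
    interhormone_spearman: float = 0.5

    max_resample: int = 1000  # bounded retries for infeasible individual draws

    # ------------------------------------------------------------------ #

    def validate(self):
        if self.n_per_sex <= 0:
            raise ConfigurationError("n_per_sex must be positive")
        if self.truncation_age < 0 or self.censor_age < 0:
            raise ConfigurationError("ages must be non-negative")
        for organ in ORGANS:
            for sex in SEXES:
                if self.lam[organ][sex] < 0:
                    raise ConfigurationError(f"lam[{organ}][{sex}] must be >= 0")
        for sex in SEXES:
            if self.trf0_mean[sex] <= self.plateau["liver"]:
                raise ConfigurationError(
                    f"TRF0 mean for sex {sex} must exceed the liver plateau"
                )
        if self.death_threshold_mean <= self.plateau["liver"]:
            raise ConfigurationError(
                "death threshold mean must exceed the liver plateau"
            )
        hazards = (
            self.background_hazard.values()
            if isinstance(self.background_hazard, dict)
            else [self.background_hazard]
        )
        if any(
            v < 0
            for v in (
                self.trf0_sd,
                self.death_threshold_sd,
                self.lam_sigma,
                self.trf_measurement_cv,
                *hazards,
            )
        ):
            raise ConfigurationError("rates and spreads must be >= 0")

    def hazard_for(self, sex):
        if isinstance(self.background_hazard, dict):
            return self.background_hazard[sex]
        return self.background_hazard
        if self.pooling not in ("arithmetic", "geometric"):
            raise ConfigurationError("pooling must be 'arithmetic' or 'geometric'")
        for sex in SEXES:
            for organ in ORGANS:
                self.latent_correlation(sex, organ)  # raises if not PSD
        return self

    # -- correlation matrices ------------------------------------------ #

    def spearman_matrix(self, sex, organ):
        """Dense 5x5 Spearman target matrix in ``PANEL_VARS`` order."""
        idx = {v: i for i, v in enumerate(PANEL_VARS)}
        m = np.eye(len(PANEL_VARS))
        for h1 in HORMONES:
            for h2 in HORMONES:
                if h1 != h2:
                    m[idx[h1], idx[h2]] = self.interhormone_spearman
        for (a, b), r in self.spearman_targets.get((sex, organ), {}).items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
        if not np.allclose(m, m.T):
            raise ConfigurationError("Spearman target matrix must be symmetric")
        return m

    def latent_correlation(self, sex, organ):
        """Latent Gaussian correlation implied by the Spearman targets.

        Raises ConfigurationError (with a nearest-PSD hint) if the converted
        matrix is not positive semidefinite.
        """
        m = spearman_to_linear(self.spearman_matrix(sex, organ))
        np.fill_diagonal(m, 1.0)
        evals = np.linalg.eigvalsh(m)
        if evals.min() < -1e-10:
            raise ConfigurationError(
                f"latent correlation matrix for ({sex}, {organ}) is not positive "
                f"semidefinite (min eigenvalue {evals.min():.4g}); project the "
                "Spearman targets to the nearest PSD matrix (e.g. clip negative "
                "eigenvalues and renormalise the diagonal) before configuring"
            )
        return m

    # -- RNG substreams ------------------------------------------------ #

    def rng(self, label):
        """Deterministic named substream of the single per-run seed."""
        return derive_rng(self.seed, label)

    # -- (de)serialisation --------------------------------------------- #

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["sampling_ages"] = list(self.sampling_ages)
        d["spearman_targets"] = {
            f"{sex}.{organ}": {f"{a}:{b}": r for (a, b), r in pairs.items()}
            for (sex, organ), pairs in self.spearman_targets.items()
        }
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "sampling_ages" in d:
            d["sampling_ages"] = tuple(float(a) for a in d["sampling_ages"])
        if "spearman_targets" in d:
            targets = {}
            for key, pairs in d["spearman_targets"].items():
                sex, organ = key.split(".")
                targets[(sex, organ)] = {
                    tuple(pk.split(":")): float(r) for pk, r in pairs.items()
                }
            d["spearman_targets"] = targets
        for attr, curve_cls in (("hormone_curves", HormoneCurve), ("ta_curves", HormoneCurve)):
            if attr in d:
                def build(node):
                    if isinstance(node, dict) and "peak_age" in node:
                        return curve_cls(**node)
                    return {k: build(v) for k, v in node.items()}
                d[attr] = build(d[attr])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self):
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def derive_rng(seed, label):
    """Named, order-independent RNG substream of a single integer seed."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
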