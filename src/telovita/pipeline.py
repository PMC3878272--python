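"""End-to-end driver: simulate -> survival -> decay -> correlations ->
critical length -> age conversion, with a reproducibility manifest."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .ageconvert import fit_model, medaka_to_human, reference_model
from .cohortsim import cohort_frame, simulate_assay_panel, simulate_cohort, simulate_organ_panel
from .config import SEXES, SimConfig
from .criticality import critical_length_analysis
from .io import sha256_file, write_json, write_table
from .stats import correlation_table
from .survival import km_estimate, km_median, logrank_test
from .telodecay import OrganTelomerePanel, fit_decay


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self):
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "files": self.files,
            "warnings": self.warnings,
        }


def run_pipeline(config: SimConfig | None = None, out_dir=None, n_boot=1000):
    """Run every stage in dependency order; returns (manifest, report).

    When ``out_dir`` is given, stage outputs (cohort, panels, survival
    curves, report, manifest) are written there and digested into the
    manifest; reruns with the same config and seed reproduce the digests.
    """
    config = config or SimConfig()
    config.validate()
    manifest = RunManifest(config_hash=config.content_hash(), seed=config.seed,
                           version=__version__)
    report = {"seed": config.seed}
    caught = []
    failed = []

    def stage(name, fn):
        """Run one stage; a failure is recorded and downstream stages that
        can still run do (partial completion)."""
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            report[name] = {"error": f"{type(exc).__name__}: {exc}"}
            failed.append(name)
            return None

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        individuals = simulate_cohort(config)
        cohort = cohort_frame(individuals)
        panel = simulate_organ_panel(config, individuals)

        # --- survival ---------------------------------------------------
        curves = {}

        def _survival():
            surv = {}
            for sex in SEXES:
                curve = km_estimate(cohort[cohort["sex"] == sex])
                med = km_median(curve)
                curves[sex] = curve
                surv[sex] = {
                    "n": curve.n_records,
                    "median_months": med.median,
                    "median_ci": [med.ci_lower, med.ci_upper],
                    "median_defined": med.defined,
                }
            report["survival"] = surv
            lr = logrank_test(cohort[cohort["sex"] == "M"],
                              cohort[cohort["sex"] == "F"])
            report["logrank"] = {"chi_square": lr.chi_square, "df": lr.df,
                                 "n": lr.n, "p_value": lr.p_value}

        stage("survival", _survival)

        # --- telomere decay ----------------------------------------------
        def _decay():
            decay = {}
            for organ in ("gill", "liver"):
                for sex in SEXES:
                    fit = fit_decay(OrganTelomerePanel.from_frame(panel, organ, sex))
                    decay[f"{organ}_{sex}"] = {
                        "trf0_bp": fit.trf0, "plateau_bp": fit.plateau,
                        "lambda_per_month": fit.lam, "lambda_ci": list(fit.ci_lam),
                        "r_squared": fit.r_squared,
                        "r_squared_means": fit.r_squared_means,
                    }
            report["decay"] = decay

        stage("decay", _decay)

        # --- hormone / telomerase correlations ---------------------------
        assay_frames = []
        for age in config.sampling_ages:
            for sex in SEXES:
                for organ in ("gill", "liver"):
                    assay_frames.append(simulate_assay_panel(config, age, sex, organ))
        assay = pd.concat(assay_frames, ignore_index=True)
        corr = correlation_table(assay)
        report["correlations"] = corr.to_dict(orient="records")

        # --- critical telomere length -------------------------------------
        models = {}

        def _critical():
            liver = panel[panel["organ"] == "liver"]
            rng = config.rng("bootstrap")
            models.update(critical_length_analysis(
                cohort, liver, list(config.sampling_ages), n_boot=n_boot, rng=rng))
            report["critical_length"] = {
                label: {
                    "l_critical_bp": m.l_critical,
                    "ci_bp": list(m.ci_l_critical),
                    "slope_per_bp": m.slope,
                    "intercept": m.intercept,
                    "r_squared": m.r_squared,
                    "flags": list(m.flags),
                }
                for label, m in models.items()
            }

        stage("critical_length", _critical)

        # --- age conversion ------------------------------------------------
        fitted = fit_model()
        ref = reference_model()
        report["age_conversion"] = {
            "fitted": {"a": fitted.a, "b": fitted.b,
                       "r_squared": fitted.r_squared,
                       "r_squared_mean": fitted.r_squared_mean},
            "reference": {"a": ref.a, "b": ref.b, "notes": list(ref.notes)},
            "estrogen_decline_window_human_years": {
                "from_8_months": medaka_to_human(ref, 8.0),
                "from_12_months": medaka_to_human(ref, 12.0),
            },
        }
        caught = [str(w.message) for w in wlist]

    manifest.warnings = caught + [f"stage failed: {name}" for name in failed]
    report["warnings"] = caught
    report["failed_stages"] = failed

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        outputs = {
            "cohort.csv": (cohort, "cohort"),
            "organ_panel.csv": (panel, "panel"),
            "assay_panel.csv": (assay, "assay_panel"),
            "correlations.csv": (corr, None),
        }
        for sex, curve in curves.items():
            outputs[f"survival_{sex}.csv"] = (curve.to_frame(), "survival_curve")
        for name, (df, schema) in outputs.items():
            path = os.path.join(out_dir, name)
            write_table(df, path, schema)
            manifest.files[name] = sha256_file(path)
        for label, m in models.items():
            path = os.path.join(out_dir, f"pairing_{label}.csv")
            write_table(m.pairing, path, "pairing")
            manifest.files[f"pairing_{label}.csv"] = sha256_file(path)
        report_path = os.path.join(out_dir, "report.json")
        write_json(report, report_path)
        manifest.files["report.json"] = sha256_file(report_path)
        write_json(manifest.to_dict(), os.path.join(out_dir, "manifest.json"))

    return manifest, report
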