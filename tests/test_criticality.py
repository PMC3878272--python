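"""Survival-vs-TRF pairing and the critical-length extrapolation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from telovita import (
    SimConfig,
    bootstrap_critical,
    build_pairing,
    cohort_frame,
    fit_critical,
    km_estimate,
    predict_survival,
    simulate_cohort,
    simulate_organ_panel,
)
from telovita.errors import InvalidModelError, PairingError

from conftest import SEED


def linear_pairing(l_crit=4000.0, span=8000.0, trfs=(6000.0, 8000.0, 10000.0, 12000.0)):
    rows = [
        {"age": a, "survival": (trf - l_crit) / span, "surv_lo": np.nan,
         "surv_hi": np.nan, "mean_trf": trf, "sem_trf": 100.0,
         "n_replicates": 15, "sex": "pooled"}
        for a, trf in zip((22.0, 15.0, 12.0, 8.0), trfs)
    ]
    return pd.DataFrame(rows)


class TestFitCritical:
    def test_exact_linear_truth(self):
        model = fit_critical(linear_pairing())
        assert model.l_critical == pytest.approx(4000.0, rel=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_unit_invariance_bp_vs_kb(self):
        pairing = linear_pairing()
        in_bp = fit_critical(pairing)
        kb = pairing.assign(mean_trf=pairing["mean_trf"] / 1000.0)
        in_kb = fit_critical(kb)
        assert in_kb.l_critical * 1000.0 == pytest.approx(in_bp.l_critical, rel=1e-9)

    def test_negative_slope_is_invalid(self):
        flipped = linear_pairing().assign(
            survival=lambda d: 1.0 - d["survival"])
        with pytest.raises(InvalidModelError):
            fit_critical(flipped)

    def test_extrapolation_flag_always_set_on_realistic_data(self):
        model = fit_critical(linear_pairing())
        assert "extrapolated_beyond_observed_range" in model.flags

    def test_too_few_pairs_rejected(self):
        with pytest.raises(PairingError):
            fit_critical(linear_pairing().head(2))


class TestPredictSurvival:
    def test_zero_at_critical_length(self):
        model = fit_critical(linear_pairing())
        assert predict_survival(model, model.l_critical) == pytest.approx(0.0, abs=1e-9)

    def test_clamped_to_unit_interval(self):
        model = fit_critical(linear_pairing())
        assert predict_survival(model, 1e6) == 1.0
        assert predict_survival(model, 0.0) == 0.0

    def test_linear_midpoint(self):
        model = fit_critical(linear_pairing())
        assert predict_survival(model, 8000.0) == pytest.approx(0.5, rel=1e-9)

    def test_negative_trf_rejected(self):
        with pytest.raises(InvalidModelError):
            predict_survival(fit_critical(linear_pairing()), -5.0)


class TestBuildPairing:
    def test_default_chain_yields_five_rows_per_sex(
            self, default_cohort_frame, default_panel, default_config):
        liver = default_panel[default_panel["organ"] == "liver"]
        for sex in ("M", "F"):
            curve = km_estimate(default_cohort_frame[default_cohort_frame.sex == sex])
            pairing = build_pairing(curve, liver[liver["sex"] == sex],
                                    list(default_config.sampling_ages), sex)
            assert len(pairing) == 5
            assert (pairing["n_replicates"] == default_config.replicates).all()
            # survival decreases with age while TRF decreases too
            assert pairing["survival"].is_monotonic_decreasing

    def test_empty_age_list_gives_empty_table(self, default_cohort_frame, default_panel):
        liver = default_panel[default_panel["organ"] == "liver"]
        curve = km_estimate(default_cohort_frame[default_cohort_frame.sex == "M"])
        assert len(build_pairing(curve, liver[liver.sex == "M"], [])) == 0

    def test_age_before_entry_excluded_with_warning(
            self, default_cohort_frame, default_panel):
        liver = default_panel[default_panel["organ"] == "liver"]
        curve = km_estimate(default_cohort_frame[default_cohort_frame.sex == "M"])
        panel = pd.concat([liver[liver.sex == "M"],
                           pd.DataFrame([{"age": 2.0, "sex": "M", "organ": "liver",
                                          "replicate": 0, "trf_bp": 12000.0}])],
                          ignore_index=True)
        with pytest.warns(UserWarning, match="precedes"):
            pairing = build_pairing(curve, panel, [2.0, 4.0, 8.0], "M")
        assert list(pairing["age"]) == [4.0, 8.0]

    def test_missing_age_raises_pairing_error(
            self, default_cohort_frame, default_panel):
        liver = default_panel[default_panel["organ"] == "liver"]
        curve = km_estimate(default_cohort_frame[default_cohort_frame.sex == "M"])
        with pytest.raises(PairingError, match="18"):
            build_pairing(curve, liver[liver.sex == "M"], [4.0, 18.0], "M")

    def test_gill_panel_rejected(self, default_cohort_frame, default_panel):
        gill = default_panel[default_panel["organ"] == "gill"]
        curve = km_estimate(default_cohort_frame[default_cohort_frame.sex == "M"])
        with pytest.raises(PairingError, match="liver"):
            build_pairing(curve, gill[gill.sex == "M"], [4.0], "M")


class TestBootstrap:
    def test_identical_sex_parameters_make_sexes_indistinguishable(self):
        # force both sexes to share every generator parameter, then check the
        # per-sex critical lengths differ by less than the bootstrap CI width
        cfg = SimConfig(seed=SEED, n_per_sex=1000)
        cfg.trf0_mean = {"M": 14500.0, "F": 14500.0}
        cfg.lam = {"liver": {"M": 0.11, "F": 0.11},
                   "gill": {"M": 0.055, "F": 0.055}}
        cfg.background_hazard = {"M": 0.015, "F": 0.015}
        inds = simulate_cohort(cfg)
        cohort = cohort_frame(inds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            panel = simulate_organ_panel(cfg, inds)
        liver = panel[panel["organ"] == "liver"]
        estimates, widths = {}, {}
        rng = np.random.default_rng(SEED)
        for sex in ("M", "F"):
            curve = km_estimate(cohort[cohort.sex == sex])
            model = fit_critical(build_pairing(
                curve, liver[liver.sex == sex], list(cfg.sampling_ages), sex), sex)
            ci, _ = bootstrap_critical(cohort, liver, list(cfg.sampling_ages),
                                       n_boot=200, rng=rng, label=sex)
            estimates[sex] = model.l_critical
            widths[sex] = ci[1] - ci[0]
        assert abs(estimates["M"] - estimates["F"]) < max(widths.values())

    def test_percentile_ci_covers_generator_truth(self):
        # scaled-down coverage check: modest cohorts, 20 replicates
        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = SimConfig(seed=100 + rep, n_per_sex=600)
            inds = simulate_cohort(cfg)
            cohort = cohort_frame(inds)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                panel = simulate_organ_panel(cfg, inds)
            liver = panel[panel["organ"] == "liver"]
            rng = np.random.default_rng(rep)
            ci, _ = bootstrap_critical(cohort, liver, list(cfg.sampling_ages),
                                       n_boot=150, rng=rng, label="pooled")
            if ci[0] <= cfg.death_threshold_mean <= ci[1]:
                covered += 1
        assert covered >= 14  # nominal 95%, allowing wide binomial slack at 20 reps
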