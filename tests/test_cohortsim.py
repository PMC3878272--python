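"""Generator contracts: trajectories, determinism, copula, fixtures."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from telovita import (
    SimConfig,
    calibrate_ladder,
    cohort_frame,
    mean_trf,
    simulate_amplification_curves,
    simulate_assay_panel,
    simulate_cohort,
    simulate_lane,
    simulate_organ_panel,
    trf_at,
)
from telovita.config import PANEL_VARS
from telovita.errors import ConfigurationError

from conftest import SEED


def degenerate_config(**kw):
    """All spreads zero: death ages become a closed-form constant."""
    cfg = SimConfig(n_per_sex=50, seed=SEED)
    cfg.trf0_mean = {"M": 15000.0, "F": 15000.0}
    cfg.trf0_sd = 0.0
    cfg.plateau = {"liver": 2000.0, "gill": 5500.0}
    cfg.lam = {"liver": {"M": 0.15, "F": 0.15}, "gill": {"M": 0.05, "F": 0.05}}
    cfg.lam_sigma = 0.0
    cfg.death_threshold_mean = 3800.0
    cfg.death_threshold_sd = 0.0
    cfg.background_hazard = 0.0
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestCohort:
    def test_closed_form_death_age_without_noise(self):
        # t = (1/lam) ln((TRF0 - plateau)/(theta - plateau))
        inds = simulate_cohort(degenerate_config())
        expected = np.log(13000.0 / 1800.0) / 0.15  # ~13.18 months
        ages = np.array([i.death_age for i in inds])
        np.testing.assert_allclose(ages, expected, rtol=1e-12)
        assert expected == pytest.approx(13.18, abs=0.01)

    def test_trajectory_hits_threshold_at_death(self, default_config, default_cohort):
        telomeric = [i for i in default_cohort if i.telomeric_death][:200]
        assert telomeric
        for ind in telomeric:
            trf_at_death = trf_at(ind, "liver", ind.death_age, default_config)
            assert trf_at_death == pytest.approx(ind.death_threshold, rel=1e-6)

    def test_censoring_window(self, default_config, default_cohort):
        for ind in default_cohort:
            assert ind.death_age > default_config.truncation_age
            if ind.censored:
                assert ind.exit_age == default_config.censor_age < ind.death_age
            assert ind.entry_age < ind.exit_age

    def test_same_seed_bytewise_identical(self, default_config, default_cohort):
        again = simulate_cohort(SimConfig(seed=default_config.seed))
        assert cohort_frame(again).to_csv() == cohort_frame(default_cohort).to_csv()

    def test_degenerate_window_warns_and_empties(self):
        cfg = degenerate_config(censor_age=2.0, truncation_age=3.0)
        cfg.lam = {"liver": {"M": 1.5, "F": 1.5}, "gill": {"M": 0.05, "F": 0.05}}
        with pytest.warns(UserWarning, match="empty"):
            inds = simulate_cohort(cfg)
        assert inds == []

    def test_infeasible_threshold_raises_configuration_error(self):
        cfg = degenerate_config()
        cfg.death_threshold_mean = 16000.0  # above TRF0: no crossing exists
        with pytest.raises(ConfigurationError):
            simulate_cohort(cfg)

    def test_female_trf_exceeds_male_at_four_months(self):
        # population-level sex ordering of young-age telomere length,
        # estimated with an enlarged panel to suppress sampling noise
        cfg = SimConfig(seed=SEED, n_per_sex=3000)
        cfg.replicates = 120
        inds = simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            panel = simulate_organ_panel(cfg, inds, ages=(4.0,))
        for organ in ("gill", "liver"):
            sub = panel[panel["organ"] == organ]
            mean_f = sub[sub["sex"] == "F"]["trf_bp"].mean()
            mean_m = sub[sub["sex"] == "M"]["trf_bp"].mean()
            assert mean_f > mean_m


class TestAssayPanel:
    def test_empirical_spearman_matches_each_configured_target(self):
        cfg = SimConfig(seed=SEED)
        panel = simulate_assay_panel(cfg, 8.0, "F", "liver", n_replicates=5000)
        cols = {"e2": "e2", "t": "t", "kt11": "kt11", "ta": "ta_rel", "trf": "trf_bp"}
        target = cfg.spearman_matrix("F", "liver")
        n = len(panel)
        for i, vi in enumerate(PANEL_VARS):
            for j in range(i + 1, len(PANEL_VARS)):
                vj = PANEL_VARS[j]
                rho = sps.spearmanr(panel[cols[vi]], panel[cols[vj]]).statistic
                # Fisher-z comparison, 3 standard errors
                z_gap = abs(np.arctanh(rho) - np.arctanh(target[i, j]))
                assert z_gap < 3.0 * 1.06 / np.sqrt(n - 3)

    def test_independence_when_targets_are_zero(self):
        cfg = SimConfig(seed=SEED)
        cfg.spearman_targets = {k: {} for k in cfg.spearman_targets}
        cfg.interhormone_spearman = 0.0
        panel = simulate_assay_panel(cfg, 8.0, "M", "gill", n_replicates=4000)
        rho = sps.spearmanr(panel["ta_rel"], panel["trf_bp"]).statistic
        assert abs(rho) < 3.0 / np.sqrt(len(panel) - 3)

    def test_comonotone_pair_gives_spearman_one_exactly(self):
        cfg = SimConfig(seed=SEED)
        cfg.spearman_targets[("M", "gill")] = {("ta", "trf"): 1.0}
        panel = simulate_assay_panel(cfg, 8.0, "M", "gill", n_replicates=500)
        rho = sps.spearmanr(panel["ta_rel"], panel["trf_bp"]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_non_psd_targets_error_mentions_projection(self):
        cfg = SimConfig(seed=SEED)
        cfg.spearman_targets[("M", "gill")] = {
            ("ta", "trf"): 0.95, ("t", "ta"): 0.95, ("t", "trf"): -0.9}
        with pytest.raises(ConfigurationError, match="PSD|positive"):
            simulate_assay_panel(cfg, 8.0, "M", "gill", n_replicates=10)

    def test_age_must_be_a_sampling_age(self):
        with pytest.raises(ConfigurationError):
            simulate_assay_panel(SimConfig(seed=SEED), 5.0, "M", "gill")


class TestLane:
    def test_round_trip_recovers_true_mean_within_two_percent(self):
        profile, ladder, flags = simulate_lane(14000.0, seed=SEED)
        cal = calibrate_ladder(ladder.sizes, ladder.positions)
        assert mean_trf(profile, cal) == pytest.approx(14000.0, rel=0.02)
        assert flags == []

    def test_narrow_smear_recovers_within_one_percent(self):
        profile, ladder, _ = simulate_lane(10000.0, smear_sd=1e-4, seed=SEED)
        cal = calibrate_ladder(ladder.sizes, ladder.positions)
        assert mean_trf(profile, cal) == pytest.approx(10000.0, rel=0.01)

    def test_fixed_seed_reproduces_profile_bytes(self):
        p1, _, _ = simulate_lane(12000.0, seed=7)
        p2, _, _ = simulate_lane(12000.0, seed=7)
        assert p1.od.tobytes() == p2.od.tobytes()
        assert p1.positions.tobytes() == p2.positions.tobytes()

    def test_out_of_calibration_range_is_flagged(self):
        _, _, flags = simulate_lane(30000.0, seed=SEED)
        assert "outside_ladder_range" in flags

    def test_non_decreasing_ladder_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_lane(10000.0, ladder_sizes=(5000, 7000, 1000), seed=SEED)


class TestAmplification:
    def test_zero_delta_cq_gives_unit_activity(self):
        from telovita.assays import cq_table, relative_activity, summarize_triplicates

        curves = simulate_amplification_curves(0.0, noise_sd=0.0, seed=SEED)
        cq = summarize_triplicates(cq_table(curves, threshold=1e-3))
        vals = dict(zip(cq["sample"], cq["cq"]))
        assert relative_activity(vals["sample"], vals["reference"]) == pytest.approx(1.0)

    @pytest.mark.parametrize("delta,expected", [(1.0, 0.5), (-2.0, 4.0)])
    def test_known_delta_cq_noise_free(self, delta, expected):
        from telovita.assays import cq_table, relative_activity, summarize_triplicates

        curves = simulate_amplification_curves(delta, noise_sd=0.0, seed=SEED)
        cq = summarize_triplicates(cq_table(curves, threshold=1e-3))
        vals = dict(zip(cq["sample"], cq["cq"]))
        assert relative_activity(vals["sample"], vals["reference"]) == pytest.approx(
            expected, rel=1e-6)

    def test_triplicate_cq_spread_small_at_low_noise(self):
        from telovita.assays import cq_table

        curves = simulate_amplification_curves(1.0, noise_sd=0.002, seed=SEED)
        cq = cq_table(curves, threshold=1e-3)
        spreads = cq.groupby("sample")["cq"].std()
        assert (spreads < 0.05).all()

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_amplification_curves(1.0, n_cycles=30)
        with pytest.raises(ConfigurationError):
            simulate_amplification_curves(1.0, noise_sd=-0.1)
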