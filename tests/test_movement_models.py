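"""Gaussian movement-outcome models: centring, joint structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from vibereach.movement_models import (
    OUTCOMES,
    centre_by_baseline,
    direction_effects,
    fit_epe_speed_model,
    fit_multivariate_model,
    fit_speed_model,
)
from vibereach.synthgen import (
    CohortTruth,
    generate_cohort,
    implied_baseline_epe_slope,
    task_design,
)

from conftest import QUICK


def test_centring_zeroes_the_baseline_condition(task2_trials):
    baseline = (
        (task2_trials.agovib == 0) & (task2_trials.antavib == 0)
    ).to_numpy()
    y = centre_by_baseline(task2_trials, "mms", baseline)
    df = task2_trials.assign(y=y)
    base_means = df[baseline].groupby("participant")["y"].mean()
    assert np.allclose(base_means, 0.0, atol=1e-10)


def test_centring_invariance_of_effect_posteriors(reported_truth):
    trials, _ = generate_cohort(reported_truth, task_design(1, reps=4))
    fit_a = fit_speed_model(trials, seed=11, **QUICK)
    shifted = trials.copy()
    shifted["mms"] = shifted["mms"] + 17.3 * (shifted["participant"] + 1)
    fit_b = fit_speed_model(shifted, seed=11, **QUICK)
    # participant-wise constants are removed by the centring (to rounding),
    # so the posteriors agree up to MCMC noise under the same seed
    for name in ("beta_antavib", "beta_agovib", "beta_vg"):
        a, b = fit_a[name], fit_b[name]
        sd = np.std(a.draws)
        assert abs(a.map - b.map) < 0.5 * sd, name
        assert abs(a.ci_low - b.ci_low) < sd and abs(a.ci_high - b.ci_high) < sd


class TestSpeedModel:
    def test_null_effects_cover_zero(self, null_truth):
        trials, _ = generate_cohort(null_truth, task_design(1, reps=4))
        fit = fit_speed_model(trials, seed=12, **QUICK)
        for name in ("beta_vg", "beta_agovib", "beta_antavib"):
            assert fit[name].covers(0.0), name

    def test_vibration_effect_recovered(self, reported_truth):
        trials, _ = generate_cohort(reported_truth, task_design(1, reps=8))
        fit = fit_speed_model(trials, seed=13, **QUICK)
        p = fit["beta_antavib"]
        assert abs(p.map - reported_truth.speed_effect_anta) <= p.ci_half_width
        # target distance strongly drives speed; slope ~ 1.1/base_mt deg/s per deg
        assert fit["beta_td"].map == pytest.approx(1.0, abs=0.3)


class TestMultivariateModel:
    @pytest.fixture(scope="class")
    def mvn_fit(self, task2_trials):
        return fit_multivariate_model(task2_trials, seed=14, **QUICK)

    def test_correlation_draws_are_valid(self, mvn_fit):
        r12 = mvn_fit.chains["corr_epe_mms"].ravel()
        r13 = mvn_fit.chains["corr_epe_mt"].ravel()
        r23 = mvn_fit.chains["corr_mms_mt"].ravel()
        assert np.all(np.abs(np.stack([r12, r13, r23])) < 1.0)
        det = 1 + 2 * r12 * r13 * r23 - r12**2 - r13**2 - r23**2
        assert np.all(det > 0)  # positive definite with unit diagonal

    def test_residual_correlation_recovered(self, mvn_fit, reported_truth):
        p = mvn_fit["corr_epe_mms"]
        assert abs(p.map - reported_truth.epe_speed_corr) < 0.1

    def test_direction_effects_table(self, mvn_fit, reported_truth):
        table = direction_effects(mvn_fit)
        assert len(table) == 18  # 3 outcomes x 3 effects x 2 directions
        anta_flex = table.query(
            "outcome == 'epe' and effect == 'antavib' and direction == 'flexion'"
        ).iloc[0]
        half = (anta_flex.ci_high - anta_flex.ci_low) / 2
        assert abs(anta_flex["map"] - reported_truth.epe_effect_anta) <= half
        # movement time is reported in ms
        mt_rows = table[table.outcome == "mt"]
        assert mt_rows["map"].abs().max() > 1.0

    def test_additive_truth_gives_null_interactions(self, mvn_fit):
        # the generator is additive in the two vibrations, so interaction
        # coefficients concentrate near zero
        for outc in OUTCOMES:
            p = mvn_fit[f"{outc}_agovib:antavib"]
            assert p.covers(0.0), outc
            assert abs(p.map) < 2 * np.std(p.draws)

    def test_missing_cells_are_listed(self, task2_trials):
        broken = task2_trials[
            ~((task2_trials.direction == "flexion") & (task2_trials.agovib == 1))
        ]
        with pytest.raises(ValueError, match="flexion/ago=1"):
            fit_multivariate_model(broken)

    def test_equal_sigma_truth_gives_null_contrasts(self, mvn_fit):
        # generator residual SDs do not vary with vibration: sigma-model
        # condition contrasts concentrate at zero (9 simultaneous 95% CIs,
        # so allow a single marginal miss) and stay small in magnitude
        misses = 0
        for outc in OUTCOMES:
            for col in ("agovib", "antavib", "agovib:antavib"):
                p = mvn_fit[f"logsd_{outc}_{col}"]
                misses += not p.covers(0.0)
                assert abs(p.map) < 0.3, (outc, col)
        assert misses <= 1


class TestEpeSpeedModel:
    def test_slope_recovery_and_row_count(self, reported_truth):
        trials, _ = generate_cohort(reported_truth, task_design(2, reps=24))
        n_rows = len(trials[(trials.agovib == 0) & (trials.antavib == 0)])
        assert n_rows == reported_truth.n_participants * 48
        fit = fit_epe_speed_model(trials, seed=15, **QUICK)
        expected = implied_baseline_epe_slope(reported_truth)
        for d in ("flexion", "extension"):
            p = fit[f"slope@{d}"]
            assert abs(p.map - expected) <= p.ci_half_width, d

    def test_independent_outcomes_give_null_slope(self, null_truth):
        trials, _ = generate_cohort(null_truth, task_design(2, reps=12))
        fit = fit_epe_speed_model(trials, seed=16, **QUICK)
        assert fit["beta_mms_z"].covers(0.0)

    def test_requires_baseline_trials(self, task2_trials):
        vib_only = task2_trials[task2_trials.antavib == 1]
        with pytest.raises(ValueError, match="baseline"):
            fit_epe_speed_model(vib_only)
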