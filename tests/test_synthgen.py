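"""Generator closed forms, counts, reproducibility and null calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from vibereach.synthgen import (
    CohortTruth,
    apply_speed_change,
    generate_cohort,
    generate_trajectory,
    task_design,
)


class TestTrajectory:
    def test_zero_distance_stays_at_start(self):
        s = generate_trajectory(10.0, 0.0, 1.0, 90.0)
        assert np.allclose(s.angle, 0.0)

    def test_peak_speed_of_minimum_jerk(self):
        # closed form: max of d/dt [d*(10 s^3 - 15 s^4 + 6 s^5)] is
        # 15 d / (8 T) at s = 1/2; check against dense numeric evaluation
        s = generate_trajectory(0.0, 80.0, 1.0, 2000.0)
        v = np.gradient(s.angle, s.t)
        assert abs(v.max() - 150.0) < 0.1
        assert abs(s.t[np.argmax(v)] - 0.5) < 2e-3

    def test_sampling_grid(self):
        s = generate_trajectory(0.0, 60.0, 1.3, 90.0)
        assert s.t.size == int(np.floor(1.3 * 90)) + 1
        assert np.allclose(np.diff(s.t), 1.0 / 90.0)
        s.validate()

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(start_angle=np.nan), "start_angle"),
            (dict(distance=np.inf), "distance"),
            (dict(duration=-1.0), "duration"),
            (dict(sample_rate=0.0), "sample_rate"),
        ],
    )
    def test_bad_inputs_name_the_parameter(self, kwargs, msg):
        base = dict(start_angle=0.0, distance=60.0, duration=1.0, sample_rate=90.0)
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            generate_trajectory(**base)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        distance=st.floats(1.0, 120.0),
        duration=st.floats(0.5, 2.5),
    )
    def test_monotone_and_bounded(self, distance, duration):
        s = generate_trajectory(0.0, distance, duration, 90.0)
        assert np.all(np.diff(s.angle) >= -1e-12)
        assert s.angle.min() >= -1e-9 and s.angle.max() <= distance + 1e-9
        assert np.all(np.diff(s.t) > 0)


class TestSpeedChange:
    def _series(self):
        return generate_trajectory(0.0, 80.0, 1.0, 90.0, trigger_angle=20.0)

    def test_zero_change_is_identity(self):
        s = self._series()
        out = apply_speed_change(s, 0.05, 0.0)
        assert np.allclose(out.angle, s.angle)
        assert np.allclose(out.x, s.x)

    def test_velocity_scaled_after_latency(self):
        s = generate_trajectory(0.0, 80.0, 1.0, 1000.0, trigger_angle=20.0)
        out = apply_speed_change(s, 0.048, -0.1)
        t_c = np.interp(20.0, s.angle, s.t)
        probe = t_c + 0.06
        v_in = np.gradient(s.angle, s.t)
        v_out = np.gradient(out.angle, out.t)
        k = np.argmin(np.abs(s.t - probe))
        assert v_out[k] == pytest.approx(0.9 * v_in[k], rel=1e-3)

    def test_pre_trigger_samples_unchanged(self):
        s = self._series()
        out = apply_speed_change(s, 0.0, -0.2)
        t_c = np.interp(20.0, s.angle, s.t)
        pre = s.t < t_c
        assert np.array_equal(out.angle[pre], s.angle[pre])
        assert not np.allclose(out.angle[~pre], s.angle[~pre])

    def test_unreached_trigger_errors_with_trial_id(self):
        s = generate_trajectory(0.0, 10.0, 1.0, 90.0, trigger_angle=20.0, trial_id=7)
        with pytest.raises(ValueError, match="7"):
            apply_speed_change(s, 0.05, -0.1)


class TestCohort:
    def test_task1_counts_and_truncation(self):
        truth = CohortTruth(seed=1)
        trials, _ = generate_cohort(truth, task_design(1))
        assert len(trials) == 17 * 5 * 4 * 18 == 6120
        trunc, _ = generate_cohort(truth, task_design(1, truncate_participant=True))
        assert len(trunc) == 5926

    def test_task2_and_task3_counts(self):
        truth = CohortTruth(seed=2)
        t2, _ = generate_cohort(truth, task_design(2))
        assert len(t2) == 3264
        t3, tracked = generate_cohort(
            truth, task_design(3, with_tracking=False)
        )
        assert tracked == []
        per_cond = t3.groupby("vib_window").size()
        assert (per_cond == 816).all() and set(per_cond.index) == {
            "none", "full", "0-20", "20-80"
        }

    def test_reproducible_and_seed_sensitive(self):
        truth = CohortTruth(n_participants=3, seed=5)
        a, _ = generate_cohort(truth, task_design(1, reps=2))
        b, _ = generate_cohort(truth, task_design(1, reps=2))
        pd.testing.assert_frame_equal(a, b)
        c, _ = generate_cohort(truth, task_design(1, reps=2), seed=6)
        assert not a["mms"].equals(c["mms"])

    def test_null_truth_calibration(self):
        truth = CohortTruth.null(n_participants=12, seed=7)
        t1, _ = generate_cohort(truth, task_design(1, reps=10))
        # participant random intercepts dominate, so the Monte-Carlo error
        # of the cohort proportion is the cluster-level standard error
        p_j = t1.groupby("participant")["rating"].mean()
        se = p_j.std(ddof=1) / np.sqrt(len(p_j))
        assert abs(t1["rating"].mean() - 0.5) < 3 * se
        t2, _ = generate_cohort(truth, task_design(2, reps=20))
        r = np.corrcoef(t2["epe"], t2["mms"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(t2))

    def test_antagonist_rating_proportion_matches_normal_cdf(self):
        # with no participant heterogeneity the Faster proportion under
        # antagonist vibration at zero gain is exactly Phi(beta0 - 0.29)
        truth = CohortTruth(
            n_participants=40, seed=8, re_sd_rating=0.0, rating_speed_slope=0.0,
            beta_anta_rating=-0.29,
        )
        trials, _ = generate_cohort(truth, task_design(1, reps=40))
        sub = trials[
            (trials.vg_units == 0) & (trials.agovib == 0) & (trials.antavib == 1)
        ]
        p_expect = ndtr(truth.beta0_rating - 0.29)
        se = np.sqrt(p_expect * (1 - p_expect) / len(sub))
        assert abs(sub["rating"].mean() - p_expect) < 3 * se

    def test_marginal_range_guard(self):
        truth = CohortTruth(n_participants=3, seed=9)
        design = task_design(2, reps=4, ranges={"mms": (0.0, 10.0)})
        with pytest.raises(ValueError, match="outside configured range"):
            generate_cohort(truth, design)

    @pytest.mark.parametrize(
        "field,value",
        [("n_participants", 0), ("tau_mean", 0.2), ("epe_speed_corr", 1.0),
         ("sd_mms", -1.0)],
    )
    def test_truth_invariants(self, field, value):
        with pytest.raises(ValueError):
            CohortTruth(**{field: value})

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortTruth(seed=1), {"task": 4})
        with pytest.raises(ValueError):
            task_design(5)
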