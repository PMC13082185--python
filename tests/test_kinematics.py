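"""Circle fitting, angular conversion, velocity estimation and delta-speed grids."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import least_squares

from vibereach.kinematics import (
    GRID_MS,
    TrackingIssueError,
    AngularTrial,
    build_speed_grids,
    finite_difference_speed,
    fit_circle_center,
    spline_speed,
    to_angles,
    trial_summaries,
    zscore_within,
)
from vibereach.synthgen import CohortTruth, generate_cohort, generate_trajectory, task_design


def _circle_points(n, radius, center, arc=(0.0, 2 * np.pi), rng=None, noise=0.0):
    th = np.linspace(*arc, n)
    pts = np.column_stack([
        center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)
    ])
    if noise > 0:
        pts += rng.normal(0, noise, pts.shape)
    return pts


class TestCircleFit:
    def test_exact_recovery_on_noiseless_points(self):
        pts = _circle_points(30, 0.361, (0.12, -0.34), arc=(0.2, 1.6))
        fit = fit_circle_center(pts)
        assert fit.center == pytest.approx((0.12, -0.34), abs=1e-10)
        assert fit.radius == pytest.approx(0.361, abs=1e-10)
        assert fit.rms_residual < 1e-10
        assert fit.n_points == 30

    def test_right_triangle_circumcircle(self):
        pts = [(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0)]
        fit = fit_circle_center(pts)
        assert fit.center == pytest.approx((0.0, 0.0), abs=1e-12)
        assert fit.radius == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_raise(self):
        pts = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        with pytest.raises(ValueError, match="collinear"):
            fit_circle_center(pts)

    def test_noise_efficiency_vs_nonlinear_oracle(self):
        # algebraic fit centre scatter stays within 2x of a geometric
        # (orthogonal-distance) least-squares oracle at 1 mm noise
        rng = np.random.default_rng(0)
        alg, geo = [], []

        def geometric(pts):
            def resid(p):
                return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]
            sol = least_squares(resid, x0=[0.0, 0.0, 0.36]).x
            return sol[:2]

        for _ in range(200):
            pts = _circle_points(30, 0.361, (0.0, 0.0), arc=(0.3, 1.7),
                                 rng=rng, noise=1e-3)
            alg.append(fit_circle_center(pts).center)
            geo.append(geometric(pts))
        sd_alg = np.std(np.asarray(alg), axis=0)
        sd_geo = np.std(np.asarray(geo), axis=0)
        assert np.all(sd_alg <= 2.0 * sd_geo)


class TestToAngles:
    def test_quarter_circle(self):
        s = generate_trajectory(0.0, 90.0, 1.0, 90.0)
        fit = fit_circle_center(np.column_stack([s.x, s.y])[::6])
        ang = to_angles(s, fit)
        assert ang.angle[0] == pytest.approx(0.0, abs=1e-9)
        assert ang.angle[-1] == pytest.approx(90.0, abs=1e-6)

    def test_round_trip_matches_generator(self):
        s = generate_trajectory(15.0, 60.0, 1.2, 90.0)
        fit = fit_circle_center(np.column_stack([s.x, s.y])[::5])
        ang = to_angles(s, fit)
        assert np.max(np.abs(ang.angle - s.angle)) < 0.01

    def test_flexion_direction_sign_convention(self):
        s = generate_trajectory(120.0, 60.0, 1.0, 90.0, direction="flexion")
        fit = fit_circle_center(np.column_stack([s.x, s.y])[::5])
        ang = to_angles(s, fit, direction="flexion")
        assert ang.angle[-1] > 0  # toward the target is positive

    def test_radius_violation_flags_tracking_issue(self):
        s = generate_trajectory(0.0, 60.0, 1.0, 90.0)
        x = s.x.copy()
        x[40] += 0.2  # 20 cm glitch
        bad = dataclasses.replace(s, x=x)
        fit = fit_circle_center(np.column_stack([s.x, s.y])[::5])
        with pytest.raises(TrackingIssueError, match="radius"):
            to_angles(bad, fit)

    def test_timestamp_gap_flags_tracking_issue(self):
        s = generate_trajectory(0.0, 60.0, 1.0, 90.0)
        t = s.t.copy()
        t[50:] += 0.1  # ~9 dropped frames
        bad = dataclasses.replace(s, t=t)
        fit = fit_circle_center(np.column_stack([s.x, s.y])[::5])
        with pytest.raises(TrackingIssueError, match="gap"):
            to_angles(bad, fit)


def _angular(t, angle):
    return AngularTrial(trial_id=0, t=t, angle=angle)


class TestSpeedEstimation:
    def test_linear_angle_reproduced_exactly(self):
        t = np.linspace(0, 1, 50)
        trial = _angular(t, 3.0 + 7.5 * t)
        sp = spline_speed(trial)
        assert np.allclose(sp.speed, 7.5, atol=1e-6)
        fd = finite_difference_speed(trial)
        assert np.allclose(fd.speed, 7.5, atol=1e-9)

    def test_central_difference_exact_for_quadratic(self):
        t = np.arange(10.0)
        fd = finite_difference_speed(_angular(t, t**2))
        assert np.allclose(fd.speed, 2.0 * t[1:-1])

    def test_spline_tracks_minimum_jerk_velocity(self):
        s = generate_trajectory(0.0, 80.0, 1.0, 90.0)
        sp = spline_speed(_angular(s.t, s.angle))
        v_true = 80.0 * (30 * s.t**2 - 60 * s.t**3 + 30 * s.t**4)
        mid = (s.t > 0.1) & (s.t < 0.9)
        err = np.abs(sp.speed[mid] - v_true[mid])
        assert err.max() < 0.01 * 150.0

    def test_spline_localises_a_speed_step(self):
        # piecewise-linear angle: slope 60 before tau, 30 after
        tau = 0.61
        t = np.arange(0, 1.2, 1 / 90)
        angle = np.where(t < tau, 60 * t, 60 * tau + 30 * (t - tau))
        dense = np.arange(0.2, 1.0, 1e-4)
        sp = spline_speed(_angular(t, angle), t_eval=dense)
        crossing = dense[np.argmin(np.abs(sp.speed - 45.0))]
        assert abs(crossing - tau) < 0.010

    def test_preconditions(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(ValueError):
            spline_speed(_angular(t, t))
        with pytest.raises(ValueError):
            finite_difference_speed(_angular(t[:2], t[:2]))


class TestTrialSummaries:
    def test_perfect_reach_has_zero_endpoint_error(self):
        s = generate_trajectory(0.0, 60.0, 1.0, 90.0)
        trial = spline_speed(_angular(s.t, s.angle))
        epe, mms, mt = trial_summaries(trial, 60.0)
        assert epe == pytest.approx(0.0, abs=1e-6)

    def test_onset_offset_trimming_raises_mean_speed(self):
        s = generate_trajectory(0.0, 80.0, 1.0, 90.0)
        trial = spline_speed(_angular(s.t, s.angle))
        epe, mms, mt = trial_summaries(trial, 80.0)
        assert mt < 1.0
        assert mms > 80.0

    def test_injected_endpoint_bias_recovered(self):
        rng = np.random.default_rng(3)
        epes = []
        for i in range(60):
            s = generate_trajectory(0.0, 80.0 - 2.76, 1.0, 90.0,
                                    noise_sd=3e-4, rng=rng, trial_id=i)
            fit = fit_circle_center(np.column_stack([s.x, s.y])[::4])
            trial = spline_speed(to_angles(s, fit))
            epes.append(trial_summaries(trial, 80.0)[0])
        assert np.mean(epes) == pytest.approx(-2.76, abs=3 * np.std(epes) / np.sqrt(60))

    def test_no_movement_errors(self):
        t = np.linspace(0, 1, 90)
        trial = spline_speed(_angular(t, np.zeros_like(t)))
        with pytest.raises(ValueError, match="suprathreshold"):
            trial_summaries(trial, 60.0)


class TestSpeedGrids:
    def test_grid_shape_and_self_subtraction(self):
        truth = CohortTruth.null(n_participants=3, seed=11)
        _, tracked = generate_cohort(truth, task_design(3, reps=6))
        grids = build_speed_grids(tracked)
        per_trial = grids.groupby("trial_id").size()
        assert (per_trial == 23).all()
        assert set(np.round(grids["t"].unique() * 1000).astype(int)) == set(GRID_MS)
        # no injected vibration effect: intervention == control in expectation
        dms = grids.dropna(subset=["dms"])
        for t_pt, sub in dms.groupby("t"):
            se = sub["dms"].std() / np.sqrt(len(sub))
            assert abs(sub["dms"].mean()) < 4 * se

    def test_latency_signature_in_mean_dms(self, task3_cohort):
        truth, _, tracked = task3_cohort
        grids = build_speed_grids(tracked)
        on = grids[grids["pair"] == "on"].dropna(subset=["dms"])
        early = on[on["t"] < truth.tau_mean - 0.015].groupby("t")["dms"].mean()
        late = on[on["t"] > truth.tau_mean + 0.03].groupby("t")["dms"].mean()
        assert np.abs(early).max() < 2.0
        assert (late < -4.0).all()  # ~10% of ~70 deg/s

    def test_missing_control_errors_with_participant(self, task3_cohort):
        _, _, tracked = task3_cohort
        subset = [s for s in tracked
                  if not (s.participant == 1 and s.condition == "none")]
        with pytest.raises(ValueError, match="participant 1"):
            build_speed_grids(subset)


def test_zscore_within_is_exact():
    rng = np.random.default_rng(4)
    v = rng.normal(3, 2, 200)
    g = np.repeat([0, 1, 2, 3], 50)
    z = zscore_within(v, g)
    for k in range(4):
        assert z[g == k].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[g == k].std() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="zero variance"):
        zscore_within(np.ones(4), np.array([0, 0, 1, 1]))
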