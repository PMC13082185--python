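"""Sigmoid blend closed forms, gradient exactness, oracle and null behaviour."""

import numpy as np
import pandas as pd
import pytest

from vibereach.changepoint import (
    SIGMOID_SCALE,
    TAU_SUPPORT,
    ChangepointModel,
    fit_changepoint,
    latency_report,
    sigmoid_blend,
)

from conftest import QUICK


class TestSigmoidBlend:
    def test_midpoint_is_exactly_half(self):
        assert sigmoid_blend(0.05, 0.05) == 0.5

    def test_ten_millisecond_offsets(self):
        # c = +/- 10 at the 1 ms scale
        assert sigmoid_blend(0.06, 0.05) == pytest.approx(
            1.0 / (1.0 + np.exp(10.0)), rel=1e-12
        )
        assert sigmoid_blend(0.04, 0.05) == pytest.approx(
            1.0 - 1.0 / (1.0 + np.exp(10.0)), rel=1e-12
        )

    def test_symmetry_identity(self):
        t = np.linspace(-0.1, 0.12, 45)
        tau = 0.037
        s = sigmoid_blend(t, tau)
        assert np.allclose(s + sigmoid_blend(2 * tau - t, tau), 1.0)

    def test_overflow_safe_far_from_changepoint(self):
        assert sigmoid_blend(1000.0, 0.0) == 0.0
        assert sigmoid_blend(-1000.0, 0.0) == 1.0

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            sigmoid_blend(0.0, 0.0, scale=0.0)


def _toy_data(J=3, trials=6, tau=0.05, drop=-5.0, noise=2.0, seed=0):
    rng = np.random.default_rng(seed)
    grid = np.arange(-100, 121, 10) / 1000.0
    t = np.tile(grid, J * trials)
    pid = np.repeat(np.arange(J), grid.size * trials)
    dms = rng.normal(0.0, noise, t.size) + np.where(t > tau, drop, 0.0)
    return pd.DataFrame({"participant": pid, "t": t, "dms": dms})


def test_analytic_gradient_matches_finite_differences():
    df = _toy_data(J=4, trials=8, seed=3)
    model = ChangepointModel(
        df["t"].to_numpy(), df["dms"].to_numpy(), df["participant"].to_numpy()
    )
    rng = np.random.default_rng(4)
    for point in range(3):
        x = rng.standard_normal(model.dim) * 0.3
        _, g = model.logp_grad(x)
        h = 1e-6
        num = np.empty_like(g)
        for i in range(model.dim):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (model.logp_grad(xp)[0] - model.logp_grad(xm)[0]) / (2 * h)
        # relative agreement, with an absolute floor for near-zero entries
        # set by finite-difference roundoff on the log-density magnitude
        atol = 1e-9 * max(abs(model.logp_grad(x)[0]), 1.0)
        np.testing.assert_allclose(num, g, rtol=1e-5, atol=atol)


def test_posterior_mode_matches_grid_search_oracle():
    """Shared changepoint, dense trials: MAP within 2 ms of profile ML."""
    df = _toy_data(J=2, trials=40, tau=0.0465, drop=-8.0, noise=2.5, seed=5)
    cp = fit_changepoint(df, seed=6, target_accept=0.95, **QUICK)

    def profile_loglik(tau):
        ll = 0.0
        for j, sub in df.groupby("participant"):
            t, y = sub["t"].to_numpy(), sub["dms"].to_numpy()
            S = sigmoid_blend(t, tau)
            X = np.column_stack([S, S * t, 1 - S, (1 - S) * t])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            ll += -0.5 * len(y) * np.log(np.mean(resid**2))
        return ll

    taus = np.arange(0.0, 0.1201, 0.001)
    tau_ml = taus[np.argmax([profile_loglik(tt) for tt in taus])]
    assert abs(cp.tau_bar.map - tau_ml) <= 0.002


def test_pure_noise_never_reports_a_confident_latency_silently():
    # without a changepoint the posterior either stays prior-wide or (the
    # parsimony-driven outcome) piles at the prior edge; both are flagged
    df = _toy_data(J=3, trials=10, drop=0.0, noise=3.0, seed=7)
    cp = fit_changepoint(df, seed=8, **QUICK)
    prior_sd = (TAU_SUPPORT[1] - TAU_SUPPORT[0]) / np.sqrt(12.0)
    wide = np.std(cp.tau_bar.draws) >= 0.5 * prior_sd
    flagged = any(("uninformative" in f) or ("edge" in f) for f in cp.flags)
    assert wide or flagged
    assert flagged


def test_changepoint_at_the_prior_edge_is_flagged():
    df = _toy_data(J=3, trials=30, tau=0.119, drop=-10.0, noise=1.5, seed=9)
    cp = fit_changepoint(df, seed=10, **QUICK)
    assert any("edge" in f for f in cp.flags)


class TestLatencyReport:
    @pytest.fixture(scope="class")
    def two_fits(self):
        on = fit_changepoint(
            _toy_data(J=3, trials=20, tau=0.0482, drop=-6.0, seed=11),
            seed=12, **QUICK,
        )
        off = fit_changepoint(
            _toy_data(J=3, trials=20, tau=0.0580, drop=+6.0, seed=13),
            seed=14, **QUICK,
        )
        return on, off

    def test_identical_fits_identical_report(self, two_fits):
        on, _ = two_fits
        a = latency_report(on, on)
        b = latency_report(on, on)
        pd.testing.assert_frame_equal(a, b)

    def test_on_off_latencies_separate_in_ms(self, two_fits):
        on, off = two_fits
        rep = latency_report(on, off)
        tau = rep[rep.parameter == "tau_bar"].set_index("fit")["map_ms"]
        assert 30.0 < tau["on"] < 60.0  # millisecond units
        assert tau["off"] - tau["on"] > 0
        assert abs(tau["on"] - 48.2) < 10.0
        assert abs(tau["off"] - 58.0) < 10.0
        # per-participant latencies present for both fits
        assert (rep.parameter.str.startswith("tau[")).sum() == 2 * 3

    def test_model_preconditions(self):
        df = _toy_data(J=1, trials=5)
        with pytest.raises(ValueError, match="2 participants"):
            fit_changepoint(df)
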