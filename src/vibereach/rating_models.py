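"""Hierarchical Bernoulli-probit models for Faster/Slower speed ratings.

The rating of the virtual arm's relative speed is modelled as a latent
standard-normal comparison crossing a threshold at zero (a
signal-detection-style rating model): the probability of answering
'Faster' is Phi(z) with z linear in the predictors.  Two analyses share
the engine:

* the main Task-1 model, z = b0 + b1*vg + b2*agovib + b3*antavib, with
  visual speed gain vg in units of +6% so the gain coefficient is the
  latent shift per +6% step, and
* the integrative baseline model on unperturbed trials (no gain, no
  vibration), z = b0 + b1*mms_z + b2*td, where mms_z is the
  within-participant z-scored mean movement speed.

All population-level predictors also get participant-level deviations
(random intercepts and slopes), priors are zero-centred and weakly
informative (N(0,1) on latent-scale effects, HalfNormal(1) on SDs).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .glmm import HierarchicalGLM
from .inference import FitResult, PosteriorSummary, fit_model, map_estimate
from .kinematics import zscore_within

__all__ = [
    "fit_rating_model",
    "fit_baseline_rating_model",
    "predict_probability",
    "plugin_probability",
]

_RATING_COLS = ["intercept", "vg_units", "agovib", "antavib"]


def _check_rating_data(df: pd.DataFrame) -> None:
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    levels = df["rating"].dropna().unique()
    if not np.all(np.isin(levels, [0.0, 1.0])) or levels.size < 2:
        raise ValueError("both rating levels (Faster=1, Slower=0) must be present")


def fit_rating_model(
    trials: pd.DataFrame,
    draws: int = 1500,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
    prior_scale_beta: float = 1.0,
    prior_scale_sd: float = 1.0,
) -> FitResult:
    """Fit the Task-1 rating model (visual gain + vibration predictors).

    ``trials`` is the long trial table; only task-1 rows with a rating are
    used.  Returns posterior summaries for beta0/beta_vg/beta_agovib/
    beta_antavib plus the participant-level SDs.
    """
    df = trials[(trials["task"] == 1) & trials["rating"].notna()].copy()
    _check_rating_data(df)
    X = np.column_stack([
        np.ones(len(df)),
        df["vg_units"].to_numpy(float),
        df["agovib"].to_numpy(float),
        df["antavib"].to_numpy(float),
    ])
    Xc, T = _centre_columns(X, [2, 3])
    model = HierarchicalGLM(
        Xc, df["rating"].to_numpy(float),
        pd.Categorical(df["participant"]).codes,
        beta_names=["beta0", "beta_vg", "beta_agovib", "beta_antavib"],
        likelihood="probit",
        prior_scale_beta=prior_scale_beta,
        prior_scale_sd=prior_scale_sd,
        beta_transform=T,
    )
    return fit_model(model, draws=draws, warmup=warmup, chains=chains, seed=seed)


def _centre_columns(X: np.ndarray, cols) -> Tuple[np.ndarray, np.ndarray]:
    """Mean-centre design columns for sampling; return (X_c, T) with
    beta_reported = T @ beta_fitted recovering the dummy-coded intercept."""
    Xc = X.copy()
    T = np.eye(X.shape[1])
    for k in cols:
        m = X[:, k].mean()
        Xc[:, k] = X[:, k] - m
        T[0, k] = -m
    return Xc, T


def fit_baseline_rating_model(
    trials: pd.DataFrame,
    draws: int = 1500,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
    prior_scale_beta: float = 1.0,
    prior_scale_sd: float = 1.0,
) -> FitResult:
    """Does trial-to-trial movement speed predict the speed rating?

    Uses only the unperturbed Task-1 trials (no visual gain, no
    vibration); mean movement speed is z-normalised within participant on
    that subset and target distance enters centred at 60 degrees.
    Summaries: beta0, beta_mms_z, beta_td (+ SDs).
    """
    df = trials[
        (trials["task"] == 1)
        & (trials["vg_units"] == 0)
        & (trials["agovib"] == 0)
        & (trials["antavib"] == 0)
        & trials["rating"].notna()
    ].copy()
    _check_rating_data(df)
    pid = pd.Categorical(df["participant"]).codes
    mms_z = zscore_within(df["mms"].to_numpy(float), pid)
    X = np.column_stack([
        np.ones(len(df)),
        mms_z,
        df["td"].to_numpy(float) - 60.0,
    ])
    model = HierarchicalGLM(
        X, df["rating"].to_numpy(float), pid,
        beta_names=["beta0", "beta_mms_z", "beta_td"],
        likelihood="probit",
        prior_scale_beta=prior_scale_beta,
        prior_scale_sd=prior_scale_sd,
    )
    return fit_model(model, draws=draws, warmup=warmup, chains=chains, seed=seed)


def plugin_probability(baseline_prob: float, latent_shift: float) -> float:
    """Plug-in probit prediction Phi(Phi^-1(p0) + delta).

    Maps a baseline 'Faster' probability and a latent-scale shift (e.g. a
    vibration coefficient or a multiple of the visual-gain coefficient) to
    the shifted response probability through the exact normal CDF.
    """
    if not (0.0 < baseline_prob < 1.0):
        raise ValueError("baseline_prob must be in (0, 1)")
    return float(ndtr(ndtri(baseline_prob) + latent_shift))


def predict_probability(
    fit: FitResult,
    condition: Optional[Dict[str, float]] = None,
    plug_in: bool = False,
) -> PosteriorSummary | float:
    """Population-level P('Faster') for a condition.

    ``condition`` maps predictor names (e.g. ``vg_units``, ``agovib``,
    ``antavib`` or ``mms_z``/``td`` for the baseline model) to values;
    omitted predictors are 0.  By default the full posterior of Phi(z) is
    summarised (MAP + 95% CI); with ``plug_in=True`` only the MAP point
    estimates enter (a fast plug-in approximation).  Conditions outside
    the design space are allowed (extrapolation on the latent scale).
    """
    condition = dict(condition or {})
    if "vg_units" in condition:  # accepted alias for the gain predictor
        condition["vg"] = condition.pop("vg_units")
    names = [n for n in fit.chains if n.startswith("beta")]
    z_draws = fit.chains["beta0"].astype(float).copy()
    z_plug = fit["beta0"].map
    for name in names:
        if name == "beta0":
            continue
        key = name[len("beta_"):]
        val = float(condition.pop(key, 0.0))
        z_draws = z_draws + fit.chains[name] * val
        z_plug += fit[name].map * val
    if condition:
        raise ValueError(f"unknown predictors in condition: {sorted(condition)}")
    if plug_in:
        return float(ndtr(z_plug))
    probs = ndtr(z_draws)
    flat = probs.reshape(-1)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    return PosteriorSummary(
        name="p_faster", map=map_estimate(flat), ci_low=float(lo),
        ci_high=float(hi), rhat=float("nan"), ess=float(flat.size), draws=flat,
    )
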