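"""Gaussian models for movement outcomes.

Three analyses:

* Task-1 mean movement speed: mms ~ N(z, sigma) with z linear in visual
  gain, the two vibration flags and target distance, after centring mms
  within participant by the no-vibration / no-gain condition mean.
* Task-2 joint outcomes: endpoint error (deg), mean movement speed
  (deg/s) and movement time (s) modelled as a trivariate Gaussian with a
  full agovib x antavib x md fixed-effect expansion plus td x md per
  outcome, a log-linear model for each outcome's residual SD over the
  vibration x direction cells, and an unrestricted residual correlation
  matrix (so the epe-mms coupling survives after conditioning on the
  design).
* Integrative baseline model: z-scored endpoint error regressed on
  z-scored speed with direction-specific slopes, on no-vibration trials.

Movement direction is coded sum-to-zero (flexion +0.5, extension -0.5),
so main effects are cross-direction averages and direction-specific
effects are linear combinations of draws (see
:func:`direction_effects`).  Target distance is centred at 60 degrees.
Movement time is modelled in seconds; millisecond conversion happens
only at the reporting layer.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .glmm import HierarchicalGLM
from .inference import FitResult, fit_model
from .kinematics import zscore_within

__all__ = [
    "fit_speed_model",
    "fit_multivariate_model",
    "fit_epe_speed_model",
    "direction_effects",
    "centre_by_baseline",
    "MvnModel",
    "OUTCOMES",
    "FIXED_COLUMNS",
    "SIGMA_COLUMNS",
]

OUTCOMES = ("epe", "mms", "mt")
FIXED_COLUMNS = [
    "intercept", "agovib", "antavib", "md", "agovib:antavib", "agovib:md",
    "antavib:md", "agovib:antavib:md", "td", "td:md",
]
SIGMA_COLUMNS = [
    "intercept", "agovib", "antavib", "md", "agovib:antavib", "agovib:md",
    "antavib:md", "agovib:antavib:md",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _md_code(direction: pd.Series) -> np.ndarray:
    """Sum-to-zero direction contrast: flexion +0.5, extension -0.5."""
    return np.where(direction.to_numpy() == "flexion", 0.5, -0.5)


def centre_by_baseline(
    df: pd.DataFrame, outcome: str, baseline_mask: np.ndarray
) -> np.ndarray:
    """Centre an outcome within participant by its baseline-condition mean."""
    vals = df[outcome].to_numpy(float).copy()
    for pid, sub in df.groupby("participant"):
        m = df["participant"] == pid
        base = df.loc[np.asarray(baseline_mask) & m.to_numpy(), outcome]
        if base.empty:
            raise ValueError(f"participant {pid}: no baseline trials to centre by")
        vals[m.to_numpy()] -= float(base.mean())
    return vals


# ---------------------------------------------------------------------------
# Task-1 speed model
# ---------------------------------------------------------------------------


def fit_speed_model(
    trials: pd.DataFrame,
    draws: int = 1500,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
) -> FitResult:
    """Task-1 mean-movement-speed regression (deg/s).

    mms is centred within participant by the no-vibration / no-gain
    condition mean; predictors are visual gain (in +6% units), the two
    vibration flags and centred target distance.  Priors scale with the
    outcome SD.  Summaries: beta0, beta_vg, beta_agovib, beta_antavib,
    beta_td (+ participant-level SDs, residual sigma).
    """
    df = trials[trials["task"] == 1].copy()
    baseline = (
        (df["vg_units"] == 0) & (df["agovib"] == 0) & (df["antavib"] == 0)
    ).to_numpy()
    y = centre_by_baseline(df, "mms", baseline)
    sd_y = max(float(np.std(y)), 1e-6)
    X = np.column_stack([
        np.ones(len(df)),
        df["vg_units"].to_numpy(float),
        df["agovib"].to_numpy(float),
        df["antavib"].to_numpy(float),
        df["td"].to_numpy(float) - 60.0,
    ])
    from .rating_models import _centre_columns

    Xc, T = _centre_columns(X, [2, 3])
    model = HierarchicalGLM(
        Xc, y, pd.Categorical(df["participant"]).codes,
        beta_names=["beta0", "beta_vg", "beta_agovib", "beta_antavib", "beta_td"],
        likelihood="gaussian",
        prior_scale_beta=2.5 * sd_y,
        prior_scale_sd=sd_y,
        prior_scale_sigma=2.5 * sd_y,
        beta_transform=T,
    )
    return fit_model(model, draws=draws, warmup=warmup, chains=chains, seed=seed)


# ---------------------------------------------------------------------------
# Task-2 multivariate model
# ---------------------------------------------------------------------------


def _corr_from_z(z: np.ndarray) -> np.ndarray:
    """3x3 correlation matrix from 3 unconstrained params (partial-corr vine).

    r12 = tanh(z0), r13 = tanh(z1) and the partial correlation
    r23|1 = tanh(z2); always positive definite.  The unconstrained
    parameters are clipped at |z| = 8 (far outside any prior mass) so the
    matrix stays numerically invertible on divergent trajectories.
    """
    r12, r13, p23 = np.tanh(np.clip(z, -8.0, 8.0))
    r23 = p23 * np.sqrt((1 - r12**2) * (1 - r13**2)) + r12 * r13
    return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])


class MvnModel:
    """Trivariate distributional regression with analytic gradients.

    y_i (3,) ~ N(eta_i, D_i C D_i) with
    eta_i^k = x_i' beta_k + z_i' (sd_u[k] * eps_{j(i),k}),
    log sigma_i^k = w_i' gamma_k, C an unrestricted correlation matrix
    (3 unconstrained parameters, weakly regularised toward identity) and
    per-participant deviations (non-centred) on the ``re_columns`` of the
    fixed design for every outcome (default: intercept and the two
    vibration main effects, mirroring heterogeneous vibration responses).

    Unconstrained layout: [beta (3 x p), gamma (3 x q), z_corr (3),
    log sd_u (3 x r), eps_u (J x 3 x r)].
    """

    def __init__(
        self,
        X: np.ndarray,
        W: np.ndarray,
        Y: np.ndarray,
        participant: np.ndarray,
        beta_names: Sequence[str],
        sigma_names: Sequence[str],
        re_columns: Sequence[int] = (0, 1, 2),
        corr_prior_scale: float = 0.5,
        beta_transform: Optional[np.ndarray] = None,
        gamma_transform: Optional[np.ndarray] = None,
        gamma_prior_mean: Optional[np.ndarray] = None,
        gamma_prior_scale: Optional[np.ndarray] = None,
        parameterisation: str = "noncentred",
    ) -> None:
        self.X = np.ascontiguousarray(X, float)
        self.W = np.ascontiguousarray(W, float)
        self.Y = np.ascontiguousarray(Y, float)
        self.pid = np.asarray(participant, dtype=np.intp)
        self.n, self.p = self.X.shape
        self.q = self.W.shape[1]
        self.J = int(self.pid.max()) + 1
        self.beta_names = list(beta_names)
        self.sigma_names = list(sigma_names)
        self.re_cols = np.asarray(re_columns, dtype=np.intp)
        self.r = self.re_cols.size
        self.Z = self.X[:, self.re_cols]
        sd_y = np.std(self.Y, axis=0)
        sd_y = np.maximum(sd_y, 1e-8)
        self._sd_y = sd_y
        self.prior_beta = np.tile(2.5 * sd_y[:, None], (1, self.p))  # (3, p)
        if gamma_prior_mean is None:
            self.gamma_mean = np.zeros((3, self.q))
            self.gamma_mean[:, 0] = np.log(sd_y)  # sigma intercepts at the data SD
        else:
            self.gamma_mean = np.asarray(gamma_prior_mean, dtype=float)
        if gamma_prior_scale is None:
            self.prior_gamma = np.full((3, self.q), 1.0)
            self.prior_gamma[:, 0] = 1.5
        else:
            self.prior_gamma = np.asarray(gamma_prior_scale, dtype=float)
        # reporting transforms (fit in an orthogonalised basis, report dummy coding)
        self.beta_T = np.eye(self.p) if beta_transform is None else np.asarray(beta_transform, float)
        self.gamma_T = np.eye(self.q) if gamma_transform is None else np.asarray(gamma_transform, float)
        self.prior_sd_u = np.tile(sd_y[:, None], (1, self.r))  # HalfNormal scales (3, r)
        self.corr_prior_scale = float(corr_prior_scale)
        if parameterisation not in ("centred", "noncentred"):
            raise ValueError("parameterisation must be 'centred' or 'noncentred'")
        self.centred = parameterisation == "centred"
        self.dim = 3 * self.p + 3 * self.q + 3 + 3 * self.r + 3 * self.J * self.r
        # fused-bincount offsets for the (outcome, re-column) aggregates
        self._off = (np.arange(3 * self.r) * self.J)[:, None]

    def _unpack(self, x):
        p, q, J, r = self.p, self.q, self.J, self.r
        i = 0
        beta = x[i : i + 3 * p].reshape(3, p); i += 3 * p
        gamma = x[i : i + 3 * q].reshape(3, q); i += 3 * q
        z = x[i : i + 3]; i += 3
        lsd_u = x[i : i + 3 * r].reshape(3, r); i += 3 * r
        eps = x[i : i + 3 * J * r].reshape(J, 3, r)
        return beta, gamma, z, lsd_u, eps

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        x0 = np.zeros(self.dim)
        p, q, r = self.p, self.q, self.r
        x0[3 * p : 3 * p + 3 * q] = self.gamma_mean.ravel()
        i = 3 * p + 3 * q + 3
        x0[i : i + 3 * r] = np.log(0.5 * self.prior_sd_u).ravel()
        return x0

    def scale_hint(self) -> np.ndarray:
        sd_y = self._sd_y
        hint = np.ones(self.dim)
        p, q, J, r = self.p, self.q, self.J, self.r
        i = 0
        info_x = (self.X**2).sum(axis=0)
        su = 0.5 * self.prior_sd_u  # (3, r)
        for k in range(3):
            var_b = sd_y[k] ** 2 / (info_x + 1e-12)
            var_b[self.re_cols] += su[k] ** 2 / self.J  # between-participant floor
            hint[i : i + p] = np.sqrt(var_b)
            i += p
        info_w = (self.W**2).sum(axis=0)
        for k in range(3):
            hint[i : i + q] = 1.0 / np.sqrt(0.5 * info_w + 1e-12)
            i += q
        hint[i : i + 3] = 2.0 / np.sqrt(self.n)  # correlation params
        i += 3
        hint[i : i + 3 * r] = 0.4  # log random-effect SDs
        i += 3 * r
        info_z = np.empty((J, r))
        for c in range(r):
            info_z[:, c] = np.bincount(self.pid, weights=self.Z[:, c] ** 2,
                                       minlength=J)
        # (J, 3, r): per-outcome shrinkage of the participant deviations
        info = info_z[:, None, :] / sd_y[None, :, None] ** 2
        if self.centred:
            hint_eps = 1.0 / np.sqrt(1.0 / su[None, :, :] ** 2 + info)
        else:
            hint_eps = 1.0 / np.sqrt(1.0 + su[None, :, :] ** 2 * info)
        hint[i : i + 3 * J * r] = hint_eps.ravel()
        return hint

    def logp_grad(self, x: np.ndarray):
        beta, gamma, z, lsd_u, eps = self._unpack(x)
        lsd_u = np.clip(lsd_u, -200.0, 200.0)
        sd_u = np.exp(lsd_u)                         # (3, r)
        U = eps if self.centred else sd_u[None, :, :] * eps  # (J, 3, r)
        eta = self.X @ beta.T + np.einsum("ic,ikc->ik", self.Z, U[self.pid])
        logsig = self.W @ gamma.T                    # (n, 3)
        sig = np.exp(np.clip(logsig, -200.0, 200.0))
        R = (self.Y - eta) / sig                     # standardised residuals

        C = _corr_from_z(z)
        _, logdet = np.linalg.slogdet(C)
        P = np.linalg.inv(C)
        RP = R @ P                                   # (n, 3)

        n = self.n
        logp = float(
            -0.5 * np.einsum("ij,ij->", RP, R)
            - logsig.sum()
            - 0.5 * n * logdet
            - 3 * n * _LOG_SQRT_2PI
        )

        # d logp / d eta and / d logsig
        g_eta = RP / sig                             # (n, 3)
        g_logsig = RP * R - 1.0                      # (n, 3)

        grad = np.zeros_like(x)
        p, q, J, r = self.p, self.q, self.J, self.r
        i = 0
        g_beta = g_eta.T @ self.X - beta / self.prior_beta**2
        logp += float(-0.5 * np.sum((beta / self.prior_beta) ** 2))
        grad[i : i + 3 * p] = g_beta.ravel(); i += 3 * p

        g_gamma = g_logsig.T @ self.W - (gamma - self.gamma_mean) / self.prior_gamma**2
        logp += float(-0.5 * np.sum(((gamma - self.gamma_mean) / self.prior_gamma) ** 2))
        grad[i : i + 3 * q] = g_gamma.ravel(); i += 3 * q

        # correlation: analytic gradient wrt C, chain to z by differentiating
        # the tiny 3x3 construction numerically (exact to ~1e-10)
        M = R.T @ R
        G_C = 0.5 * (P @ M @ P) - 0.5 * n * P
        g_z = np.empty(3)
        h = 1e-6
        for k in range(3):
            zp, zm = z.copy(), z.copy()
            zp[k] += h
            zm[k] -= h
            dC = (_corr_from_z(zp) - _corr_from_z(zm)) / (2 * h)
            g_z[k] = float(np.sum(G_C * dC))
        g_z -= z / self.corr_prior_scale**2
        logp += float(-0.5 * np.sum((z / self.corr_prior_scale) ** 2))
        grad[i : i + 3] = g_z; i += 3

        # per-participant aggregates d logp / d U[j, k, c], one fused bincount
        Wts = (g_eta[:, :, None] * self.Z[:, None, :]).reshape(self.n, 3 * r).T
        GU = np.bincount(
            (self.pid[None, :] + self._off).ravel(),
            weights=Wts.ravel(), minlength=3 * r * J,
        ).reshape(3, r, J).transpose(2, 0, 1)        # (J, 3, r)

        if self.centred:
            inv_su2 = np.exp(-2.0 * lsd_u)           # (3, r)
            g_lsd = (
                -J + np.sum(eps**2, axis=0) * inv_su2
                - sd_u**2 / self.prior_sd_u**2 + 1.0
            )
            grad_eps = GU - eps * inv_su2[None, :, :]
            logp += float(
                -0.5 * np.sum(eps**2 * inv_su2[None, :, :]) - J * np.sum(lsd_u)
            )
        else:
            g_lsd = (
                np.sum(GU * eps, axis=0) * sd_u
                - sd_u**2 / self.prior_sd_u**2 + 1.0
            )
            grad_eps = GU * sd_u[None, :, :] - eps
            logp += float(-0.5 * np.sum(eps**2))
        logp += float(np.sum(-0.5 * sd_u**2 / self.prior_sd_u**2 + lsd_u))
        grad[i : i + 3 * r] = g_lsd.ravel(); i += 3 * r
        grad[i : i + 3 * J * r] = grad_eps.ravel()
        return logp, grad

    def transform_draws(self, draws: np.ndarray) -> Dict[str, np.ndarray]:
        p, q, r = self.p, self.q, self.r
        out: Dict[str, np.ndarray] = {}
        beta = draws[:, : 3 * p].reshape(-1, 3, p) @ self.beta_T.T
        for k, outc in enumerate(OUTCOMES):
            for c, col in enumerate(self.beta_names):
                out[f"{outc}_{col}"] = beta[:, k, c]
        gamma = draws[:, 3 * p : 3 * p + 3 * q].reshape(-1, 3, q) @ self.gamma_T.T
        for k, outc in enumerate(OUTCOMES):
            for c, col in enumerate(self.sigma_names):
                out[f"logsd_{outc}_{col}"] = gamma[:, k, c]
        z = draws[:, 3 * p + 3 * q : 3 * p + 3 * q + 3]
        r12 = np.tanh(z[:, 0])
        r13 = np.tanh(z[:, 1])
        r23 = np.tanh(z[:, 2]) * np.sqrt((1 - r12**2) * (1 - r13**2)) + r12 * r13
        out["corr_epe_mms"] = r12
        out["corr_epe_mt"] = r13
        out["corr_mms_mt"] = r23
        i = 3 * p + 3 * q + 3
        lsd_u = draws[:, i : i + 3 * r].reshape(-1, 3, r)
        for k, outc in enumerate(OUTCOMES):
            for c, col in enumerate(self.re_cols):
                out[f"sd_u_{outc}_{self.beta_names[col]}"] = np.exp(lsd_u[:, k, c])
        return out


def _task2_designs(df: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    md = _md_code(df["direction"])
    ago = df["agovib"].to_numpy(float)
    anta = df["antavib"].to_numpy(float)
    td = df["td"].to_numpy(float) - 60.0
    X = np.column_stack([
        np.ones(len(df)), ago, anta, md, ago * anta, ago * md, anta * md,
        ago * anta * md, td, td * md,
    ])
    W = np.column_stack([
        np.ones(len(df)), ago, anta, md, ago * anta, ago * md, anta * md,
        ago * anta * md,
    ])
    return X, W


def fit_multivariate_model(
    trials: pd.DataFrame,
    draws: int = 1500,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
    corr_prior_scale: float = 0.5,
) -> FitResult:
    """Joint Task-2 model of (epe, mms, mt) with condition-dependent SDs.

    Outcomes are centred within participant by the no-vibration condition
    mean before fitting.  Requires both movement directions and all four
    vibration cells.  Summaries: per-outcome fixed effects (see
    :data:`FIXED_COLUMNS`), per-outcome log-SD coefficients over the
    vibration x direction cells, the residual correlations and the
    random-intercept SDs.  Direction-specific condition effects are
    obtained with :func:`direction_effects`.
    """
    df = trials[trials["task"] == 2].copy()
    missing = []
    for direction in ("extension", "flexion"):
        for ago, anta in ((0, 0), (1, 0), (0, 1), (1, 1)):
            m = (
                (df["direction"] == direction)
                & (df["agovib"] == ago) & (df["antavib"] == anta)
            )
            if not m.any():
                missing.append(f"{direction}/ago={ago}/anta={anta}")
    if missing:
        raise ValueError("missing design cells: " + ", ".join(missing))
    baseline = ((df["agovib"] == 0) & (df["antavib"] == 0)).to_numpy()
    Y = np.column_stack([
        centre_by_baseline(df, out, baseline) for out in OUTCOMES
    ])
    X, W = _task2_designs(df)

    # sample in an orthogonalised basis (mean-centred factors; cell-indicator
    # sigma design) and map draws back to the dummy-coded coefficients
    md = _md_code(df["direction"])
    ago_c = df["agovib"].to_numpy(float) - df["agovib"].mean()
    anta_c = df["antavib"].to_numpy(float) - df["antavib"].mean()
    td = df["td"].to_numpy(float) - 60.0
    Xc = np.column_stack([
        np.ones(len(df)), ago_c, anta_c, md, ago_c * anta_c, ago_c * md,
        anta_c * md, ago_c * anta_c * md, td, td * md,
    ])
    Xc[:, 1:] -= Xc[:, 1:].mean(axis=0)
    A, res, *_ = np.linalg.lstsq(Xc, X, rcond=None)
    beta_T = np.linalg.inv(A)

    cell = (
        df["agovib"].astype(int) * 4 + df["antavib"].astype(int) * 2
        + (df["direction"] == "flexion").astype(int)
    ).to_numpy()
    Wc = np.zeros((len(df), 8))
    Wc[np.arange(len(df)), cell] = 1.0
    B = np.zeros((8, 8))
    for c in range(8):
        ago, anta, flex = c // 4, (c // 2) % 2, c % 2
        m = 0.5 if flex else -0.5
        B[c] = [1.0, ago, anta, m, ago * anta, ago * m, anta * m, ago * anta * m]
    gamma_T = np.linalg.inv(B)
    sd_y = np.maximum(np.std(Y, axis=0), 1e-8)
    gamma_prior_mean = np.tile(np.log(sd_y)[:, None], (1, 8))
    gamma_prior_scale = np.full((3, 8), 1.5)

    model = MvnModel(
        Xc, Wc, Y, pd.Categorical(df["participant"]).codes,
        beta_names=FIXED_COLUMNS, sigma_names=SIGMA_COLUMNS,
        corr_prior_scale=corr_prior_scale,
        beta_transform=beta_T, gamma_transform=gamma_T,
        gamma_prior_mean=gamma_prior_mean, gamma_prior_scale=gamma_prior_scale,
    )
    return fit_model(model, draws=draws, warmup=warmup, chains=chains, seed=seed)


def direction_effects(fit: FitResult, outcomes: Sequence[str] = OUTCOMES) -> pd.DataFrame:
    """Per-direction condition effects from a multivariate-model fit.

    With the sum-to-zero direction code (flexion +0.5, extension -0.5),
    the flexion-direction effect of e.g. antagonist vibration is
    beta_antavib + 0.5 * beta_antavib:md (per draw, then summarised).
    Movement time is reported in ms.
    """
    rows = []
    for outc in outcomes:
        for eff in ("agovib", "antavib", "agovib:antavib"):
            for direction, sign in (("flexion", 0.5), ("extension", -0.5)):
                name = f"{outc}_{eff}@{direction}"
                summ = fit.derived(
                    name,
                    lambda ch, o=outc, e=eff, s=sign: ch[f"{o}_{e}"] + s * ch[f"{o}_{e}:md"],
                )
                scale = 1000.0 if outc == "mt" else 1.0
                rows.append((outc, eff, direction, scale * summ.map,
                             scale * summ.ci_low, scale * summ.ci_high))
    return pd.DataFrame(rows, columns=["outcome", "effect", "direction",
                                       "map", "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# integrative endpoint-error ~ speed model
# ---------------------------------------------------------------------------


def fit_epe_speed_model(
    trials: pd.DataFrame,
    draws: int = 1500,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
) -> FitResult:
    """Baseline (no-vibration) Task-2 model: epe_z ~ mms_z with
    direction-specific slopes.

    Endpoint error and mean movement speed are z-scored within
    participant-and-direction; the linear predictor is
    b0 + b1 mms_z x md + b2 td x md (full expansion).  Direction-specific
    slopes are derived as b_mms +/- 0.5 b_mms:md.
    """
    df = trials[
        (trials["task"] == 2) & (trials["agovib"] == 0) & (trials["antavib"] == 0)
    ].copy()
    if df.empty:
        raise ValueError("no baseline (no-vibration) trials")
    group = (
        df["participant"].astype(str) + "/" + df["direction"].astype(str)
    ).to_numpy()
    epe_z = zscore_within(df["epe"].to_numpy(float), group)
    mms_z = zscore_within(df["mms"].to_numpy(float), group)
    md = _md_code(df["direction"])
    td = df["td"].to_numpy(float) - 60.0
    X = np.column_stack([
        np.ones(len(df)), mms_z, mms_z * md, td, td * md, md,
    ])
    model = HierarchicalGLM(
        X, epe_z, pd.Categorical(df["participant"]).codes,
        beta_names=["beta0", "beta_mms_z", "beta_mms_z:md", "beta_td",
                    "beta_td:md", "beta_md"],
        likelihood="gaussian",
        re_columns=[0, 1, 2],
        prior_scale_beta=1.0,
        prior_scale_sd=1.0,
        prior_scale_sigma=1.0,
    )
    fit = fit_model(model, draws=draws, warmup=warmup, chains=chains, seed=seed)
    for direction, sign in (("flexion", 0.5), ("extension", -0.5)):
        fit.derived(
            f"slope@{direction}",
            lambda ch, s=sign: ch["beta_mms_z"] + s * ch["beta_mms_z:md"],
        )
    return fit
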