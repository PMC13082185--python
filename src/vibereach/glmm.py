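"""Hierarchical generalised linear models with analytic gradients.

One model class covers the Bernoulli-probit rating analyses and the
Gaussian movement-speed / endpoint-error analyses: a population-level
linear predictor plus per-participant deviations on (by default) every
population column, in the non-centred parameterisation

    eta_i = x_i' beta + x_i[re]' (sigma_u * eps_{j(i)}),   eps_jk ~ N(0, 1)

with weakly informative zero-centred priors: beta_k ~ N(0, s_k),
sigma_u,k ~ HalfNormal(h_k) and, for the Gaussian likelihood, a
HalfNormal prior on the residual SD.  Unconstrained parameters are
``[beta, log sigma_u, eps (J x q), (log sigma_res)]``.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
from scipy.special import log_ndtr

__all__ = ["HierarchicalGLM"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class HierarchicalGLM:
    """Probit or Gaussian mixed model on an explicit design matrix.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column).
    y : (n,) response; {0, 1} for ``likelihood="probit"``, real-valued
        for ``likelihood="gaussian"``.
    participant : (n,) integer codes 0..J-1.
    beta_names : column names, used to label posterior summaries.
    re_columns : indices of columns that get participant-level deviations
        (default: all columns).
    prior_scale_beta : SD of the zero-centred normal prior per column.
    prior_scale_sd : HalfNormal scale for the random-effect SDs.
    prior_scale_sigma : HalfNormal scale for the residual SD (Gaussian only).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        participant: np.ndarray,
        beta_names: Sequence[str],
        likelihood: str = "probit",
        re_columns: Optional[Sequence[int]] = None,
        prior_scale_beta: float | Sequence[float] = 1.0,
        prior_scale_sd: float | Sequence[float] = 1.0,
        prior_scale_sigma: float = 1.0,
        beta_transform: Optional[np.ndarray] = None,
        parameterisation: str = "noncentred",
    ) -> None:
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.pid = np.asarray(participant, dtype=np.intp)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X and y are inconsistent")
        if self.pid.min() < 0:
            raise ValueError("participant codes must be non-negative")
        self.n, self.p = self.X.shape
        self.J = int(self.pid.max()) + 1
        if likelihood not in ("probit", "gaussian"):
            raise ValueError("likelihood must be 'probit' or 'gaussian'")
        if likelihood == "probit":
            uniq = np.unique(self.y)
            if not np.all(np.isin(uniq, [0.0, 1.0])):
                raise ValueError("probit responses must be coded 0/1")
            if uniq.size < 2:
                raise ValueError(
                    "both rating levels must be present; a constant response "
                    "is separable and cannot identify the effects"
                )
        self.likelihood = likelihood
        self.beta_names = list(beta_names)
        if len(self.beta_names) != self.p:
            raise ValueError("beta_names must match design columns")
        self.re_cols = (
            np.arange(self.p) if re_columns is None else np.asarray(re_columns, dtype=np.intp)
        )
        self.q = self.re_cols.size
        self.Z = self.X[:, self.re_cols]
        self.tau_beta = np.broadcast_to(
            np.asarray(prior_scale_beta, dtype=float), (self.p,)
        ).copy()
        self.h_sd = np.broadcast_to(
            np.asarray(prior_scale_sd, dtype=float), (self.q,)
        ).copy()
        self.h_sigma = float(prior_scale_sigma)
        # optional reporting transform: summaries are of T @ beta_fitted
        # (used to fit in an orthogonalised basis but report dummy coding)
        self.beta_T = (
            np.eye(self.p) if beta_transform is None
            else np.asarray(beta_transform, dtype=float)
        )
        if parameterisation not in ("centred", "noncentred"):
            raise ValueError("parameterisation must be 'centred' or 'noncentred'")
        # centred (u_j sampled directly) mixes better when participants have
        # many trials, which is the regime of these cohorts; the non-centred
        # variant is kept for sparse-data uses
        self.centred = parameterisation == "centred"
        self.dim = self.p + self.q + self.J * self.q + (
            1 if likelihood == "gaussian" else 0
        )

    # -- parameter vector layout helpers ------------------------------------
    def _unpack(self, x: np.ndarray):
        p, q, J = self.p, self.q, self.J
        beta = x[:p]
        log_su = x[p : p + q]
        eps = x[p + q : p + q + J * q].reshape(J, q)
        log_sigma = x[-1] if self.likelihood == "gaussian" else None
        return beta, log_su, eps, log_sigma

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        x0 = np.zeros(self.dim)
        p, q = self.p, self.q
        x0[p : p + q] = np.log(0.5 * self.h_sd)
        if self.likelihood == "gaussian":
            resid_sd = max(np.std(self.y), 1e-3)
            x0[-1] = np.log(resid_sd)
        return x0

    def scale_hint(self) -> np.ndarray:
        """Rough posterior-scale guesses used to seed the mass matrix."""
        if self.likelihood == "probit":
            w = 0.6 * np.ones(self.n)  # probit information per obs, roughly
        else:
            w = np.full(self.n, 1.0 / max(np.var(self.y) * 0.5, 1e-12))
        hint = np.ones(self.dim)
        info_beta = (self.X**2 * w[:, None]).sum(axis=0)
        var_beta = 1.0 / (info_beta + 1e-12)
        # group means of columns with participant deviations keep a
        # between-participant variance floor of sd_u^2 / J
        su = 0.5 * self.h_sd
        var_beta[self.re_cols] += su**2 / self.J
        hint[: self.p] = np.minimum(np.sqrt(var_beta), self.tau_beta)
        hint[self.p : self.p + self.q] = 0.4
        # non-centred deviations: info scales with per-participant data
        su = 0.5 * self.h_sd
        info_eps = np.zeros((self.J, self.q))
        np.add.at(info_eps, self.pid, self.Z**2 * w[:, None])
        if self.centred:
            hint_eps = 1.0 / np.sqrt(1.0 / su[None, :] ** 2 + info_eps)
        else:
            hint_eps = 1.0 / np.sqrt(1.0 + su[None, :] ** 2 * info_eps)
        hint[self.p + self.q : self.p + self.q + self.J * self.q] = hint_eps.ravel()
        if self.likelihood == "gaussian":
            hint[-1] = 1.0 / np.sqrt(2.0 * self.n)
        return hint

    # -- log posterior + gradient -------------------------------------------
    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        beta, log_su, eps, log_sigma = self._unpack(x)
        log_su = np.clip(log_su, -200.0, 200.0)
        su = np.exp(log_su)
        U = eps if self.centred else su * eps  # (J, q)
        eta = self.X @ beta + np.einsum("ij,ij->i", self.Z, U[self.pid])

        grad = np.zeros_like(x)
        p, q, J = self.p, self.q, self.J

        if self.likelihood == "probit":
            # |eta| > 37 saturates the normal CDF at double precision; the
            # clip keeps divergent trajectories finite without changing logp
            eta = np.clip(eta, -37.0, 37.0)
            lp_eta = -0.5 * eta * eta - _LOG_SQRT_2PI
            lcdf = log_ndtr(eta)
            lsf = log_ndtr(-eta)
            logp = float(np.sum(np.where(self.y > 0.5, lcdf, lsf)))
            # d log Bernoulli(Phi(eta)) / d eta
            g_eta = np.where(
                self.y > 0.5,
                np.exp(lp_eta - lcdf),
                -np.exp(lp_eta - lsf),
            )
        else:
            log_sigma = float(np.clip(log_sigma, -200.0, 200.0))
            inv_var = np.exp(-2.0 * log_sigma)
            sigma_sq = np.exp(2.0 * log_sigma)
            resid = self.y - eta
            ss = float(resid @ resid)
            logp = -self.n * log_sigma - 0.5 * ss * inv_var - self.n * _LOG_SQRT_2PI
            g_eta = resid * inv_var
            # d/d log sigma: likelihood + HalfNormal prior (with log jacobian)
            grad[-1] = (
                -self.n + ss * inv_var - sigma_sq / self.h_sigma**2 + 1.0
            )
            logp += -0.5 * sigma_sq / self.h_sigma**2 + log_sigma

        # fixed effects
        grad[:p] = self.X.T @ g_eta - beta / self.tau_beta**2
        logp += float(-0.5 * np.sum((beta / self.tau_beta) ** 2))

        # random effects
        GU = np.empty((J, q))
        for k in range(q):
            GU[:, k] = np.bincount(self.pid, weights=g_eta * self.Z[:, k], minlength=J)
        if self.centred:
            # u_j ~ N(0, su); SDs get the implied likelihood J*log su term
            inv_su2 = np.exp(-2.0 * log_su)
            grad[p + q : p + q + J * q] = (GU - eps * inv_su2).ravel()
            logp += float(
                -0.5 * np.sum(eps**2 * inv_su2) - J * np.sum(log_su)
            )
            grad[p : p + q] = (
                -J + np.sum(eps**2, axis=0) * inv_su2
                - su**2 / self.h_sd**2 + 1.0
            )
        else:
            grad[p + q : p + q + J * q] = (GU * su - eps).ravel()
            logp += float(-0.5 * np.sum(eps * eps))
            grad[p : p + q] = (
                np.sum(GU * eps, axis=0) * su - su**2 / self.h_sd**2 + 1.0
            )
        logp += float(np.sum(-0.5 * su**2 / self.h_sd**2 + log_su))

        return logp, grad

    # -- summaries ------------------------------------------------------------
    def transform_draws(self, draws: np.ndarray) -> Dict[str, np.ndarray]:
        p, q = self.p, self.q
        out: Dict[str, np.ndarray] = {}
        beta_rep = draws[:, :p] @ self.beta_T.T
        for k, name in enumerate(self.beta_names):
            out[name] = beta_rep[:, k]
        for k, col in enumerate(self.re_cols):
            out[f"sd_{self.beta_names[col]}"] = np.exp(draws[:, p + k])
        if self.likelihood == "gaussian":
            out["sigma"] = np.exp(draws[:, -1])
        return out
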