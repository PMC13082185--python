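"""Gradient-based MCMC engine and posterior summaries.

All hierarchical models in this package expose a differentiable
log-posterior over an unconstrained parameter vector and are sampled with
the No-U-Turn Sampler (NUTS), a self-tuning variant of Hamiltonian Monte
Carlo.  Warm-up adapts the leapfrog step size by dual averaging toward a
target acceptance statistic and estimates a diagonal mass matrix from an
intermediate adaptation window.

Posterior marginals are summarised the way the analyses report them: the
maximum a posteriori (MAP) point is the mode of a Gaussian kernel density
estimate over the draws (Silverman bandwidth) and the 95% credible
interval is equal-tailed (2.5/97.5 percentiles).  Convergence is judged
against R-hat < 1.005 for every reported parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Protocol, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "Model",
    "PosteriorSummary",
    "FitResult",
    "nuts_sample",
    "fit_model",
    "map_estimate",
    "RHAT_THRESHOLD",
]

#: convergence rule: every reported parameter must satisfy rhat below this
RHAT_THRESHOLD = 1.005


class Model(Protocol):
    """Protocol for a differentiable unconstrained-space posterior."""

    dim: int

    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]: ...

    def initial(self, rng: np.random.Generator) -> np.ndarray: ...

    def transform_draws(self, draws: np.ndarray) -> Dict[str, np.ndarray]:
        """Map raw draws (n, dim) to named constrained-scale arrays."""
        ...


# ---------------------------------------------------------------------------
# NUTS
# ---------------------------------------------------------------------------

_MAX_DEPTH = 8
_DELTA_MAX = 1000.0  # divergence threshold on energy error


def _find_initial_step(logp_grad, x, rng, inv_mass):
    eps = 1.0
    lp, grad = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(inv_mass * p * p)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**a
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * math.log(0.5):
            break
    return max(eps, 1e-8)


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


class _Tree:
    __slots__ = (
        "x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
        "x_prop", "lp_prop", "g_prop", "n", "s", "alpha", "n_alpha",
    )


def _build_tree(logp_grad, x, p, grad, log_u, v, j, eps, h0, inv_mass, rng):
    tree = _Tree()
    if j == 0:
        x1, p1, lp1, g1 = _leapfrog(logp_grad, x, p, grad, v * eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        tree.x_minus = tree.x_plus = tree.x_prop = x1
        tree.p_minus = tree.p_plus = p1
        tree.g_minus = tree.g_plus = tree.g_prop = g1
        tree.lp_prop = lp1
        tree.n = 1 if log_u <= h1 else 0
        tree.s = 1 if log_u < h1 + _DELTA_MAX else 0
        tree.alpha = min(1.0, math.exp(min(h1 - h0, 0.0)))
        tree.n_alpha = 1
        return tree

    left = _build_tree(logp_grad, x, p, grad, log_u, v, j - 1, eps, h0, inv_mass, rng)
    tree.x_minus, tree.p_minus, tree.g_minus = left.x_minus, left.p_minus, left.g_minus
    tree.x_plus, tree.p_plus, tree.g_plus = left.x_plus, left.p_plus, left.g_plus
    tree.x_prop, tree.lp_prop, tree.g_prop = left.x_prop, left.lp_prop, left.g_prop
    tree.n, tree.s = left.n, left.s
    tree.alpha, tree.n_alpha = left.alpha, left.n_alpha
    if left.s == 1:
        if v == -1:
            right = _build_tree(
                logp_grad, left.x_minus, left.p_minus, left.g_minus,
                log_u, v, j - 1, eps, h0, inv_mass, rng)
            tree.x_minus, tree.p_minus, tree.g_minus = (
                right.x_minus, right.p_minus, right.g_minus)
        else:
            right = _build_tree(
                logp_grad, left.x_plus, left.p_plus, left.g_plus,
                log_u, v, j - 1, eps, h0, inv_mass, rng)
            tree.x_plus, tree.p_plus, tree.g_plus = (
                right.x_plus, right.p_plus, right.g_plus)
        total = right.n + left.n
        if total > 0 and rng.random() < right.n / total:
            tree.x_prop, tree.lp_prop, tree.g_prop = (
                right.x_prop, right.lp_prop, right.g_prop)
        dx = tree.x_plus - tree.x_minus
        no_uturn = (
            np.dot(dx, inv_mass * tree.p_minus) >= 0
            and np.dot(dx, inv_mass * tree.p_plus) >= 0
        )
        tree.s = right.s * int(no_uturn)
        tree.n = total
        tree.alpha = left.alpha + right.alpha
        tree.n_alpha = left.n_alpha + right.n_alpha
    return tree


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_draws: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = _MAX_DEPTH,
    inv_mass0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, dict]:
    """Run one NUTS chain; returns (draws (n_draws, dim), stats dict).

    ``inv_mass0`` seeds the diagonal inverse mass matrix (posterior-scale
    guesses squared); warm-up refines it from windowed draw variances.
    """
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, float).copy()

    # dual-averaging state (Hoffman & Gelman 2014)
    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # warm-up schedule: a fast step-size interval, then doubling "slow"
    # windows each ending in a diagonal mass-matrix update, then a final
    # fast interval (the usual windowed-adaptation layout)
    fast_head = min(75, int(0.15 * n_warmup))
    fast_tail = min(50, int(0.1 * n_warmup))
    slow_total = max(n_warmup - fast_head - fast_tail, 0)
    mass_updates: List[int] = []
    w = 25
    pos = fast_head
    while slow_total > 0 and pos < fast_head + slow_total:
        end = min(pos + w, fast_head + slow_total)
        if fast_head + slow_total - end < 25:  # absorb the remainder
            end = fast_head + slow_total
        mass_updates.append(end)
        pos = end
        w *= 2
    window: List[np.ndarray] = []

    lp, grad = logp_grad(x)
    draws = np.empty((n_draws, dim))
    divergences = 0
    accept_sum = 0.0
    depth_sum = 0
    m_adapt = 0  # dual-averaging step counter (reset after mass update)

    for m in range(n_warmup + n_draws):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p * p)
        log_u = h0 + math.log(rng.random())
        x_minus = x_plus = x
        p_minus = p_plus = p
        g_minus = g_plus = grad
        x_new, lp_new, g_new = x, lp, grad
        n, s, j = 1, 1, 0
        alpha, n_alpha = 1.0, 1
        while s == 1 and j < max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                tree = _build_tree(logp_grad, x_minus, p_minus, g_minus,
                                   log_u, v, j, eps, h0, inv_mass, rng)
                x_minus, p_minus, g_minus = tree.x_minus, tree.p_minus, tree.g_minus
            else:
                tree = _build_tree(logp_grad, x_plus, p_plus, g_plus,
                                   log_u, v, j, eps, h0, inv_mass, rng)
                x_plus, p_plus, g_plus = tree.x_plus, tree.p_plus, tree.g_plus
            if tree.s == 1 and tree.n > 0 and rng.random() < min(1.0, tree.n / n):
                x_new, lp_new, g_new = tree.x_prop, tree.lp_prop, tree.g_prop
            n += tree.n
            dx = x_plus - x_minus
            no_uturn = (
                np.dot(dx, inv_mass * p_minus) >= 0
                and np.dot(dx, inv_mass * p_plus) >= 0
            )
            s = tree.s * int(no_uturn)
            alpha, n_alpha = tree.alpha, tree.n_alpha
            j += 1
        x, lp, grad = x_new, lp_new, g_new
        accept_stat = alpha / max(n_alpha, 1)

        if m < n_warmup:
            m_adapt += 1
            frac = 1.0 / (m_adapt + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - math.sqrt(m_adapt) / gamma * h_bar
            eta = m_adapt ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if m >= fast_head and mass_updates:
                window.append(x.copy())
            if mass_updates and m == mass_updates[0] - 1:
                mass_updates.pop(0)
                if len(window) >= 10:
                    var = np.var(np.asarray(window), axis=0)
                    n_w = len(window)
                    # regularised like Stan: shrink slightly toward unit
                    inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    # restart step-size adaptation around a fresh heuristic
                    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
                window = []
            if m == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            if accept_stat < 1e-12 or not np.isfinite(lp):
                divergences += 1
            accept_sum += accept_stat
            depth_sum += j
            draws[m - n_warmup] = x

    stats = {
        "divergences": divergences,
        "mean_accept": accept_sum / max(n_draws, 1),
        "step_size": eps,
        "mean_treedepth": depth_sum / max(n_draws, 1),
    }
    return draws, stats


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def map_estimate(draws: np.ndarray) -> float:
    """Mode of a Silverman-bandwidth Gaussian KDE over MCMC draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("no draws")
    if np.ptp(draws) < 1e-12:
        return float(draws[0])
    kde = gaussian_kde(draws)  # scipy default is Silverman-like (scott); set silverman
    kde.set_bandwidth("silverman")
    grid = np.linspace(draws.min(), draws.max(), 512)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


@dataclass
class PosteriorSummary:
    """MAP + 95% credible interval + diagnostics for one scalar parameter."""

    name: str
    map: float
    ci_low: float
    ci_high: float
    rhat: float
    ess: float
    draws: np.ndarray = field(repr=False)

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    @property
    def ci_half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


def _summaries_from_chains(chains: np.ndarray, name: str) -> PosteriorSummary:
    """chains: (n_chains, n_draws) for one scalar."""
    flat = chains.reshape(-1)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    if chains.shape[0] >= 2:
        da = az.convert_to_dataset({"x": chains})
        rhat = float(az.rhat(da)["x"].values)
        ess = float(az.ess(da)["x"].values)
    else:
        rhat, ess = np.nan, float(flat.size)
    return PosteriorSummary(
        name=name, map=map_estimate(flat), ci_low=float(lo), ci_high=float(hi),
        rhat=rhat, ess=ess, draws=flat,
    )


@dataclass
class FitResult:
    """A fitted model: named posterior summaries plus raw draws.

    ``params[name]`` is a :class:`PosteriorSummary`; ``chains[name]`` keeps
    the per-chain draw array (n_chains, n_draws) or (n_chains, n_draws, k)
    for vector-valued names.
    """

    params: Dict[str, PosteriorSummary]
    chains: Dict[str, np.ndarray]
    sampler_stats: List[dict]
    flags: List[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(
            (np.isnan(p.rhat) or p.rhat < RHAT_THRESHOLD)
            for p in self.params.values()
        )

    @property
    def max_rhat(self) -> float:
        vals = [p.rhat for p in self.params.values() if np.isfinite(p.rhat)]
        return max(vals) if vals else float("nan")

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.params[name]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": p.name, "map": p.map, "ci_low": p.ci_low,
                "ci_high": p.ci_high, "rhat": p.rhat, "ess": p.ess,
            }
            for p in self.params.values()
        ]
        return pd.DataFrame(rows).set_index("parameter")

    def derived(self, name: str, fn: Callable[[Dict[str, np.ndarray]], np.ndarray]) -> PosteriorSummary:
        """Summarise a per-draw function of the stored chains (linear combos etc.)."""
        out = fn(self.chains)
        summ = _summaries_from_chains(np.asarray(out), name)
        self.params[name] = summ
        return summ


def fit_model(
    model: Model,
    draws: int = 1500,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
    target_accept: float = 0.8,
    jitter: float = 0.5,
) -> FitResult:
    """Sample ``model`` with NUTS and summarise every named parameter.

    Defaults mirror the full analysis profile (4 chains; reduce ``draws``/
    ``warmup``/``chains`` for quick exploratory fits).  Seeds for the chains
    are spawned deterministically from ``seed``.
    """
    if chains < 1:
        raise ValueError("need at least one chain")
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)
    raw = np.empty((chains, draws, model.dim))
    stats = []
    hint = getattr(model, "scale_hint", None)
    inv_mass0 = None if hint is None else np.maximum(hint(), 1e-8) ** 2
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        x0 = model.initial(rng)
        if jitter > 0:
            x0 = x0 + jitter * rng.standard_normal(model.dim) * 0.1
        d, st = nuts_sample(
            model.logp_grad, x0, draws, warmup, rng,
            target_accept=target_accept, inv_mass0=inv_mass0,
        )
        raw[c] = d
        stats.append(st)

    # transform to constrained scale, chain structure preserved
    named_chains: Dict[str, np.ndarray] = {}
    per_chain = [model.transform_draws(raw[c]) for c in range(chains)]
    for key in per_chain[0]:
        named_chains[key] = np.stack([pc[key] for pc in per_chain], axis=0)

    params: Dict[str, PosteriorSummary] = {}
    for key, arr in named_chains.items():
        if arr.ndim == 2:
            params[key] = _summaries_from_chains(arr, key)
        else:
            for k in range(arr.shape[-1]):
                nm = f"{key}[{k}]"
                params[nm] = _summaries_from_chains(arr[..., k], nm)

    fit = FitResult(params=params, chains=named_chains, sampler_stats=stats)
    n_div = sum(s["divergences"] for s in stats)
    if n_div:
        fit.flags.append(f"{n_div} divergent transitions")
    if not fit.converged:
        fit.flags.append(
            f"convergence check failed: max rhat {fit.max_rhat:.4f} >= {RHAT_THRESHOLD}"
        )
    return fit
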