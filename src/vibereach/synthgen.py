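"""Synthetic cohorts for the three vibration-reaching tasks.

The generator emulates the statistical structure of a single-joint
(elbow) VR reaching study in which muscle vibration biases perceived
movement speed: 17 participants; Task 1 crosses five visual speed gains
(-12..+12% in 6% steps) with four vibration conditions (agonist,
antagonist, both, none) and collects Faster/Slower ratings of a virtual
arm; Task 2 crosses the four vibration conditions with movement
direction and measures endpoint error, mean movement speed and movement
time; Task 3 switches the antagonist vibration motor on or off 20° into
an 80° extension and records 90 Hz controller positions so that the
latency of the speed correction can be estimated.

Every effect is drawn from known group-level distributions held in
:class:`CohortTruth`, so downstream model fits can be validated by
parameter recovery.  Angular trajectories are minimum-jerk (bell-shaped
speed profile, closed form), sampled at the headset rate and converted
to 2-D controller positions on a circle whose radius matches the
forearm pivot geometry (default 0.361 m).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "CohortTruth",
    "TrackedSeries",
    "generate_trajectory",
    "apply_speed_change",
    "generate_cohort",
    "task_design",
    "speed_deviation_sd",
    "implied_baseline_epe_slope",
    "corr_for_epe_slope",
    "write_trials_csv",
    "write_tracked",
    "write_truth_json",
    "TRIAL_COLUMNS",
]

#: column dictionary for the long-format trial table
TRIAL_COLUMNS = {
    "participant": "participant id, 0-based int",
    "task": "task number, 1|2|3",
    "trial": "within-participant trial index (presentation order)",
    "direction": "'extension' or 'flexion'",
    "vg": "visual speed gain in percent, one of -12,-6,0,6,12 (task 1; else 0)",
    "vg_units": "visual gain in +6% units, -2..2",
    "agovib": "agonist vibration flag 0/1",
    "antavib": "antagonist vibration flag 0/1",
    "vib_window": "'none'|'full'|'0-20'|'20-80' (task 3; else 'none')",
    "td": "target distance, degrees",
    "epe": "signed endpoint error, degrees (negative = undershoot)",
    "mms": "mean movement speed, deg/s",
    "mt": "movement time, s",
    "rating": "1 = 'Faster', 0 = 'Slower' (task 1 only, else NaN)",
}

_VIB_CELLS: Tuple[Tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))


@dataclass
class CohortTruth:
    """Ground-truth generative parameters of a synthetic cohort.

    Rating-model parameters live on the latent probit scale; movement
    effects are in degrees, deg/s and seconds.  Movement effects are the
    flexion-direction values; extension effects are scaled by
    ``ext_scale`` (Task 1, extension-only, uses the values unscaled).
    Defaults are the study's reported condition effects; baseline
    self-paced kinematics (``base_mt`` and friends) are assumptions, as
    baseline speeds are not part of the reported summaries.
    """

    n_participants: int = 17
    seed: int = 0

    # rating model (latent probit scale)
    beta0_rating: float = 0.04          # Phi(0.04) ~ 51.6% baseline 'Faster'
    beta_vg: float = 0.41               # latent shift per +6% visual gain
    beta_ago_rating: float = 0.0
    beta_anta_rating: float = -0.29
    rating_speed_slope: float = 0.37    # latent shift per SD of speed residual

    # movement-outcome effects (flexion values; extension scaled by ext_scale)
    speed_effect_ago: float = 2.71      # deg/s
    speed_effect_anta: float = -3.13
    epe_effect_ago: float = 1.45        # degrees
    epe_effect_anta: float = -2.76
    mt_effect_ago: float = -0.0739      # seconds
    mt_effect_anta: float = 0.05248
    ext_scale: float = 0.45
    vg_speed_effect: float = 0.0        # deg/s per +6% gain on actual speed

    # residual structure
    epe_speed_corr: float = 0.20        # residual corr(epe, mms)
    epe_mt_corr: float = 0.0
    mms_mt_corr: float = 0.0
    sd_epe: float = 3.0                 # degrees
    sd_mms: float = 8.0                 # deg/s
    sd_mt: float = 0.12                 # seconds

    # changepoint (task 3)
    tau_mean: float = 0.0482            # s, group mean latency
    tau_sd: float = 0.005               # s, between-participant SD
    vib_speed_change: float = -0.10     # fractional speed change under antagonist vibration

    # random-effect SDs (between-participant)
    re_sd_rating: float = 0.30          # latent-scale intercept + slopes
    re_sd_epe: float = 1.5              # degrees, intercepts and vibration slopes
    re_sd_mms: float = 2.0              # deg/s
    re_sd_mt: float = 0.05              # seconds

    # baseline self-paced kinematics (assumption; not a reported quantity)
    base_mt: float = 1.1                # s, group mean movement duration
    base_mt_sd: float = 0.15            # s, between-participant SD
    mt_trial_cv: float = 0.10           # lognormal trial-to-trial CV of duration
    epe_bias: float = 0.0               # baseline endpoint bias, degrees
    td_epe_slope: float = -0.02         # deg epe per deg td (mild undershoot scaling)

    # tracking geometry / noise
    radius_m: float = 0.361
    sample_rate: float = 90.0
    tracking_noise_m: float = 3e-4
    hardware_delay: float = 0.1188      # s, trigger-to-vibration delay

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.tau_mean <= 0.12):
            raise ValueError("tau_mean must lie in [0, 0.12] s")
        if abs(self.epe_speed_corr) >= 1:
            raise ValueError("|epe_speed_corr| must be < 1")
        for name in ("tau_sd", "sd_epe", "sd_mms", "sd_mt", "re_sd_rating",
                     "re_sd_epe", "re_sd_mms", "re_sd_mt", "base_mt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def null(cls, **kwargs) -> "CohortTruth":
        """All condition effects and couplings zero (calibration truth)."""
        zero = dict(
            beta0_rating=0.0, beta_vg=0.0, beta_ago_rating=0.0,
            beta_anta_rating=0.0, rating_speed_slope=0.0,
            speed_effect_ago=0.0, speed_effect_anta=0.0,
            epe_effect_ago=0.0, epe_effect_anta=0.0,
            mt_effect_ago=0.0, mt_effect_anta=0.0,
            vg_speed_effect=0.0, epe_speed_corr=0.0,
            epe_mt_corr=0.0, mms_mt_corr=0.0, vib_speed_change=0.0,
        )
        zero.update(kwargs)
        return cls(**zero)


@dataclass
class TrackedSeries:
    """Timestamped controller samples for one trial (nominal 90 Hz)."""

    trial_id: int
    t: np.ndarray                  # seconds
    x: np.ndarray                  # metres
    y: np.ndarray                  # metres
    angle: np.ndarray              # degrees of task progress (0 at start)
    vib_state: np.ndarray          # per-sample 0/1
    trigger_angle: float = np.nan  # degrees at which vibration state changes
    direction: str = "extension"
    participant: int = 0
    condition: str = "none"
    center: Tuple[float, float] = (0.0, 0.0)
    radius: float = 0.361

    def validate(self) -> None:
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")
        med = np.median(np.diff(self.t))
        if not (0.8 / 90.0 <= med <= 1.2 / 90.0):
            raise ValueError("median sampling interval outside 20% of 1/90 s")


def _minjerk(s: np.ndarray) -> np.ndarray:
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _angles_to_xy(angle_deg, start_world_deg, direction, center, radius):
    sign = 1.0 if direction == "extension" else -1.0
    world = np.deg2rad(start_world_deg + sign * angle_deg)
    return center[0] + radius * np.cos(world), center[1] + radius * np.sin(world)


def generate_trajectory(
    start_angle: float,
    distance: float,
    duration: float,
    sample_rate: float = 90.0,
    *,
    radius: float = 0.361,
    center: Tuple[float, float] = (0.0, 0.0),
    direction: str = "extension",
    noise_sd: float = 0.0,
    trigger_angle: float = np.nan,
    trial_id: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> TrackedSeries:
    """Minimum-jerk angular reach sampled at the headset rate.

    theta(t) = start + distance * (10 s^3 - 15 s^4 + 6 s^5), s = t/duration.
    The ``angle`` field stores task progress in degrees (0 at start); 2-D
    positions are placed on a circle of ``radius`` about ``center`` with
    ``start_angle`` as the world-frame start and extension increasing the
    world angle.  With ``noise_sd`` > 0, isotropic Gaussian jitter (metres)
    is added to the positions to emulate tracking noise.
    """
    for name, val in (("start_angle", start_angle), ("distance", distance),
                      ("duration", duration), ("sample_rate", sample_rate)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")

    n = int(np.floor(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    angle = distance * _minjerk(t / duration)
    x, y = _angles_to_xy(angle, start_angle, direction, center, radius)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + rng.normal(0.0, noise_sd, size=n)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return TrackedSeries(
        trial_id=trial_id, t=t, x=x, y=y, angle=angle,
        vib_state=np.zeros(n, dtype=int), trigger_angle=trigger_angle,
        direction=direction, center=center, radius=radius,
    )


def _crossing_time(series: TrackedSeries, trigger_angle: float) -> float:
    a = series.angle
    above = a >= trigger_angle
    if not above.any():
        raise ValueError(
            f"trial {series.trial_id}: trajectory never reaches the "
            f"trigger angle {trigger_angle} deg"
        )
    k = int(np.argmax(above))
    if k == 0:
        return float(series.t[0])
    # linear interpolation of the crossing
    a0, a1 = a[k - 1], a[k]
    t0, t1 = series.t[k - 1], series.t[k]
    return float(t0 + (trigger_angle - a0) / (a1 - a0) * (t1 - t0))


def _rescale_from(series: TrackedSeries, t_switch: float, factor: float) -> TrackedSeries:
    """Multiply angular velocity by ``factor`` for t >= t_switch (exact).

    Because the post-switch velocity is a pure scaling of the original, the
    re-integrated angle is ``a_sw + factor * (angle(t) - a_sw)`` with
    ``a_sw`` the angle interpolated at the switch time; pre-switch samples
    are untouched.
    """
    a_sw = float(np.interp(t_switch, series.t, series.angle))
    new_angle = series.angle.copy()
    post = series.t >= t_switch
    new_angle[post] = a_sw + factor * (series.angle[post] - a_sw)
    x, y = _angles_to_xy(new_angle, 0.0, series.direction, series.center, series.radius)
    # preserve the world-frame start implied by the original first sample
    return dataclasses.replace(series, angle=new_angle, x=x, y=y)


def apply_speed_change(
    series: TrackedSeries, latency: float, relative_change: float
) -> TrackedSeries:
    """Scale angular velocity by (1 + relative_change) from trigger + latency.

    The trigger time is where the trajectory first crosses
    ``series.trigger_angle``; positions are re-derived from the modified
    angle.  ``relative_change = 0`` returns an identical copy.
    """
    if latency < 0:
        raise ValueError("latency must be >= 0")
    if not np.isfinite(series.trigger_angle):
        raise ValueError(f"trial {series.trial_id}: no trigger angle set")
    t_c = _crossing_time(series, series.trigger_angle)
    return _rescale_from(series, t_c + latency, 1.0 + relative_change)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def task_design(task: int, reps: Optional[int] = None, **options) -> Dict:
    """Default design for a task: cells and repetitions per cell."""
    defaults = {1: 18, 2: 24, 3: 48}
    if task not in defaults:
        raise ValueError("task must be 1, 2 or 3")
    d = {"task": task, "reps": defaults[task] if reps is None else int(reps)}
    d.update(options)
    return d


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (narrow use, bounds generous)."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def _residual_cov(truth: CohortTruth) -> np.ndarray:
    sds = np.array([truth.sd_epe, truth.sd_mms, truth.sd_mt])
    C = np.array([
        [1.0, truth.epe_speed_corr, truth.epe_mt_corr],
        [truth.epe_speed_corr, 1.0, truth.mms_mt_corr],
        [truth.epe_mt_corr, truth.mms_mt_corr, 1.0],
    ])
    cov = C * np.outer(sds, sds)
    # guard against an invalid user-configured correlation triple
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("residual correlation matrix is not positive semi-definite")
    return cov


def generate_cohort(
    truth: CohortTruth,
    design: Dict,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, List[TrackedSeries]]:
    """Simulate one cohort for a task layout.

    Returns the long-format trial table (see :data:`TRIAL_COLUMNS`) and,
    for Task 3 (or when ``design['with_tracking']`` is true), the list of
    raw tracked series.  Fully reproducible: the random stream derives
    from ``seed`` if given, else ``truth.seed``.

    Design keys: ``task`` (1|2|3), ``reps`` per cell, ``with_tracking``,
    ``truncate_participant`` (Task 1: drop the last 194 trials of the
    first participant, emulating the incomplete session), ``ranges``
    (dict outcome -> (lo, hi) bounds on the empirical cohort mean;
    violations raise).
    """
    if "task" not in design or design["task"] not in (1, 2, 3):
        raise ValueError("design must specify task in {1, 2, 3}")
    task = design["task"]
    reps = int(design.get("reps", task_design(task)["reps"]))
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    J = truth.n_participants

    # participant-level draws
    part = {
        "u0_rating": rng.normal(0, truth.re_sd_rating, J),
        "u_vg": rng.normal(0, truth.re_sd_rating, J),
        "u_ago_rating": rng.normal(0, truth.re_sd_rating, J),
        "u_anta_rating": rng.normal(0, truth.re_sd_rating, J),
        "u_epe0": rng.normal(0, truth.re_sd_epe, J),
        "u_epe_ago": rng.normal(0, truth.re_sd_epe, J),
        "u_epe_anta": rng.normal(0, truth.re_sd_epe, J),
        "u_mms_ago": rng.normal(0, truth.re_sd_mms, J),
        "u_mms_anta": rng.normal(0, truth.re_sd_mms, J),
        "u_mt_ago": rng.normal(0, truth.re_sd_mt, J),
        "u_mt_anta": rng.normal(0, truth.re_sd_mt, J),
        "base_mt": np.maximum(rng.normal(truth.base_mt, truth.base_mt_sd, J), 0.4),
        "tau": _truncnorm(rng, truth.tau_mean, truth.tau_sd, 0.0, 0.12, J),
    }

    if task == 1:
        trials = _gen_task1(truth, part, reps, rng,
                            truncate=bool(design.get("truncate_participant", False)))
        tracked: List[TrackedSeries] = []
    elif task == 2:
        trials = _gen_task2(truth, part, reps, rng)
        tracked = []
    else:
        trials, tracked = _gen_task3(truth, part, reps, rng,
                                     with_tracking=bool(design.get("with_tracking", True)))

    ranges = design.get("ranges")
    if ranges:
        for col, (lo, hi) in ranges.items():
            m = float(trials[col].mean())
            if not (lo <= m <= hi):
                raise ValueError(
                    f"cohort mean {col} = {m:.3g} outside configured range [{lo}, {hi}]"
                )
    return trials, tracked


def _dir_scale(truth: CohortTruth, direction: str) -> float:
    return 1.0 if direction == "flexion" else truth.ext_scale


_TD_VAR = 40.0**2 / 12.0  # variance of the uniform 40-80 deg target distance


def speed_deviation_sd(truth: CohortTruth, duration: Optional[float] = None) -> float:
    """Marginal SD of within-participant mean-speed deviations (deg/s).

    Speed varies with the trial's target distance (td/duration scaling)
    and with the trial-level residual; this is the SD the within-
    participant z-normalisation divides by, up to sampling noise.
    """
    dur = truth.base_mt if duration is None else duration
    return float(np.sqrt(_TD_VAR * (1.1 / dur) ** 2 + truth.sd_mms**2))


def implied_baseline_epe_slope(
    truth: CohortTruth, n_participants: int = 300, oracle_seed: int = 987654,
) -> float:
    """The epe_z ~ mms_z regression slope implied by the residual correlation.

    Speed inherits extra target-distance variance that endpoint error
    barely does, so the baseline-trial slope on within-participant
    z-scores exceeds the residual correlation (as in real reaching data);
    the exact value also reflects finite-sample z-scoring and
    between-participant duration spread.  It is therefore evaluated by a
    large-cohort simulation from the generative model itself (pooled OLS
    of epe_z on mms_z and centred target distance, per direction,
    averaged).  Deterministic given ``oracle_seed``.
    """
    big = dataclasses.replace(truth, n_participants=n_participants)
    trials, _ = generate_cohort(big, {"task": 2, "reps": 24}, seed=oracle_seed)
    df = trials[(trials["agovib"] == 0) & (trials["antavib"] == 0)]
    group = (df["participant"].astype(str) + "/" + df["direction"]).to_numpy()
    epe_z = _zscore(df["epe"].to_numpy(float), group)
    mms_z = _zscore(df["mms"].to_numpy(float), group)
    slopes = []
    for direction in ("extension", "flexion"):
        m = (df["direction"] == direction).to_numpy()
        X = np.column_stack([
            np.ones(m.sum()), mms_z[m], df.loc[m, "td"].to_numpy(float) - 60.0,
        ])
        coef, *_ = np.linalg.lstsq(X, epe_z[m], rcond=None)
        slopes.append(coef[1])
    return float(np.mean(slopes))


def corr_for_epe_slope(truth: CohortTruth, slope: float, **oracle_kwargs) -> float:
    """Residual correlation that makes the implied baseline slope equal ``slope``.

    The implied slope is linear in the residual correlation, so one oracle
    evaluation at a reference correlation suffices.
    """
    base = dataclasses.replace(truth, epe_speed_corr=0.5)
    unit = implied_baseline_epe_slope(base, **oracle_kwargs) / 0.5
    return slope / unit


def _zscore(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    for g in np.unique(groups):
        m = groups == g
        out[m] = (values[m] - values[m].mean()) / values[m].std(ddof=0)
    return out


def _gen_task1(truth, part, reps, rng, truncate=False) -> pd.DataFrame:
    J = truth.n_participants
    rows = []
    cells = [(vg, ago, anta) for vg in (-2, -1, 0, 1, 2) for ago, anta in _VIB_CELLS]
    for j in range(J):
        n_j = len(cells) * reps
        vgs = np.repeat([c[0] for c in cells], reps)
        agos = np.repeat([c[1] for c in cells], reps)
        antas = np.repeat([c[2] for c in cells], reps)
        order = rng.permutation(n_j)
        vgs, agos, antas = vgs[order], agos[order], antas[order]
        td = rng.uniform(40, 80, n_j)
        dur_j = part["base_mt"][j]
        e_mms = rng.normal(0, truth.sd_mms, n_j)
        mms = (
            td / dur_j * 1.1
            + (truth.speed_effect_ago + part["u_mms_ago"][j]) * agos
            + (truth.speed_effect_anta + part["u_mms_anta"][j]) * antas
            + truth.vg_speed_effect * vgs
            + e_mms
        )
        mt = dur_j * np.exp(rng.normal(0, truth.mt_trial_cv, n_j))
        # perceived-speed coupling: the latent shares the standardised
        # self-generated speed deviation (target-distance + noise driven,
        # not the vibration-induced change), so trials moved faster than
        # usual feel underestimated; the fitted baseline model's z-scored
        # speed predictor is this same quantity up to sampling noise
        s_mms_j = speed_deviation_sd(truth, dur_j)
        dev = (td / dur_j * 1.1 + e_mms - 60.0 / dur_j * 1.1) / s_mms_j
        # the coupling adds latent variance; scaling the systematic part by
        # sqrt(1 + slope^2) keeps the truth coefficients equal to the
        # marginal probit estimands of the rating model (which omits speed)
        c = np.sqrt(1.0 + truth.rating_speed_slope**2)
        z = c * (
            truth.beta0_rating + part["u0_rating"][j]
            + (truth.beta_vg + part["u_vg"][j]) * vgs
            + (truth.beta_ago_rating + part["u_ago_rating"][j]) * agos
            + (truth.beta_anta_rating + part["u_anta_rating"][j]) * antas
        ) + truth.rating_speed_slope * dev
        rating = (rng.random(n_j) < ndtr(z)).astype(float)
        epe = truth.epe_bias + rng.normal(0, truth.sd_epe, n_j)
        for i in range(n_j):
            rows.append((j, 1, i, "extension", int(vgs[i]) * 6, int(vgs[i]),
                         int(agos[i]), int(antas[i]), "none", td[i], epe[i],
                         mms[i], mt[i], rating[i]))
    df = _frame(rows)
    if truncate:
        mask = ~((df["participant"] == 0) & (df["trial"] >= len(cells) * reps - 194))
        df = df.loc[mask].reset_index(drop=True)
    return df


def _gen_task2(truth, part, reps, rng) -> pd.DataFrame:
    J = truth.n_participants
    cov = _residual_cov(truth)
    rows = []
    for j in range(J):
        dur_j = part["base_mt"][j]
        trial_idx = 0
        for direction in ("extension", "flexion"):
            scale = _dir_scale(truth, direction)
            n_d = len(_VIB_CELLS) * reps
            agos = np.repeat([c[0] for c in _VIB_CELLS], reps)
            antas = np.repeat([c[1] for c in _VIB_CELLS], reps)
            order = rng.permutation(n_d)
            agos, antas = agos[order], antas[order]
            td = rng.uniform(40, 80, n_d)
            e = rng.multivariate_normal(np.zeros(3), cov, size=n_d)
            epe = (
                truth.epe_bias + part["u_epe0"][j]
                + truth.td_epe_slope * (td - 60.0)
                + (truth.epe_effect_ago * scale + part["u_epe_ago"][j]) * agos
                + (truth.epe_effect_anta * scale + part["u_epe_anta"][j]) * antas
                + e[:, 0]
            )
            mms = (
                td / dur_j * 1.1
                + (truth.speed_effect_ago * scale + part["u_mms_ago"][j]) * agos
                + (truth.speed_effect_anta * scale + part["u_mms_anta"][j]) * antas
                + e[:, 1]
            )
            mt = (
                dur_j
                + (truth.mt_effect_ago * scale + part["u_mt_ago"][j]) * agos
                + (truth.mt_effect_anta * scale + part["u_mt_anta"][j]) * antas
                + e[:, 2]
            )
            mt = np.maximum(mt, 0.1)
            mms = np.maximum(mms, 1.0)
            for i in range(n_d):
                rows.append((j, 2, trial_idx, direction, 0, 0, int(agos[i]),
                             int(antas[i]), "none", td[i], epe[i], mms[i],
                             mt[i], np.nan))
                trial_idx += 1
    return _frame(rows)


_T3_CONDITIONS = ("none", "full", "0-20", "20-80")


def _gen_task3(truth, part, reps, rng, with_tracking=True):
    J = truth.n_participants
    rows = []
    tracked: List[TrackedSeries] = []
    trial_id = 0
    rc = truth.vib_speed_change
    for j in range(J):
        tau_j = part["tau"][j]
        dur_j = part["base_mt"][j]
        conds = np.repeat(np.arange(4), reps)
        conds = conds[rng.permutation(conds.size)]
        for i, ci in enumerate(conds):
            cond = _T3_CONDITIONS[ci]
            dur = dur_j * np.exp(rng.normal(0, truth.mt_trial_cv))
            # leave room for the analysis window after the 20 deg crossing
            dur = max(dur, 0.9)
            series = generate_trajectory(
                0.0, 80.0, dur * 1.4, truth.sample_rate,
                radius=truth.radius_m, direction="extension",
                trigger_angle=20.0, trial_id=trial_id, noise_sd=0.0,
            )
            # interpret dur as the nominal movement duration of the clean reach
            series = dataclasses.replace(
                series,
                angle=80.0 * _minjerk(np.clip(series.t / dur, 0, 1)),
            )
            lat = truth.hardware_delay + tau_j
            if cond == "none":
                vib_on_at, vib_off_at = np.inf, np.inf
            elif cond == "full":
                series = _rescale_from(series, 0.0, 1.0 + rc)
                vib_on_at, vib_off_at = 0.0, np.inf
            elif cond == "20-80":
                t_c = _crossing_time(series, 20.0)
                series = _rescale_from(series, t_c + lat, 1.0 + rc)
                vib_on_at, vib_off_at = t_c + truth.hardware_delay, np.inf
            else:  # "0-20": vibrating (slowed) from the start, off at 20 deg
                series = _rescale_from(series, 0.0, 1.0 + rc)
                t_c = _crossing_time(series, 20.0)
                series = _rescale_from(series, t_c + lat, 1.0 / (1.0 + rc))
                vib_on_at, vib_off_at = 0.0, t_c + truth.hardware_delay
            vib = ((series.t >= vib_on_at) & (series.t < vib_off_at)).astype(int)
            x, y = _angles_to_xy(series.angle, 0.0, "extension",
                                 series.center, series.radius)
            if truth.tracking_noise_m > 0:
                x = x + rng.normal(0, truth.tracking_noise_m, x.size)
                y = y + rng.normal(0, truth.tracking_noise_m, y.size)
            series = dataclasses.replace(
                series, x=x, y=y, vib_state=vib, participant=j, condition=cond,
            )
            if with_tracking:
                tracked.append(series)
            final_angle = float(series.angle[-1])
            rows.append((j, 3, i, "extension", 0, 0,
                         0 if cond == "none" else 1,
                         0 if cond == "none" else 1,
                         cond, 80.0, final_angle - 80.0, 80.0 / dur, dur, np.nan))
            trial_id += 1
    return _frame(rows), tracked


def _frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=[
        "participant", "task", "trial", "direction", "vg", "vg_units",
        "agovib", "antavib", "vib_window", "td", "epe", "mms", "mt", "rating",
    ])
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def write_tracked(tracked: Iterable[TrackedSeries], path, fmt: str = "csv") -> None:
    """Write tracked samples long-format: trial_id, participant, condition, t, x, y, vib_state."""
    frames = [
        pd.DataFrame({
            "trial_id": s.trial_id, "participant": s.participant,
            "condition": s.condition, "t": s.t, "x": s.x, "y": s.y,
            "vib_state": s.vib_state,
        })
        for s in tracked
    ]
    df = pd.concat(frames, ignore_index=True)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError("fmt must be 'csv' or 'parquet'")


def write_truth_json(truth: CohortTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
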