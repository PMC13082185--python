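"""Angular kinematics from tracked controller positions.

The controller rides on a rotating armrest, so its positions lie on a
circle about the elbow's axis of rotation.  The axis is not tracked
directly: it is re-estimated per trial by a least-squares circle fit to
points sampled along the movement arc.  Positions are then converted to
elbow-joint angles, angular speed is estimated either by the analytic
derivative of a cubic smoothing spline or by central finite differences,
and Task-3 trials are reduced to delta-movement-speed grids time-locked
to the (hardware-delay-corrected) vibration state change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .synthgen import TrackedSeries

__all__ = [
    "CircleFit",
    "AngularTrial",
    "TrackingIssueError",
    "fit_circle_center",
    "to_angles",
    "spline_speed",
    "finite_difference_speed",
    "trial_summaries",
    "build_speed_grids",
    "zscore_within",
    "GRID_MS",
    "DEFAULT_SMOOTH",
    "HARDWARE_DELAY",
]

#: analysis grid, ms relative to the corrected vibration state change
GRID_MS = np.arange(-100, 121, 10)
#: trigger-to-vibration hardware delay (s), subtracted-in when time-locking
HARDWARE_DELAY = 0.1188
#: default roughness penalty of the smoothing spline (deg^2 s^3 units of
#: the squared-second-derivative penalty); calibrated so spline- and
#: finite-difference-based latency estimates agree within 2 ms
DEFAULT_SMOOTH = 1e-7


class TrackingIssueError(ValueError):
    """Raised when a trial's samples are inconsistent with the circle fit."""


@dataclass
class CircleFit:
    center: Tuple[float, float]
    radius: float
    rms_residual: float
    n_points: int


@dataclass
class AngularTrial:
    """One trial as elbow-angle samples (degrees, 0 at start, target-positive)."""

    trial_id: int
    t: np.ndarray
    angle: np.ndarray
    speed: Optional[np.ndarray] = None  # deg/s, aligned with t (or t_speed)
    t_speed: Optional[np.ndarray] = None
    method: str = "none"
    participant: int = 0
    condition: str = "none"
    direction: str = "extension"


def fit_circle_center(points: Sequence[Sequence[float]]) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through 2-D points.

    Minimises sum (x^2 + y^2 + D x + E y + F)^2, which is linear in
    (D, E, F); the centre is (-D/2, -E/2).  Requires >= 3 non-collinear
    points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three 2-D points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle fit is singular")
    D, E, F = sol
    cx, cy = -D / 2.0, -E / 2.0
    r2 = cx**2 + cy**2 - F
    if r2 <= 0:
        raise ValueError("points are collinear; circle fit is singular")
    r = float(np.sqrt(r2))
    resid = np.hypot(x - cx, y - cy) - r
    return CircleFit(center=(float(cx), float(cy)), radius=r,
                     rms_residual=float(np.sqrt(np.mean(resid**2))),
                     n_points=pts.shape[0])


def circle_fit_from_series(series: TrackedSeries, n_points: int = 30) -> CircleFit:
    """Fit the rotation axis from ``n_points`` equally distributed samples."""
    idx = np.linspace(0, series.t.size - 1, n_points).round().astype(int)
    return fit_circle_center(np.column_stack([series.x[idx], series.y[idx]]))


def to_angles(
    series: TrackedSeries,
    fit: CircleFit,
    direction: Optional[str] = None,
    radius_tolerance: float = 0.20,
    max_gap_frames: float = 3.0,
) -> AngularTrial:
    """Convert positions to unwrapped joint angles about the fitted centre.

    Angles are re-zeroed at the start position with the sign chosen so
    movement toward the target is positive for both directions.  Trials
    whose samples stray more than ``radius_tolerance`` from the fitted
    radius, or with a timestamp gap over ``max_gap_frames`` nominal
    frames, are rejected as tracking issues.
    """
    direction = direction or series.direction
    cx, cy = fit.center
    dx, dy = series.x - cx, series.y - cy
    dist = np.hypot(dx, dy)
    if np.any(np.abs(dist - fit.radius) > radius_tolerance * fit.radius):
        raise TrackingIssueError(
            f"trial {series.trial_id}: sample distance from centre outside "
            f"{radius_tolerance:.0%} of the fitted radius"
        )
    dt = np.diff(series.t)
    nominal = np.median(dt)
    if np.max(dt) > max_gap_frames * nominal:
        raise TrackingIssueError(
            f"trial {series.trial_id}: timestamp gap exceeds "
            f"{max_gap_frames} nominal frames"
        )
    raw = np.unwrap(np.arctan2(dy, dx))
    ang = np.rad2deg(raw - raw[0])
    if ang[-1] < 0:  # sign convention: toward the target is positive
        ang = -ang
    return AngularTrial(
        trial_id=series.trial_id, t=series.t.copy(), angle=ang,
        participant=series.participant, condition=series.condition,
        direction=direction,
    )


def spline_speed(
    trial: AngularTrial,
    smooth: float = DEFAULT_SMOOTH,
    t_eval: Optional[np.ndarray] = None,
) -> AngularTrial:
    """Angular speed as the analytic derivative of a cubic smoothing spline.

    ``smooth`` is the roughness-penalty weight on the integrated squared
    second derivative (0 = interpolation).  The derivative is evaluated on
    the trial's native grid, or on ``t_eval`` when given.
    """
    if trial.t.size < 8:
        raise ValueError("need at least 8 samples for a smoothing spline")
    spl = make_smoothing_spline(trial.t, trial.angle, lam=smooth)
    dspl = spl.derivative()
    tt = trial.t if t_eval is None else np.asarray(t_eval, dtype=float)
    return AngularTrial(
        trial_id=trial.trial_id, t=trial.t, angle=trial.angle,
        speed=dspl(tt), t_speed=tt, method="spline",
        participant=trial.participant, condition=trial.condition,
        direction=trial.direction,
    )


def finite_difference_speed(
    trial: AngularTrial, t_eval: Optional[np.ndarray] = None
) -> AngularTrial:
    """Central-difference angular speed on interior samples.

    ms_i = (angle_{i+1} - angle_{i-1}) / (t_{i+1} - t_{i-1}); linearly
    interpolated onto ``t_eval`` when given.
    """
    if trial.t.size < 3:
        raise ValueError("need at least 3 samples for central differences")
    t, a = trial.t, trial.angle
    speed = (a[2:] - a[:-2]) / (t[2:] - t[:-2])
    t_mid = t[1:-1]
    if t_eval is not None:
        tt = np.asarray(t_eval, dtype=float)
        speed = np.interp(tt, t_mid, speed)
        t_mid = tt
    return AngularTrial(
        trial_id=trial.trial_id, t=trial.t, angle=trial.angle,
        speed=speed, t_speed=t_mid, method="finite_difference",
        participant=trial.participant, condition=trial.condition,
        direction=trial.direction,
    )


def trial_summaries(
    trial: AngularTrial,
    target_distance: float,
    threshold_frac: float = 0.05,
    sustain: float = 0.030,
) -> Tuple[float, float, float]:
    """(epe, mms, mt) for one trial.

    Movement onset/offset are the first/last times the speed stays above
    ``threshold_frac`` of peak speed for at least ``sustain`` seconds;
    mt = offset - onset, mms = net angle over that window / mt and
    epe = final indicated angle - target distance (negative = undershoot).
    """
    if trial.speed is None:
        raise ValueError("estimate speed first (spline or finite differences)")
    t, v = trial.t_speed, np.asarray(trial.speed, dtype=float)
    peak = np.max(np.abs(v))
    if peak <= 0:
        raise ValueError("no suprathreshold movement")
    above = np.abs(v) > threshold_frac * peak
    dt = np.median(np.diff(t))
    min_run = max(int(np.ceil(sustain / dt)), 1)
    onset_i = offset_i = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run == min_run and onset_i is None:
            onset_i = i - min_run + 1
    run = 0
    for i in range(above.size - 1, -1, -1):
        run = run + 1 if above[i] else 0
        if run == min_run:
            offset_i = i + min_run - 1
            break
    if onset_i is None or offset_i is None or offset_i <= onset_i:
        raise ValueError("no suprathreshold movement")
    t_on, t_off = float(t[onset_i]), float(t[offset_i])
    a_on = float(np.interp(t_on, trial.t, trial.angle))
    a_off = float(np.interp(t_off, trial.t, trial.angle))
    mt = t_off - t_on
    mms = (a_off - a_on) / mt
    epe = float(trial.angle[-1]) - target_distance
    return epe, mms, mt


# ---------------------------------------------------------------------------
# Task-3 delta-speed grids
# ---------------------------------------------------------------------------

#: intervention condition -> matched within-participant control condition
CONTROL_PAIRS = {"20-80": "none", "0-20": "full"}
_PAIR_NAME = {"20-80": "on", "0-20": "off"}


def build_speed_grids(
    tracked: Iterable[TrackedSeries],
    hardware_delay: float = HARDWARE_DELAY,
    method: str = "spline",
    smooth: float = DEFAULT_SMOOTH,
    trigger_angle: float = 20.0,
    circle_points: int = 30,
) -> pd.DataFrame:
    """Per-trial speed on the 23-point grid, time-locked to the vibration change.

    Every trial (intervention and control alike) is reduced to angular
    speed at -100..+120 ms in 10 ms steps around its own software trigger
    (first crossing of ``trigger_angle``) plus ``hardware_delay``.  Within
    participant, the grid-point-wise mean of the matched control condition
    is subtracted from each intervention trial, giving the delta movement
    speed ``dms`` (NaN on control rows).

    Returns a long DataFrame (participant, trial_id, condition, pair, t,
    speed, dms); trials failing the tracking checks are dropped and
    counted in ``df.attrs['n_excluded']``.
    """
    if method not in ("spline", "finite_difference"):
        raise ValueError("method must be 'spline' or 'finite_difference'")
    grid_s = GRID_MS / 1000.0
    rows = []
    excluded = 0
    for series in tracked:
        fit = circle_fit_from_series(series, circle_points)
        try:
            ang = to_angles(series, fit)
        except TrackingIssueError:
            excluded += 1
            continue
        above = ang.angle >= trigger_angle
        if not above.any() or above[0]:
            excluded += 1
            continue
        k = int(np.argmax(above))
        t_c = float(np.interp(trigger_angle, ang.angle[k - 1:k + 1], ang.t[k - 1:k + 1]))
        t0 = t_c + hardware_delay
        t_grid = t0 + grid_s
        if t_grid[-1] > ang.t[-1] or t_grid[0] < ang.t[0]:
            excluded += 1
            continue
        if method == "spline":
            est = spline_speed(ang, smooth=smooth, t_eval=t_grid)
        else:
            est = finite_difference_speed(ang, t_eval=t_grid)
        for g_ms, v in zip(GRID_MS, est.speed):
            rows.append((series.participant, series.trial_id, series.condition,
                         _PAIR_NAME.get(series.condition, "control"),
                         g_ms / 1000.0, float(v)))
    df = pd.DataFrame(rows, columns=["participant", "trial_id", "condition",
                                     "pair", "t", "speed"])
    df.attrs["n_excluded"] = excluded
    if df.empty:
        raise ValueError("no usable trials")

    # subtract the within-participant control-condition mean per grid point
    df["dms"] = np.nan
    for interv, control in CONTROL_PAIRS.items():
        for pid, sub in df[df["condition"] == interv].groupby("participant"):
            ctrl = df[(df["condition"] == control) & (df["participant"] == pid)]
            if ctrl.empty:
                raise ValueError(
                    f"participant {pid}: no '{control}' control trials to "
                    f"pair with '{interv}'"
                )
            means = ctrl.groupby("t")["speed"].mean()
            df.loc[sub.index, "dms"] = (
                sub["speed"].to_numpy() - means.loc[sub["t"]].to_numpy()
            )
    df.attrs["hardware_delay"] = hardware_delay
    df.attrs["method"] = method
    return df


def zscore_within(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Within-group z-scores (group mean 0, SD 1 by construction)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for g in np.unique(groups):
        m = groups == g
        sd = values[m].std(ddof=0)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance; cannot z-score")
        out[m] = (values[m] - values[m].mean()) / sd
    return out
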