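"""Instantaneous kinematics of apico-basal nuclear trajectories.

Velocity is the first difference of raw depth divided by the sampling
interval, v[i] = (z[i+1] - z[i]) / delta_t (um/min); acceleration is the
analogous first difference of velocity (um/min^2).  Both are smoothed with a
centred moving average for event-phase detection.  Apically directed motion
is negative by the depth sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FeatureMissingError, InsufficientDataError, ParameterError
from .io_tracks import Trajectory

__all__ = [
    "KinematicSeries",
    "compute_velocity",
    "compute_acceleration",
    "moving_average",
    "compute_kinematics",
    "lateral_displacement",
]

DEFAULT_WINDOW = 5  # frames (50 min at delta_t = 10 min)


@dataclass(frozen=True)
class KinematicSeries:
    """Velocity/acceleration series derived from one N-frame trajectory.

    ``v`` has length N-1 (v[i] spans frames i -> i+1) and ``a`` length N-2
    (a[i] is centred on frame i+1).  Smoothed variants preserve length.
    """

    v: np.ndarray
    a: np.ndarray
    v_smooth: np.ndarray
    a_smooth: np.ndarray
    window: int
    delta_t: float


def compute_velocity(traj: Trajectory) -> np.ndarray:
    """Instantaneous velocity v[i] = (z[i+1] - z[i]) / delta_t in um/min."""
    if traj.n_frames < 2:
        raise InsufficientDataError("velocity needs >= 2 frames")
    return np.diff(traj.z) / traj.delta_t


def compute_acceleration(v: np.ndarray, delta_t: float) -> np.ndarray:
    """Acceleration a[i] = (v[i+1] - v[i]) / delta_t in um/min^2."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("acceleration needs >= 2 velocity values")
    return np.diff(v) / delta_t


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge windows truncated to available frames.

    ``window`` must be odd; the output has the same length as the input.
    Near the edges the window simply covers whatever frames exist, so the
    first value averages frames [0, half], etc.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window > series.size:
        raise ParameterError(
            f"window {window} exceeds series length {series.size}"
        )
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    n = series.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_kinematics(
    traj: Trajectory, window: int = DEFAULT_WINDOW
) -> KinematicSeries:
    """Velocity, acceleration and their moving averages for one trajectory.

    The smoothing window (in frames) is clipped down to the longest odd
    window the series supports, so short tracks remain analysable.
    """
    v = compute_velocity(traj)
    a = compute_acceleration(v, traj.delta_t)

    def _fit_window(length: int) -> int:
        w = min(window, length)
        return w if w % 2 == 1 else w - 1

    v_smooth = moving_average(v, _fit_window(v.size))
    a_smooth = moving_average(a, _fit_window(a.size)) if a.size else a.copy()
    return KinematicSeries(
        v=v, a=a, v_smooth=v_smooth, a_smooth=a_smooth,
        window=window, delta_t=traj.delta_t,
    )


def lateral_displacement(traj: Trajectory) -> tuple[float, float]:
    """Net radial |dz| and net lateral |dxy| over the full track, in um."""
    if traj.xy is None:
        raise FeatureMissingError(
            f"track {traj.track_id!r} has no tangential (xy) coordinates"
        )
    net_radial = abs(float(traj.z[-1] - traj.z[0]))
    net_lateral = float(np.hypot(*(traj.xy[-1] - traj.xy[0])))
    return net_radial, net_lateral
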