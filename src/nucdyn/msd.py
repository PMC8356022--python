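"""Mean squared displacement profiles and their model fits.

The per-trajectory estimator is the overlapping-pairs time average

    MSD(n*dt) = 1/(N-n) * sum_{i=1..N-n} [z((i+n)dt) - z(i*dt)]^2

for lag index n = 1..max_lag, where N is the number of time points.
Population profiles average per-trajectory MSDs lag-by-lag (unweighted
across tracks), with the SEM across tracks as the dispersion estimate.

Two origin-constrained models quantify a profile:

* linear, MSD = 2*R*D*dt with dimensionality R = 1 — D is the coefficient
  of movement (um^2/min) of non-directional motion;
* quadratic, MSD = a*dt^2 — a (um^2/min^2) measures curve steepness of
  directed translocation; for constant speed v, a = v^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InsufficientDataError, ParameterError
from .io_tracks import RecordingSet, Trajectory

__all__ = [
    "MsdProfile",
    "MsdFit",
    "msd_single",
    "msd_pooled",
    "fit_linear_msd",
    "fit_quadratic_msd",
]

#: dimensionality R of the linear model MSD = 2*R*D*dt (1-D depth series)
DIMENSIONALITY = 1


@dataclass(frozen=True)
class MsdProfile:
    """Lag-indexed MSD. ``sem`` and per-lag track counts are None for a
    single-trajectory profile."""

    lags: np.ndarray                 # min, starting at delta_t
    msd: np.ndarray                  # um^2
    sem: np.ndarray | None = None    # um^2, across-track standard error
    n_tracks: np.ndarray | None = None
    delta_t: float | None = None


@dataclass(frozen=True)
class MsdFit:
    """An origin-constrained fit of an MSD profile."""

    model: str                       # "linear" | "quadratic"
    coefficient: float               # D (um^2/min) or a (um^2/min^2)
    fit_lag_max: float               # largest lag used, min
    rss: float                       # residual sum of squares over fit lags
    n_lags: int


def msd_single(
    traj: Trajectory, max_lag_frames: int | None = None
) -> MsdProfile:
    """Overlapping-pairs MSD of one trajectory for lags 1..max_lag_frames."""
    n_frames = traj.n_frames
    if n_frames < 2:
        raise InsufficientDataError("MSD needs >= 2 frames")
    if max_lag_frames is None:
        max_lag_frames = n_frames - 1
    if not 1 <= max_lag_frames <= n_frames - 1:
        raise ParameterError(
            f"max_lag_frames must be in [1, {n_frames - 1}], "
            f"got {max_lag_frames}"
        )
    z = traj.z
    msd = np.empty(max_lag_frames)
    for n in range(1, max_lag_frames + 1):
        d = z[n:] - z[:-n]
        msd[n - 1] = np.mean(d * d)
    lags = np.arange(1, max_lag_frames + 1) * traj.delta_t
    return MsdProfile(lags=lags, msd=msd, delta_t=traj.delta_t)


def msd_pooled(
    recording: RecordingSet, max_lag_frames: int | None = None
) -> MsdProfile:
    """Population MSD: per-lag unweighted mean of per-trajectory MSDs.

    A trajectory contributes at lag n only if it has more than n frames, so
    ``n_tracks`` decreases at long lags for mixed-length recordings.  SEM is
    the across-track sample standard deviation / sqrt(n_tracks) (zero where
    a single track contributes).
    """
    if len(recording) == 0:
        raise InsufficientDataError("empty recording")
    longest = max(traj.n_frames for traj in recording)
    if max_lag_frames is None:
        max_lag_frames = longest - 1
    if not 1 <= max_lag_frames <= longest - 1:
        raise ParameterError(
            f"max_lag_frames must be in [1, {longest - 1}]"
        )
    per_track = np.full((len(recording), max_lag_frames), np.nan)
    for k, traj in enumerate(recording):
        m = min(max_lag_frames, traj.n_frames - 1)
        per_track[k, :m] = msd_single(traj, m).msd
    n_tracks = np.sum(~np.isnan(per_track), axis=0)
    if np.any(n_tracks == 0):
        raise ParameterError(
            "no trajectory contributes at the longest requested lag"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_track, axis=0)
        sd = np.nanstd(per_track, axis=0, ddof=1)
    sem = np.where(n_tracks > 1, sd / np.sqrt(n_tracks), 0.0)
    lags = np.arange(1, max_lag_frames + 1) * recording.delta_t
    return MsdProfile(
        lags=lags, msd=mean, sem=sem, n_tracks=n_tracks,
        delta_t=recording.delta_t,
    )


def _fit_range(profile: MsdProfile, fit_lag_max: float | None) -> np.ndarray:
    if fit_lag_max is None:
        # long-lag estimates are high-variance; default to the first third
        fit_lag_max = float(profile.lags[-1]) / 3.0
        if np.count_nonzero(profile.lags <= fit_lag_max + 1e-12) < 2:
            fit_lag_max = float(profile.lags[-1])
    mask = profile.lags <= fit_lag_max + 1e-12
    if np.count_nonzero(mask) < 2:
        raise ParameterError(
            f"fewer than 2 lags within fit_lag_max={fit_lag_max:g} min"
        )
    return mask


def _origin_fit(x: np.ndarray, y: np.ndarray, model: str) -> tuple[float, float]:
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise DegenerateFitError("all fit lags are zero")
    coef = float(np.dot(x, y)) / denom
    if coef < 0.0:
        warnings.warn(
            f"{model} MSD fit produced a negative coefficient "
            f"({coef:.3g}); clipping to 0",
            stacklevel=3,
        )
        coef = 0.0
    resid = y - coef * x
    return coef, float(np.dot(resid, resid))


def fit_linear_msd(
    profile: MsdProfile, fit_lag_max: float | None = None
) -> MsdFit:
    """Fit MSD = 2*R*D*dt through the origin; returns the coefficient of
    movement D = slope / (2R) in um^2/min."""
    mask = _fit_range(profile, fit_lag_max)
    slope, rss = _origin_fit(profile.lags[mask], profile.msd[mask], "linear")
    return MsdFit(
        model="linear",
        coefficient=slope / (2.0 * DIMENSIONALITY),
        fit_lag_max=float(profile.lags[mask][-1]),
        rss=rss,
        n_lags=int(np.count_nonzero(mask)),
    )


def fit_quadratic_msd(
    profile: MsdProfile, fit_lag_max: float | None = None
) -> MsdFit:
    """Fit MSD = a*dt^2 through the origin; a (um^2/min^2) is the quadratic
    steepness factor of directed motion."""
    mask = _fit_range(profile, fit_lag_max)
    a, rss = _origin_fit(
        profile.lags[mask] ** 2, profile.msd[mask], "quadratic"
    )
    return MsdFit(
        model="quadratic",
        coefficient=a,
        fit_lag_max=float(profile.lags[mask][-1]),
        rss=rss,
        n_lags=int(np.count_nonzero(mask)),
    )
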