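"""Trajectory and table I/O.

Trajectories are one-dimensional apico-basal depth series z(t) of individual
photoreceptor nuclei, sampled at a uniform interval ``delta_t`` (minutes).
Depth is measured in micrometres basal to the apical tissue margin, so
apically directed motion has *negative* velocity.  Tables are plain CSV with
a header row, as exported by spot-tracking software.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SamplingError, SchemaError

__all__ = [
    "Trajectory",
    "RecordingSet",
    "read_tracks",
    "write_tracks",
    "write_table",
    "read_table",
    "concat_recordings",
]

#: relative tolerance on frame-spacing uniformity
_SPACING_RTOL = 1e-9

_REQUIRED_COLUMNS = ("track_id", "t_min", "z_um")
_OPTIONAL_COLUMNS = ("x_um", "y_um", "condition", "recording_id")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered apico-basal depth series of one nucleus.

    Parameters
    ----------
    track_id
        Opaque identifier of the tracked nucleus.
    t
        Acquisition times in minutes, strictly increasing and uniformly
        spaced.
    z
        Depth in micrometres basal to the apical margin; finite everywhere.
    xy
        Optional ``(n_frames, 2)`` tangential positions in micrometres.
    condition, recording_id, age
        Free-form labels carried through the pipeline.
    """

    track_id: str
    t: np.ndarray
    z: np.ndarray
    xy: np.ndarray | None = None
    condition: str | None = None
    recording_id: str | None = None
    age: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "z", z)
        if self.xy is not None:
            xy = np.asarray(self.xy, dtype=float)
            if xy.shape != (t.size, 2):
                raise SamplingError(
                    f"track {self.track_id!r}: xy shape {xy.shape} does not "
                    f"match {t.size} frames"
                )
            object.__setattr__(self, "xy", xy)
        if t.size < 2:
            raise SamplingError(
                f"track {self.track_id!r}: needs >= 2 frames, got {t.size}"
            )
        if t.size != z.size:
            raise SamplingError(
                f"track {self.track_id!r}: t and z lengths differ"
            )
        if not np.all(np.isfinite(z)):
            raise SamplingError(f"track {self.track_id!r}: non-finite depth")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingError(
                f"track {self.track_id!r}: times not strictly increasing"
            )
        if not np.allclose(dt, dt[0], rtol=_SPACING_RTOL, atol=0.0):
            raise SamplingError(
                f"track {self.track_id!r}: non-uniform frame spacing "
                f"(intervals range {dt.min():g}-{dt.max():g} min)"
            )

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def delta_t(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration_min(self) -> float:
        """Trajectory duration (n_frames - 1) * delta_t in minutes."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class RecordingSet:
    """A collection of trajectories sharing one sampling interval."""

    trajectories: tuple[Trajectory, ...]
    delta_t: float
    condition: str | None = None

    def __post_init__(self) -> None:
        trajs = tuple(self.trajectories)
        object.__setattr__(self, "trajectories", trajs)
        for traj in trajs:
            if not np.isclose(traj.delta_t, self.delta_t,
                              rtol=_SPACING_RTOL, atol=0.0):
                raise SamplingError(
                    f"track {traj.track_id!r}: delta_t {traj.delta_t:g} does "
                    f"not match recording delta_t {self.delta_t:g}"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def cumulative_recording_min(self) -> float:
        """Sum of trajectory durations: sigma (n_frames - 1) * delta_t."""
        return float(sum(traj.duration_min for traj in self.trajectories))


def read_tracks(
    path,
    delta_t: float = 10.0,
    min_length: int = 2,
) -> RecordingSet:
    """Read a trajectory CSV into a validated :class:`RecordingSet`.

    The file must contain columns ``track_id, t_min, z_um`` and may contain
    ``x_um, y_um, condition, recording_id``.  Every distinct ``track_id``
    becomes one :class:`Trajectory`, frames sorted by time.  Tracks with
    fewer than ``min_length`` frames are rejected; frames are never
    interpolated and gaps are an error.
    """
    frame = pd.read_csv(path, dtype={"track_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    for col in ("t_min", "z_um", "x_um", "y_um"):
        if col not in frame.columns:
            continue
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} in "
                f"column {col!r} at file row {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise ParseError(f"{path}: empty value in {col!r} at row {row}")
        frame[col] = numeric

    if frame.duplicated(subset=["track_id", "t_min"]).any():
        dup = frame[frame.duplicated(subset=["track_id", "t_min"])].iloc[0]
        raise SamplingError(
            f"{path}: duplicate frame (track {dup['track_id']!r}, "
            f"t={dup['t_min']:g} min)"
        )

    has_xy = "x_um" in frame.columns and "y_um" in frame.columns
    trajectories = []
    for track_id, grp in frame.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        if len(grp) < max(min_length, 2):
            raise SamplingError(
                f"{path}: track {track_id!r} has {len(grp)} frame(s), "
                f"minimum is {max(min_length, 2)}"
            )
        t = grp["t_min"].to_numpy(dtype=float)
        dt = np.diff(t)
        if not np.allclose(dt, delta_t, rtol=_SPACING_RTOL, atol=0.0):
            raise SamplingError(
                f"{path}: track {track_id!r} is not uniformly sampled at "
                f"delta_t={delta_t:g} min (intervals "
                f"{np.unique(np.round(dt, 9)).tolist()})"
            )
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float) if has_xy else None
        condition = (
            str(grp["condition"].iloc[0]) if "condition" in grp else None
        )
        recording_id = (
            str(grp["recording_id"].iloc[0]) if "recording_id" in grp else None
        )
        trajectories.append(
            Trajectory(
                track_id=str(track_id),
                t=t,
                z=grp["z_um"].to_numpy(dtype=float),
                xy=xy,
                condition=condition,
                recording_id=recording_id,
            )
        )
    conditions = {tr.condition for tr in trajectories}
    condition = conditions.pop() if len(conditions) == 1 else None
    return RecordingSet(
        trajectories=tuple(trajectories),
        delta_t=float(delta_t),
        condition=condition,
    )


def write_tracks(recording: RecordingSet, path) -> None:
    """Write a RecordingSet back to the canonical trajectory CSV."""
    rows = []
    for traj in recording:
        for i in range(traj.n_frames):
            row = {
                "track_id": traj.track_id,
                "t_min": traj.t[i],
                "z_um": traj.z[i],
            }
            if traj.xy is not None:
                row["x_um"] = traj.xy[i, 0]
                row["y_um"] = traj.xy[i, 1]
            if traj.condition is not None:
                row["condition"] = traj.condition
            if traj.recording_id is not None:
                row["recording_id"] = traj.recording_id
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, dict):
            rows.append(rec)
        else:
            raise TypeError(f"cannot serialise record of type {type(rec)}")
    return pd.DataFrame(rows)


def write_table(records, path, columns: Sequence[str] | None = None) -> None:
    """Write any result collection (dataclasses, dicts, DataFrame) as CSV.

    An empty collection with declared ``columns`` produces a header-only
    file; round-trips via :func:`read_table` are field-for-field faithful.
    """
    frame = _records_to_frame(records)
    if frame.empty and columns is not None:
        frame = pd.DataFrame(columns=list(columns))
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` back into a DataFrame."""
    return pd.read_csv(path)


def concat_recordings(recordings: Iterable[RecordingSet]) -> RecordingSet:
    """Concatenate RecordingSets sharing delta_t.

    Cumulative recording time is additive under this operation.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings to concatenate")
    delta_t = recordings[0].delta_t
    trajs: list[Trajectory] = []
    for rec in recordings:
        if not np.isclose(rec.delta_t, delta_t, rtol=_SPACING_RTOL, atol=0.0):
            raise SamplingError("recordings have differing delta_t")
        trajs.extend(rec.trajectories)
    conditions = {rec.condition for rec in recordings}
    condition = conditions.pop() if len(conditions) == 1 else None
    return RecordingSet(tuple(trajs), delta_t, condition)
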