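"""Movement-event detection, phase localization and summary statistics.

Event vocabulary (depth increases basally, so apical motion is negative):

``directional_apical`` / ``directional_basal``
    Maximal runs of same-signed smoothed velocity persisting >= 60 min.
``rapid_apical``
    Net displacement <= -10 um within a 30-min sliding window; overlapping
    qualifying windows are merged into one event, then phase landmarks are
    located: the peak of the translocation at the local minimum of smoothed
    velocity, and its initiation/cessation at the nearest preceding local
    minimum / following local maximum of smoothed acceleration.
``basal_persistent``
    Net displacement >= +15 um over a window of >= 120 min (about twice an
    apico-basal rod somal length), distinguishing persistent basal drift
    from stochastic rest.
``oscillation``
    One full rapid-apical -> basal -> rapid-apical cycle of one nucleus.

Event counts are normalized per 1000 cumulative recording minutes so that
recordings with different trajectory numbers and durations are comparable:
normalized count = absolute count / cumulative recording min x 1000.

All thresholds are inclusive and configurable; the defaults above are the
conventional criteria for developing rod photoreceptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .io_tracks import RecordingSet, Trajectory
from .kinematics import DEFAULT_WINDOW, KinematicSeries, compute_kinematics

__all__ = [
    "EVENT_CLASSES",
    "MovementEvent",
    "EventSummary",
    "EventConfig",
    "AlignedEvents",
    "detect_directional_segments",
    "detect_rapid_apical",
    "detect_basal_persistent",
    "detect_oscillations",
    "detect_all",
    "summarize_events",
    "align_events_to_onset",
]

EVENT_CLASSES = (
    "directional_apical",
    "directional_basal",
    "rapid_apical",
    "basal_persistent",
    "oscillation",
)


@dataclass(frozen=True)
class MovementEvent:
    """A classified motion episode on one track.

    Frames index the trajectory; ``start_frame < end_frame``.  The phase
    landmarks ``onset/peak/cessation`` are set for rapid apical events (and
    propagated to oscillations) and satisfy onset <= peak <= cessation.
    Net displacement is signed (apical negative), duration in minutes.
    """

    event_class: str
    track_id: str
    start_frame: int
    end_frame: int
    net_displacement: float
    duration: float
    start_depth: float
    onset_frame: int | None = None
    peak_frame: int | None = None
    cessation_frame: int | None = None


@dataclass(frozen=True)
class EventConfig:
    """Detection thresholds (all inclusive, um / min units)."""

    rapid_disp: float = -10.0        # net displacement threshold, um
    rapid_window: float = 30.0       # sliding-window length, min
    basal_disp: float = 15.0         # net displacement threshold, um
    basal_window: float = 120.0      # minimum window length, min
    persist_min: float = 60.0        # directional persistence, min
    smooth_window: int = DEFAULT_WINDOW  # frames
    max_interruption: int = 0        # tolerated opposite-sign frames in runs
    depth_bin: float = 5.0           # start-depth histogram bin width, um


@dataclass(frozen=True)
class EventSummary:
    """Per-class counts and rates for one recording."""

    counts: dict
    normalized_counts: dict          # events per 1000 recording min
    start_depth_histogram: dict      # bin left edge (um) -> rate per 1000 min
    cumulative_recording_min: float
    depth_bin: float


@dataclass(frozen=True)
class AlignedEvents:
    """Depth traces of rapid apical events re-based to movement onset."""

    offsets_min: np.ndarray          # time relative to onset, min
    depths: np.ndarray               # (n_events, n_offsets), NaN-padded, um
    track_ids: tuple
    n_skipped: int


# ---------------------------------------------------------------------------
# directional segments


def _signed_runs(sign: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of constant nonzero sign as (start, stop_exclusive, sign)."""
    runs = []
    i = 0
    n = sign.size
    while i < n:
        s = sign[i]
        j = i + 1
        while j < n and sign[j] == s:
            j += 1
        if s != 0:
            runs.append((i, j, int(s)))
        i = j
    return runs


def _merge_runs(
    runs: list[tuple[int, int, int]], max_gap: int
) -> list[tuple[int, int, int]]:
    """Merge same-signed runs separated by at most ``max_gap`` frames.

    Interrupting frames of the other sign are absorbed into the merged
    run; the interrupting runs themselves are too short to qualify as
    segments on their own when max_gap is small."""
    if max_gap <= 0 or not runs:
        return runs
    merged: list[tuple[int, int, int]] = []
    for sgn in (-1, 1):
        same = [r for r in runs if r[2] == sgn]
        if not same:
            continue
        acc = [same[0]]
        for start, stop, s in same[1:]:
            pstart, pstop, _ = acc[-1]
            if start - pstop <= max_gap:
                acc[-1] = (pstart, stop, s)
            else:
                acc.append((start, stop, s))
        merged.extend(acc)
    return sorted(merged)


def detect_directional_segments(
    kin: KinematicSeries,
    traj: Trajectory,
    persist_min: float = 60.0,
    max_interruption: int = 0,
) -> list[MovementEvent]:
    """Persistent same-signed movement segments (>= ``persist_min`` minutes).

    A segment is a maximal run of smoothed velocity with one strict sign;
    runs shorter than the persistence criterion are discarded.  Zero
    smoothed velocity breaks runs.  ``max_interruption`` > 0 tolerates that
    many interior frames of non-matching sign between same-signed runs.
    """
    sign = np.sign(kin.v_smooth).astype(int)
    runs = _merge_runs(_signed_runs(sign), max_interruption)
    events = []
    for start, stop, s in runs:
        duration = (stop - start) * traj.delta_t
        if duration < persist_min:
            continue
        cls = "directional_basal" if s > 0 else "directional_apical"
        events.append(
            MovementEvent(
                event_class=cls,
                track_id=traj.track_id,
                start_frame=start,
                end_frame=stop,
                net_displacement=float(traj.z[stop] - traj.z[start]),
                duration=float(duration),
                start_depth=float(traj.z[start]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# rapid apical translocations


def _plateau_extrema(x: np.ndarray, find_max: bool) -> np.ndarray:
    """Indices of interior local extrema; plateaus yield their first index."""
    x = np.asarray(x, dtype=float)
    if find_max:
        x = -x
    starts, values = [], []
    i = 0
    while i < x.size:
        j = i + 1
        while j < x.size and x[j] == x[i]:
            j += 1
        starts.append(i)
        values.append(x[i])
        i = j
    out = []
    for k in range(1, len(starts) - 1):
        if values[k] < values[k - 1] and values[k] < values[k + 1]:
            out.append(starts[k])
    return np.asarray(out, dtype=int)


def _merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of integer frame spans, merging overlapping or abutting spans."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_rapid_apical(
    traj: Trajectory,
    kin: KinematicSeries | None = None,
    disp: float = -10.0,
    window_min: float = 30.0,
    smooth_window: int = DEFAULT_WINDOW,
) -> list[MovementEvent]:
    """Rapid apically directed translocations with phase landmarks.

    Any sliding window of ``window_min`` minutes whose net displacement is
    <= ``disp`` (inclusive) seeds an event; overlapping or abutting
    qualifying windows merge into one.  Within each merged event the peak is
    the minimum of smoothed velocity; the onset is the nearest preceding
    local minimum of smoothed acceleration and the cessation the nearest
    following local maximum (falling back to the extreme value near the
    event boundary when no interior extremum exists).
    """
    if kin is None:
        kin = compute_kinematics(traj, smooth_window)
    w = int(round(window_min / traj.delta_t))
    if w < 1:
        raise ParameterError("rapid window shorter than one frame interval")
    n = traj.n_frames
    if n <= w:
        return []
    net = traj.z[w:] - traj.z[:-w]
    seeds = np.flatnonzero(net <= disp)
    spans = _merge_spans([(int(i), int(i) + w) for i in seeds])

    v_s, a_s = kin.v_smooth, kin.a_smooth
    # acceleration index j is centred on frame j + 1
    acc_min_frames = _plateau_extrema(a_s, find_max=False) + 1
    acc_max_frames = _plateau_extrema(a_s, find_max=True) + 1

    events = []
    for s, e in spans:
        # velocity indices covering the event's intervals
        vidx = np.arange(s, e)
        peak_frame = int(vidx[np.argmin(v_s[vidx])])

        before = acc_min_frames[acc_min_frames <= peak_frame]
        if before.size:
            onset = int(before[-1])
        else:
            lo = max(0, s - w)
            cand = np.arange(lo, peak_frame + 1)
            aidx = np.clip(cand - 1, 0, a_s.size - 1)
            onset = int(cand[np.argmin(a_s[aidx])])

        after = acc_max_frames[acc_max_frames >= peak_frame]
        if after.size:
            cessation = int(after[0])
        else:
            hi = min(n - 1, e + w)
            cand = np.arange(peak_frame, hi + 1)
            aidx = np.clip(cand - 1, 0, a_s.size - 1)
            cessation = int(cand[np.argmax(a_s[aidx])])

        events.append(
            MovementEvent(
                event_class="rapid_apical",
                track_id=traj.track_id,
                start_frame=s,
                end_frame=e,
                net_displacement=float(traj.z[e] - traj.z[s]),
                duration=float((e - s) * traj.delta_t),
                start_depth=float(traj.z[s]),
                onset_frame=onset,
                peak_frame=peak_frame,
                cessation_frame=cessation,
            )
        )
    return events


# ---------------------------------------------------------------------------
# persistent basal movements


def detect_basal_persistent(
    traj: Trajectory,
    disp: float = 15.0,
    window_min: float = 120.0,
) -> list[MovementEvent]:
    """Persistent basally directed movements (net >= +15 um over >= 2 h).

    Every frame span of at least ``window_min`` minutes whose net
    displacement is >= ``disp`` qualifies; overlapping qualifying spans are
    merged into maximal events.
    """
    w = int(np.ceil(window_min / traj.delta_t))
    n = traj.n_frames
    if n <= w:
        return []
    z = traj.z
    spans = []
    # all (i, j) with j - i >= w and z[j] - z[i] >= disp
    for i in range(0, n - w):
        js = np.arange(i + w, n)
        ok = np.flatnonzero(z[js] - z[i] >= disp)
        if ok.size:
            spans.append((i, int(js[ok[-1]])))
    merged = _merge_spans(spans)
    events = []
    for s, e in merged:
        events.append(
            MovementEvent(
                event_class="basal_persistent",
                track_id=traj.track_id,
                start_frame=s,
                end_frame=e,
                net_displacement=float(z[e] - z[s]),
                duration=float((e - s) * traj.delta_t),
                start_depth=float(z[s]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# oscillations


def detect_oscillations(events: Sequence[MovementEvent]) -> list[MovementEvent]:
    """Full rapid-apical -> basal -> rapid-apical cycles on one track.

    Events must come from one track.  Counting is greedy left-to-right and
    chained: the closing rapid apical event of one cycle may open the next,
    so K rapid events interleaved with basal movements yield K - 1 cycles.
    """
    track_ids = {ev.track_id for ev in events}
    if len(track_ids) > 1:
        raise ParameterError("oscillation detection expects a single track")
    seq = sorted(
        (ev for ev in events
         if ev.event_class in ("rapid_apical", "basal_persistent")),
        key=lambda ev: (ev.start_frame, ev.end_frame),
    )
    oscillations = []
    last_rapid: MovementEvent | None = None
    basal_seen = False
    for ev in seq:
        if ev.event_class == "basal_persistent":
            if last_rapid is not None:
                basal_seen = True
            continue
        if last_rapid is not None and basal_seen:
            start = (last_rapid.onset_frame
                     if last_rapid.onset_frame is not None
                     else last_rapid.start_frame)
            end = (ev.cessation_frame
                   if ev.cessation_frame is not None
                   else ev.end_frame)
            if end <= start:
                start, end = last_rapid.start_frame, ev.end_frame
            oscillations.append(
                MovementEvent(
                    event_class="oscillation",
                    track_id=ev.track_id,
                    start_frame=int(start),
                    end_frame=int(end),
                    net_displacement=np.nan,
                    duration=np.nan,
                    start_depth=last_rapid.start_depth,
                    onset_frame=last_rapid.onset_frame,
                    peak_frame=None,
                    cessation_frame=ev.cessation_frame,
                )
            )
        last_rapid = ev
        basal_seen = False
    return oscillations


def detect_all(
    recording: RecordingSet,
    config: EventConfig = EventConfig(),
) -> list[MovementEvent]:
    """Run every detector on every trajectory of a recording."""
    all_events: list[MovementEvent] = []
    for traj in recording:
        kin = compute_kinematics(traj, config.smooth_window)
        per_track = []
        per_track += detect_directional_segments(
            kin, traj, config.persist_min, config.max_interruption
        )
        per_track += detect_rapid_apical(
            traj, kin, config.rapid_disp, config.rapid_window,
            config.smooth_window,
        )
        per_track += detect_basal_persistent(
            traj, config.basal_disp, config.basal_window
        )
        per_track += detect_oscillations(per_track)
        # fill oscillation duration/net from the trajectory
        filled = []
        for ev in per_track:
            if ev.event_class == "oscillation":
                ev = replace(
                    ev,
                    net_displacement=float(
                        traj.z[ev.end_frame] - traj.z[ev.start_frame]
                    ),
                    duration=float(
                        (ev.end_frame - ev.start_frame) * traj.delta_t
                    ),
                )
            filled.append(ev)
        all_events += filled
    return all_events


# ---------------------------------------------------------------------------
# summaries


def summarize_events(
    events: Iterable[MovementEvent],
    recording: RecordingSet,
    depth_bin: float = 5.0,
) -> EventSummary:
    """Per-class counts, per-1000-min rates and the start-depth histogram.

    Rates use the recording's cumulative recording time:
    normalized = count / cumulative_recording_min * 1000.  The start-depth
    histogram bins rapid apical event start depths into left-closed,
    right-open bins of ``depth_bin`` um anchored at depth 0, each bin
    reported as a rate so the bins sum to the class rate.
    """
    cum = recording.cumulative_recording_min
    if cum <= 0:
        raise ZeroDivisionError("cumulative recording time is zero")
    events = list(events)
    counts = {cls: 0 for cls in EVENT_CLASSES}
    for ev in events:
        counts[ev.event_class] = counts.get(ev.event_class, 0) + 1
    normalized = {cls: c / cum * 1000.0 for cls, c in counts.items()}

    hist: dict[float, float] = {}
    for ev in events:
        if ev.event_class != "rapid_apical":
            continue
        left = float(np.floor(ev.start_depth / depth_bin) * depth_bin)
        hist[left] = hist.get(left, 0.0) + 1.0 / cum * 1000.0
    return EventSummary(
        counts=counts,
        normalized_counts=normalized,
        start_depth_histogram=dict(sorted(hist.items())),
        cumulative_recording_min=cum,
        depth_bin=depth_bin,
    )


def align_events_to_onset(
    events: Iterable[MovementEvent],
    recording: RecordingSet,
) -> AlignedEvents:
    """Re-base rapid apical depth traces so onset is (t, z) = (0, 0).

    Events without an onset landmark are skipped and counted.  The returned
    matrix is NaN-padded where a track does not extend to an offset.
    """
    trajs = {traj.track_id: traj for traj in recording}
    usable = []
    skipped = 0
    for ev in events:
        if ev.event_class != "rapid_apical" or ev.onset_frame is None:
            skipped += 1
            continue
        usable.append(ev)
    if not usable:
        return AlignedEvents(
            offsets_min=np.empty(0), depths=np.empty((0, 0)),
            track_ids=(), n_skipped=skipped,
        )
    lo = min(-ev.onset_frame for ev in usable)
    hi = max(trajs[ev.track_id].n_frames - 1 - ev.onset_frame
             for ev in usable)
    offsets = np.arange(lo, hi + 1)
    depths = np.full((len(usable), offsets.size), np.nan)
    for row, ev in enumerate(usable):
        traj = trajs[ev.track_id]
        frames = np.arange(traj.n_frames)
        cols = frames - ev.onset_frame - lo
        depths[row, cols] = traj.z - traj.z[ev.onset_frame]
    return AlignedEvents(
        offsets_min=offsets * recording.delta_t,
        depths=depths,
        track_ids=tuple(ev.track_id for ev in usable),
        n_skipped=skipped,
    )
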