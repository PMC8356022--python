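import numpy as np
import pytest

from nucdyn import RecordingSet, SimulationConfig, Trajectory, simulate_cohort


def make_traj(z, delta_t=10.0, track_id="t0", xy=None, **kw):
    z = np.asarray(z, dtype=float)
    return Trajectory(
        track_id=track_id, t=np.arange(z.size) * delta_t, z=z, xy=xy, **kw
    )


@pytest.fixture
def flat_traj():
    return make_traj(np.full(20, 42.0))


@pytest.fixture
def ballistic_traj():
    """Constant apical drift -0.5 um/min over 73 frames at delta_t=10."""
    return make_traj(100.0 - 0.5 * np.arange(73) * 10.0)


@pytest.fixture
def rapid_traj():
    """Flat, then -0.5 um/min for 60 min, then flat (one rapid event)."""
    z = np.concatenate(
        [np.full(10, 50.0), 50.0 - 5.0 * np.arange(1, 7), np.full(10, 20.0)]
    )
    return make_traj(z)


@pytest.fixture(scope="session")
def brownian_recording():
    """300 pure-diffusion tracks, D = 0.25 um^2/min, 73 frames."""
    cfg = SimulationConfig(
        seed=20260921, n_tracks=300, diffusion_D=0.25,
        rapid_event_rate=0.0, basal_event_rate=0.0,
    )
    recording, _ = simulate_cohort(cfg)
    return recording


def single_track_recording(traj):
    return RecordingSet((traj,), delta_t=traj.delta_t)
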