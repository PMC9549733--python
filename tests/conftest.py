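import numpy as np
import pytest

from motilitylab.io import Track, TrackSet
from motilitylab.simulate import SimulationConfig, simulate_tracks


def make_track(positions, frames=None, frame_interval=1.0, track_id="t0",
               condition="untreated"):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Track(track_id=track_id, condition=condition,
                 frame_interval=frame_interval, frames=np.asarray(frames),
                 positions=positions)


@pytest.fixture
def line_track():
    """20-point straight line along x, 1 μm/min."""
    x = np.arange(20, dtype=float)
    return make_track(np.column_stack([x, np.zeros(20)]))


@pytest.fixture
def zigzag_track():
    """(0,0),(1,1),(2,0),(3,1) at 10 min/frame — the hand-arithmetic oracle."""
    return make_track([(0, 0), (1, 1), (2, 0), (3, 1)], frame_interval=10.0)


@pytest.fixture
def loop_track():
    """Closed unit-square loop."""
    return make_track([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])


@pytest.fixture
def stationary_track():
    return make_track(np.zeros((20, 2)))


@pytest.fixture(scope="session")
def brownian_ensemble():
    """200 seeded Brownian tracks × 72 frames, σ = 1 μm/frame, 10 min/frame."""
    cfg = SimulationConfig(model="brownian", n_tracks=200, n_frames=72,
                           frame_interval=10.0, dim=2, seed=5, sigma=1.0)
    ts, _ = simulate_tracks(cfg, "untreated")
    return ts


@pytest.fixture(scope="session")
def planted_feature_table():
    """Feature table for a two-condition planted mixture (shared across
    state-space tests to avoid recomputation)."""
    from motilitylab.features import feature_table
    from motilitylab.simulate import default_2d_config

    tracks, truth = [], []
    for i, cond in enumerate(("untreated", "treated")):
        ts, labels = simulate_tracks(default_2d_config(n_tracks=144, seed=100 + i), cond)
        tracks.extend(ts.tracks)
        truth.extend(labels)
    fm = feature_table(TrackSet(tracks, 10.0))
    return fm, np.array(truth)
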