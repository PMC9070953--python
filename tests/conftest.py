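import numpy as np
import pytest

from barrierassay import Arena, SimulationConfig, Track, TrackSet


@pytest.fixture
def arena() -> Arena:
    return Arena()


@pytest.fixture
def symmetric_arena() -> Arena:
    # barrier exactly mid-field, handy for mirror-symmetry checks
    return Arena(fov_width=47.0, barrier_x=23.5)


def make_track(
    track_id: str,
    x,
    y=None,
    units: str = "mm",
    frame0: int = 0,
    frame_rate: float = 3.0,
) -> Track:
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) + 10.0 if y is None else np.asarray(y, dtype=float)
    frames = np.arange(frame0, frame0 + x.size)
    return Track(
        track_id=track_id,
        frame=frames,
        time=frames / frame_rate,
        x=x,
        y=y,
        units=units,
    )


def make_set(tracks, arena: Arena | None = None, **kw) -> TrackSet:
    return TrackSet(tracks=list(tracks), arena=arena or Arena(), **kw)


@pytest.fixture
def fast_sim_config() -> SimulationConfig:
    """Small, quick simulation used by multiple test modules."""
    return SimulationConfig(n_animals=10, duration=600.0, seed=11)
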