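import numpy as np
import pytest

from motion3c import SimConfig, Track, TrackSet, simulate_population


@pytest.fixture
def ballistic_track() -> TrackSet:
    """One cell moving at constant velocity (1, 0) μm/min, sampled at 40 min."""
    times = 40.0 * np.arange(8)
    xy = np.column_stack([times, np.zeros_like(times)])
    tr = Track(id="ball", frames=np.arange(8), times=times, xy=xy)
    return TrackSet(tracks=[tr], interval=40.0)


@pytest.fixture
def tiny_track() -> TrackSet:
    """Three samples on a straight line: steps (3,4) then (3,4)."""
    tr = Track(
        id="a",
        frames=np.arange(3),
        times=40.0 * np.arange(3),
        xy=np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]]),
    )
    return TrackSet(tracks=[tr], interval=40.0)


@pytest.fixture(scope="session")
def persistent_population() -> TrackSet:
    """Standard validation run: persistence only (p=8 μm, no bias)."""
    return simulate_population(SimConfig(p_in=8.0, b_module=0.0, seed=0))


@pytest.fixture(scope="session")
def biased_population() -> TrackSet:
    """Standard validation run: bias only (b=8 μm, no persistence)."""
    return simulate_population(SimConfig(p_in=0.0, b_module=8.0, seed=0))


def random_trackset(rng: np.random.Generator, n_tracks=3, n_samples=5) -> TrackSet:
    """Small TrackSet with arbitrary positions, for oracle comparisons."""
    tracks = []
    for i in range(n_tracks):
        n = int(rng.integers(2, n_samples + 1))
        tracks.append(
            Track(
                id=f"t{i}",
                frames=np.arange(n),
                times=40.0 * np.arange(n),
                xy=rng.normal(scale=10.0, size=(n, 2)),
            )
        )
    return TrackSet(tracks=tracks, interval=40.0)
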