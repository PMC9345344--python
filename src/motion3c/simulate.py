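"""Stochastic simulator of 2D cell populations with three motion components.

Each displacement over one analysis interval Δt is the vector sum of

* a **random** component — itself a brief random walk of ``n_substeps``
  sub-steps, each of fixed length ``sqrt(msd_random / n_substeps)`` and
  independent uniform direction, so that the expected squared modulus of
  the resultant equals ``msd_random``.  Sub-stepping spreads the step-length
  distribution instead of producing vectors identical in module;
* a **persistence** component — a vector of fixed module ``p_in`` aligned
  with the cell's previous total displacement (absent for the first step,
  which has no predecessor);
* a **bias** component — one constant vector shared by all cells, modelling
  a uniform directional stimulus such as a wound edge.

Populations are reproducible: the same :class:`SimConfig` (including seed)
yields a bit-identical :class:`~motion3c.tracks.TrackSet`.  Per-cell random
streams are spawned deterministically from the seed and the cell index, so
enlarging ``n_cells`` extends a population without reshuffling the
trajectories of existing cells.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .tracks import Track, TrackSet

__all__ = [
    "SimConfig",
    "random_component",
    "simulate_population",
    "mean_module_to_msd",
    "msd_to_mean_module",
]


@dataclass
class SimConfig:
    """All knobs of the trajectory generator.

    Defaults reproduce the standard validation population: 30 cells
    followed for 24 h at 40-minute intervals, with a random mean squared
    displacement of 100 μm² per interval built from 10 sub-steps.
    """

    n_cells: int = 30
    n_steps: int = 36
    dt: float = 40.0  # minutes per interval
    msd_random: float = 100.0  # μm² per interval
    n_substeps: int = 10
    p_in: float = 0.0  # persistence module, μm per interval
    b_module: float = 0.0  # bias module, μm per interval
    b_angle: float = 0.0  # bias direction, radians
    seed: int = 0
    start_positions: str = "grid"  # "grid" or "origin"
    grid_spacing: float = 200.0  # μm between grid start points

    def __post_init__(self) -> None:
        if self.msd_random < 0:
            raise ValueError("msd_random must be >= 0")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        if self.p_in < 0:
            raise ValueError("p_in must be >= 0")
        if self.b_module < 0:
            raise ValueError("b_module must be >= 0")
        if self.start_positions not in ("grid", "origin"):
            raise ValueError("start_positions must be 'grid' or 'origin'")

    @property
    def bias_vector(self) -> np.ndarray:
        return self.b_module * np.array(
            [math.cos(self.b_angle), math.sin(self.b_angle)]
        )

    def to_dict(self) -> dict:
        return asdict(self)


def random_component(
    msd_random: float, n_substeps: int, rng: np.random.Generator, size: int = None
):
    """Draw the random component of one displacement (or ``size`` of them).

    The component is the resultant of ``n_substeps`` sub-steps of fixed
    module ``sqrt(msd_random / n_substeps)`` and independent uniform
    directions, so E[|result|²] = msd_random for any sub-step count.

    Returns a length-2 vector, or a ``(size, 2)`` array if ``size`` is
    given.
    """
    n = int(size) if size is not None else 1
    module = math.sqrt(msd_random / n_substeps)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=(n, n_substeps))
    res = module * np.stack(
        [np.cos(theta).sum(axis=1), np.sin(theta).sum(axis=1)], axis=1
    )
    return res if size is not None else res[0]


def simulate_population(cfg: SimConfig) -> TrackSet:
    """Simulate a cell population and return it as a TrackSet.

    Each cell starts at rest: its first displacement has no persistence
    term (there is no previous displacement to follow).  From the second
    step on, displacement = random + p_in·û(previous displacement) + bias.
    A zero-length previous displacement likewise contributes no
    persistence.
    """
    bias = cfg.bias_vector
    n = cfg.n_cells
    if cfg.start_positions == "grid":
        side = max(1, math.ceil(math.sqrt(n)))
        starts = cfg.grid_spacing * np.array(
            [(i % side, i // side) for i in range(n)], dtype=float
        )
    else:
        starts = np.zeros((n, 2))

    times = cfg.dt * np.arange(cfg.n_steps + 1)
    frames = np.arange(cfg.n_steps + 1)
    tracks = []
    for c in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(c,)))
        rand = random_component(cfg.msd_random, cfg.n_substeps, rng, size=cfg.n_steps)
        xy = np.empty((cfg.n_steps + 1, 2))
        xy[0] = starts[c]
        prev = np.zeros(2)
        for t in range(cfg.n_steps):
            d = rand[t] + bias
            norm = math.hypot(prev[0], prev[1])
            if norm > 0.0:
                d = d + cfg.p_in * prev / norm
            xy[t + 1] = xy[t] + d
            prev = d
        tracks.append(Track(id=f"sim{c:04d}", frames=frames, times=times, xy=xy))
    return TrackSet(tracks=tracks, interval=cfg.dt)


def mean_module_to_msd(m: float) -> float:
    """Convert a requested mean random step length (μm) to the MSD (μm²).

    The summed sub-step walk is asymptotically Rayleigh, for which the
    mean modulus is sqrt(π·MSD/4); inverting gives MSD = 4m²/π.
    """
    if m < 0:
        raise ValueError("mean module must be >= 0")
    return 4.0 * m * m / math.pi


def msd_to_mean_module(msd: float) -> float:
    """Inverse of :func:`mean_module_to_msd`: sqrt(π·MSD/4)."""
    if msd < 0:
        raise ValueError("MSD must be >= 0")
    return math.sqrt(math.pi * msd / 4.0)
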