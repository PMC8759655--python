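"""Analytic rigid-particle collision-rate model.

For N hard disks of diameter L (area S) moving at speed V in an arena of
area A, the expected number of contact events per hour is

    Z = N (N - 1) L V / (2 (A - N S))

The N(N-1)/2 factor counts unordered pairs; L V is the collision corridor a
particle sweeps per hour; A - N S is the free area available to particle
centres. With V in um/h, Z is collisions per hour over the whole arena.

The default parameter set corresponds to fast-migrating amoeboid cells in a
100-um-diameter circular island: L = 8.42 um, V = 234.6 um/h (= 3.91
um/min), A = 7853 um^2, S = 55.7 um^2.

Two area-density conventions are deliberately both supported (see
:class:`DensityConvention`): the model's own per-particle footprint S =
55.7 um^2, and the smaller effective footprint (~12.57 um^2) implied by the
experimental correspondence of 200 cells to a 32% area density in the same
arena. Neither is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CollisionModelParams",
    "DensityConvention",
    "predict_collision_count",
    "collision_curve",
    "count_from_density",
    "density_from_count",
    "DEFAULT_PARAMS",
    "EXPERIMENT_DENSITY_CONVENTION",
    "MODEL_DENSITY_CONVENTION",
]


@dataclass(frozen=True)
class CollisionModelParams:
    """Parameters of the rigid-particle collision model.

    Attributes
    ----------
    L : particle diameter, um
    V : particle speed, um/h
    A : arena area, um^2
    S : particle area, um^2
    """

    L: float = 8.42
    V: float = 234.6
    A: float = 7853.0
    S: float = 55.7

    def __post_init__(self) -> None:
        if min(self.L, self.V, self.A, self.S) <= 0:
            raise ValueError("all model parameters must be strictly positive")
        if self.S > self.A:
            raise ValueError("particle area S cannot exceed arena area A")


#: Default parameter set for amoeboid cells in the 100-um circular island.
DEFAULT_PARAMS = CollisionModelParams()


@dataclass(frozen=True)
class DensityConvention:
    """Converts between cell counts and percent area density.

    density_percent = 100 * N * per_cell_area / arena_area
    """

    per_cell_area: float
    arena_area: float = 7853.0

    def __post_init__(self) -> None:
        if self.per_cell_area <= 0 or self.arena_area <= 0:
            raise ValueError("areas must be positive")


#: Effective footprint implied by the observed 200-cell <-> 32% correspondence.
EXPERIMENT_DENSITY_CONVENTION = DensityConvention(
    per_cell_area=0.32 * 7853.0 / 200.0, arena_area=7853.0
)

#: Footprint equal to the model's particle area S.
MODEL_DENSITY_CONVENTION = DensityConvention(per_cell_area=55.7, arena_area=7853.0)


def predict_collision_count(params: CollisionModelParams, N) -> float:
    """Expected collisions per hour among ``N`` particles.

    ``N`` may be fractional for smooth plotting; for N < 1 the pair count
    N(N-1) is clamped at zero.
    """
    N = float(N)
    if N < 0:
        raise ValueError("N must be non-negative")
    free_area = params.A - N * params.S
    if free_area <= 0:
        raise ValueError(
            f"arena over-packed: N*S = {N * params.S:.1f} um^2 >= A = {params.A:.1f} um^2"
        )
    pairs2 = max(N * (N - 1.0), 0.0)
    return pairs2 * params.L * params.V / (2.0 * free_area)


def density_from_count(N, conv: DensityConvention) -> float:
    """Percent of the arena area covered by ``N`` cell footprints."""
    return 100.0 * float(N) * conv.per_cell_area / conv.arena_area


def count_from_density(density_percent: float, conv: DensityConvention) -> int:
    """Cell count corresponding to a percent area density (nearest integer)."""
    if density_percent < 0:
        raise ValueError("density must be non-negative")
    n = density_percent / 100.0 * conv.arena_area / conv.per_cell_area
    return int(round(n))


def collision_curve(
    params: CollisionModelParams,
    N_values: Sequence[float],
    conv: DensityConvention,
) -> np.ndarray:
    """(density %, Z) pairs for each N, as a (len(N), 2) array."""
    out = np.empty((len(N_values), 2))
    for i, N in enumerate(N_values):
        out[i, 0] = density_from_count(N, conv)
        out[i, 1] = predict_collision_count(params, N)
    return out
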