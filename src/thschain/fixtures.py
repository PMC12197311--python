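"""Idealized configurations and toy curves for testing the analysis chain.

The generators realize the reference phases of the order-parameter
construction exactly: straight rods all along one axis (ideal prolate,
q = 1), straight rods with axes equally spaced in the xy-plane (ideal
oblate, q = -0.5), and straight rods with axes uniform on the sphere
(isotropic, q -> 0 up to the O(Nch^-1/2) finite-sample bias).  Straight
rods are used instead of thermalized chains because they reproduce the
ideal reference Q tensors exactly.  ``make_toy_curve`` generates noisy
evaluations of the empirical transition laws for fit-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SIGMA, ChainSystem, SimulationCell

__all__ = [
    "FixtureSpec",
    "make_ideal_prolate",
    "make_ideal_oblate",
    "make_isotropic_random",
    "make_toy_curve",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for one synthetic configuration or curve."""

    kind: str  # ideal_prolate | ideal_oblate | isotropic_random | toy_curve
    params: dict = field(default_factory=dict)
    seed: int = 0

    _KINDS = ("ideal_prolate", "ideal_oblate", "isotropic_random",
              "toy_curve")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")

    def build(self):
        if self.kind == "ideal_prolate":
            return make_ideal_prolate(seed=self.seed, **self.params)
        if self.kind == "ideal_oblate":
            return make_ideal_oblate(**self.params)
        if self.kind == "isotropic_random":
            return make_isotropic_random(seed=self.seed, **self.params)
        return make_toy_curve(seed=self.seed, **self.params)


def _straight_rod(origin: np.ndarray, axis: np.ndarray, n: int) -> np.ndarray:
    """n tangent spheres along a unit axis, bonds exactly sigma."""
    return origin + np.arange(n)[:, None] * SIGMA * axis


def make_ideal_prolate(n_chains: int, n: int, spacing: float = 1.5,
                       seed: int = 0) -> tuple[ChainSystem, SimulationCell]:
    """Perfectly aligned straight rods: Nch N-mers along x on a y-z grid.

    Realizes the ideal prolate nematic phase (q = 1, director x).  The
    cubic cell is sized to keep periodic images of each rod at least one
    diameter apart.
    """
    if spacing < SIGMA:
        raise ValueError("lattice spacing must be at least sigma")
    if n_chains < 1 or n < 2:
        raise ValueError("need at least one chain of two spheres")
    side = int(np.ceil(np.sqrt(n_chains)))
    L = max((n + 1) * SIGMA, (side + 1) * spacing)
    chains = []
    for c in range(n_chains):
        iy, iz = divmod(c, side)
        origin = np.array([0.5, (iy + 0.5) * spacing, (iz + 0.5) * spacing])
        chains.append(_straight_rod(origin, np.array([1.0, 0.0, 0.0]), n))
    return ChainSystem.from_chains(chains), SimulationCell(L=L, dconf=0)


def make_ideal_oblate(n_chains: int, n: int = 12,
                      spacing: float = 1.5
                      ) -> tuple[ChainSystem, SimulationCell]:
    """Straight rods with long axes equally spaced in the xy-plane.

    Any Nch >= 3 realizes the ideal oblate nematic phase exactly
    (q = -0.5, director z): the planar average of u u^T over equally
    spaced directions is isotropic in the plane.  Rods are stacked at
    distinct z levels so the configuration is overlap free.
    """
    if n_chains < 3:
        raise ValueError("the planar average needs at least 3 chains")
    if n < 2:
        raise ValueError("rods need at least two spheres")
    half_extent = (n - 1) / 2.0 + 1.0
    L = max(2 * half_extent + 2.0, n_chains * spacing + 1.0)
    center = L / 2.0
    chains = []
    for c in range(n_chains):
        ang = np.pi * c / n_chains  # axes modulo pi: equally spaced
        axis = np.array([np.cos(ang), np.sin(ang), 0.0])
        z = 0.5 + c * spacing
        origin = np.array([center, center, z]) - axis * (n - 1) / 2.0
        chains.append(_straight_rod(origin, axis, n))
    return ChainSystem.from_chains(chains), SimulationCell(L=L, dconf=0)


def make_isotropic_random(n_chains: int, n: int = 12, phi: float = 0.01,
                          seed: int = 0, max_tries: int = 2000
                          ) -> tuple[ChainSystem, SimulationCell]:
    """Straight rods with axes uniform on the sphere, placed without overlap.

    Rejection placement, valid in the dilute regime (phi <= 0.05).
    """
    if phi > 0.05:
        raise ValueError("rejection placement requires phi <= 0.05")
    from .model import cell_size_for_density

    rng = np.random.default_rng(seed)
    n_atoms = n_chains * n
    L = cell_size_for_density(n_atoms, phi)
    cell = SimulationCell(L=L, dconf=0)
    placed: list[np.ndarray] = []
    occupied = np.empty((0, 3))
    for _ in range(n_chains):
        for attempt in range(max_tries):
            v = rng.normal(size=3)
            axis = v / np.linalg.norm(v)
            origin = rng.random(3) * L
            rod = _straight_rod(origin, axis, n)
            if len(occupied):
                d = occupied[None, :, :] - rod[:, None, :]
                d -= L * np.round(d / L)
                if (np.einsum("ijk,ijk->ij", d, d) < SIGMA ** 2).any():
                    continue
            placed.append(rod)
            occupied = np.concatenate([occupied, rod], axis=0)
            break
        else:
            raise RuntimeError(f"rod placement failed after {max_tries} tries")
    from .order import wrap_positions

    chains = [wrap_positions(rod, cell) for rod in placed]
    return ChainSystem.from_chains(chains), cell


def make_toy_curve(model_id: str, coefficients: dict, grid: np.ndarray,
                   noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Transition-law evaluations plus i.i.d. Gaussian noise.

    Returns an (n, 2) array of (predictor, density) points consumable
    by the fitting routines.
    """
    from .transition import evaluate_model

    grid = np.asarray(grid, dtype=float)
    y = np.array([evaluate_model(model_id, coefficients, x) for x in grid])
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma,
                                                   size=len(grid))
    return np.column_stack([grid, y])
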