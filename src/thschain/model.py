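"""Core model types and packing-density bookkeeping.

Polymers are linear chains of tangent hard spheres of uniform diameter
``sigma`` (the unit of length, so ``sigma = 1`` throughout).  Non-bonded
pairs interact through the hard-sphere potential (overlap forbidden,
contact allowed); bonded neighbours must sit in the thin shell
``[sigma, sigma + dl]``; chain stiffness enters through a harmonic
bending potential ``U(theta) = k_bend * (theta - theta0)**2`` on the
angle ``theta`` between successive bond vectors (``theta = 0`` means a
collinear triplet).  Temperature is fixed at ``kB*T = 1``, so all
energies are in units of ``kB*T``.

The simulation cell is cubic with edge ``L``.  Confinement replaces the
periodic boundary on ``dconf`` axes by a pair of flat impenetrable walls
a distance ``dwall = L`` apart; sphere centres must then stay in
``[sigma/2, L - sigma/2]`` along those axes.  The packing density is

    phi = (pi/6) * Nat * sigma**3 / L**3

and the effective packing density corrects for the wall-excluded shell
of width ``sigma/2`` per wall:

    phi_eff = (pi/6) * Nat * sigma**3 / ((L - sigma)**dconf * L**(3 - dconf))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIGMA = 1.0
#: default bond-length tolerance, in units of sigma
DEFAULT_DL = 6.5e-4
#: relative slack absorbing floating-point noise in hard-overlap tests:
#: pair distances >= sigma*(1 - OVERLAP_SLACK) are treated as non-overlapping
OVERLAP_SLACK = 1e-12

__all__ = [
    "SIGMA",
    "DEFAULT_DL",
    "OVERLAP_SLACK",
    "SimulationCell",
    "ModelParams",
    "ChainSystem",
    "DensityReport",
    "Violation",
    "hard_overlap",
    "bending_energy",
    "bond_angle",
    "packing_density",
    "cell_size_for_density",
    "effective_packing_density",
    "density_report",
    "minimum_image",
    "pair_distances",
    "validate",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationCell:
    """Cubic simulation cell with mixed periodic/wall boundaries.

    ``dconf`` counts the confined axes: 0 = bulk (fully periodic),
    1 = slit pore, 2 = rectangular channel, 3 = closed box.  By fixed
    convention confinement is applied from the last axis backwards:
    ``dconf=1`` confines z, ``dconf=2`` confines y and z, ``dconf=3``
    confines all three.  For confined axes the inter-wall distance
    ``dwall`` equals the cell edge ``L``.
    """

    L: float
    dconf: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"cell edge must be positive, got {self.L}")
        if not 0 <= self.dconf <= 3:
            raise ValueError(f"dconf must be in 0..3, got {self.dconf}")

    @property
    def dwall(self) -> float:
        return self.L

    @property
    def wall_axes(self) -> tuple[int, ...]:
        return tuple(range(3 - self.dconf, 3))

    @property
    def periodic_axes(self) -> tuple[int, ...]:
        return tuple(range(3 - self.dconf))

    @property
    def periodic_mask(self) -> np.ndarray:
        m = np.zeros(3, dtype=bool)
        m[list(self.periodic_axes)] = True
        return m

    @property
    def volume(self) -> float:
        return self.L ** 3

    def with_edge(self, L: float) -> "SimulationCell":
        return SimulationCell(L=L, dconf=self.dconf)

    def with_dconf(self, dconf: int) -> "SimulationCell":
        return SimulationCell(L=self.L, dconf=dconf)


@dataclass(frozen=True)
class ModelParams:
    """Interaction parameters and the fluctuating-length ensemble window.

    ``mu`` is the chemical-potential spectrum of the semigrand ensemble,
    one value (in kB*T) per length class in ``[n_min, n_max]``; a flat
    spectrum (the default) together with symmetric length-transfer moves
    targets a uniform length distribution.
    """

    k_bend: float = 9.0
    theta0: float = 0.0
    dl: float = DEFAULT_DL
    n_min: int = 6
    n_max: int = 18
    mu: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_bend < 0:
            raise ValueError("bending constant must be non-negative")
        if not 0 <= self.theta0 < np.pi:
            raise ValueError("theta0 must lie in [0, pi)")
        if self.dl <= 0:
            raise ValueError("bond tolerance dl must be positive")
        if self.n_min > self.n_max:
            raise ValueError("n_min must not exceed n_max")

    def mu_of(self, n: int) -> float:
        return self.mu.get(n, 0.0)

    @property
    def n_classes(self) -> int:
        return self.n_max - self.n_min + 1


class ChainSystem:
    """Sphere coordinates plus the partition into chains.

    Coordinates are stored in a single ``(Nat, 3)`` array, chain by
    chain, with ``starts`` giving the offset of each chain (length
    ``Nch + 1``).  Along periodic axes coordinates are wrapped to
    ``[0, L)``; along confined axes they are absolute and must stay in
    ``[sigma/2, L - sigma/2]``.  Because every bond is ~1 sigma long and
    cells are always several sigma wide, minimum-image unwrapping along
    a chain is unambiguous.
    """

    def __init__(self, positions: np.ndarray, starts: np.ndarray):
        positions = np.asarray(positions, dtype=float)
        starts = np.asarray(starts, dtype=np.int64)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ValueError("positions must have shape (Nat, 3)")
        if starts.ndim != 1 or len(starts) < 2:
            raise ValueError("starts must list at least one chain")
        if starts[0] != 0 or starts[-1] != len(positions):
            raise ValueError("starts must span 0..Nat")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("every chain must contain at least one sphere")
        self.positions = positions
        self.starts = starts

    @classmethod
    def from_chains(cls, chains: list[np.ndarray]) -> "ChainSystem":
        starts = np.concatenate([[0], np.cumsum([len(c) for c in chains])])
        return cls(np.concatenate(chains, axis=0), starts)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return len(self.starts) - 1

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.starts)

    @property
    def chain_ids(self) -> np.ndarray:
        """Chain index of every sphere, shape (Nat,)."""
        return np.repeat(np.arange(self.n_chains), self.lengths)

    def chain_slice(self, i: int) -> slice:
        return slice(int(self.starts[i]), int(self.starts[i + 1]))

    def chain_coords(self, i: int) -> np.ndarray:
        return self.positions[self.chain_slice(i)]

    def copy(self) -> "ChainSystem":
        return ChainSystem(self.positions.copy(), self.starts.copy())


@dataclass(frozen=True)
class DensityReport:
    """Packing-density summary for one configuration."""

    phi: float
    phi_eff: float
    dwall: float
    n_atoms: int
    dconf: int


@dataclass(frozen=True)
class Violation:
    """One constraint violation found by :func:`validate`."""

    kind: str  # "overlap" | "bond" | "wall" | "length"
    items: tuple
    value: float


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Apply the minimum-image convention on periodic axes only."""
    delta = np.array(delta, dtype=float, copy=True)
    for ax in cell.periodic_axes:
        delta[..., ax] -= cell.L * np.round(delta[..., ax] / cell.L)
    return delta


def pair_distances(a: np.ndarray, b: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Minimum-image distances between corresponding rows of a and b."""
    d = minimum_image(np.asarray(a) - np.asarray(b), cell)
    return np.sqrt(np.einsum("...i,...i->...", d, d))


def bond_angle(r0: np.ndarray, r1: np.ndarray, r2: np.ndarray,
               cell: SimulationCell | None = None) -> float:
    """Bending angle of the triplet (r0, r1, r2), 0 for collinear.

    The angle is measured between successive bond vectors b1 = r1 - r0
    and b2 = r2 - r1, minimum-imaged if a cell is given.
    """
    b1 = np.asarray(r1, float) - np.asarray(r0, float)
    b2 = np.asarray(r2, float) - np.asarray(r1, float)
    if cell is not None:
        b1 = minimum_image(b1, cell)
        b2 = minimum_image(b2, cell)
    c = float(np.dot(b1, b2) / (np.linalg.norm(b1) * np.linalg.norm(b2)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


# --------------------------------------------------------------------------
# energetics
# --------------------------------------------------------------------------

def hard_overlap(positions: np.ndarray, i: int, j: int,
                 cell: SimulationCell) -> bool:
    """True iff non-bonded spheres i and j overlap (r_ij < sigma).

    Contact (r_ij = sigma) is allowed; a relative slack of
    ``OVERLAP_SLACK`` absorbs floating-point noise.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"sphere index out of range: {i}, {j} (Nat={n})")
    if i == j:
        raise ValueError("hard_overlap requires two distinct spheres")
    r = pair_distances(positions[i], positions[j], cell)
    return bool(r < SIGMA * (1.0 - OVERLAP_SLACK))


def bending_energy(theta: float | np.ndarray, params: ModelParams) -> float | np.ndarray:
    """Harmonic bending energy k_bend*(theta - theta0)**2 in kB*T."""
    return params.k_bend * (np.asarray(theta) - params.theta0) ** 2


# --------------------------------------------------------------------------
# packing-density bookkeeping
# --------------------------------------------------------------------------

def packing_density(n_atoms: int, cell: SimulationCell) -> float:
    """Volume fraction occupied by n_atoms unit spheres in the cell.

    For a cubic cell the general mixed-boundary expression
    (pi/6)*Nat / (dwall**dconf * L**(3-dconf)) reduces to
    (pi/6)*Nat / L**3 regardless of dconf.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return (np.pi / 6.0) * n_atoms * SIGMA ** 3 / (
        cell.dwall ** cell.dconf * cell.L ** (3 - cell.dconf))


def cell_size_for_density(n_atoms: int, phi: float, dconf: int = 0) -> float:
    """Cubic cell edge L that realizes packing density phi.

    Inverse of :func:`packing_density`; exact round-trip.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError(f"packing density must lie in (0, 1), got {phi}")
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return ((np.pi / 6.0) * n_atoms * SIGMA ** 3 / phi) ** (1.0 / 3.0)


def effective_packing_density(n_atoms: int, cell: SimulationCell) -> float:
    """Packing density relative to the wall-accessible volume.

    Equals phi * (L/(L - sigma))**dconf for cubic cells; phi at dconf=0.
    """
    if cell.dconf >= 1 and cell.L <= SIGMA:
        raise ValueError("cell edge must exceed sigma under confinement")
    return (np.pi / 6.0) * n_atoms * SIGMA ** 3 / (
        (cell.dwall - SIGMA) ** cell.dconf * cell.L ** (3 - cell.dconf))


def density_report(system: ChainSystem, cell: SimulationCell) -> DensityReport:
    return DensityReport(
        phi=packing_density(system.n_atoms, cell),
        phi_eff=effective_packing_density(system.n_atoms, cell),
        dwall=cell.dwall,
        n_atoms=system.n_atoms,
        dconf=cell.dconf,
    )


# --------------------------------------------------------------------------
# configuration validation
# --------------------------------------------------------------------------

def _bonded_pairs(system: ChainSystem) -> np.ndarray:
    """(Nb, 2) array of bonded index pairs (successive spheres)."""
    pairs = []
    for c in range(system.n_chains):
        s = system.chain_slice(c)
        idx = np.arange(s.start, s.stop)
        if len(idx) >= 2:
            pairs.append(np.column_stack([idx[:-1], idx[1:]]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(pairs, axis=0)


def validate(system: ChainSystem, cell: SimulationCell,
             params: ModelParams) -> list[Violation]:
    """Report-only legality check of a full configuration.

    Lists every non-bonded overlap, every bond outside
    ``[sigma, sigma + dl]``, every wall violation, and every chain length
    outside ``[n_min, n_max]``.  An empty report means a legal state.
    """
    from scipy.spatial import cKDTree

    out: list[Violation] = []
    pos = system.positions
    L = cell.L

    # chain-length window
    for c, n in enumerate(system.lengths):
        if not params.n_min <= n <= params.n_max:
            out.append(Violation("length", (c,), float(n)))

    # wall containment
    for ax in cell.wall_axes:
        lo = pos[:, ax] < SIGMA / 2 - 1e-12
        hi = pos[:, ax] > L - SIGMA / 2 + 1e-12
        for i in np.nonzero(lo | hi)[0]:
            out.append(Violation("wall", (int(i), ax), float(pos[i, ax])))

    # bonds
    bonds = _bonded_pairs(system)
    if len(bonds):
        bl = pair_distances(pos[bonds[:, 0]], pos[bonds[:, 1]], cell)
        bad = (bl < SIGMA * (1.0 - OVERLAP_SLACK)) | (bl > SIGMA + params.dl)
        for k in np.nonzero(bad)[0]:
            out.append(Violation("bond", tuple(int(x) for x in bonds[k]),
                                 float(bl[k])))

    # non-bonded overlaps: neighbour search with per-axis torus trick —
    # periodic axes use box size L, confined axes a fictitious 2L (their
    # real separations never exceed L, so no spurious wrapping occurs).
    if system.n_atoms >= 2:
        box = np.array([L if ax in cell.periodic_axes else 2.0 * L
                        for ax in range(3)])
        wrapped = np.mod(pos, box)
        tree = cKDTree(wrapped, boxsize=box)
        cand = tree.query_pairs(SIGMA * (1.0 - OVERLAP_SLACK),
                                output_type="ndarray")
        if len(cand):
            bonded = {tuple(sorted(p)) for p in bonds.tolist()}
            r = pair_distances(pos[cand[:, 0]], pos[cand[:, 1]], cell)
            for (i, j), rij in zip(cand.tolist(), r):
                if tuple(sorted((i, j))) in bonded:
                    continue
                out.append(Violation("overlap", (int(i), int(j)), float(rij)))
    return out
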