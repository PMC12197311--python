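"""System preparation, compression, confinement, and density scans.

The standard preparation workflow mirrors the simulation protocol of
the underlying model: chains are grown as self-avoiding tangent walks
at very dilute conditions (phi = 0.001), optionally thinned by
stratified chain deletion (which preserves the chain-length spectrum
and therefore the average length), confined by switching periodic
boundaries to hard walls, and then isotropically compressed in small
affine steps — with Monte Carlo relaxation whenever a step would create
a hard violation — until the target packing density is reached.  A
density scan walks a strictly increasing density grid, equilibrating
and sampling the nematic order parameter at every point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import MCState, run_sweeps
from .model import (
    SIGMA,
    ChainSystem,
    ModelParams,
    SimulationCell,
    cell_size_for_density,
    effective_packing_density,
    packing_density,
    validate,
)
from .order import nematic_order_of_system, unwrap_chain, wrap_positions
from .transition import TransitionCurve

__all__ = [
    "CompressionSchedule",
    "ScanPlan",
    "initialize_dilute",
    "delete_chains",
    "compress_to",
    "apply_confinement",
    "density_scan",
]


@dataclass(frozen=True)
class CompressionSchedule:
    """Stepwise isotropic compression parameters.

    Every step shrinks the cell edge by the factor ``shrink``; a step
    that would create any violation is reverted and retried after
    ``sweeps_on_reject`` MC sweeps.  ``jamming_guard`` refuses targets
    above the random-close-packing region of rod-like chains.
    """

    shrink: float = 0.999
    sweeps_on_reject: int = 10
    max_steps: int = 2_000_000
    jamming_guard: float = 0.60

    def __post_init__(self) -> None:
        if not 0.0 < self.shrink < 1.0:
            raise ValueError("shrink factor must lie in (0, 1)")
        if self.sweeps_on_reject < 0 or self.max_steps < 1:
            raise ValueError("invalid compression schedule")


@dataclass(frozen=True)
class ScanPlan:
    """Density grid plus sampling budget for one scan."""

    grid: tuple[float, ...]
    equil_sweeps: int = 200
    max_equil_sweeps: int = 800
    production_sweeps: int = 200
    snapshot_stride: int = 10
    stationarity_tol: float = 0.01

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if len(g) < 1 or np.any(np.diff(g) <= 0):
            raise ValueError("density grid must be non-empty and increasing")


# --------------------------------------------------------------------------
# dilute growth
# --------------------------------------------------------------------------

def _grow_chain(n: int, cell: SimulationCell, params: ModelParams,
                occupied: np.ndarray, rng: np.random.Generator,
                n_dir_trials: int = 20, max_restarts: int = 200
                ) -> np.ndarray:
    """Grow one self-avoiding tangent walk with bending-biased angles.

    Candidate growth directions are drawn uniformly and selected with
    probability proportional to their bending Boltzmann weight among
    the non-overlapping ones; the chain is regrown from scratch after a
    dead end.  The whole chain is kept inside [sigma/2, L - sigma/2]
    on every axis — connectivity is never broken by the periodic
    boundary, so hard walls can later be applied on any axis without
    moving a sphere.  Coordinates are returned unwrapped.
    """
    L = cell.L
    lo = np.full(3, SIGMA / 2)
    hi = np.full(3, L - SIGMA / 2)

    def clear(x: np.ndarray, extra: np.ndarray) -> bool:
        for ax in range(3):
            if not (SIGMA / 2 <= x[ax] <= L - SIGMA / 2):
                return False
        pool = occupied if not len(extra) else np.concatenate([occupied, extra])
        if not len(pool):
            return True
        d = pool - x
        for ax in cell.periodic_axes:
            d[:, ax] -= L * np.round(d[:, ax] / L)
        return bool((np.einsum("ij,ij->i", d, d)
                     >= SIGMA ** 2 * (1 - 1e-12)).all())

    for _ in range(max_restarts):
        first = lo + rng.random(3) * (hi - lo)
        if not clear(first, np.empty((0, 3))):
            continue
        coords = [first]
        failed = False
        for k in range(1, n):
            dirs = rng.normal(size=(n_dir_trials, 3))
            dirs /= np.linalg.norm(dirs, axis=1)[:, None]
            blen = SIGMA + params.dl * rng.random(n_dir_trials)
            cand = coords[-1] + dirs * blen[:, None]
            w = np.zeros(n_dir_trials)
            grown = np.array(coords)
            for t in range(n_dir_trials):
                xw = wrap_positions(cand[t][None, :], cell)[0]
                # exclude the bonded predecessor from the overlap test
                if not clear(xw, grown[:-1]):
                    continue
                u = 0.0
                if k >= 2:
                    b1 = coords[-1] - coords[-2]
                    b2 = cand[t] - coords[-1]
                    cth = float(np.dot(b1, b2)
                                / (np.linalg.norm(b1) * np.linalg.norm(b2)))
                    theta = math.acos(max(-1.0, min(1.0, cth)))
                    u = params.k_bend * (theta - params.theta0) ** 2
                w[t] = math.exp(-u)
            if w.sum() <= 0:
                failed = True
                break
            coords.append(cand[int(rng.choice(n_dir_trials, p=w / w.sum()))])
        if not failed:
            return np.array(coords)
    raise RuntimeError(f"failed to grow a {n}-mer after {max_restarts} restarts")


def _draw_lengths(n_chains: int, params: ModelParams, total: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Near-uniform chain lengths conditioned on an exact total.

    Starts from an unconstrained uniform draw, repairs the sum with
    random +/-1 adjustments, then randomizes with symmetric pair
    transfers inside the window (a random walk whose stationary law is
    uniform on the constrained composition set).
    """
    lo, hi = params.n_min, params.n_max
    if not n_chains * lo <= total <= n_chains * hi:
        raise ValueError(f"total {total} unreachable with window [{lo},{hi}]")
    lengths = rng.integers(lo, hi + 1, size=n_chains)
    diff = total - int(lengths.sum())
    while diff != 0:
        i = int(rng.integers(n_chains))
        if diff > 0 and lengths[i] < hi:
            lengths[i] += 1
            diff -= 1
        elif diff < 0 and lengths[i] > lo:
            lengths[i] -= 1
            diff += 1
    for _ in range(20 * n_chains):
        i, j = rng.integers(n_chains, size=2)
        if i != j and lengths[i] < hi and lengths[j] > lo:
            lengths[i] += 1
            lengths[j] -= 1
    return lengths


def initialize_dilute(n_chains: int, params: ModelParams,
                      phi0: float = 0.001, dconf: int = 0,
                      seed: int = 0, total_atoms: int | None = None
                      ) -> tuple[ChainSystem, SimulationCell]:
    """Legal dilute configuration with uniformly distributed chain lengths.

    Chain lengths are uniform over [n_min, n_max] conditioned on the
    exact total sphere count ``Nat = Nch * Nav`` (with Nav the window
    midpoint) unless ``total_atoms`` overrides it; the cell is sized so
    the packing density is exactly phi0.  Chains are grown unwrapped
    (connectivity never broken by the periodic boundary) and wrapped
    for storage.
    """
    if phi0 > 0.01:
        raise ValueError("dilute initialization requires phi0 <= 0.01")
    rng = np.random.default_rng(seed)
    n_atoms = (int(total_atoms) if total_atoms is not None
               else round(n_chains * (params.n_min + params.n_max) / 2))
    lengths = _draw_lengths(n_chains, params, n_atoms, rng)
    L = cell_size_for_density(n_atoms, phi0, dconf)
    cell = SimulationCell(L=L, dconf=dconf)
    occupied = np.empty((0, 3))
    chains = []
    for n in lengths:
        coords = _grow_chain(int(n), cell, params, occupied, rng)
        wrapped = wrap_positions(coords, cell)
        chains.append(wrapped)
        occupied = np.concatenate([occupied, wrapped], axis=0)
    system = ChainSystem.from_chains(chains)
    return system, cell


# --------------------------------------------------------------------------
# chain deletion
# --------------------------------------------------------------------------

def delete_chains(system: ChainSystem, x: float,
                  seed: int = 0) -> ChainSystem:
    """Randomly remove chains, stratified by length class.

    Keeps x*Nch chains (x*Nch must be integral), the cell untouched, and
    the surviving chains' coordinates unchanged.  Removal is random but
    stratified by chain length so the length spectrum — and with it the
    average chain length — is preserved as closely as integer counts
    allow.
    """
    if not 0.0 < x <= 1.0:
        raise ValueError("deletion fraction x must lie in (0, 1]")
    n_keep_f = x * system.n_chains
    n_keep = round(n_keep_f)
    if abs(n_keep_f - n_keep) > 1e-9:
        raise ValueError(f"x*Nch = {n_keep_f} is not integral")
    if x == 1.0:
        return system.copy()
    rng = np.random.default_rng(seed)
    lengths = system.lengths
    classes = {}
    for c, n in enumerate(lengths):
        classes.setdefault(int(n), []).append(c)

    # largest-remainder apportionment of the survivor count per class
    quotas = {n: x * len(idx) for n, idx in classes.items()}
    keep_per_class = {n: int(math.floor(qv)) for n, qv in quotas.items()}
    deficit = n_keep - sum(keep_per_class.values())
    remainders = sorted(classes, key=lambda n: quotas[n] - keep_per_class[n],
                        reverse=True)
    for n in remainders[:deficit]:
        keep_per_class[n] += 1

    survivors: list[int] = []
    for n, idx in classes.items():
        chosen = rng.choice(len(idx), size=keep_per_class[n], replace=False)
        survivors.extend(idx[i] for i in chosen)
    survivors.sort()
    return ChainSystem.from_chains(
        [system.chain_coords(c).copy() for c in survivors])


# --------------------------------------------------------------------------
# compression
# --------------------------------------------------------------------------

def _rescale(state: MCState, L_new: float) -> np.ndarray:
    """Rigid-chain rescale for a cell edge change (walls move too).

    Chain centres of mass follow the compression map while each chain's
    internal conformation is kept rigid — a plain affine map of sphere
    coordinates would shrink the tangent bonds below contact.  On
    periodic axes the centre scales affinely; on confined axes it is
    mapped through the wall-accessible slab [sigma/2, L - sigma/2], so
    a chain centred anywhere in the accessible region stays in the
    correspondingly rescaled region.  Chains are unwrapped for the
    shift and re-wrapped in the new cell.
    """
    old_cell = state.cell
    new_cell = old_cell.with_edge(L_new)
    L = old_cell.L
    s = L_new / L
    s_wall = (L_new - SIGMA) / (L - SIGMA)
    out = state.pos.copy()
    for idx in state.chains:
        ai = np.asarray(idx, dtype=np.int64)
        uw = unwrap_chain(state.pos[ai], old_cell)
        com = uw.mean(axis=0)
        shift = np.empty(3)
        for ax in range(3):
            if ax in old_cell.wall_axes:
                new_com = SIGMA / 2 + (com[ax] - SIGMA / 2) * s_wall
            else:
                new_com = com[ax] * s
            shift[ax] = new_com - com[ax]
        out[ai] = wrap_positions(uw + shift, new_cell)
    return out


def _step_legal(state: MCState, pos_new: np.ndarray, L_new: float) -> bool:
    trial = ChainSystem(pos_new,
                        np.concatenate([[0], np.cumsum(
                            [len(c) for c in state.chains])]))
    # reorder into contiguous layout for validation
    order = np.concatenate([np.asarray(c) for c in state.chains])
    trial = ChainSystem(pos_new[order], trial.starts)
    return not validate(trial, state.cell.with_edge(L_new), state.params)


def compress_to(state: MCState, target_phi: float,
                schedule: CompressionSchedule | None = None) -> MCState:
    """Isotropic stepwise compression to the target packing density.

    The cell edge is reduced by the schedule's shrink factor with affine
    rescaling of all coordinates (hard walls move with the cell); any
    step that would create a violation is reverted and retried after MC
    relaxation sweeps.  The final step lands exactly on the target
    (|phi - target| <= 1e-6).  Aborts with the last legal state attached
    to the raised error if the step budget is exhausted.
    """
    schedule = schedule or CompressionSchedule()
    phi_now = state.phi
    if target_phi > schedule.jamming_guard:
        raise ValueError(
            f"target phi {target_phi} above jamming guard "
            f"{schedule.jamming_guard}")
    if target_phi < phi_now - 1e-12:
        raise ValueError("compression target below current density")
    L_target = cell_size_for_density(state.n_atoms, target_phi,
                                     state.cell.dconf)
    steps = 0
    # adaptive step: grow the shrink amount while steps keep succeeding
    # (dilute systems tolerate large strides), reset to the schedule's
    # fine step after any rejection
    shrink = schedule.shrink
    while state.cell.L > L_target * (1 + 1e-12):
        L_new = max(state.cell.L * shrink, L_target)
        pos_new = _rescale(state, L_new)
        if _step_legal(state, pos_new, L_new):
            state.set_positions(pos_new)
            state.cell = state.cell.with_edge(L_new)
            shrink = max(shrink ** 1.5, 0.97)
        else:
            shrink = schedule.shrink
            run_sweeps(state, schedule.sweeps_on_reject)
        steps += 1
        if steps > schedule.max_steps:
            raise RuntimeError(
                f"compression stalled at phi={state.phi:.4f} "
                f"(target {target_phi}) after {steps} steps")
    return state


# --------------------------------------------------------------------------
# confinement
# --------------------------------------------------------------------------

def apply_confinement(system: ChainSystem, cell: SimulationCell,
                      dconf: int, params: ModelParams
                      ) -> tuple[ChainSystem, SimulationCell]:
    """Switch periodic boundaries to hard walls on the last dconf axes.

    Chains crossing the former periodic boundary along a newly confined
    axis are unwrapped first; the system is then rigidly translated to
    fit between the walls.  Raises if the configuration cannot fit
    without violation at the current density.
    """
    if not 0 <= dconf <= 3:
        raise ValueError("dconf must be in 0..3")
    new_cell = cell.with_dconf(dconf)
    if dconf == 0:
        return system.copy(), new_cell
    unwrapped = [unwrap_chain(system.chain_coords(c), cell)
                 for c in range(system.n_chains)]
    L = cell.L
    for ax in new_cell.wall_axes:
        # each chain covers an arc of the periodic circle along this
        # axis (padded by sigma/2 for the wall shell); the walls can be
        # inserted at any circle point left uncovered
        arcs = []
        for uw in unwrapped:
            lo, hi = uw[:, ax].min(), uw[:, ax].max()
            if hi - lo > L - SIGMA:
                raise ValueError(
                    f"cannot confine axis {ax}: a chain spans "
                    f"{hi - lo:.3f} of the {L:.3f} cell")
            arcs.append((float(np.mod(lo - SIGMA / 2, L)),
                         float(hi - lo + SIGMA)))
        cut = None
        for start, width in arcs:
            candidate = (start + width) % L  # just past this arc
            if all((candidate - s) % L >= w for s, w in arcs):
                cut = candidate
                break
        if cut is None:
            raise ValueError(
                f"cannot confine axis {ax}: no wall position free of "
                f"chains at the current density")
        # re-anchor every chain rigidly in the cut frame: its lower end
        # maps to (lo - cut) mod L, which the free cut guarantees to
        # leave the whole chain inside [sigma/2, L - sigma/2]
        for uw in unwrapped:
            lo = uw[:, ax].min()
            uw[:, ax] += np.mod(lo - cut, L) - lo
    wrapped = [wrap_positions(uw, new_cell) for uw in unwrapped]
    out = ChainSystem.from_chains(wrapped)
    report = validate(out, new_cell, params)
    if report:
        raise ValueError(f"confinement produced violations: {report[:5]}")
    return out, new_cell


# --------------------------------------------------------------------------
# density scan
# --------------------------------------------------------------------------

def _equilibrate(state: MCState, plan: ScanPlan) -> None:
    """Fixed minimum sweeps plus stationarity of q across 3 blocks."""
    run_sweeps(state, plan.equil_sweeps)
    block = max(plan.equil_sweeps // 4, 10)
    means: list[float] = []
    extra = 0
    while extra < plan.max_equil_sweeps - plan.equil_sweeps:
        qs = []
        for _ in range(block):
            state.sweep()
            qs.append(nematic_order_of_system(state.system(), state.cell).q)
        means.append(float(np.mean(qs)))
        extra += block
        if len(means) >= 3 and (max(means[-3:]) - min(means[-3:])
                                < plan.stationarity_tol):
            return


def density_scan(state: MCState, plan: ScanPlan,
                 schedule: CompressionSchedule | None = None,
                 on_point=None) -> TransitionCurve:
    """Compress along the density grid, sampling q at every point.

    At each grid density the state is compressed (progressively, from
    the previous point), equilibrated, and sampled every
    ``snapshot_stride`` production sweeps; the curve reports the mean
    and standard error of the per-snapshot q.  Scans of confined
    systems report the effective packing density.  A failed compression
    marks the point as missing and the scan continues.  ``on_point``
    (density, q samples, state) is invoked after each point, e.g. to
    persist snapshots.
    """
    dens, qm, qe = [], [], []
    confined = state.cell.dconf >= 1
    for phi in plan.grid:
        try:
            compress_to(state, phi, schedule)
        except RuntimeError:
            continue
        _equilibrate(state, plan)
        qs = []
        n_prod = max(plan.production_sweeps // plan.snapshot_stride, 0)
        for _ in range(n_prod):
            run_sweeps(state, plan.snapshot_stride)
            qs.append(nematic_order_of_system(state.system(), state.cell).q)
        d = (effective_packing_density(state.n_atoms, state.cell) if confined
             else packing_density(state.n_atoms, state.cell))
        dens.append(d)
        if qs:
            qm.append(float(np.mean(qs)))
            qe.append(float(np.std(qs, ddof=1) / np.sqrt(len(qs)))
                      if len(qs) > 1 else float("nan"))
        else:
            qm.append(float(nematic_order_of_system(state.system(),
                                                    state.cell).q))
            qe.append(float("nan"))
        if on_point is not None:
            on_point(d, qs, state)
    return TransitionCurve(np.array(dens), np.array(qm), np.array(qe),
                           "phi_eff" if confined else "phi")
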