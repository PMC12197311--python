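"""Metropolis Monte Carlo engine for tangent hard-sphere chains.

The engine works in a semigrand ensemble: the number of chains ``Nch``
and the number of spheres ``Nat`` are strictly conserved, while
individual chain lengths fluctuate inside the window
``[n_min, n_max]`` under a chemical-potential spectrum ``mu(N)``.

Move set
--------
Conventional moves (single- or few-bead displacements):

* ``reptation``        — delete one chain end, regrow at the other end;
* ``end_rotation``     — resample a terminal sphere about its anchor;
* ``flip``             — rotate an interior sphere about the axis through
  its two bonded neighbours (both adjacent bond lengths preserved);
* ``inter_reptation``  — transfer a terminal sphere from one chain end to
  the end of another chain (changes both lengths by one);
* ``end_group_rotation`` — rigid rotation of a terminal segment of m
  spheres (m uniform in 2..4) about the bond connecting it to the chain.

Chain-connectivity-altering moves (no sphere is displaced):

* ``seb``  — simplified end bridging: a chain end bonds to an interior
  monomer of another chain lying within the bond window
  ``[sigma, sigma + dl]``; the victim chain is severed there and the
  freed tail joins the attacker;
* ``sieb`` — simplified intramolecular end bridging: same construction
  with attacker and victim the same chain, relocating the chain end.

Single-bead regrowth moves use an orientational configurational-bias
scheme: ``n_trial`` candidate positions are drawn on the bond shell
with orientations sampled directly from the bending Boltzmann
distribution (so the bending factor cancels between proposal and
target), one admissible candidate is selected uniformly, and the move
is accepted with the ratio of new to old Rosenbluth weights — here the
counts of hard-constraint-admissible trials.  With ``n_trial = 1`` and
no hard neighbours this accepts almost every move; at high packing
density a larger trial count recovers acceptance.  Hard-sphere
overlaps, wall violations, bonds outside the tolerance window and
chain lengths outside the length window all carry zero acceptance
probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    OVERLAP_SLACK,
    SIGMA,
    ChainSystem,
    ModelParams,
    SimulationCell,
    validate,
)

__all__ = [
    "MoveMix",
    "MoveStats",
    "Proposal",
    "MCState",
    "metropolis_accept",
    "run_sweeps",
    "default_n_trial",
]

CONVENTIONAL_MOVES = ("reptation", "end_rotation", "flip",
                      "inter_reptation", "end_group_rotation")
BRIDGING_MOVES = ("seb", "sieb")
ALL_MOVES = CONVENTIONAL_MOVES + BRIDGING_MOVES


def default_n_trial(phi: float) -> int:
    """Configurational-bias trial count schedule.

    A single trial suffices at low density; above phi = 0.1 the count
    grows with density (denser systems leave fewer open insertion
    directions) and is capped at 20.
    """
    if phi < 0.1:
        return 1
    return min(20, math.ceil(30.0 * phi))


@dataclass(frozen=True)
class MoveMix:
    """Attempt probabilities per move kind plus the trial-count schedule."""

    probabilities: dict[str, float] = field(default_factory=lambda: {
        "reptation": 0.16,
        "end_rotation": 0.16,
        "flip": 0.16,
        "inter_reptation": 0.16,
        "end_group_rotation": 0.16,
        "seb": 0.15,
        "sieb": 0.05,
    })

    def __post_init__(self) -> None:
        for kind, p in self.probabilities.items():
            if kind not in ALL_MOVES:
                raise ValueError(f"unknown move kind {kind!r}")
            if p < 0:
                raise ValueError("move probabilities must be non-negative")
        total = sum(self.probabilities.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"move probabilities must sum to 1, got {total}")

    @classmethod
    def single(cls, kind: str) -> "MoveMix":
        return cls({kind: 1.0})

    @classmethod
    def conventional_only(cls) -> "MoveMix":
        p = 1.0 / len(CONVENTIONAL_MOVES)
        return cls({k: p for k in CONVENTIONAL_MOVES})

    def kinds_and_weights(self) -> tuple[list[str], np.ndarray]:
        kinds = sorted(self.probabilities)
        w = np.array([self.probabilities[k] for k in kinds])
        return kinds, w


@dataclass
class MoveStats:
    attempted: dict[str, int] = field(default_factory=dict)
    accepted: dict[str, int] = field(default_factory=dict)

    def record(self, kind: str, accepted: bool) -> None:
        self.attempted[kind] = self.attempted.get(kind, 0) + 1
        if accepted:
            self.accepted[kind] = self.accepted.get(kind, 0) + 1

    def acceptance_rate(self, kind: str) -> float:
        att = self.attempted.get(kind, 0)
        return self.accepted.get(kind, 0) / att if att else float("nan")


@dataclass
class Proposal:
    """One attempted move, in the form consumed by :func:`metropolis_accept`.

    ``log_w_ratio`` carries the configurational-bias (Rosenbluth) weight
    ratio for biased regrowth moves; for those moves the bending-energy
    change of the regrown bead is already folded into the weights and
    ``d_ubend`` holds only the remainder.  ``log_sel_ratio`` is the
    forward/reverse selection-count ratio of bridging moves.  ``legal``
    is False for proposals that violate a hard constraint (acceptance
    probability exactly zero); ``null`` marks moves with no eligible
    geometry, counted as attempted-and-rejected.
    """

    kind: str
    legal: bool = True
    null: bool = False
    d_ubend: float = 0.0
    d_mu: float = 0.0
    log_w_ratio: float = 0.0
    log_sel_ratio: float = 0.0
    apply: object = None  # zero-argument callable mutating the state


def metropolis_accept(proposal: Proposal, params: ModelParams,
                      rng: np.random.Generator) -> bool:
    """Metropolis test: min(1, W_ratio * exp(-dU + d_mu) * sel_ratio)."""
    if proposal.null or not proposal.legal:
        return False
    log_p = (proposal.log_w_ratio + proposal.log_sel_ratio
             - proposal.d_ubend + proposal.d_mu)
    if log_p >= 0:
        return True
    return bool(rng.random() < math.exp(log_p))


# ==========================================================================
# engine state
# ==========================================================================

class MCState:
    """Mutable simulation state: coordinates, connectivity, cell, PRNG.

    Internally chains are index lists into a fixed coordinate array so
    connectivity-altering moves are pure list splices; a canonical
    contiguous :class:`ChainSystem` is materialized on demand.
    """

    def __init__(self, system: ChainSystem, cell: SimulationCell,
                 params: ModelParams, seed: int,
                 mix: MoveMix | None = None,
                 n_trial: int | None = None):
        self.pos = system.positions.copy()
        self.chains: list[list[int]] = [
            list(range(int(system.starts[c]), int(system.starts[c + 1])))
            for c in range(system.n_chains)
        ]
        # atom -> owning chain index, kept current by every apply()
        self.chain_of = np.repeat(np.arange(system.n_chains),
                                  system.lengths).astype(np.int64)
        self.cell = cell
        self.params = params
        self.seed = int(seed)
        self.rng = np.random.default_rng(int(seed))
        self.mix = mix if mix is not None else MoveMix()
        self._n_trial_override = n_trial
        self._bend_table: tuple[np.ndarray, np.ndarray] | None = None
        self.stats = MoveStats()

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.pos)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def phi(self) -> float:
        from .model import packing_density
        return packing_density(self.n_atoms, self.cell)

    @property
    def n_trial(self) -> int:
        if self._n_trial_override is not None:
            return self._n_trial_override
        return default_n_trial(self.phi)

    def system(self) -> ChainSystem:
        """Canonical contiguous snapshot of the current configuration."""
        return ChainSystem.from_chains(
            [self.pos[np.asarray(c, dtype=np.int64)] for c in self.chains])

    def set_positions(self, positions: np.ndarray) -> None:
        """Replace all coordinates (used by affine compression steps)."""
        self.pos = np.asarray(positions, dtype=float).copy()

    # -- geometry helpers --------------------------------------------------
    # inner-loop helpers use scalar math on purpose: per-call numpy
    # overhead on 3-vectors dominates the move cost otherwise

    def _wrap_point(self, x: np.ndarray) -> np.ndarray:
        L = self.cell.L
        out = np.array(x, dtype=float, copy=True)
        for ax in self.cell.periodic_axes:
            out[ax] = out[ax] % L
        return out

    def _in_walls(self, x: np.ndarray) -> bool:
        lim = self.cell.L - SIGMA / 2
        for ax in self.cell.wall_axes:
            if not SIGMA / 2 <= x[ax] <= lim:
                return False
        return True

    def _min_image3(self, dx: float, dy: float, dz: float
                    ) -> tuple[float, float, float]:
        L = self.cell.L
        n_per = 3 - self.cell.dconf
        if n_per >= 1:
            dx -= L * math.floor(dx / L + 0.5)
        if n_per >= 2:
            dy -= L * math.floor(dy / L + 0.5)
        if n_per >= 3:
            dz -= L * math.floor(dz / L + 0.5)
        return dx, dy, dz

    def _dist2_to_all(self, x: np.ndarray) -> np.ndarray:
        d = self.pos - x
        L = self.cell.L
        nper = 3 - self.cell.dconf  # periodic axes are the leading block
        if nper:
            dp = d[:, :nper]
            np.subtract(dp, L * np.round(dp / L), out=dp)
        return np.einsum("ij,ij->i", d, d)

    def _free_of_overlap(self, x: np.ndarray, exclude: list[int]) -> bool:
        """True iff a sphere at x overlaps no sphere outside `exclude`."""
        if not self._in_walls(x):
            return False
        d2 = self._dist2_to_all(x)
        if exclude:
            d2[exclude] = np.inf
        return bool(d2.min(initial=np.inf) >= (SIGMA * (1 - OVERLAP_SLACK)) ** 2)

    def _angle(self, i: int, j: int, k: int) -> float:
        """Bending angle at sphere j of the bonded triplet i-j-k."""
        return self._angle_pos(self.pos[i], self.pos[j], self.pos[k])

    def _angle_pos(self, a, b, c) -> float:
        ux, uy, uz = self._min_image3(b[0] - a[0], b[1] - a[1], b[2] - a[2])
        vx, vy, vz = self._min_image3(c[0] - b[0], c[1] - b[1], c[2] - b[2])
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        cosv = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        return math.acos(min(1.0, max(-1.0, cosv)))

    def _bend(self, theta: float) -> float:
        p = self.params
        return p.k_bend * (theta - p.theta0) ** 2

    def _angle_energy_pos(self, a, b, c) -> float:
        return self._bend(self._angle_pos(a, b, c))

    def _random_directions(self, n: int) -> np.ndarray:
        v = self.rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1)[:, None]

    def _bond_lengths(self, n: int) -> np.ndarray:
        return SIGMA + self.params.dl * self.rng.random(n)

    def _sample_bend_angles(self, n: int) -> np.ndarray:
        """Bond angles drawn from p(theta) ~ sin(theta)*exp(-U_bend).

        Inverse-CDF sampling from a cached table; the hard 1-3 cutoff
        is left to the overlap test.
        """
        if self._bend_table is None:
            grid = np.linspace(0.0, np.pi, 4096)
            p = self.params
            pdf = np.sin(grid) * np.exp(-p.k_bend * (grid - p.theta0) ** 2)
            cdf = np.cumsum(pdf)
            cdf /= cdf[-1]
            self._bend_table = (grid, cdf)
        grid, cdf = self._bend_table
        return np.interp(self.rng.random(n), cdf, grid)

    def _biased_directions(self, u_prev: np.ndarray | None,
                           n: int) -> np.ndarray:
        """Trial growth directions, bending-Boltzmann biased about u_prev.

        With no predecessor bond the distribution is uniform on the
        sphere (no bending energy is at stake).
        """
        if u_prev is None:
            return self._random_directions(n)
        theta = self._sample_bend_angles(n)
        phi = self.rng.uniform(0.0, 2.0 * np.pi, size=n)
        ux, uy, uz = float(u_prev[0]), float(u_prev[1]), float(u_prev[2])
        if abs(ux) < 0.9:  # e1 = normalize(u x xhat), e2 = u x e1
            e1 = np.array([0.0, uz, -uy])
        else:
            e1 = np.array([-uz, 0.0, ux])
        e1 /= math.sqrt(e1 @ e1)
        e2 = np.array([uy * e1[2] - uz * e1[1],
                       uz * e1[0] - ux * e1[2],
                       ux * e1[1] - uy * e1[0]])
        st = np.sin(theta)
        return (np.cos(theta)[:, None] * u_prev
                + (st * np.cos(phi))[:, None] * e1
                + (st * np.sin(phi))[:, None] * e2)

    # ======================================================================
    # single-bead configurational-bias machinery
    # ======================================================================

    def _rosenbluth(self, anchor: int, prev: int | None,
                    exclude: list[int], n_trial: int,
                    actual: np.ndarray | None = None
                    ) -> tuple[float, np.ndarray | None]:
        """Hard-constraint Rosenbluth weight for one bead off `anchor`.

        Generates ``n_trial`` candidate positions on the bond shell
        around ``anchor``, with orientations drawn from the bending
        Boltzmann distribution about the preceding bond (so the bending
        factor cancels between proposal and target and the trial weight
        is the 0/1 hard-constraint indicator).  One candidate is
        replaced by ``actual`` when computing a reverse weight.  Returns
        the number of admissible trials and the selected position
        (uniform among admissible; None for reverse weights).
        """
        a = self.pos[anchor]
        L = self.cell.L
        u_prev = None
        if prev is not None:
            u_prev = np.array(self._min_image3(*(a - self.pos[prev])))
            u_prev /= math.sqrt(u_prev @ u_prev)
        dirs = self._biased_directions(u_prev, n_trial)
        trials = a + dirs * self._bond_lengths(n_trial)[:, None]
        if actual is not None:
            trials[0] = actual
        nper = 3 - self.cell.dconf
        if nper:
            trials[:, :nper] %= L

        if nper < 3:
            tw = trials[:, nper:]
            ok = ((tw >= SIGMA / 2) & (tw <= L - SIGMA / 2)).all(axis=1)
        else:
            ok = np.ones(n_trial, dtype=bool)
        if n_trial == 1:
            if ok[0]:
                d2 = self._dist2_to_all(trials[0])[None, :]
            else:
                d2 = np.full((1, len(self.pos)), np.inf)
        else:
            d = self.pos[None, :, :] - trials[:, None, :]
            if nper:
                dp = d[:, :, :nper]
                np.subtract(dp, L * np.round(dp / L), out=dp)
            d2 = np.einsum("ijk,ijk->ij", d, d)
        if exclude:
            d2[:, exclude] = np.inf
        ok &= d2.min(axis=1) >= (SIGMA * (1 - OVERLAP_SLACK)) ** 2

        W = float(ok.sum())
        if actual is not None or W <= 0.0:
            return W, None
        pick = int(self.rng.choice(np.nonzero(ok)[0]))
        return W, trials[pick]

    def _shuttle_bead(self, donor_chain: int, donor_end: int,
                      acceptor_chain: int, acceptor_end: int,
                      kind: str) -> Proposal:
        """Move a terminal bead from one chain end to a chain end.

        Shared machinery of reptation (same chain, opposite ends),
        end rotation (same chain, same end) and inter-reptation
        (different chains).  The shuttling bead is removed from the
        environment; new and old Rosenbluth weights are both evaluated
        in that same environment, which makes the scheme exactly
        balanced.
        """
        dch = self.chains[donor_chain]
        ach = self.chains[acceptor_chain]
        bead = dch[0] if donor_end == 0 else dch[-1]
        old_anchor = dch[1] if donor_end == 0 else dch[-2]
        old_prev = None
        if len(dch) >= 3:
            old_prev = dch[2] if donor_end == 0 else dch[-3]

        same = donor_chain == acceptor_chain
        if same and donor_end == acceptor_end:  # end rotation re-growth
            new_anchor, new_prev = old_anchor, old_prev
        else:
            if same:  # reptation: anchor is the opposite terminal
                a_idx = [i for i in dch if i != bead]
            else:
                a_idx = ach
            new_anchor = a_idx[0] if acceptor_end == 0 else a_idx[-1]
            new_prev = None
            if len(a_idx) >= 2:
                new_prev = a_idx[1] if acceptor_end == 0 else a_idx[-2]

        exclude = [bead, new_anchor]
        nt = self.n_trial
        old_pos = self.pos[bead].copy()
        w_new, x_new = self._rosenbluth(new_anchor, new_prev, exclude, nt)
        if w_new <= 0.0 or x_new is None:
            return Proposal(kind, legal=False)
        w_old, _ = self._rosenbluth(old_anchor, old_prev,
                                    [bead, old_anchor], nt, actual=old_pos)
        if w_old <= 0.0:
            return Proposal(kind, legal=False)

        d_mu = 0.0
        if not same:
            mu = self.params.mu_of
            n_d, n_a = len(dch), len(ach)
            d_mu = (mu(n_d - 1) + mu(n_a + 1)) - (mu(n_d) + mu(n_a))

        def apply() -> None:
            self.pos[bead] = x_new
            if same:
                dch.remove(bead)
                target = dch
            else:
                dch.pop(0 if donor_end == 0 else -1)
                target = ach
                self.chain_of[bead] = acceptor_chain
            if acceptor_end == 0:
                target.insert(0, bead)
            else:
                target.append(bead)

        return Proposal(kind, log_w_ratio=math.log(w_new / w_old),
                        d_mu=d_mu, apply=apply)

    # ======================================================================
    # conventional moves
    # ======================================================================

    def propose_local_move(self, kind: str) -> Proposal:
        if kind not in CONVENTIONAL_MOVES:
            raise ValueError(f"not a conventional move: {kind!r}")
        if not self.chains:
            raise ValueError("empty system")
        return getattr(self, f"_propose_{kind}")()

    def _propose_reptation(self) -> Proposal:
        c = int(self.rng.integers(self.n_chains))
        if len(self.chains[c]) < 3:
            return Proposal("reptation", null=True)
        end = int(self.rng.integers(2))
        return self._shuttle_bead(c, end, c, 1 - end, "reptation")

    def _propose_end_rotation(self) -> Proposal:
        c = int(self.rng.integers(self.n_chains))
        if len(self.chains[c]) < 2:
            return Proposal("end_rotation", null=True)
        end = int(self.rng.integers(2))
        return self._shuttle_bead(c, end, c, end, "end_rotation")

    def _propose_inter_reptation(self) -> Proposal:
        if self.n_chains < 2:
            return Proposal("inter_reptation", null=True)
        cd = int(self.rng.integers(self.n_chains))
        ca = int(self.rng.integers(self.n_chains - 1))
        if ca >= cd:
            ca += 1
        p = self.params
        if len(self.chains[cd]) - 1 < p.n_min or len(self.chains[ca]) + 1 > p.n_max:
            return Proposal("inter_reptation", null=True)
        end_d = int(self.rng.integers(2))
        end_a = int(self.rng.integers(2))
        return self._shuttle_bead(cd, end_d, ca, end_a, "inter_reptation")

    def _propose_flip(self) -> Proposal:
        c = int(self.rng.integers(self.n_chains))
        ch = self.chains[c]
        if len(ch) < 3:
            return Proposal("flip", null=True)
        k = int(self.rng.integers(1, len(ch) - 1))
        i, j, l = ch[k - 1], ch[k], ch[k + 1]
        pi, pj, pl = self.pos[i], self.pos[j], self.pos[l]
        axis = np.array(self._min_image3(pl[0] - pi[0], pl[1] - pi[1],
                                         pl[2] - pi[2]))
        norm = math.sqrt(axis @ axis)
        if norm < 1e-9:  # neighbours coincide: rotation undefined
            return Proposal("flip", null=True)
        axis = axis / norm
        angle = self.rng.uniform(0.0, 2.0 * np.pi)
        rel = np.array(self._min_image3(pj[0] - pi[0], pj[1] - pi[1],
                                        pj[2] - pi[2]))
        x_new = self._wrap_point(pi + _rotate(rel, axis, angle))

        if not self._free_of_overlap(x_new, [j, i, l]):
            return Proposal("flip", legal=False)

        # adjacent angles at the neighbours change; angle at j is preserved
        d_u = 0.0
        ch_arr = ch
        if k - 2 >= 0:
            h = ch_arr[k - 2]
            d_u += (self._angle_energy_pos(self.pos[h], self.pos[i], x_new)
                    - self._bend(self._angle(h, i, j)))
        if k + 2 < len(ch_arr):
            m = ch_arr[k + 2]
            d_u += (self._angle_energy_pos(x_new, self.pos[l], self.pos[m])
                    - self._bend(self._angle(j, l, m)))

        def apply() -> None:
            self.pos[j] = x_new

        return Proposal("flip", d_ubend=d_u, apply=apply)

    def _propose_end_group_rotation(self) -> Proposal:
        c = int(self.rng.integers(self.n_chains))
        ch = self.chains[c]
        m = int(self.rng.integers(2, 5))  # segment size, uniform in 2..4
        if len(ch) < m + 1:
            return Proposal("end_group_rotation", null=True)
        end = int(self.rng.integers(2))
        if end == 0:
            seg = ch[:m][::-1]  # seg[0] is the sphere bonded to the anchor
            anchor = ch[m]
        else:
            seg = ch[-m:]
            anchor = ch[-m - 1]
        pivot = seg[0]
        pp, pa = self.pos[pivot], self.pos[anchor]
        # the rotation axis is the single bond anchor-pivot (length ~1,
        # always well inside the minimum-image radius)
        axis = np.array(self._min_image3(pp[0] - pa[0], pp[1] - pa[1],
                                         pp[2] - pa[2]))
        axis = axis / math.sqrt(axis @ axis)
        angle = self.rng.uniform(0.0, 2.0 * np.pi)

        moved = seg[1:]
        origin = pp
        # offsets from the pivot accumulated bond by bond, so the
        # segment geometry is exact even when its extent nears L/2
        new_pos = np.empty((len(moved), 3))
        rel = np.zeros(3)
        prev = pivot
        for t, idx in enumerate(moved):
            pm, pv = self.pos[idx], self.pos[prev]
            step = self._min_image3(pm[0] - pv[0], pm[1] - pv[1],
                                    pm[2] - pv[2])
            rel = rel + np.array(step)
            new_pos[t] = self._wrap_point(origin + _rotate(rel, axis, angle))
            prev = idx

        # all intra-segment distances and distances to the rotation axis
        # (pivot, anchor) are preserved, so only moved-vs-rest overlaps
        # and walls can change; no bending angle changes either.
        exclude = list(seg) + [anchor]
        for t in range(len(moved)):
            if not self._free_of_overlap(new_pos[t], exclude):
                return Proposal("end_group_rotation", legal=False)
        # rigid rotation preserves intra-segment distances exactly, but
        # pairs of moved beads that are non-bonded (e.g. 1-3) were already
        # checked in the old state; nothing further needed.

        def apply() -> None:
            for t, idx in enumerate(moved):
                self.pos[idx] = new_pos[t]

        return Proposal("end_group_rotation", apply=apply)

    # ======================================================================
    # chain-connectivity-altering moves
    # ======================================================================

    def _bridge_candidates(self, terminal: int, chain_idx: int,
                           intra: bool) -> list[tuple[int, int, int]]:
        """Admissible (victim_chain, victim_pos, side) bridging targets.

        A victim is an interior monomer lying within the bond window of
        the attacking terminal.  ``side`` selects the severed bond:
        0 severs the bond before the victim (the attacker gains the
        victim-to-tail segment), 1 severs the bond after it (the
        attacker gains the head-to-victim segment, reversed).  Only
        combinations keeping both resulting lengths inside
        [n_min, n_max] are admissible; intramolecular bridging conserves
        the length and needs no window check.
        """
        p = self.params
        lo2 = (SIGMA * (1 - OVERLAP_SLACK)) ** 2
        hi2 = (SIGMA + p.dl) ** 2
        d2 = self._dist2_to_all(self.pos[terminal])
        near = np.nonzero((d2 >= lo2) & (d2 <= hi2))[0]
        if not len(near):
            return []
        out: list[tuple[int, int, int]] = []
        att_len = len(self.chains[chain_idx])
        for a in near:
            a = int(a)
            vc = int(self.chain_of[a])
            if intra != (vc == chain_idx):
                continue
            ch = self.chains[vc]
            n = len(ch)
            k = ch.index(a)
            if k == 0 or k == n - 1:  # interior monomers only
                continue
            if intra:
                # the victim must not be bonded to the terminal and the
                # severed bond lies inside the ring the new bond closes:
                # head attack severs the bond before the victim (side 0),
                # tail attack the bond after it (side 1)
                term_pos = 0 if ch[0] == terminal else n - 1
                if term_pos == 0 and k >= 2:
                    out.append((vc, k, 0))
                elif term_pos == n - 1 and k <= n - 3:
                    out.append((vc, k, 1))
            else:
                # side 0: attacker gains ch[k:], victim keeps ch[:k]
                if (p.n_min <= att_len + (n - k) <= p.n_max
                        and p.n_min <= k <= p.n_max):
                    out.append((vc, k, 0))
                # side 1: attacker gains ch[:k+1] reversed
                if (p.n_min <= att_len + (k + 1) <= p.n_max
                        and p.n_min <= n - k - 1 <= p.n_max):
                    out.append((vc, k, 1))
        return out

    def _bridge_delta_u(self, attacker_tail: list[int], victim: list[int],
                        k: int, side: int, terminal: int,
                        term_neighbor: int) -> float:
        """Bending-energy change of a bridging reconnection.

        New bond: terminal-victim[k].  Severed bond: (victim[k-1],
        victim[k]) for side 0, (victim[k], victim[k+1]) for side 1.
        Only angles touching those two bonds change; no bead moves.
        """
        v = victim
        d_u = 0.0
        # angles gained at the terminal and at the victim monomer
        d_u += self._bend(self._angle(term_neighbor, terminal, v[k]))
        nxt = v[k + 1] if side == 0 else v[k - 1]
        d_u += self._bend(self._angle(terminal, v[k], nxt))
        # angles lost around the severed bond
        if side == 0:
            d_u -= self._bend(self._angle(v[k - 1], v[k], v[k + 1]))
            if k - 2 >= 0:
                d_u -= self._bend(self._angle(v[k - 2], v[k - 1], v[k]))
        else:
            d_u -= self._bend(self._angle(v[k - 1], v[k], v[k + 1]))
            if k + 2 < len(v):
                d_u -= self._bend(self._angle(v[k], v[k + 1], v[k + 2]))
        return d_u

    def propose_bridging_move(self, kind: str) -> Proposal:
        if kind not in BRIDGING_MOVES:
            raise ValueError(f"not a bridging move: {kind!r}")
        intra = kind == "sieb"
        if not intra and self.n_chains < 2:
            return Proposal(kind, null=True)
        c = int(self.rng.integers(self.n_chains))
        ch = self.chains[c]
        if intra and len(ch) < 4:
            return Proposal(kind, null=True)
        end = int(self.rng.integers(2))
        terminal = ch[0] if end == 0 else ch[-1]
        term_neighbor = ch[1] if end == 0 else ch[-2]

        cands = self._bridge_candidates(terminal, c, intra)
        if not cands:
            return Proposal(kind, null=True)
        n_fwd = len(cands)
        vc, k, side = cands[int(self.rng.integers(n_fwd))]
        victim = self.chains[vc]

        d_u = self._bridge_delta_u(ch, victim, k, side, terminal,
                                   term_neighbor)

        # build the new connectivity (pure list surgery, no coordinates)
        if intra:
            # the new bond terminal-ch[k] closes a ring; severing the ring
            # bond adjacent to ch[k] relocates the chain end and reverses
            # the intervening segment, conserving the chain length
            if end == 1:  # tail attack: sever (ch[k], ch[k+1])
                new_ch = ch[:k + 1] + ch[k + 1:][::-1]
            else:  # head attack: sever (ch[k-1], ch[k])
                new_ch = ch[:k][::-1] + ch[k:]
            d_mu = 0.0
        else:
            if side == 0:
                gained = victim[k:]
                remain = victim[:k]
            else:
                gained = victim[:k + 1][::-1]
                remain = victim[k + 1:]
            if end == 0:
                new_att = gained[::-1] + ch
            else:
                new_att = ch + gained
            mu = self.params.mu_of
            d_mu = (mu(len(new_att)) + mu(len(remain))
                    - mu(len(ch)) - mu(len(victim)))

        def _install() -> None:
            if intra:
                self.chains[c] = list(new_ch)
            else:
                self.chains[c] = list(new_att)
                self.chains[vc] = list(remain)
                self.chain_of[np.asarray(self.chains[c])] = c
                self.chain_of[np.asarray(self.chains[vc])] = vc

        # trial application to count reverse candidates in the new topology
        saved_chains = [list(x) for x in self.chains]
        saved_owner = self.chain_of.copy()
        _install()
        if intra:
            rev_terminal = new_ch[0] if end == 0 else new_ch[-1]
            rev = self._bridge_candidates(rev_terminal, c, True)
        else:
            # the freed end of the victim remainder is its tail for a
            # side-0 severing and its head for side 1
            rev_terminal = remain[-1] if side == 0 else remain[0]
            rev = self._bridge_candidates(rev_terminal, vc, False)
        n_rev = max(len(rev), 1)
        self.chains = saved_chains
        self.chain_of = saved_owner

        return Proposal(kind, d_ubend=d_u, d_mu=d_mu,
                        log_sel_ratio=math.log(n_fwd / n_rev),
                        apply=_install)

    # ======================================================================
    # driver
    # ======================================================================

    def attempt(self, kind: str) -> bool:
        if kind in CONVENTIONAL_MOVES:
            prop = self.propose_local_move(kind)
        else:
            prop = self.propose_bridging_move(kind)
        ok = metropolis_accept(prop, self.params, self.rng)
        if ok:
            prop.apply()
        self.stats.record(kind, ok)
        return ok

    def sweep(self) -> None:
        """One sweep = Nat attempted moves drawn from the move mix."""
        kinds, w = self.mix.kinds_and_weights()
        draws = self.rng.choice(len(kinds), size=self.n_atoms, p=w)
        for d in draws:
            self.attempt(kinds[int(d)])

    def validate(self) -> list:
        return validate(self.system(), self.cell, self.params)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about the unit vector axis."""
    c, s = math.cos(angle), math.sin(angle)
    vx, vy, vz = float(v[0]), float(v[1]), float(v[2])
    ax, ay, az = float(axis[0]), float(axis[1]), float(axis[2])
    dot = ax * vx + ay * vy + az * vz
    return np.array([
        vx * c + (ay * vz - az * vy) * s + ax * dot * (1.0 - c),
        vy * c + (az * vx - ax * vz) * s + ay * dot * (1.0 - c),
        vz * c + (ax * vy - ay * vx) * s + az * dot * (1.0 - c),
    ])


def run_sweeps(state: MCState, n_sweeps: int,
               validate_every: int = 0) -> MoveStats:
    """Run n_sweeps sweeps; optionally validate the state periodically.

    Identical seed and configuration reproduce the identical trajectory.
    A validation failure aborts with a diagnostic listing.
    """
    for s in range(n_sweeps):
        state.sweep()
        if validate_every and (s + 1) % validate_every == 0:
            report = state.validate()
            if report:
                raise RuntimeError(
                    f"illegal state after sweep {s + 1}: "
                    f"{report[:5]}{'...' if len(report) > 5 else ''}")
    return state.stats
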