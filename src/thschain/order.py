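"""Long-range orientational order of chain systems.

Each chain is reduced to a unit vector u along its long axis — the
eigenvector of the smallest eigenvalue of the chain's inertia tensor
(equivalently the largest-eigenvalue eigenvector of the gyration
tensor), computed from unwrapped, centred coordinates with unit monomer
masses.  The average orientation tensor

    Q = (1/Nch) * sum_i (u_i u_i^T - delta/3)

is symmetric and traceless.  Diagonalizing Q and sorting eigenvalues by
decreasing absolute value, the scalar nematic order parameter is
q = (3/2)*lambda_1 and the director n is the matching eigenvector:
q = 1 for the ideal prolate (fully aligned) phase, q = -0.5 for the
ideal oblate phase (axes uniform in a plane), q -> 0 for an isotropic
system (up to an O(Nch^-1/2) finite-sample bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ChainSystem, SimulationCell, minimum_image

__all__ = [
    "Q_PROLATE",
    "Q_OBLATE",
    "OrderResult",
    "unwrap_chain",
    "wrap_positions",
    "chain_long_axis",
    "chain_axes",
    "nematic_order",
    "nematic_order_of_system",
    "end_to_end",
]

#: reference Q tensor of the ideal prolate nematic phase (director x)
Q_PROLATE = np.diag([2.0 / 3.0, -1.0 / 3.0, -1.0 / 3.0])
#: reference Q tensor of the ideal oblate nematic phase (axes in xy)
Q_OBLATE = np.diag([1.0 / 6.0, 1.0 / 6.0, -1.0 / 3.0])


@dataclass(frozen=True)
class OrderResult:
    """Q tensor, its spectrum, the scalar order parameter and director."""

    Q: np.ndarray
    eigenvalues: np.ndarray  # sorted by decreasing |lambda|
    q: float
    director: np.ndarray

    def __post_init__(self) -> None:
        if abs(np.trace(self.Q)) > 1e-10:
            raise ValueError("Q tensor must be traceless")


# --------------------------------------------------------------------------
# unwrapping
# --------------------------------------------------------------------------

def unwrap_chain(coords: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Undo periodic wrapping along one chain.

    Walks the chain bond by bond, placing each sphere at the minimum
    image relative to its predecessor.  Raises if a reconstructed bond
    exceeds L/2 (inconsistent wrapping).
    """
    coords = np.asarray(coords, dtype=float)
    out = coords.copy()
    for k in range(1, len(out)):
        # bond vector recovered as the minimum image of the wrapped step
        step = minimum_image(coords[k] - coords[k - 1], cell)
        if np.linalg.norm(step) > cell.L / 2:
            raise ValueError(f"inconsistent wrap at bond {k - 1}-{k}")
        out[k] = out[k - 1] + step
    return out


def wrap_positions(coords: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Wrap coordinates to [0, L) on periodic axes; confined axes untouched."""
    out = np.array(coords, dtype=float, copy=True)
    for ax in cell.periodic_axes:
        out[:, ax] = np.mod(out[:, ax], cell.L)
    return out


# --------------------------------------------------------------------------
# chain axes
# --------------------------------------------------------------------------

def chain_long_axis(coords: np.ndarray) -> np.ndarray:
    """Unit vector along the long axis of one (unwrapped) chain.

    The inertia tensor I = sum_i (|x_i - x_cm|^2 delta - (x_i - x_cm)(x_i - x_cm)^T)
    is computed with unit masses and centred coordinates; the returned
    axis is the eigenvector of its smallest eigenvalue.  Sign
    convention: first non-zero component positive (physically n == -n).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("a chain axis needs at least two monomers")
    x = coords - coords.mean(axis=0)
    if not np.any(np.abs(x) > 1e-12):
        raise ValueError("degenerate chain: all monomers coincide")
    gyr = x.T @ x
    inertia = np.trace(gyr) * np.eye(3) - gyr
    w, v = np.linalg.eigh(inertia)
    u = v[:, np.argmin(w)]
    u = u / np.linalg.norm(u)
    nz = np.nonzero(np.abs(u) > 1e-12)[0]
    if len(nz) and u[nz[0]] < 0:
        u = -u
    return u


def chain_axes(system: ChainSystem, cell: SimulationCell) -> np.ndarray:
    """Long-axis unit vector of every chain, shape (Nch, 3)."""
    return np.array([
        chain_long_axis(unwrap_chain(system.chain_coords(c), cell))
        for c in range(system.n_chains)
    ])


# --------------------------------------------------------------------------
# Q tensor and scalar order parameter
# --------------------------------------------------------------------------

def nematic_order(axes: np.ndarray) -> OrderResult:
    """Q tensor, eigen-spectrum, scalar q and director from chain axes."""
    u = np.asarray(axes, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3 or len(u) < 1:
        raise ValueError("axes must have shape (Nch, 3) with Nch >= 1")
    Q = (u[:, :, None] * u[:, None, :]).mean(axis=0) - np.eye(3) / 3.0
    w, v = np.linalg.eigh(Q)
    order = np.argsort(-np.abs(w))
    w = w[order]
    v = v[:, order]
    q = 1.5 * float(w[0])
    n = v[:, 0] / np.linalg.norm(v[:, 0])
    nz = np.nonzero(np.abs(n) > 1e-12)[0]
    if len(nz) and n[nz[0]] < 0:
        n = -n
    return OrderResult(Q=Q, eigenvalues=w, q=q, director=n)


def nematic_order_of_system(system: ChainSystem,
                            cell: SimulationCell) -> OrderResult:
    return nematic_order(chain_axes(system, cell))


# --------------------------------------------------------------------------
# end-to-end statistics
# --------------------------------------------------------------------------

def end_to_end(system: ChainSystem, cell: SimulationCell,
               length_class: int | None = None) -> float:
    """Root-mean-square end-to-end distance sqrt(<Ree^2>).

    Restricted to chains of ``length_class`` spheres when given;
    raises ValueError if that class is empty.  Distances are between the
    centres of the two terminal spheres, in the unwrapped frame.
    """
    ree2 = []
    for c in range(system.n_chains):
        coords = system.chain_coords(c)
        if length_class is not None and len(coords) != length_class:
            continue
        if len(coords) < 2:
            continue
        uw = unwrap_chain(coords, cell)
        ree2.append(float(np.sum((uw[-1] - uw[0]) ** 2)))
    if not ree2:
        raise ValueError(f"no chains of length class {length_class}")
    return float(np.sqrt(np.mean(ree2)))
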