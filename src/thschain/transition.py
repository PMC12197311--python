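"""Locating the isotropic-to-nematic transition and the empirical laws.

The transition point ``phi_IN`` of a density scan is the lowest grid
density whose mean nematic order parameter reaches q >= 0.5.  Three
empirical laws describe how the transition moves with the control
parameters:

* chain length      phi_IN      = a + b*Nav + c*r**Nav
* chain stiffness   phi_IN      = a*exp(b*k_bend) + c
* confinement       phi_eff_IN  = a - b*c**dwall

Each law is fitted to (predictor, transition-density) points by
nonlinear least squares with bounded, jittered restarts; goodness of
fit is reported as R^2 = 1 - SS_res/SS_tot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MODELS",
    "TransitionCurve",
    "FitResult",
    "find_transition",
    "fit_model",
    "evaluate_model",
]


# --------------------------------------------------------------------------
# model definitions
# --------------------------------------------------------------------------

def _length_law(nav, a, b, c, r):
    # r**nav overflows for |r|>1 during fit exploration; clip the
    # exponent's magnitude rather than letting inf poison the solver
    with np.errstate(over="ignore"):
        decay = np.power(r, nav)
    return a + b * nav + c * np.clip(decay, -1e30, 1e30)


def _stiffness_law(k, a, b, c):
    return a * np.exp(b * k) + c


def _confinement_law(dwall, a, b, c):
    return a - b * np.power(c, dwall)


MODELS: dict[str, dict] = {
    "length": {"func": _length_law, "coeffs": ("a", "b", "c", "r")},
    "stiffness": {"func": _stiffness_law, "coeffs": ("a", "b", "c")},
    "confinement": {"func": _confinement_law, "coeffs": ("a", "b", "c")},
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TransitionCurve:
    """Ordered (density, mean q, standard error) samples from one scan."""

    density: np.ndarray
    q_mean: np.ndarray
    q_err: np.ndarray
    density_kind: str = "phi"  # "phi" (bulk) or "phi_eff" (confined)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.q_mean = np.asarray(self.q_mean, dtype=float)
        self.q_err = np.asarray(self.q_err, dtype=float)
        if not (len(self.density) == len(self.q_mean) == len(self.q_err)):
            raise ValueError("curve arrays must have equal length")
        if len(self.density) and np.any(np.diff(self.density) <= 0):
            raise ValueError("densities must be strictly increasing")
        if self.density_kind not in ("phi", "phi_eff"):
            raise ValueError("density_kind must be 'phi' or 'phi_eff'")

    def __len__(self) -> int:
        return len(self.density)


@dataclass
class FitResult:
    """Fitted coefficients of one empirical law plus fit diagnostics."""

    model_id: str
    coefficients: dict[str, float]
    r_squared: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __call__(self, x):
        return evaluate_model(self.model_id, self.coefficients, x)


# --------------------------------------------------------------------------
# transition location
# --------------------------------------------------------------------------

def find_transition(curve: TransitionCurve, threshold: float = 0.5,
                    interpolate: bool = False) -> float | None:
    """Lowest scan density whose mean q reaches the threshold.

    Returns None when the curve never reaches the threshold (no
    transition within the scanned range, e.g. very flexible chains).
    With ``interpolate=True`` the crossing is linearly interpolated
    between the bracketing grid points instead (never the default).
    """
    if len(curve) == 0:
        raise ValueError("empty transition curve")
    above = curve.q_mean >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if not interpolate or k == 0:
        return float(curve.density[k])
    x0, x1 = curve.density[k - 1], curve.density[k]
    y0, y1 = curve.q_mean[k - 1], curve.q_mean[k]
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _initial_guesses(model_id: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    span = float(y.max() - y.min()) or 0.1
    if model_id == "length":
        # log-linearized pre-fit of the decay constant
        return np.array([float(y.min()), 0.0, span, 0.9])
    if model_id == "stiffness":
        return np.array([span, -0.5, float(y.min())])
    return np.array([float(y.max()), span, 0.9])


def fit_model(points: np.ndarray, model_id: str,
              initial: np.ndarray | None = None,
              n_restarts: int = 10, seed: int = 0) -> FitResult:
    """Nonlinear least-squares fit of one empirical law.

    ``points`` is an (n, 2) array of (predictor, transition density);
    rows with a non-finite density (undefined transitions) are dropped.
    Deterministic given identical inputs and guesses.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    pts = np.asarray(points, dtype=float)
    pts = pts[np.isfinite(pts).all(axis=1)]
    names = MODELS[model_id]["coeffs"]
    func = MODELS[model_id]["func"]
    if len(pts) < len(names):
        raise ValueError(
            f"{model_id} law has {len(names)} coefficients but only "
            f"{len(pts)} usable points were given")
    x, y = pts[:, 0], pts[:, 1]

    guess = (np.asarray(initial, dtype=float) if initial is not None
             else _initial_guesses(model_id, x, y))
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    g = guess.copy()
    for attempt in range(max(1, n_restarts)):
        try:
            popt, _ = curve_fit(func, x, y, p0=g, maxfev=20000)
            ss_res = float(np.sum((y - func(x, *popt)) ** 2))
            if best is None or ss_res < best[0]:
                best = (ss_res, popt)
            if ss_res <= 1e-20 * max(1.0, float(np.sum(y ** 2))):
                break
        except RuntimeError:
            pass
        g = guess * (1.0 + 0.3 * rng.standard_normal(len(guess)))
    if best is None:
        return FitResult(model_id, dict(zip(names, guess)), float("nan"),
                         converged=False)
    ss_res, popt = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    resid = y - func(x, *popt)
    return FitResult(model_id, dict(zip(names, map(float, popt))),
                     float(r2), resid)


def evaluate_model(model_id: str, coefficients: dict[str, float] | FitResult,
                   predictor: float) -> float:
    """Closed-form evaluation of an empirical law.

    For the confinement law, the dwall -> infinity limit returns the
    additive constant a (the bulk transition density).
    """
    if isinstance(coefficients, FitResult):
        coefficients = coefficients.coefficients
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    names = MODELS[model_id]["coeffs"]
    args = [float(coefficients[n]) for n in names]
    if model_id == "confinement" and np.isinf(predictor):
        return args[0]
    return float(MODELS[model_id]["func"](float(predictor), *args))
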