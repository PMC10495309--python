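"""Dose-dependent relative biological effectiveness of the alpha emitter.

With a linear dose-effect for the investigated radiation, N = b_ac * D_ac,
and a linear-quadratic one for the reference, N = a_lu * D_lu^2 + b_lu *
D_lu, the isoeffect condition gives closed forms for the RBE as a function
of either dose axis:

    RBE(D_lu) = (b_ac / b_lu) / ((a_lu / b_lu) * D_lu + 1)
    RBE(D_ac) = 2 b_ac / (sqrt(b_lu^2 + 4 a_lu b_ac D_ac) + b_lu)

Both are monotonically non-increasing, share the zero-dose limit
b_ac / b_lu, and equal 1 at the crossover dose (b_ac - b_lu) / a_lu.
With a_lu = 0 (initial damage) the RBE is the dose-independent ratio
b_ac / b_lu.  Uncertainties are first-order delta-method propagation of
the fit-parameter sigmas, treated as independent unless a covariance is
supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RbeModel",
    "RbeCurve",
    "NoCrossoverError",
    "rbe_vs_dose_lu",
    "rbe_vs_dose_ac",
    "dose_conversion",
    "crossover_dose",
    "propagate_rbe_sigma",
    "rbe_curve",
]


class NoCrossoverError(ValueError):
    """Raised when a_lu = 0: the RBE is constant and never crosses 1."""


@dataclass(frozen=True)
class RbeModel:
    """Fitted dose-effect parameters of the two emitters for one condition.

    ``a_lu`` is zero for initial-damage models.  Uncertainties are 1-sigma.
    ``cov`` optionally carries the 3x3 covariance of (b_ac, b_lu, a_lu);
    when absent the parameters are treated as independent.
    """

    b_ac: float
    b_lu: float
    a_lu: float = 0.0
    b_ac_sd: float | None = None
    b_lu_sd: float | None = None
    a_lu_sd: float | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.b_ac <= 0 or self.b_lu <= 0:
            raise ValueError("b_ac and b_lu must be positive")
        if self.a_lu < 0:
            raise ValueError("a_lu must be non-negative")

    def _sigmas(self) -> tuple[float, float, float]:
        if None in (self.b_ac_sd, self.b_lu_sd) or (self.a_lu > 0 and self.a_lu_sd is None):
            raise ValueError("parameter uncertainties are required for propagation")
        return (self.b_ac_sd, self.b_lu_sd, self.a_lu_sd or 0.0)


@dataclass(frozen=True)
class RbeCurve:
    """RBE sampled on a dose grid along one dose axis."""

    axis: str  # "dose_lu" | "dose_ac"
    dose_gy: np.ndarray
    rbe: np.ndarray
    rbe_sigma: np.ndarray | None = None


def _check_dose(dose) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    return d


def rbe_vs_dose_lu(m: RbeModel, d_lu):
    """RBE as a function of the reference (Lu-177) absorbed dose."""
    d = _check_dose(d_lu)
    out = (m.b_ac / m.b_lu) / ((m.a_lu / m.b_lu) * d + 1.0)
    return float(out) if out.ndim == 0 else out


def rbe_vs_dose_ac(m: RbeModel, d_ac):
    """RBE as a function of the investigated (Ac-225) absorbed dose."""
    d = _check_dose(d_ac)
    q = np.sqrt(m.b_lu**2 + 4.0 * m.a_lu * m.b_ac * d)
    out = 2.0 * m.b_ac / (q + m.b_lu)
    return float(out) if out.ndim == 0 else out


def dose_conversion(m: RbeModel, dose, direction: str):
    """Isoeffect dose conversion between the two emitters.

    ``lu_to_ac``: D_ac = (a_lu/b_ac) D^2 + (b_lu/b_ac) D
    ``ac_to_lu``: D_lu = (sqrt(b_lu^2 + 4 a_lu b_ac D) - b_lu) / (2 a_lu),
    with the a_lu -> 0 limit D * b_ac / b_lu handled analytically.
    """
    d = _check_dose(dose)
    if direction == "lu_to_ac":
        out = (m.a_lu / m.b_ac) * d**2 + (m.b_lu / m.b_ac) * d
    elif direction == "ac_to_lu":
        if m.a_lu == 0:
            out = d * m.b_ac / m.b_lu
        else:
            out = (np.sqrt(m.b_lu**2 + 4.0 * m.a_lu * m.b_ac * d) - m.b_lu) / (2.0 * m.a_lu)
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    return float(out) if out.ndim == 0 else out


def _crossover_gradient(m: RbeModel) -> tuple[float, np.ndarray]:
    d = (m.b_ac - m.b_lu) / m.a_lu
    grad = np.array([1.0 / m.a_lu, -1.0 / m.a_lu, -d / m.a_lu])
    return d, grad


def crossover_dose(m: RbeModel, with_sigma: bool = True) -> tuple[float, float | None]:
    """Dose at which both RBE parametrizations equal 1, with delta-method sigma.

    Only defined for a_lu > 0 and b_ac > b_lu (otherwise the curves never
    reach 1 at a positive finite dose).
    """
    if m.a_lu == 0:
        raise NoCrossoverError("a_lu = 0: RBE is constant, no crossover dose")
    if m.b_ac < m.b_lu:
        raise ValueError("crossover requires b_ac >= b_lu")
    d, grad = _crossover_gradient(m)
    if not with_sigma:
        return d, None
    sig = _delta_sigma(m, grad)
    return d, sig


def _delta_sigma(m: RbeModel, grad: np.ndarray) -> float:
    if m.cov is not None:
        return float(math.sqrt(grad @ np.asarray(m.cov) @ grad))
    s_ac, s_lu, s_a = m._sigmas()
    return float(math.sqrt((grad[0] * s_ac) ** 2 + (grad[1] * s_lu) ** 2 + (grad[2] * s_a) ** 2))


def propagate_rbe_sigma(m: RbeModel, dose, axis: str):
    """First-order uncertainty of the RBE at the given dose(s).

    ``axis`` is ``dose_lu`` or ``dose_ac``.  At zero dose both reduce to
    (b_ac/b_lu) * sqrt((s_ac/b_ac)^2 + (s_lu/b_lu)^2).
    """
    d = _check_dose(dose)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if axis == "dose_lu":
        denom = m.a_lu * d + m.b_lu
        g_ac = 1.0 / denom
        g_lu = -m.b_ac / denom**2
        g_a = -m.b_ac * d / denom**2
    elif axis == "dose_ac":
        q = np.sqrt(m.b_lu**2 + 4.0 * m.a_lu * m.b_ac * d)
        s = q + m.b_lu
        g_ac = 2.0 / s - (2.0 * m.b_ac / s**2) * (2.0 * m.a_lu * d / q)
        g_lu = -2.0 * m.b_ac * (m.b_lu / q + 1.0) / s**2
        g_a = -4.0 * m.b_ac**2 * d / (q * s**2)
    else:
        raise ValueError(f"unknown axis: {axis!r}")
    if m.cov is not None:
        cov = np.asarray(m.cov)
        grads = np.stack([g_ac, g_lu, g_a], axis=-1)
        var = np.einsum("...i,ij,...j->...", grads, cov, grads)
    else:
        s_ac, s_lu, s_a = m._sigmas()
        var = (g_ac * s_ac) ** 2 + (g_lu * s_lu) ** 2 + (g_a * s_a) ** 2
    sig = np.sqrt(var)
    return float(sig[0]) if scalar else sig


def rbe_curve(
    m: RbeModel,
    axis: str = "dose_ac",
    dose_gy: np.ndarray | None = None,
    with_sigma: bool = True,
) -> RbeCurve:
    """Sample the RBE (and its uncertainty band) on a dose grid.

    The default grid is 0..50 Gy in 501 points, the range over which the
    post-repair parametrizations are reported clinically.
    """
    if dose_gy is None:
        dose_gy = np.linspace(0.0, 50.0, 501)
    d = _check_dose(dose_gy)
    fn = rbe_vs_dose_ac if axis == "dose_ac" else rbe_vs_dose_lu
    if axis not in ("dose_ac", "dose_lu"):
        raise ValueError(f"unknown axis: {axis!r}")
    values = np.atleast_1d(fn(m, d))
    sigma = None
    if with_sigma:
        sigma = np.atleast_1d(propagate_rbe_sigma(m, d, axis))
    return RbeCurve(axis=axis, dose_gy=d, rbe=values, rbe_sigma=sigma)
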