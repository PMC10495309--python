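"""Dose-effect curve fitting: N_DSB(D) through the origin.

High-LET damage (and low-LET initial damage) is fitted as N = b*D; low-LET
post-repair damage as N = a*D^2 + b*D.  There is no intercept because there
are no DSBs at zero dose.  Fits are unweighted least squares via
scipy.optimize.curve_fit; parameter uncertainties are 1-sigma values from
the estimator covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseEffectDataset",
    "DoseEffectFit",
    "FitError",
    "fit_dose_effect",
    "select_model",
]

Model = Literal["linear", "linear_quadratic"]
Stage = Literal["initial", "post_repair"]


class FitError(ValueError):
    """Raised for degenerate dose-effect designs."""


@dataclass(frozen=True)
class DoseEffectDataset:
    """Dose-effect points for one (nuclide, geometry, arrangement, internalization, stage)."""

    dose_gy: np.ndarray
    n_dsb: np.ndarray
    sd: np.ndarray | None = None
    radionuclide: str | None = None
    geometry: int | None = None
    arrangement: str | None = None
    internalization: str | None = None
    stage: Stage | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_gy, dtype=float)
        y = np.asarray(self.n_dsb, dtype=float)
        if d.shape != y.shape or d.ndim != 1:
            raise ValueError("dose and effect arrays must be 1-D and equally long")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "n_dsb", y)

    def __len__(self) -> int:
        return self.dose_gy.size


@dataclass(frozen=True)
class DoseEffectFit:
    """Fitted zero-intercept dose-effect parameters with 1-sigma uncertainties."""

    model: Model
    b: float  # DSB / Gy
    b_sd: float
    a: float = 0.0  # DSB / Gy^2 (linear_quadratic only)
    a_sd: float = 0.0
    cov: np.ndarray | None = None  # covariance of (a, b) or (b,)
    r_squared: float = float("nan")


def select_model(radionuclide: str, stage: Stage) -> Model:
    """Model choice per emitter and damage stage.

    High-LET damage is linear at both stages; low-LET damage is linear
    initially and develops upward curvature after repair.
    """
    key = (radionuclide, stage)
    table: dict[tuple[str, str], Model] = {
        ("Ac225", "initial"): "linear",
        ("Ac225", "post_repair"): "linear",
        ("Lu177", "initial"): "linear",
        ("Lu177", "post_repair"): "linear_quadratic",
    }
    if key not in table:
        raise ValueError(f"unknown (radionuclide, stage) combination: {key}")
    return table[key]


def fit_dose_effect(
    data: DoseEffectDataset,
    model: Model,
    nonneg_a: bool = True,
) -> DoseEffectFit:
    """Unweighted least-squares fit of N_DSB(D) through the origin.

    ``nonneg_a`` bounds the quadratic coefficient below by zero, which
    stabilises near-linear post-repair data without changing its structure
    (can be disabled).  R^2 uses the total sum of squares about the data
    mean; for zero-intercept models this is one of several conventions and
    is reported for comparability only.
    """
    d = data.dose_gy
    y = data.n_dsb
    if len(data) < 3:
        raise FitError("at least 3 points are required to fit")
    if np.ptp(d) == 0:
        raise FitError("degenerate design: all doses equal")
    if model == "linear":
        popt, pcov = curve_fit(
            lambda x, b: b * x, d, y, p0=[max(np.sum(d * y) / np.sum(d * d), 1e-12)],
            bounds=(0.0, np.inf),
        )
        b = float(popt[0])
        a, a_sd = 0.0, 0.0
        b_sd = float(np.sqrt(pcov[0, 0]))
        pred = b * d
    elif model == "linear_quadratic":
        lower = [0.0, 0.0] if nonneg_a else [-np.inf, 0.0]
        popt, pcov = curve_fit(
            lambda x, a, b: a * x * x + b * x,
            d,
            y,
            p0=[max(0.0, 1e-6) if nonneg_a else 0.0, max(np.sum(d * y) / np.sum(d * d), 1e-12)],
            bounds=(lower, [np.inf, np.inf]),
        )
        a, b = (float(v) for v in popt)
        a_sd = float(np.sqrt(pcov[0, 0]))
        b_sd = float(np.sqrt(pcov[1, 1]))
        pred = a * d * d + b * d
    else:
        raise ValueError(f"unknown model: {model!r}")
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DoseEffectFit(model=model, b=b, b_sd=b_sd, a=a, a_sd=a_sd, cov=pcov, r_squared=r2)
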