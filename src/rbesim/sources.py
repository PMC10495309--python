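"""Source planning: from clinical activity data to per-cell decay counts.

The number of decays a cell contributes over the (long) course of therapy is
taken as the number of radionuclides initially in the cell, N = A * T1/2 /
ln 2, with no excretion: every source point undergoes exactly one decay
(for Ac-225, one full chain decay).  Activity concentrations are normalized
to the injected activity, so counts are "per GBq injected".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NuclideConstants",
    "LU177",
    "AC225",
    "LesionRecord",
    "SourceCountGrid",
    "SOURCE_GRID",
    "SourcePlan",
    "sources_per_cell",
    "ac_scaling_factor",
    "synth_lesion_cohort",
    "default_conc_range",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class NuclideConstants:
    """Physical half-life and routine clinical activity of one radionuclide."""

    name: str
    half_life_days: float
    clinical_activity_mbq: float

    def __post_init__(self) -> None:
        if self.half_life_days <= 0 or self.clinical_activity_mbq <= 0:
            raise ValueError("half-life and clinical activity must be positive")

    @property
    def half_life_seconds(self) -> float:
        return self.half_life_days * SECONDS_PER_DAY


# 6.647 d is the Lu-177 half-life used in the activity-scaling fraction;
# clinical activities are 7400 MBq (200 mCi) Lu-177 and 8 MBq Ac-225.
LU177 = NuclideConstants("Lu177", half_life_days=6.647, clinical_activity_mbq=7400.0)
AC225 = NuclideConstants("Ac225", half_life_days=9.92, clinical_activity_mbq=8.0)


@dataclass(frozen=True)
class LesionRecord:
    """One lesion from a (synthetic) SPECT-derived cohort."""

    label: str
    norm_activity_conc: float  # kBq mL^-1 per GBq injected
    volume_ml: float

    def __post_init__(self) -> None:
        if self.norm_activity_conc < 0:
            raise ValueError("norm_activity_conc must be non-negative")


@dataclass(frozen=True)
class SourceCountGrid:
    """The per-cell source-count levels the simulations are run at."""

    lu_counts: tuple[int, ...] = (100, 300, 500, 700, 900, 1000, 2000, 3000, 4000, 5000)
    ac_counts: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)

    def __post_init__(self) -> None:
        if len(self.lu_counts) != len(self.ac_counts):
            raise ValueError("lu and ac grids must have equal length")

    def counts_for(self, radionuclide: str) -> tuple[int, ...]:
        if radionuclide == "Lu177":
            return self.lu_counts
        if radionuclide == "Ac225":
            return self.ac_counts
        raise ValueError(f"unknown radionuclide: {radionuclide!r}")


SOURCE_GRID = SourceCountGrid()


@dataclass(frozen=True)
class SourcePlan:
    """Per-cell source placement for one simulation run.

    The same number of source points is placed in every cell of the
    cluster; ``scenario`` selects the internalization assumption
    (membrane-bound vs fully internalized).  Explicit positions, when
    supplied, are cell-local coordinates of shape (n_cells, n_per_cell, 3);
    otherwise the simulators sample them.
    """

    radionuclide: str
    scenario: str
    n_per_cell: int
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_per_cell < 0:
            raise ValueError("n_per_cell must be non-negative")
        if self.radionuclide not in ("Lu177", "Ac225"):
            raise ValueError(f"unknown radionuclide: {self.radionuclide!r}")
        if self.scenario not in ("membrane_bound", "internalized"):
            raise ValueError(f"unknown scenario: {self.scenario!r}")


def sources_per_cell(
    norm_activity_conc: float, cell_volume_ml: float, half_life_s: float
) -> float:
    """Number of source points per cell per GBq injected.

    N = (T1/2 / ln 2) * 1000 * [norm. activity conc., kBq mL^-1 GBq^-1]
        * [cell volume, mL]

    The factor 1000 converts kBq to Bq; the planning value is real-valued,
    rounding happens only when a simulation is instantiated.
    """
    for name, v in (
        ("norm_activity_conc", norm_activity_conc),
        ("cell_volume_ml", cell_volume_ml),
        ("half_life_s", half_life_s),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return half_life_s / math.log(2.0) * 1000.0 * norm_activity_conc * cell_volume_ml


def ac_scaling_factor(lu: NuclideConstants = LU177, ac: NuclideConstants = AC225) -> float:
    """Ratio by which Lu-177 per-cell source counts are divided to get Ac-225 counts.

    (A_Lu * T1/2,Lu) / (A_Ac * T1/2,Ac) = (7400 MBq * 6.647 d) / (8 MBq * 9.92 d)
    ~ 619.8 with the default clinical activities.
    """
    denom = ac.clinical_activity_mbq * ac.half_life_days
    if denom == 0:
        raise ValueError("Ac activity-half-life product must be non-zero")
    return (lu.clinical_activity_mbq * lu.half_life_days) / denom


def round_half_away_from_zero(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def default_conc_range(
    cell_volume_ml: float,
    count_range: tuple[float, float] = (100.0, 5000.0),
    nuclide: NuclideConstants = LU177,
) -> tuple[float, float]:
    """Concentration interval whose per-cell counts span ``count_range``.

    Inverts the per-cell count relation for the given cell volume, so a
    log-uniform draw over the returned interval lands in the stated Lu-177
    per-cell count range by construction.
    """
    per_unit = sources_per_cell(1.0, cell_volume_ml, nuclide.half_life_seconds)
    return (count_range[0] / per_unit, count_range[1] / per_unit)


def synth_lesion_cohort(
    n_lesions: int,
    rng: np.random.Generator | int | None = None,
    conc_range: tuple[float, float] | None = None,
    cell_volume_ml: float = 4.18879e-9,
    volume_range_ml: tuple[float, float] = (1.0, 100.0),
) -> list[LesionRecord]:
    """Draw a synthetic SPECT-like lesion cohort.

    Normalized activity concentrations are log-uniform over ``conc_range``
    (default: the interval mapping to 100..5000 Lu-177 source points per
    cell of the catalog volume); lesion volumes are log-uniform over
    ``volume_range_ml``.  The cohort stands in for segmented patient SPECT
    data, which is not publicly deposited.
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    if conc_range is None:
        conc_range = default_conc_range(cell_volume_ml)
    lo, hi = conc_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid concentration range: {conc_range}")
    rng = np.random.default_rng(rng)
    if hi == lo:
        concs = np.full(n_lesions, lo)
    else:
        concs = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_lesions))
    vols = np.exp(
        rng.uniform(math.log(volume_range_ml[0]), math.log(volume_range_ml[1]), size=n_lesions)
    )
    return [
        LesionRecord(label=f"lesion_{i:03d}", norm_activity_conc=float(c), volume_ml=float(v))
        for i, (c, v) in enumerate(zip(concs, vols))
    ]


def cohort_to_frame(cohort: list[LesionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in cohort],
            "norm_conc_kBq_per_mL_per_GBq": [r.norm_activity_conc for r in cohort],
            "volume_mL": [r.volume_ml for r in cohort],
        }
    )


def cohort_from_frame(df: pd.DataFrame) -> list[LesionRecord]:
    return [
        LesionRecord(
            label=str(r["label"]),
            norm_activity_conc=float(r["norm_conc_kBq_per_mL_per_GBq"]),
            volume_ml=float(r["volume_mL"]),
        )
        for _, r in df.iterrows()
    ]
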