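"""Ellipsoidal cells, cluster layouts and source-position sampling.

Cells are equal-volume ellipsoids (a membrane shell, a cytoplasm and a
concentric spherical nucleus) tiled on a rectangular grid around a central
target cell.  The lateral extent of the grid is set by the range of the
emitted particles: electrons for the low-LET emitter (Lu-177), alpha
particles for the high-LET emitter (Ac-225).  Only the central cell's
nucleus is ever scored, so the cluster exists to supply cross-irradiation.

All lengths are in micrometres; coordinates are Cartesian with the central
cell's nucleus centre at the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "EllipsoidCell",
    "ClusterSpec",
    "RangeCatalog",
    "RANGE_CATALOG",
    "load_geometry_catalog",
    "get_geometry",
    "cells_per_axis",
    "build_cluster",
    "sample_source_positions",
    "point_region",
]

Arrangement = Literal["planar_2d", "lattice_3d"]
Radionuclide = Literal["Lu177", "Ac225"]
Scenario = Literal["membrane_bound", "internalized"]

#: Radius of the spherical nucleus, um (fibroblast G0/G1 model).
NUCLEUS_RADIUS_UM = 4.65
#: Membrane shell thickness, um (10 nm).
MEMBRANE_THICKNESS_UM = 0.01


@dataclass(frozen=True)
class RangeCatalog:
    """Particle ranges (um) that set the lateral extent of the cell clusters.

    ``lu_range_2d`` is the electron CSDA range at the mean Lu-177 beta
    energy; 3-D clusters use half of it to keep the cell count tractable
    (the cross-dose falls off exponentially with distance, so the outer
    shell contributes negligibly).  ``ac_range`` is the CSDA range of the
    most energetic alpha in the Ac-225 chain (8.5 MeV).
    """

    lu_range_2d: float = 280.0
    lu_range_3d: float = 140.0
    ac_range: float = 86.53

    def __post_init__(self) -> None:
        if not math.isclose(self.lu_range_3d, self.lu_range_2d / 2.0):
            raise ValueError("lu_range_3d must equal lu_range_2d / 2")

    def range_for(self, radionuclide: Radionuclide, arrangement: Arrangement) -> float:
        if radionuclide == "Ac225":
            return self.ac_range
        if radionuclide == "Lu177":
            return self.lu_range_2d if arrangement == "planar_2d" else self.lu_range_3d
        raise ValueError(f"unknown radionuclide: {radionuclide!r}")


RANGE_CATALOG = RangeCatalog()


@dataclass(frozen=True)
class EllipsoidCell:
    """One cell: ellipsoidal membrane + cytoplasm with a spherical nucleus.

    ``half_lengths`` are the principal half-axes of the outer membrane
    surface.  The nucleus is concentric with the cell.
    """

    half_lengths: tuple[float, float, float]
    membrane_thickness: float = MEMBRANE_THICKNESS_UM
    nucleus_radius: float = NUCLEUS_RADIUS_UM
    geometry_id: int | None = None

    def __post_init__(self) -> None:
        hl = np.asarray(self.half_lengths, dtype=float)
        if hl.shape != (3,) or np.any(hl <= 0):
            raise ValueError("half_lengths must be three positive lengths")
        if np.any(hl <= self.nucleus_radius + self.membrane_thickness):
            raise ValueError("nucleus plus membrane must fit strictly inside the cell")
        object.__setattr__(self, "half_lengths", tuple(float(x) for x in hl))

    @property
    def volume(self) -> float:
        """Cell volume in um^3."""
        a, b, c = self.half_lengths
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def volume_ml(self) -> float:
        """Cell volume in mL (1 um^3 = 1e-12 mL)."""
        return self.volume * 1e-12

    @property
    def nucleus_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.nucleus_radius**3

    @property
    def cytoplasm_volume(self) -> float:
        """Volume between the inner membrane surface and the nucleus, um^3."""
        a, b, c = (h - self.membrane_thickness for h in self.half_lengths)
        return 4.0 / 3.0 * math.pi * a * b * c - self.nucleus_volume


def load_geometry_catalog() -> pd.DataFrame:
    """Load the packaged catalog of the five equal-volume cell geometries."""
    with resources.files("rbesim.data").joinpath("geometries.csv").open("rb") as fh:
        return pd.read_csv(fh)


def get_geometry(geometry_id: int) -> EllipsoidCell:
    """Return the catalog cell with the given id (1..5)."""
    cat = load_geometry_catalog()
    row = cat[cat["id"] == geometry_id]
    if row.empty:
        raise KeyError(f"no catalog geometry with id {geometry_id}")
    r = row.iloc[0]
    return EllipsoidCell(
        half_lengths=(float(r.hlx_um), float(r.hly_um), float(r.hlz_um)),
        geometry_id=int(r.id),
    )


def cells_per_axis(particle_range: float, nucleus_radius: float, half_length: float) -> int:
    """Odd number of cells along one axis so the grid covers the particle range.

    n = 2 * ceil(((particle_range + R_nucleus)/HL - 1) / 2) + 1, clamped at 1.
    The grid is symmetric about the central cell, hence always odd.
    """
    for name, v in (
        ("particle_range", particle_range),
        ("nucleus_radius", nucleus_radius),
        ("half_length", half_length),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    n = 2 * math.ceil(((particle_range + nucleus_radius) / half_length - 1.0) / 2.0) + 1
    return max(n, 1)


@dataclass(frozen=True)
class ClusterSpec:
    """Rectangular grid of identical cells around a central target cell.

    Cells tile space with pitch ``2*HL`` per axis; lattice indices are signed
    integers centred at (0, 0, 0), which is the central (scored) cell.
    """

    cell: EllipsoidCell
    arrangement: Arrangement
    counts_per_axis: tuple[int, int, int]
    particle_range: float
    radionuclide: Radionuclide
    central_index: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        for n in self.counts_per_axis:
            if n < 1 or n % 2 == 0:
                raise ValueError("counts_per_axis entries must be odd positive integers")
        if self.arrangement == "planar_2d" and min(self.counts_per_axis) != 1:
            if 1 not in self.counts_per_axis:
                raise ValueError("planar clusters must fix one axis count to 1")

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.counts_per_axis
        return nx * ny * nz

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 3) array of cell centres, um; central cell first."""
        axes = []
        for n, hl in zip(self.counts_per_axis, self.cell.half_lengths):
            k = (n - 1) // 2
            axes.append(np.arange(-k, k + 1) * 2.0 * hl)
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        # move the central cell to the front for convenience
        d2 = np.einsum("ij,ij->i", centers, centers)
        order = np.argsort(d2, kind="stable")
        return centers[order]

    def to_frame(self) -> pd.DataFrame:
        """Cluster description as a table (lattice index triple + centre)."""
        centers = self.cell_centers()
        hl = np.asarray(self.cell.half_lengths)
        idx = np.rint(centers / (2.0 * hl)).astype(int)
        return pd.DataFrame(
            {
                "ix": idx[:, 0],
                "iy": idx[:, 1],
                "iz": idx[:, 2],
                "cx_um": centers[:, 0],
                "cy_um": centers[:, 1],
                "cz_um": centers[:, 2],
            }
        )


def _planar_axes(cell: EllipsoidCell) -> tuple[int, int]:
    """Indices of the two axes spanning the monolayer.

    The monolayer lies in the plane of the two largest half-lengths; this is
    the unique choice consistent with the per-axis counts of all catalog
    clusters.
    """
    hl = np.asarray(cell.half_lengths)
    order = np.argsort(-hl, kind="stable")
    return int(order[0]), int(order[1])


def build_cluster(
    cell: EllipsoidCell,
    arrangement: Arrangement,
    radionuclide: Radionuclide,
    ranges: RangeCatalog = RANGE_CATALOG,
) -> ClusterSpec:
    """Size the cluster for the given emitter and arrangement."""
    if arrangement not in ("planar_2d", "lattice_3d"):
        raise ValueError(f"unknown arrangement: {arrangement!r}")
    if radionuclide not in ("Lu177", "Ac225"):
        raise ValueError(f"unknown radionuclide: {radionuclide!r}")
    particle_range = ranges.range_for(radionuclide, arrangement)
    counts = [1, 1, 1]
    if arrangement == "lattice_3d":
        active: Iterable[int] = range(3)
    else:
        active = _planar_axes(cell)
    for i in active:
        counts[i] = cells_per_axis(particle_range, cell.nucleus_radius, cell.half_lengths[i])
    return ClusterSpec(
        cell=cell,
        arrangement=arrangement,
        counts_per_axis=tuple(counts),
        particle_range=particle_range,
        radionuclide=radionuclide,
    )


def point_region(cell: EllipsoidCell, p) -> str:
    """Classify a point (cell-local coordinates) as nucleus / cytoplasm / membrane / outside."""
    p = np.asarray(p, dtype=float)
    if np.dot(p, p) <= cell.nucleus_radius**2:
        return "nucleus"
    hl = np.asarray(cell.half_lengths)
    if np.sum((p / hl) ** 2) > 1.0:
        return "outside"
    inner = hl - cell.membrane_thickness
    if np.sum((p / inner) ** 2) > 1.0:
        return "membrane"
    return "cytoplasm"


def _sample_ellipsoid_surface(hl: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-by-area points on an ellipsoid surface by gradient-norm rejection.

    Directions are drawn on the unit sphere and mapped to the ellipsoid; a
    candidate is kept with probability proportional to the local area
    magnification sqrt((bc u_x)^2 + (ac u_y)^2 + (ab u_z)^2), which is exact.
    """
    a, b, c = hl
    w = np.array([b * c, a * c, a * b])
    w_max = w.max()
    out = np.empty((0, 3))
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 1024)
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        g = np.sqrt(np.sum((u * w) ** 2, axis=1))
        keep = rng.random(m) < g / w_max
        out = np.vstack([out, u[keep] * hl])
    return out[:n]


def _sample_cytoplasm(cell: EllipsoidCell, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-by-volume points in the cytoplasm by bounding-box rejection."""
    inner = np.asarray(cell.half_lengths) - cell.membrane_thickness
    r2 = cell.nucleus_radius**2
    out = np.empty((0, 3))
    while out.shape[0] < n:
        m = max(3 * (n - out.shape[0]), 4096)
        p = rng.uniform(-inner, inner, size=(m, 3))
        inside = np.sum((p / inner) ** 2, axis=1) <= 1.0
        outside_nucleus = np.einsum("ij,ij->i", p, p) > r2
        out = np.vstack([out, p[inside & outside_nucleus]])
    return out[:n]


def sample_source_positions(
    cell: EllipsoidCell,
    scenario: Scenario,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample decay-site positions for one cell, cell-local coordinates (um).

    ``membrane_bound`` places points uniformly per unit area on the outer
    ellipsoid surface (the 10 nm membrane thickness is negligible at the
    micrometre scale); ``internalized`` places points uniformly per unit
    volume in the cytoplasm (inside the inner membrane surface, outside the
    nucleus).
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = np.random.default_rng(rng)
    if n == 0:
        return np.empty((0, 3))
    if scenario == "membrane_bound":
        return _sample_ellipsoid_surface(np.asarray(cell.half_lengths), n, rng)
    if scenario == "internalized":
        return _sample_cytoplasm(cell, n, rng)
    raise ValueError(f"unknown scenario: {scenario!r}")
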