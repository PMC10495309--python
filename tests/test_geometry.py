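"""Cell geometry, cluster sizing and source-position sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rbesim.geometry import (
    EllipsoidCell,
    build_cluster,
    cells_per_axis,
    get_geometry,
    load_geometry_catalog,
    point_region,
    sample_source_positions,
)

# (radionuclide, geometry, arrangement) -> total cell count of the catalog cluster
CLUSTER_TOTALS = {
    ("Lu177", 1, "planar_2d"): 841,
    ("Lu177", 1, "lattice_3d"): 3375,
    ("Lu177", 2, "planar_2d"): 667,
    ("Lu177", 2, "lattice_3d"): 3705,
    ("Lu177", 3, "planar_2d"): 435,
    ("Lu177", 3, "lattice_3d"): 3915,
    ("Lu177", 4, "planar_2d"): 513,
    ("Lu177", 4, "lattice_3d"): 4205,
    ("Lu177", 5, "planar_2d"): 441,
    ("Lu177", 5, "lattice_3d"): 3509,
    ("Ac225", 1, "planar_2d"): 121,
    ("Ac225", 1, "lattice_3d"): 1331,
    ("Ac225", 2, "planar_2d"): 99,
    ("Ac225", 2, "lattice_3d"): 1287,
    ("Ac225", 3, "planar_2d"): 55,
    ("Ac225", 3, "lattice_3d"): 1045,
    ("Ac225", 4, "planar_2d"): 57,
    ("Ac225", 4, "lattice_3d"): 1083,
    ("Ac225", 5, "planar_2d"): 49,
    ("Ac225", 5, "lattice_3d"): 931,
}


@pytest.mark.parametrize(
    "particle_range,nucleus_radius,half_length,expected",
    [
        (140.0, 4.65, 10.0, 15),
        (86.53, 4.65, 5.0, 19),
        (280.0, 4.65, 40.0, 9),
        (1.0, 4.65, 10.0, 1),
    ],
)
def test_cells_per_axis_examples(particle_range, nucleus_radius, half_length, expected):
    assert cells_per_axis(particle_range, nucleus_radius, half_length) == expected


@pytest.mark.parametrize("bad", [(-1, 4.65, 10), (140, 0, 10), (140, 4.65, -5)])
def test_cells_per_axis_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        cells_per_axis(*bad)


@given(
    particle_range=st.floats(0.1, 500.0),
    nucleus_radius=st.floats(0.1, 10.0),
    half_length=st.floats(1.0, 50.0),
)
def test_cells_per_axis_is_odd_and_monotone(particle_range, nucleus_radius, half_length):
    n = cells_per_axis(particle_range, nucleus_radius, half_length)
    assert n >= 1 and n % 2 == 1
    assert cells_per_axis(particle_range * 1.5, nucleus_radius, half_length) >= n
    assert cells_per_axis(particle_range, nucleus_radius, half_length * 1.5) <= n


def test_catalog_geometries_have_equal_volume():
    target = 4188.79
    for gid in range(1, 6):
        cell = get_geometry(gid)
        assert cell.volume == pytest.approx(target, rel=5e-3)


def test_nucleus_fits_inside_every_catalog_cell():
    for gid in range(1, 6):
        cell = get_geometry(gid)
        assert min(cell.half_lengths) > cell.nucleus_radius + cell.membrane_thickness


def test_invalid_cell_rejected():
    with pytest.raises(ValueError):
        EllipsoidCell(half_lengths=(4.0, 10.0, 10.0))  # nucleus would not fit


@pytest.mark.parametrize("key,total", sorted(CLUSTER_TOTALS.items()))
def test_cluster_totals_match_catalog(key, total):
    nuc, gid, arr = key
    cluster = build_cluster(get_geometry(gid), arr, nuc)
    assert cluster.n_cells == total


def test_planar_cluster_axis_assignment():
    # geometry 4 (half-lengths 5, 40, 5): the monolayer spans the 40 um axis
    # (3 cells) and one 5 um axis (19 cells) under the alpha range rule
    cluster = build_cluster(get_geometry(4), "planar_2d", "Ac225")
    assert sorted(cluster.counts_per_axis) == [1, 3, 19]
    assert cluster.counts_per_axis[1] == 3  # 40 um axis


def test_cluster_ranges():
    assert build_cluster(get_geometry(1), "planar_2d", "Lu177").particle_range == 280.0
    assert build_cluster(get_geometry(1), "lattice_3d", "Lu177").particle_range == 140.0
    assert build_cluster(get_geometry(1), "planar_2d", "Ac225").particle_range == 86.53


def test_build_cluster_rejects_unknown_inputs(sphere_cell):
    with pytest.raises(ValueError):
        build_cluster(sphere_cell, "planar_2d", "I131")
    with pytest.raises(ValueError):
        build_cluster(sphere_cell, "helix", "Lu177")


def test_cluster_centers_tile_without_overlap(sphere_cell):
    cluster = build_cluster(sphere_cell, "lattice_3d", "Ac225")
    centers = cluster.cell_centers()
    assert centers.shape == (cluster.n_cells, 3)
    assert np.allclose(centers[0], 0.0)  # central cell first
    # nearest-neighbour distance equals the grid pitch
    d = np.linalg.norm(centers[1:] - centers[0], axis=1)
    assert d.min() == pytest.approx(2 * sphere_cell.half_lengths[0])


@pytest.mark.parametrize(
    "gid,point,region",
    [
        (1, (0, 0, 0), "nucleus"),
        (1, (9.999, 0, 0), "membrane"),
        (4, (0, 41, 0), "outside"),
        (1, (0, 7, 0), "cytoplasm"),
    ],
)
def test_point_region_examples(gid, point, region):
    assert point_region(get_geometry(gid), point) == region


def test_point_regions_are_exhaustive(sphere_cell, rng):
    pts = rng.uniform(-12, 12, size=(2000, 3))
    regions = {point_region(sphere_cell, p) for p in pts}
    assert regions <= {"nucleus", "cytoplasm", "membrane", "outside"}


def test_source_sampling_edge_cases(sphere_cell):
    assert sample_source_positions(sphere_cell, "internalized", 0, 1).shape == (0, 3)
    with pytest.raises(ValueError):
        sample_source_positions(sphere_cell, "internalized", -1, 1)
    with pytest.raises(ValueError):
        sample_source_positions(sphere_cell, "floating", 5, 1)


def test_source_sampling_deterministic(sphere_cell):
    a = sample_source_positions(sphere_cell, "membrane_bound", 100, 7)
    b = sample_source_positions(sphere_cell, "membrane_bound", 100, 7)
    assert np.array_equal(a, b)


def test_sphere_surface_sampling_is_uniform(sphere_cell):
    n = 100_000
    pts = sample_source_positions(sphere_cell, "membrane_bound", n, 42)
    r = np.linalg.norm(pts, axis=1)
    assert abs(r.mean() - 10.0) < 1e-3
    # equal-area latitude bands: z/R is uniform on a sphere
    counts, _ = np.histogram(pts[:, 2] / 10.0, bins=np.linspace(-1, 1, 21))
    chi2 = ((counts - n / 20) ** 2 / (n / 20)).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=19)


def _triangulated_ellipsoid_sample(hl, n, rng):
    """Independent oracle: area-weighted draw from a fine surface triangulation."""
    verts = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )
    faces = [
        (0, 2, 4), (2, 1, 4), (1, 3, 4), (3, 0, 4),
        (2, 0, 5), (1, 2, 5), (3, 1, 5), (0, 3, 5),
    ]
    tris = verts[np.array(faces)]
    for _ in range(5):  # 8 * 4^5 = 8192 spherical triangles
        a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
        ab = (a + b) / 2
        bc = (b + c) / 2
        ca = (c + a) / 2
        for m in (ab, bc, ca):
            m /= np.linalg.norm(m, axis=1, keepdims=True)
        tris = np.concatenate(
            [
                np.stack([a, ab, ca], 1),
                np.stack([ab, b, bc], 1),
                np.stack([ca, bc, c], 1),
                np.stack([ab, bc, ca], 1),
            ]
        )
    tris = tris * hl  # map to the ellipsoid
    area = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
    )
    pick = rng.choice(len(tris), size=n, p=area / area.sum())
    u, v = rng.random(n), rng.random(n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    t = tris[pick]
    return t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])


def test_ellipsoid_surface_sampling_matches_triangulation_oracle():
    cell = get_geometry(2)  # 12.5 x 8 x 10 um
    n = 50_000
    ours = sample_source_positions(cell, "membrane_bound", n, 3)
    oracle = _triangulated_ellipsoid_sample(
        np.asarray(cell.half_lengths), n, np.random.default_rng(4)
    )
    for axis in range(3):
        ks = stats.ks_2samp(ours[:, axis], oracle[:, axis]).statistic
        assert ks < 0.015


def test_cytoplasm_sampling_avoids_nucleus_and_matches_volume_fractions():
    cell = get_geometry(2)
    n = 100_000
    pts = sample_source_positions(cell, "internalized", n, 11)
    r = np.linalg.norm(pts, axis=1)
    assert np.all(r > cell.nucleus_radius)
    inner = np.asarray(cell.half_lengths) - cell.membrane_thickness
    assert np.all(np.sum((pts / inner) ** 2, axis=1) <= 1.0 + 1e-12)

    # independent rejection oracle for the volume fraction of the r < 7 um shell
    oracle_rng = np.random.default_rng(99)
    box = oracle_rng.uniform(-inner, inner, size=(400_000, 3))
    in_cyto = (np.sum((box / inner) ** 2, axis=1) <= 1.0) & (
        np.einsum("ij,ij->i", box, box) > cell.nucleus_radius**2
    )
    sub = in_cyto & (np.linalg.norm(box, axis=1) < 7.0)
    frac_oracle = sub.sum() / in_cyto.sum()
    frac_ours = (r < 7.0).mean()
    sigma = math.sqrt(frac_oracle * (1 - frac_oracle) * (1 / n + 1 / in_cyto.sum()))
    assert abs(frac_ours - frac_oracle) < 3 * sigma + 1e-4


def test_geometry_catalog_contents():
    cat = load_geometry_catalog()
    assert list(cat["id"]) == [1, 2, 3, 4, 5]
    assert get_geometry(1).half_lengths == (10.0, 10.0, 10.0)
    with pytest.raises(KeyError):
        get_geometry(9)
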