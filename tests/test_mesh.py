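"""Surface extraction, projection thickness/transmurality, nodal DICE,
LV dimension measurement."""

import numpy as np
import pytest

from lvcoreg.core import BACKGROUND, CAVITY, LabelMap, MVPlane, MYOCARDIUM, SCAR
from lvcoreg.mesh import (
    SurfaceMesh,
    extract_surface,
    measure_lv_dimensions,
    nodal_dice_scar,
    nodal_scar_and_transmurality,
    pair_nearest_epi,
    wall_thickness,
)


def _sphere_shell_labels(r_endo=20.0, r_epi=30.0, voxel=1.0, pad=4.0):
    n = int(2 * (r_epi + pad) / voxel)
    origin = -np.full(3, (r_epi + pad) - voxel / 2)
    ax = origin[0] + voxel * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    data = np.zeros((n, n, n), dtype=np.int16)
    data[r < r_epi] = MYOCARDIUM
    data[r < r_endo] = CAVITY
    return LabelMap(data, voxel, origin)


def test_sphere_endo_surface_area():
    lab = _sphere_shell_labels()
    endo = extract_surface(lab, "endo")
    assert endo.surface_area() == pytest.approx(4 * np.pi * 20.0**2, rel=0.05)


def test_empty_cavity_errors():
    lab = LabelMap(np.full((5, 5, 5), MYOCARDIUM, dtype=np.int16), 1.0, np.zeros(3))
    with pytest.raises(ValueError, match="cavity"):
        extract_surface(lab, "endo")
    with pytest.raises(ValueError):
        extract_surface(lab, "bogus")


def test_spherical_shell_thickness():
    lab = _sphere_shell_labels(20.0, 30.0)
    endo = extract_surface(lab, "endo")
    epi = extract_surface(lab, "epi")
    rec = pair_nearest_epi(endo, epi)
    th = wall_thickness(rec)
    assert th.mean() == pytest.approx(10.0, abs=0.5)
    assert np.all(th >= 0)


def test_thickness_converges_with_refinement():
    coarse = _sphere_shell_labels(voxel=2.0)
    fine = _sphere_shell_labels(voxel=1.0)

    def mean_th(lab):
        endo = extract_surface(lab, "endo")
        epi = extract_surface(lab, "epi")
        return wall_thickness(pair_nearest_epi(endo, epi)).mean()

    assert abs(mean_th(coarse) - mean_th(fine)) < 0.25


def test_concentric_pairing_is_radial():
    lab = _sphere_shell_labels()
    endo = extract_surface(lab, "endo")
    epi = extract_surface(lab, "epi")
    rec = pair_nearest_epi(endo, epi)
    u = rec.endo_points / np.linalg.norm(rec.endo_points, axis=1, keepdims=True)
    v = rec.epi_points / np.linalg.norm(rec.epi_points, axis=1, keepdims=True)
    # paired node aligned with the radial direction within ~one edge length
    angles = np.degrees(np.arccos(np.clip((u * v).sum(axis=1), -1, 1)))
    assert np.median(angles) < 5.0


def test_identical_meshes_zero_segments():
    lab = _sphere_shell_labels()
    endo = extract_surface(lab, "endo")
    rec = pair_nearest_epi(endo, endo)
    assert np.allclose(rec.lengths, 0.0)
    flag, tau = nodal_scar_and_transmurality(rec, scar=lab)
    assert not flag.any() and np.allclose(tau, 0.0)  # no scar voxels at all


def _slab_with_scar(scar_frac=0.5):
    """Straight wall: cavity below, wall above, scar in the inner slab part."""
    n = 40
    data = np.zeros((n, n, 30), dtype=np.int16)
    data[:, :, :10] = CAVITY
    data[:, :, 10:20] = MYOCARDIUM
    k_scar = 10 + int(10 * scar_frac)
    data[:, :, 10:k_scar] = SCAR
    return LabelMap(data, 1.0, np.zeros(3))


def test_transmurality_half_wall_slab():
    lab = _slab_with_scar(0.5)
    n_nodes = 200
    rng = np.random.default_rng(0)
    xy = rng.uniform(8, 32, size=(n_nodes, 2))
    endo_pts = np.column_stack([xy, np.full(n_nodes, 9.5)])
    epi_pts = np.column_stack([xy, np.full(n_nodes, 19.5)])
    endo = SurfaceMesh(endo_pts, np.zeros((0, 3), dtype=int))
    epi = SurfaceMesh(epi_pts, np.zeros((0, 3), dtype=int))
    rec = pair_nearest_epi(endo, epi)
    flag, tau = nodal_scar_and_transmurality(rec, scar=lab)
    assert flag.all()
    step = 0.5 * lab.voxel_size_mm / rec.lengths.mean()
    assert tau.mean() == pytest.approx(0.5, abs=2 * step)


def test_fully_transmural_column():
    lab = _slab_with_scar(1.0)
    endo = SurfaceMesh(np.array([[20.0, 20.0, 10.0]]), np.zeros((0, 3), dtype=int))
    epi = SurfaceMesh(np.array([[20.0, 20.0, 19.4]]), np.zeros((0, 3), dtype=int))
    rec = pair_nearest_epi(endo, epi)
    flag, tau = nodal_scar_and_transmurality(rec, scar=lab)
    assert flag[0] and tau[0] == pytest.approx(1.0)


def test_zero_length_segment_flag_from_endpoint():
    lab = _slab_with_scar(1.0)
    pt = np.array([[20.0, 20.0, 15.0]])  # inside scar
    mesh = SurfaceMesh(pt, np.zeros((0, 3), dtype=int))
    rec = pair_nearest_epi(mesh, mesh)
    flag, tau = nodal_scar_and_transmurality(rec, scar=lab)
    assert flag[0] and tau[0] == 0.0


def test_nodal_dice_formula_and_edge_cases():
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 10, size=(10, 3))
    faces = np.zeros((0, 3), dtype=int)
    # 8 scar on each side with 6 common -> 2*6/16 = 0.75
    fa = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0], dtype=bool)
    fb = np.array([1, 1, 1, 1, 1, 1, 0, 0, 1, 1], dtype=bool)
    a = SurfaceMesh(pts, faces, {"scar_flag": fa})
    b = SurfaceMesh(pts.copy(), faces, {"scar_flag": fb})
    assert nodal_dice_scar(a, b) == pytest.approx(0.75)
    assert nodal_dice_scar(b, a) == pytest.approx(0.75)  # symmetric on shared nodes
    assert nodal_dice_scar(a, a) == 1.0
    none = SurfaceMesh(pts.copy(), faces, {"scar_flag": np.zeros(10, bool)})
    assert nodal_dice_scar(a, none) == 0.0
    with pytest.warns(UserWarning):
        assert nodal_dice_scar(none, none) == 1.0
    with pytest.raises(ValueError):
        nodal_dice_scar(SurfaceMesh(pts, faces), a)


def _ellipsoid_cavity_labels(a=60.0, b=25.0, voxel=1.5):
    nxy = int(2 * (b + 6) / voxel)
    nz = int((a + 12) / voxel)
    origin = np.array([-(b + 6) + voxel / 2, -(b + 6) + voxel / 2, -(a + 6) + voxel / 2])
    ax = [origin[d] + voxel * np.arange(n) for d, n in enumerate((nxy, nxy, nz))]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    inside = (X / b) ** 2 + (Y / b) ** 2 + (Z / a) ** 2 < 1
    data = np.where(inside & (Z <= 0), CAVITY, BACKGROUND).astype(np.int16)
    lm = LabelMap(data, voxel, origin)
    lm.meta["mv_plane"] = MVPlane(point=(0, 0, 0), normal=(0, 0, 1))
    return lm


def test_lv_dimensions_on_analytic_ellipsoid():
    lab = _ellipsoid_cavity_labels()
    long_axis, d1, d2 = measure_lv_dimensions(lab)
    assert long_axis == pytest.approx(60.0, abs=lab.voxel_size_mm)
    # expected diameter at 25% depth: 2 b sqrt(1 - 0.25^2)
    expected = 2 * 25.0 * np.sqrt(1 - 0.25**2)
    assert d1 == pytest.approx(expected, rel=0.05)
    assert d2 == pytest.approx(expected, rel=0.05)


def test_lv_dimensions_sphere_symmetry():
    lab = _ellipsoid_cavity_labels(a=30.0, b=30.0, voxel=1.0)
    _, d1, d2 = measure_lv_dimensions(lab)
    assert d1 == pytest.approx(d2, rel=0.02)


def test_lv_dimensions_requires_plane_and_cavity():
    lab = _ellipsoid_cavity_labels()
    lab.meta.pop("mv_plane")
    with pytest.raises(ValueError, match="MV plane"):
        measure_lv_dimensions(lab)
    empty = LabelMap(np.zeros((4, 4, 4), dtype=np.int16), 1.0, np.zeros(3))
    empty.meta["mv_plane"] = MVPlane(point=(0, 0, 0), normal=(0, 0, 1))
    with pytest.raises(ValueError, match="cavity"):
        measure_lv_dimensions(empty)


def test_endo_inside_epi_on_phantom(small_pair):
    from scipy.spatial import Delaunay

    lab = small_pair["lab_in"]
    endo = extract_surface(lab, "endo")
    epi = extract_surface(lab, "epi")
    # the epicardium of the truncated phantom is convex: every endocardial
    # vertex must lie inside the hull of the epicardial vertices
    hull = Delaunay(epi.vertices[:: max(1, len(epi) // 2000)])
    sample = endo.vertices[:: max(1, len(endo) // 400)]
    assert (hull.find_simplex(sample) >= 0).mean() > 0.99


def test_scar_flag_implies_positive_transmurality(small_pair):
    lab = small_pair["lab_in"]
    endo = extract_surface(lab, "endo")
    epi = extract_surface(lab, "epi")
    rec = pair_nearest_epi(endo, epi)
    flag, tau = nodal_scar_and_transmurality(rec, scar=lab)
    assert np.all(tau[flag & (rec.lengths > 0)] > 0)
    assert np.all((tau >= 0) & (tau <= 1))
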