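"""Landmark fit, transform algebra, rigid/affine/FFD recovery, resampling."""

import numpy as np
import pytest

from conftest import FuncTransform
from lvcoreg.core import CAVITY, LabelMap, MYOCARDIUM, SCAR
from lvcoreg.phantom import LandmarkSet
from lvcoreg.registration import (
    AffineTransform,
    BsplineLevel,
    FFDTransform,
    RegistrationConfig,
    RigidTransform,
    _bending_value_grad,
    apply_transform,
    fit_rigid_landmarks,
    register_affine,
    register_ffd,
    register_rigid,
    transform_from_dict,
)
from lvcoreg.stats import voxel_dice


def _random_rigid(rng) -> RigidTransform:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(R, rng.normal(scale=10, size=3))


# ---------------------------------------------------------------------------
# landmark rigid fit
# ---------------------------------------------------------------------------


def _lms(names, pts):
    return LandmarkSet(list(names), np.asarray(pts, dtype=float))


def test_landmark_identity():
    pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
    lms = _lms("abcd", pts)
    tr, rms = fit_rigid_landmarks(lms, lms)
    assert rms == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(tr.translation, 0, atol=1e-12)


def test_landmark_known_rotation_translation():
    # 90 degrees about z plus translation (1, 2, 3)
    pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    t = np.array([1.0, 2.0, 3.0])
    moving = _lms("abcd", pts @ Rz.T + t)
    tr, rms = fit_rigid_landmarks(moving, _lms("abcd", pts))
    assert rms < 1e-9
    assert np.allclose(tr.rotation, Rz, atol=1e-9)
    assert np.allclose(tr.translation, t, atol=1e-9)


def test_landmark_random_transforms_recovered_exactly():
    rng = np.random.default_rng(0)
    pts = rng.uniform(-30, 30, size=(5, 3))
    for _ in range(25):
        tr = _random_rigid(rng)
        moving = _lms("abcde", tr.apply(pts))
        rec, rms = fit_rigid_landmarks(moving, _lms("abcde", pts))
        assert rms < 1e-9
        assert np.allclose(rec.rotation, tr.rotation, atol=1e-9)
        assert np.allclose(rec.translation, tr.translation, atol=1e-9)


def test_landmark_noise_rms_bounded():
    rng = np.random.default_rng(7)
    pts = rng.uniform(-30, 30, size=(5, 3))
    rmss = []
    for _ in range(100):
        tr = _random_rigid(rng)
        noisy = tr.apply(pts) + rng.normal(scale=1.0, size=(5, 3))
        _, rms = fit_rigid_landmarks(_lms("abcde", noisy), _lms("abcde", pts))
        rmss.append(rms)
    # expected residual RMS is sigma * sqrt((3n-6)/n) ~ 1.34 mm at n=5
    assert np.mean(rmss) <= 2.0


def test_landmark_failure_modes():
    pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
    with pytest.raises(ValueError, match="shared"):
        fit_rigid_landmarks(_lms("abcd", pts), _lms("wxyz", pts))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
    with pytest.raises(ValueError):
        _lms("abcd", line)  # collinear rejected at construction


# ---------------------------------------------------------------------------
# transform algebra
# ---------------------------------------------------------------------------


def test_composition_equals_chain():
    rng = np.random.default_rng(3)
    aff = AffineTransform(np.eye(3) * 0.9 + rng.normal(scale=0.02, size=(3, 3)), rng.normal(size=3))
    lat = BsplineLevel(np.array([-50.0, -50.0, -50.0]), 20.0, rng.normal(scale=1.0, size=(8, 8, 8, 3)))
    ffd = FFDTransform(aff, [lat])
    pts = rng.uniform(-30, 30, size=(200, 3))
    manual = aff.apply(pts) + lat.displacement(pts)
    assert np.allclose(ffd.apply(pts), manual, atol=1e-9)
    # numeric inversion round-trips
    back = ffd.invert_points(ffd.apply(pts))
    assert np.max(np.abs(back - pts)) < 1e-4


def test_transform_serialization_roundtrip():
    rng = np.random.default_rng(4)
    tr = _random_rigid(rng)
    tr2 = transform_from_dict(tr.to_dict())
    assert np.allclose(tr.rotation, tr2.rotation)
    ffd = FFDTransform(
        tr.to_affine(),
        [BsplineLevel(np.zeros(3), 10.0, rng.normal(size=(5, 5, 5, 3)))],
    )
    ffd2 = transform_from_dict(ffd.to_dict())
    pts = rng.uniform(-20, 20, size=(50, 3))
    assert np.allclose(ffd.apply(pts), ffd2.apply(pts), atol=1e-12)


def test_bending_energy_zero_for_affine_field():
    # coefficients sampled from an affine displacement have zero second
    # differences, hence exactly zero bending energy and gradient
    ii, jj, kk = np.meshgrid(*[np.arange(6.0)] * 3, indexing="ij")
    coeffs = np.stack(
        [0.3 * ii + 0.1 * jj - 0.2 * kk + 1.0, 0.5 * jj, ii - kk], axis=-1
    )
    value, grad = _bending_value_grad(coeffs)
    assert value == pytest.approx(0.0, abs=1e-20)
    assert np.allclose(grad, 0.0, atol=1e-15)
    # and a curved field has positive energy
    value2, _ = _bending_value_grad(coeffs + np.sin(ii)[..., None])
    assert value2 > 0


def test_bending_gradient_matches_finite_differences():
    rng = np.random.default_rng(9)
    coeffs = rng.normal(size=(5, 5, 5, 3))
    value, grad = _bending_value_grad(coeffs)
    eps = 1e-6
    for _ in range(5):
        idx = tuple(rng.integers(0, 5, size=3)) + (rng.integers(0, 3),)
        c2 = coeffs.copy()
        c2[idx] += eps
        v2, _ = _bending_value_grad(c2)
        assert (v2 - value) / eps == pytest.approx(grad[idx], rel=1e-3, abs=1e-8)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _block_labelmap():
    data = np.zeros((7, 7, 7), dtype=np.int16)
    data[2:5, 2:5, 2:5] = MYOCARDIUM
    data[3, 3, 3] = SCAR
    return LabelMap(data, 1.0, np.zeros(3))


def test_apply_identity_bit_identical():
    lm = _block_labelmap()
    out = apply_transform(lm, AffineTransform.identity(), lm)
    assert np.array_equal(out.data, lm.data)


def test_apply_one_voxel_translation():
    lm = _block_labelmap()
    # map fixed x to moving x + 1 voxel -> content shifts by -1 voxel
    tr = AffineTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
    out = apply_transform(lm, tr, lm)
    assert np.array_equal(out.data[1:4, 2:5, 2:5] > 0, lm.data[2:5, 2:5, 2:5] > 0)
    assert (out.data > 0).sum() == (lm.data > 0).sum()


def test_apply_ground_truth_field_consistency(default_pair):
    # resampling the in-vivo labels through the analytic inverse map must
    # reproduce the generated ex-vivo labels almost exactly
    inv = FuncTransform(default_pair["field"].inverse_points)
    out = apply_transform(default_pair["lab_in"], inv, default_pair["lab_ex"])
    d = voxel_dice(out.wall_mask(), default_pair["lab_ex"].wall_mask())
    assert d >= 0.97


# ---------------------------------------------------------------------------
# image registration
# ---------------------------------------------------------------------------

FAST = RegistrationConfig(
    control_spacings_mm=(16.0, 8.0), pyramid_factors=(2, 1), max_iterations=40
)


def test_register_rigid_self_is_identity(small_pair):
    lab = small_pair["lab_in"]
    tr = register_rigid(lab, lab, None, FAST)
    assert np.allclose(tr.rotation, np.eye(3), atol=1e-3)
    assert np.allclose(tr.translation, 0.0, atol=0.2)


def test_register_rigid_recovers_known_shift(small_pair):
    lab = small_pair["lab_in"]
    true = RigidTransform(np.eye(3), np.array([3.1, -2.3, 1.7]))
    moving = apply_transform(lab, true.inverse(), lab)
    rec = register_rigid(lab, moving, None, FAST)
    # recovered translation within half a fixed voxel
    assert np.all(np.abs(rec.apply(np.zeros(3)) - true.apply(np.zeros(3))) < 1.0)


def test_register_affine_recovers_known_scale(small_pair):
    lab = small_pair["lab_in"]
    center = lab.origin_mm + np.asarray(lab.shape) * lab.voxel_size_mm / 2
    S = np.diag([0.8, 0.8, 0.9])
    true = AffineTransform(S, center - S @ center)
    moving = apply_transform(lab, true.inverse(), lab)
    rec = register_affine(lab, moving, None, FAST)
    assert np.allclose(np.diag(rec.matrix), np.diag(S), rtol=0.02)


def test_register_affine_self_identity(small_pair):
    lab = small_pair["lab_in"]
    rec = register_affine(lab, lab, None, FAST)
    assert np.allclose(rec.matrix, np.eye(3), atol=5e-3)


def test_register_ffd_identity_stays_put(small_pair):
    lab = small_pair["lab_in"]
    ffd = register_ffd(lab, lab, None, FAST)
    assert ffd.max_control_displacement() < 0.1


def test_register_ffd_recovers_sinusoidal_warp(small_pair):
    lab = small_pair["lab_in"]

    def warp(pts):
        out = pts.copy()
        out[:, 0] += 3.0 * np.sin(2 * np.pi * pts[:, 2] / 40.0)
        out[:, 2] += 3.0 * np.cos(2 * np.pi * pts[:, 1] / 40.0)
        return out

    true = FuncTransform(warp)
    fixed = apply_transform(lab, true, lab)  # fixed(x) = lab(warp(x))
    ffd = register_ffd(fixed, lab, None, FAST)
    reg = apply_transform(lab, ffd, fixed)
    assert voxel_dice(reg.wall_mask(), fixed.wall_mask()) >= 0.95
    wall_pts = fixed.origin_mm + np.argwhere(fixed.wall_mask()) * fixed.voxel_size_mm
    err = np.linalg.norm(ffd.apply(wall_pts) - warp(wall_pts), axis=1)
    assert err.mean() < fixed.voxel_size_mm


def test_register_ffd_random_representable_warps(small_pair):
    """Mean recovered-vs-true displacement error inside the wall stays
    below one fixed-grid voxel for random smooth warps in the FFD's own
    representable class."""
    lab = small_pair["lab_in"]
    rng = np.random.default_rng(21)
    wall_pts = lab.origin_mm + np.argwhere(lab.wall_mask()) * lab.voxel_size_mm
    errs = []
    for _ in range(10):
        lo = lab.origin_mm - 16.0
        shape = tuple(
            int(np.ceil(s * lab.voxel_size_mm / 16.0)) + 4 for s in lab.shape
        )
        coeffs = rng.normal(scale=1.2, size=shape + (3,))
        true = FFDTransform(
            AffineTransform.identity(), [BsplineLevel(lo, 16.0, coeffs)]
        )
        fixed = apply_transform(lab, true, lab)
        ffd = register_ffd(fixed, lab, None, FAST)
        err = np.linalg.norm(ffd.apply(wall_pts) - true.apply(wall_pts), axis=1)
        errs.append(err.mean())
    assert np.mean(errs) < lab.voxel_size_mm


def test_registration_chain_improves_overlap(small_pair):
    lab_in, lms_in = small_pair["lab_in"], small_pair["lms_in"]
    lms_ex = small_pair["lms_ex"]
    from lvcoreg.segmentation import downsample_labels

    ds = downsample_labels(small_pair["lab_ex"], small_pair["spec"].invivo_voxel)
    lm, _ = fit_rigid_landmarks(lms_ex, lms_in)
    rigid = register_rigid(lab_in, ds, lm, FAST)
    affine = register_affine(lab_in, ds, rigid, FAST)

    def wall_dice(tr):
        return voxel_dice(
            apply_transform(ds, tr, lab_in).wall_mask(), lab_in.wall_mask()
        )

    d_rigid, d_affine = wall_dice(rigid), wall_dice(affine)
    assert d_affine > d_rigid  # affine captures the anisotropic shrinkage
    ffd = register_ffd(lab_in, ds, affine, FAST)
    assert wall_dice(ffd) > d_affine


def test_empty_overlap_raises(small_pair):
    lab = small_pair["lab_in"]
    far = RigidTransform(np.eye(3), np.array([1e4, 0.0, 0.0]))
    with pytest.raises(ValueError, match="overlap"):
        register_rigid(lab, lab, far, FAST)
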