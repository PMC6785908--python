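"""Thresholding rules, connected-component seeding, label downsampling."""

import dataclasses

import numpy as np
import pytest

from lvcoreg.core import BACKGROUND, CAVITY, LabelMap, MYOCARDIUM, SCAR
from lvcoreg.phantom import PhantomSpec, make_exvivo_pair, make_invivo_phantom
from lvcoreg.core import Volume3D
from lvcoreg.segmentation import (
    RegionOfInterest,
    SegmentationParams,
    auto_seed_and_rois,
    connected_component_filter,
    downsample_labels,
    exvivo_scar,
    fwhm_scar,
    scar_threshold_exvivo,
)


def _volume(data):
    return Volume3D(np.asarray(data, dtype=float), 1.0, np.zeros(3))


def test_fwhm_half_maximum_rule():
    # uniform wall SI 10 with a seeded bright blob at 200 -> T = 100
    data = np.full((10, 10, 10), 10.0)
    wall = np.zeros((10, 10, 10), dtype=bool)
    wall[2:8, 2:8, 2:8] = True
    data[4:6, 4:6, 4:6] = 200.0
    params = SegmentationParams(seeds=[(4, 4, 4)], reference_percentile=100.0)
    scar = fwhm_scar(_volume(data), wall, params)
    assert np.array_equal(scar, wall & (data >= 100.0))
    assert scar.sum() == 8


def test_fwhm_recovers_known_mixture():
    # healthy ~ N(30, 5^2), scar ~ N(150, 10^2): threshold sits far from
    # both modes, so the recovered count matches the generated count
    rng = np.random.default_rng(42)
    shape = (24, 24, 24)
    wall = np.zeros(shape, dtype=bool)
    wall[2:22, 2:22, 2:22] = True
    scar_true = np.zeros(shape, dtype=bool)
    scar_true[8:16, 8:16, 8:16] = True
    data = np.where(scar_true, 150.0, 30.0) + rng.normal(
        scale=np.where(scar_true, 10.0, 5.0)
    )
    params = SegmentationParams(seeds=[(12, 12, 12)])
    rec = fwhm_scar(_volume(data), wall, params)
    assert rec.sum() == pytest.approx(scar_true.sum(), rel=0.05)


def test_fwhm_connectivity_keeps_seeded_blob_only():
    data = np.full((12, 12, 12), 10.0)
    wall = np.ones((12, 12, 12), dtype=bool)
    data[2:4, 2:4, 2:4] = 200.0
    data[8:10, 8:10, 8:10] = 200.0
    params = SegmentationParams(seeds=[(2, 2, 2)], connectivity=6)
    scar = fwhm_scar(_volume(data), wall, params)
    assert scar[2:4, 2:4, 2:4].all() and not scar[8:10, 8:10, 8:10].any()


def test_fwhm_requires_seed_in_wall():
    wall = np.zeros((4, 4, 4), dtype=bool)
    wall[1, 1, 1] = True
    with pytest.raises(ValueError):
        fwhm_scar(_volume(np.ones((4, 4, 4))), wall, SegmentationParams(seeds=[(0, 0, 0)]))
    with pytest.raises(ValueError):
        fwhm_scar(_volume(np.ones((4, 4, 4))), wall, SegmentationParams(seeds=[]))


def test_exvivo_threshold_arithmetic():
    # forced by the stated formula: mean 100, SD 10, k=1 -> 90
    vals = np.array([90.0, 100.0, 110.0, 100.0, 100.0])
    sd = vals.std()
    assert scar_threshold_exvivo(vals, 1.0) == pytest.approx(100.0 - sd)
    assert scar_threshold_exvivo(vals, 0.0) == pytest.approx(100.0)


def test_exvivo_scar_thresholds_and_excludes():
    shape = (12, 12, 12)
    wall = np.ones(shape, dtype=bool)
    data = np.full(shape, 40.0)
    data[2:10, 2:10, 2:10] = 160.0
    roi = RegionOfInterest(np.argwhere(data == 160.0)[:50], "scar_roi")
    remote = RegionOfInterest(np.argwhere(data == 40.0)[:50], "remote_roi")
    # tiny SD in ROI -> reject degenerate, so add spread
    data[2, 2, 2] = 150.0
    params = SegmentationParams(seeds=[(5, 5, 5)])
    scar = exvivo_scar(_volume(data), wall, roi, remote, params)
    assert scar.sum() == (data >= scar_threshold_exvivo(roi.values(_volume(data)))).sum()
    excl = np.zeros(shape, dtype=bool)
    excl[2:10, 2:10, 2] = True
    scar2 = exvivo_scar(_volume(data), wall, roi, remote, params, exclusion_mask=excl)
    assert not (scar2 & excl).any() and scar2.sum() < scar.sum()


def test_exvivo_degenerate_roi_errors():
    vol = _volume(np.full((4, 4, 4), 7.0))
    wall = np.ones((4, 4, 4), dtype=bool)
    roi = RegionOfInterest(np.array([[1, 1, 1]]), "scar_roi")
    remote = RegionOfInterest(np.array([[0, 0, 0]]), "remote_roi")
    with pytest.raises(ValueError, match="degenerate"):
        exvivo_scar(vol, wall, roi, remote, SegmentationParams(seeds=[(1, 1, 1)]))


def test_exvivo_recovery_on_phantom(small_pair):
    vol, lab = small_pair["vol_ex"], small_pair["lab_ex"]
    wall = lab.wall_mask()
    seeds, roi, remote = auto_seed_and_rois(vol, wall)
    params = SegmentationParams(seeds=seeds)
    seg = exvivo_scar(vol, wall, roi, remote, params)
    assert np.all(seg <= wall)
    assert seg.sum() == pytest.approx(lab.scar_mask().sum(), rel=0.10)


def test_threshold_monotonicity(small_pair):
    # raising the threshold never adds voxels
    vol, lab = small_pair["vol_in"], small_pair["lab_in"]
    wall = lab.wall_mask()
    seeds, _, _ = auto_seed_and_rois(vol, wall)
    lo = fwhm_scar(vol, wall, SegmentationParams(seeds=seeds, fwhm_fraction=0.4))
    hi = fwhm_scar(vol, wall, SegmentationParams(seeds=seeds, fwhm_fraction=0.6))
    assert np.all(hi <= lo)


def test_connected_component_filter_cases():
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[0, 0, 0] = True
    mask[1, 1, 1] = True  # diagonal touch
    # connectivity 26 joins the diagonal pair; 6 separates it
    joined = connected_component_filter(mask, [(0, 0, 0)], connectivity=26)
    assert joined.sum() == 2
    split = connected_component_filter(mask, [(0, 0, 0)], connectivity=6)
    assert split.sum() == 1
    # single blob with interior seed is unchanged
    blob = np.zeros((5, 5, 5), dtype=bool)
    blob[1:4, 1:4, 1:4] = True
    assert np.array_equal(connected_component_filter(blob, [(2, 2, 2)]), blob)
    # seeds outside the mask leave an empty result with a warning
    with pytest.warns(UserWarning):
        out = connected_component_filter(blob, [(0, 0, 0)])
    assert not out.any()


def test_downsample_uniform_block():
    lm = LabelMap(np.full((6, 6, 6), CAVITY, dtype=np.int16), 1.0, np.zeros(3))
    ds = downsample_labels(lm, 3.0)
    assert np.all(ds.data == CAVITY)
    assert ds.voxel_size_mm == 3.0


def test_downsample_tie_prefers_scar():
    data = np.zeros((2, 2, 2), dtype=np.int16)
    data.ravel()[:4] = SCAR
    data.ravel()[4:] = MYOCARDIUM
    lm = LabelMap(data, 1.0, np.zeros(3))
    ds = downsample_labels(lm, 2.0)
    assert ds.data.shape == (1, 1, 1)
    assert ds.data[0, 0, 0] == SCAR


def test_downsample_rejects_upsampling():
    lm = LabelMap(np.zeros((4, 4, 4), dtype=np.int16), 2.0, np.zeros(3))
    with pytest.raises(ValueError):
        downsample_labels(lm, 1.0)


def test_downsample_noninteger_ratio_preserves_geometry():
    data = np.zeros((9, 9, 9), dtype=np.int16)
    data[2:7, 2:7, 2:7] = MYOCARDIUM
    lm = LabelMap(data, 1.0, np.zeros(3))
    ds = downsample_labels(lm, 1.5)
    v_fine = (lm.data == MYOCARDIUM).sum() * lm.voxel_volume_mm3()
    v_coarse = (ds.data == MYOCARDIUM).sum() * ds.voxel_volume_mm3()
    assert v_coarse == pytest.approx(v_fine, rel=0.35)  # 5 mm cube, 1-voxel shell


def test_downsample_volume_within_surface_shell_bound():
    """Wall volume after majority downsampling stays within one
    coarse-voxel shell of the fine-grid wall surface, over 20 random
    phantoms."""
    rng = np.random.default_rng(11)
    for trial in range(20):
        a = rng.uniform(22, 30)
        b = rng.uniform(10, 14)
        spec = PhantomSpec(
            endo_semiaxes=(a, b, b),
            wall_thickness=rng.uniform(5.0, 7.0),
            invivo_voxel=2.5,
            exvivo_voxel=1.0,
            pad_mm=6.0,
            seed=int(rng.integers(1 << 30)),
        )
        _, lab_in, _ = make_invivo_phantom(spec)
        _, lab_ex, _, _ = make_exvivo_pair(spec, lab_in)
        ds = downsample_labels(lab_ex, 2.0)
        wall = lab_ex.wall_mask()
        # open-face count approximates the wall surface area in voxel faces
        faces = 0
        for ax in range(3):
            sl = np.diff(wall.astype(np.int8), axis=ax)
            faces += np.abs(sl).sum()
            faces += wall.take(0, axis=ax).sum() + wall.take(-1, axis=ax).sum()
        area = faces * lab_ex.voxel_size_mm**2
        bound = area * ds.voxel_size_mm
        v_fine = wall.sum() * lab_ex.voxel_volume_mm3()
        v_coarse = ds.wall_mask().sum() * ds.voxel_volume_mm3()
        assert abs(v_coarse - v_fine) < bound


def test_scar_mask_subset_of_wall(small_pair):
    vol, lab = small_pair["vol_in"], small_pair["lab_in"]
    wall = lab.wall_mask()
    seeds, _, _ = auto_seed_and_rois(vol, wall)
    seg = fwhm_scar(vol, wall, SegmentationParams(seeds=seeds))
    assert np.all(seg <= wall)
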