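"""Scar segmentation by intensity thresholding inside a given wall mask.

Two procedures, matching the different contrast of the two conditions:

* in-vivo LGE: full-width-at-half-maximum (FWHM) — scar is every wall voxel
  whose signal exceeds half of a robust reference maximum taken in the
  seeded enhancing region, then a connected-component filter keeps only
  components touching a seed;
* ex-vivo T1w: the lower scar boundary is one standard deviation below the
  mean signal of a user-supplied scar ROI, with the same connected-component
  seeding; an optional exclusion mask stands in for manual voxel deletion
  (no voxels are ever added).

Myocardium segmentation itself is taken as given (manual in the original
workflow, ground truth from the phantom here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BACKGROUND, LABEL_PRIORITY, LabelMap, Volume3D

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationParams:
    """Parameters of both thresholding procedures.

    ``fwhm_fraction``: fraction of the reference maximum (0.5 = half max).
    ``reference_percentile``: robust-max percentile among wall voxels in the
    seed neighbourhood. ``seed_radius_mm``: radius of that neighbourhood.
    ``sd_multiplier``: standard deviations below the scar-ROI mean for the
    ex-vivo threshold.  ``connectivity``: 6, 18 or 26.
    """

    fwhm_fraction: float = 0.5
    reference_percentile: float = 99.0
    seed_radius_mm: float = 6.0
    sd_multiplier: float = 1.0
    connectivity: int = 26
    seeds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.fwhm_fraction < 1:
            raise ValueError("fwhm_fraction must lie in (0, 1)")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class RegionOfInterest:
    """Voxel-index set on a label-map grid with a role tag."""

    indices: np.ndarray  # (N, 3) integer voxel indices
    role: str = "scar_roi"  # "scar_roi" | "remote_roi"

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValueError("ROI must be non-empty")
        if self.role not in ("scar_roi", "remote_roi"):
            raise ValueError("role must be scar_roi or remote_roi")

    def values(self, volume: Volume3D) -> np.ndarray:
        i, j, k = self.indices.T
        return np.asarray(volume.data)[i, j, k]


def connected_component_filter(
    mask: np.ndarray, seeds: list[tuple[int, int, int]], connectivity: int = 26
) -> np.ndarray:
    """Union of connected components of ``mask`` containing at least one seed.

    Seeds falling outside the mask are ignored with a warning; with no seeds
    inside the mask the result is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or not seeds:
        if seeds and not mask.any():
            warnings.warn("no seeds inside mask; empty result")
        return np.zeros_like(mask)
    lbl, _ = ndimage.label(mask, structure=_STRUCTS[connectivity])
    keep = set()
    outside = 0
    for s in seeds:
        v = lbl[tuple(int(c) for c in s)]
        if v == 0:
            outside += 1
        else:
            keep.add(int(v))
    if outside:
        warnings.warn(f"{outside} seed(s) outside mask ignored")
    if not keep:
        warnings.warn("no seeds inside mask; empty result")
        return np.zeros_like(mask)
    return np.isin(lbl, sorted(keep))


def _check_seeds(seeds, wall: np.ndarray) -> None:
    if not seeds:
        raise ValueError("seeds must be non-empty")
    for s in seeds:
        if not wall[tuple(int(c) for c in s)]:
            raise ValueError(f"seed {tuple(s)} outside the wall mask")


def fwhm_scar(
    invivo: Volume3D, wall: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """In-vivo FWHM scar mask.

    The reference maximum is the ``reference_percentile`` intensity among
    wall voxels within ``seed_radius_mm`` of any seed; the threshold is
    ``fwhm_fraction`` times that reference.  Voxels at or above threshold are
    kept only if connected (at ``params.connectivity``) to a seed.
    """
    wall = np.asarray(wall, dtype=bool)
    _check_seeds(params.seeds, wall)
    data = np.asarray(invivo.data, dtype=float)
    r_vox = max(1, int(round(params.seed_radius_mm / invivo.voxel_size_mm)))
    nb = np.zeros(wall.shape, dtype=bool)
    for s in params.seeds:
        nb[tuple(int(c) for c in s)] = True
    nb = ndimage.binary_dilation(nb, iterations=r_vox) & wall
    ref = np.percentile(data[nb], params.reference_percentile)
    threshold = params.fwhm_fraction * ref
    above = wall & (data >= threshold)
    if not above.any():
        warnings.warn("all wall voxels below FWHM threshold; empty scar mask")
        return above
    return connected_component_filter(above, params.seeds, params.connectivity)


def exvivo_scar(
    exvivo: Volume3D,
    wall: np.ndarray,
    scar_roi: RegionOfInterest,
    remote_roi: RegionOfInterest,
    params: SegmentationParams,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Ex-vivo scar mask by the mean-minus-k-SD rule.

    ``SI_scar = mean(scar ROI) - sd_multiplier * SD(scar ROI)``; wall voxels
    at or above ``SI_scar`` are kept if connected to a seed.  The optional
    ``exclusion_mask`` removes voxels (replacement for manual deletion);
    nothing is ever added.  Remote-ROI statistics are recorded for QC in the
    returned mask's companion dict (via ``exvivo_scar.last_qc``).
    """
    wall = np.asarray(wall, dtype=bool)
    _check_seeds(params.seeds, wall)
    vals = scar_roi.values(exvivo).astype(float)
    if len(vals) < 2 or float(np.std(vals)) == 0.0:
        raise ValueError("degenerate ROI: cannot estimate SD")
    si_scar = float(np.mean(vals) - params.sd_multiplier * np.std(vals, ddof=0))
    remote_vals = remote_roi.values(exvivo).astype(float)
    exvivo_scar.last_qc = {  # type: ignore[attr-defined]
        "si_scar": si_scar,
        "scar_roi_mean": float(np.mean(vals)),
        "scar_roi_sd": float(np.std(vals, ddof=0)),
        "remote_roi_mean": float(np.mean(remote_vals)),
        "remote_roi_sd": float(np.std(remote_vals, ddof=0)),
    }
    above = wall & (np.asarray(exvivo.data, dtype=float) >= si_scar)
    if exclusion_mask is not None:
        above &= ~np.asarray(exclusion_mask, dtype=bool)
    if not above.any():
        warnings.warn("all wall voxels below SI_scar; empty scar mask")
        return above
    return connected_component_filter(above, params.seeds, params.connectivity)


def scar_threshold_exvivo(scar_roi_values: np.ndarray, sd_multiplier: float = 1.0) -> float:
    """The stated threshold formula, exposed for direct use/QC."""
    v = np.asarray(scar_roi_values, dtype=float)
    return float(v.mean() - sd_multiplier * v.std(ddof=0))


def auto_seed_and_rois(
    volume: Volume3D,
    wall: np.ndarray,
    connectivity: int = 26,
    roi_radius_mm: float = 8.0,
    remote_margin_mm: float = 15.0,
    max_roi_voxels: int = 2000,
) -> tuple[list[tuple[int, int, int]], RegionOfInterest, RegionOfInterest]:
    """Deterministic stand-in for the observer's seed and ROI placement.

    Enhancing candidates are wall voxels above Otsu's threshold of the wall
    intensity histogram; the largest connected candidate component is the
    infarct territory.  The seed is that component's brightest voxel (after
    2 mm smoothing, for stability); the scar ROI is the ball of *wall*
    voxels around the component's central voxel — a representative patch
    of clear scar rather than the hottest spot; the remote ROI collects wall
    voxels far from any candidate.
    """
    from skimage.filters import threshold_otsu

    wall = np.asarray(wall, dtype=bool)
    data = np.asarray(volume.data, dtype=float)
    thr = threshold_otsu(data[wall])
    cand = wall & (data > thr)
    if not cand.any():
        raise ValueError("no enhancing wall voxels above Otsu threshold")
    lbl, ncomp = ndimage.label(cand, structure=_STRUCTS[connectivity])
    sizes = ndimage.sum_labels(cand, lbl, index=np.arange(1, ncomp + 1))
    comp = lbl == (1 + int(np.argmax(sizes)))
    smoothed = ndimage.gaussian_filter(data, 2.0 / volume.voxel_size_mm)
    comp_idx = np.argwhere(comp)
    seed = tuple(int(c) for c in comp_idx[np.argmax(smoothed[comp])])
    # representative interior patch: wall voxels near the component's center
    center = comp_idx.mean(axis=0)
    nearest = comp_idx[np.argmin(np.sum((comp_idx - center) ** 2, axis=1))]
    r_vox = roi_radius_mm / volume.voxel_size_mm
    wall_idx = np.argwhere(wall)
    ball = np.sum((wall_idx - nearest) ** 2, axis=1) <= r_vox**2
    scar_roi = RegionOfInterest(wall_idx[ball][:max_roi_voxels], "scar_roi")
    far = wall & ~ndimage.binary_dilation(
        cand, iterations=max(1, int(round(remote_margin_mm / volume.voxel_size_mm)))
    )
    if not far.any():
        far = wall & ~cand
    far_idx = np.argwhere(far)
    stride = max(1, len(far_idx) // max_roi_voxels)
    remote_roi = RegionOfInterest(far_idx[::stride], "remote_roi")
    return [seed], scar_roi, remote_roi


# ---------------------------------------------------------------------------
# label downsampling
# ---------------------------------------------------------------------------


def downsample_labels(fine: LabelMap, target_voxel_mm: float) -> LabelMap:
    """Majority-vote downsampling of a label map to a coarser isotropic grid.

    Integer voxel ratios use an exact block majority; non-integer ratios fall
    back to world-space box averaging of per-label indicator fractions.  Ties
    are broken by the fixed priority scar > cavity > myocardium > aorta >
    background.
    """
    if target_voxel_mm < fine.voxel_size_mm - 1e-9:
        raise ValueError("target voxel must be >= fine voxel")
    ratio = target_voxel_mm / fine.voxel_size_mm
    data = np.asarray(fine.data)
    if abs(ratio - round(ratio)) < 1e-8:
        r = int(round(ratio))
        # pad up to a multiple of r with background
        pad = [(0, (-s) % r) for s in data.shape]
        padded = np.pad(data, pad, constant_values=BACKGROUND)
        ns = tuple(s // r for s in padded.shape)
        blocks = padded.reshape(ns[0], r, ns[1], r, ns[2], r)
        counts = np.stack(
            [(blocks == lab).sum(axis=(1, 3, 5)) for lab in LABEL_PRIORITY]
        )
        out = np.asarray(LABEL_PRIORITY, dtype=data.dtype)[counts.argmax(axis=0)]
        origin = fine.origin_mm + (r - 1) / 2.0 * fine.voxel_size_mm
    else:
        # world-space box averaging of indicator fractions via zoom
        from scipy.ndimage import zoom

        ns = tuple(max(1, int(np.ceil(s / ratio))) for s in data.shape)
        fracs = []
        for lab in LABEL_PRIORITY:
            ind = (data == lab).astype(float)
            fracs.append(zoom(ind, [n / s for n, s in zip(ns, data.shape)], order=1))
        counts = np.stack(fracs)
        out = np.asarray(LABEL_PRIORITY, dtype=data.dtype)[counts.argmax(axis=0)]
        origin = fine.origin_mm + (ratio - 1) / 2.0 * fine.voxel_size_mm
    return LabelMap(out, target_voxel_mm, origin, dict(fine.meta))
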