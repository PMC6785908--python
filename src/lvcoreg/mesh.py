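"""Surface extraction and projection morphometry.

Endocardial and epicardial surfaces are extracted from binary segmentations
by marching cubes, truncated at the MV disc plane and lightly smoothed.
The projection operators follow the literal construction: each endocardial
node is joined to its *nearest* epicardial node by a straight segment;
wall thickness is the segment length, a node is scar if at least one sample
along the segment falls inside a scar voxel, and transmurality is the
fraction of samples inside scar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .core import CAVITY, MYOCARDIUM, SCAR, LabelMap


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-node attributes (world mm)."""

    vertices: np.ndarray  # (N, 3)
    faces: np.ndarray  # (M, 3) int
    attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.vertices)

    def with_attr(self, name: str, values: np.ndarray) -> "SurfaceMesh":
        if len(values) != len(self.vertices):
            raise ValueError("attribute length must match node count")
        self.attrs[name] = np.asarray(values)
        return self

    def transformed(self, transform) -> "SurfaceMesh":
        """New mesh with vertices mapped through a point transform."""
        return SurfaceMesh(transform.apply(self.vertices), self.faces.copy(), dict(self.attrs))

    def surface_area(self) -> float:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2)


@dataclass
class ProjectionRecords:
    """Vectorized endo->nearest-epi projection segments."""

    endo_idx: np.ndarray
    epi_idx: np.ndarray
    lengths: np.ndarray  # mm
    endo_points: np.ndarray
    epi_points: np.ndarray

    def __len__(self) -> int:
        return len(self.endo_idx)


def _laplacian_smooth(
    vertices: np.ndarray, faces: np.ndarray, iterations: int = 5, lam: float = 0.5
) -> np.ndarray:
    """Uniform-weight Laplacian smoothing with boundary vertices fixed."""
    n = len(vertices)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary_v = np.unique(uniq[counts == 1])
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    A = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    A.data[:] = 1.0  # duplicate edges collapse to unit weight
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = vertices.copy()
    interior = np.ones(n, dtype=bool)
    interior[boundary_v] = False
    for _ in range(iterations):
        mean = A @ v / deg[:, None]
        v[interior] += lam * (mean[interior] - v[interior])
    return v


def extract_surface(
    labels: LabelMap, which: str, smooth_iterations: int = 5
) -> SurfaceMesh:
    """Marching-cubes surface of the endo- or epicardial interface.

    ``which``: ``"endo"`` (cavity/wall boundary) or ``"epi"`` (outer wall
    boundary).  The iso-surface is taken at level 0.5 on the binary
    indicator, truncated at the MV disc plane stored in the label map's
    metadata and smoothed by 5 fixed Laplacian iterations (boundary ring
    held in place).  A disconnected mask keeps its largest component with a
    warning.
    """
    if which not in ("endo", "epi"):
        raise ValueError("which must be 'endo' or 'epi'")
    if which == "endo":
        mask = labels.mask(CAVITY)
        if not mask.any():
            raise ValueError("empty cavity: cannot extract endocardium")
    else:
        mask = labels.mask(CAVITY, MYOCARDIUM, SCAR)
        if not mask.any():
            raise ValueError("empty wall: cannot extract epicardium")
    lbl, ncomp = ndimage.label(mask)
    if ncomp > 1:
        warnings.warn(f"{which} mask has {ncomp} components; using largest")
        sizes = ndimage.sum_labels(mask, lbl, index=np.arange(1, ncomp + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    v = labels.voxel_size_mm
    verts, faces, _, _ = marching_cubes(
        np.pad(mask, 1).astype(np.uint8), level=0.5, spacing=(v, v, v)
    )
    verts = verts - v + labels.origin_mm  # undo pad, to world
    plane = labels.mv_plane
    if plane is not None:
        depth = plane.depth_below(verts)
        keep_face = (depth[faces] >= 0.75 * v).all(axis=1)
        faces = faces[keep_face]
        used = np.unique(faces)
        remap = -np.ones(len(verts), dtype=int)
        remap[used] = np.arange(len(used))
        verts = verts[used]
        faces = remap[faces]
    if smooth_iterations > 0 and len(faces):
        verts = _laplacian_smooth(verts, faces, iterations=smooth_iterations)
    return SurfaceMesh(verts, faces)


def pair_nearest_epi(endo: SurfaceMesh, epi: SurfaceMesh) -> ProjectionRecords:
    """Pair every endocardial node with its nearest epicardial node.

    Distance ties resolve to the lowest epicardial index (KD-tree contract).
    """
    if len(endo) == 0 or len(epi) == 0:
        raise ValueError("meshes must be non-empty")
    dist, idx = cKDTree(epi.vertices).query(endo.vertices)
    return ProjectionRecords(
        endo_idx=np.arange(len(endo)),
        epi_idx=idx,
        lengths=dist,
        endo_points=endo.vertices,
        epi_points=epi.vertices[idx],
    )


def wall_thickness(records: ProjectionRecords) -> np.ndarray:
    """Per-node wall thickness = projection segment length (mm)."""
    return records.lengths.copy()


def nodal_scar_and_transmurality(
    records: ProjectionRecords,
    scar: LabelMap | None = None,
    scar_mask: np.ndarray | None = None,
    grid: LabelMap | None = None,
    sample_step_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample each projection segment against the scar segmentation.

    Samples are evenly spaced at no more than half a voxel (endpoints
    included); a point lies in a voxel under the half-open box convention.
    Returns ``(scar_flag, transmurality)`` per endocardial node; zero-length
    segments get transmurality 0 with the flag taken from the single sample.
    """
    if scar is not None:
        mask = scar.scar_mask()
        geom = scar
    else:
        if scar_mask is None or grid is None:
            raise ValueError("provide a scar LabelMap or (scar_mask, grid)")
        mask = np.asarray(scar_mask, dtype=bool)
        geom = grid
    step = sample_step_mm or 0.5 * geom.voxel_size_mm
    n = len(records)
    nsamp = np.maximum(np.ceil(records.lengths / step).astype(int), 1) + 1
    nmax = int(nsamp.max())
    # per-node sample parameter j/(nsamp-1); samples beyond nsamp are masked
    j = np.arange(nmax)[None, :]
    denom = np.maximum(nsamp - 1, 1)[:, None]
    t = j / denom
    valid = j < nsamp[:, None]
    seg = records.epi_points - records.endo_points
    pts = records.endo_points[:, None, :] + t[:, :, None] * seg[:, None, :]
    idx = np.floor(
        (pts - geom.origin_mm) / geom.voxel_size_mm + 0.5
    ).astype(int)
    # +0.5: voxel i spans [origin + (i-0.5)v, origin + (i+0.5)v) (half-open)
    inb = np.all((idx >= 0) & (idx < np.asarray(geom.shape)), axis=2) & valid
    hit = np.zeros((n, nmax), dtype=bool)
    ii = idx[inb]
    hit[inb] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    n_in = hit.sum(axis=1)
    total = valid.sum(axis=1)
    flag = n_in > 0
    trans = n_in / total
    zero_len = records.lengths <= 0
    trans[zero_len] = 0.0
    return flag, np.clip(trans, 0.0, 1.0)


def nodal_dice_scar(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> float:
    """Nodal-wise scar DICE between two endocardial meshes.

    Each node of ``mesh_a`` pairs with its nearest node of ``mesh_b``;
    DICE = 2 |both scar| / (|a scar| + |b scar mapped|).  Returns 1 with a
    warning when neither mesh carries any scar node.
    """
    for m in (mesh_a, mesh_b):
        if "scar_flag" not in m.attrs:
            raise ValueError("meshes must carry a 'scar_flag' attribute")
    fa = np.asarray(mesh_a.attrs["scar_flag"], dtype=bool)
    _, idx = cKDTree(mesh_b.vertices).query(mesh_a.vertices)
    fb = np.asarray(mesh_b.attrs["scar_flag"], dtype=bool)[idx]
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        warnings.warn("no scar nodes on either mesh; DICE defined as 1")
        return 1.0
    return float(2.0 * np.sum(fa & fb) / denom)


def measure_lv_dimensions(labels: LabelMap) -> tuple[float, float, float]:
    """LV long-axis and two basal short-axis cavity dimensions (mm).

    Long axis: distance from the cavity point farthest below the MV plane
    (the apex) to that plane.  Short axes: extents of the cavity
    cross-section along its two principal directions, measured in the slab
    parallel to the MV disc at 25% of the long axis below it.
    """
    plane = labels.mv_plane
    if plane is None:
        raise ValueError("label map lacks MV plane metadata")
    cav = labels.cavity_mask()
    if not cav.any():
        raise ValueError("empty cavity")
    ii, jj, kk = np.nonzero(cav)
    pts = labels.origin_mm + labels.voxel_size_mm * np.column_stack([ii, jj, kk]).astype(float)
    depth = plane.depth_below(pts)
    long_axis = float(depth.max())
    level = 0.25 * long_axis
    half = labels.voxel_size_mm / 2
    sel = np.abs(depth - level) <= half
    if not sel.any():
        raise ValueError("basal slice empty")
    slab = pts[sel]
    nrm = np.asarray(plane.normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    # in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(nrm @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(nrm, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nrm, e1)
    xy = np.column_stack([slab @ e1, slab @ e2])
    xy = xy - xy.mean(axis=0)
    cov = np.cov(xy.T) if len(xy) > 1 else np.eye(2)
    _, vecs = np.linalg.eigh(cov)
    proj = xy @ vecs
    d1 = float(np.ptp(proj[:, 1])) + labels.voxel_size_mm
    d2 = float(np.ptp(proj[:, 0])) + labels.voxel_size_mm
    return long_axis, d1, d2
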