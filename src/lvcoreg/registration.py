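"""Co-registration chain: landmark rigid fit, image-based rigid and affine
refinement, and multi-level cubic B-spline free-form deformation (FFD).

All transforms map world points of the *fixed* space (in-vivo) to the
*moving* space (ex-vivo, downsampled), so resampling the moving image onto
the fixed grid needs only forward evaluation.  The image metric is the mean
sum-of-squared-differences over Gaussian-smoothed per-label indicator
channels (myocardial wall, cavity, scar weighted equally) — segmentations
are binary, and smoothing gives usable gradients.

The FFD is the classic lattice-of-control-points model: displacement is a
cubic B-spline interpolation of per-control-point coefficients, optimized
level by level (default control spacings 20, 10, 5 mm paired with image
pyramid factors 4, 2, 1) with a bending-energy penalty; the total transform
is the initial affine plus the sum of the per-level displacement fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import BACKGROUND, CAVITY, LABEL_PRIORITY, LabelMap, MYOCARDIUM, SCAR, Volume3D
from .phantom import LandmarkSet


# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """x_moving = R @ x_fixed + t, with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_affine(self) -> "AffineTransform":
        return AffineTransform(self.rotation.copy(), self.translation.copy())

    def to_dict(self) -> dict:
        return {
            "type": "rigid",
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }


@dataclass
class AffineTransform:
    """x_moving = A @ x_fixed + t, with A any invertible matrix."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.matrix)
        return AffineTransform(Ainv, -Ainv @ self.translation)

    def to_dict(self) -> dict:
        return {
            "type": "affine",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
        }


@dataclass
class BsplineLevel:
    """One FFD level: a control-point lattice with vector coefficients."""

    origin: np.ndarray  # lattice origin (world mm of control point (0,0,0))
    spacing: float  # control spacing (mm)
    coeffs: np.ndarray  # (n0, n1, n2, 3) displacement coefficients (mm)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return _bspline_eval(self.coeffs, self.origin, self.spacing, points)


@dataclass
class FFDTransform:
    """Composed transform: initial affine plus summed B-spline displacements.

    ``apply(x) = A x + t + sum_l u_l(x)`` — applying the full chain equals
    applying this composition by construction.
    """

    affine: AffineTransform
    levels: list[BsplineLevel] = field(default_factory=list)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.affine.apply(pts)
        for lev in self.levels:
            out = out + lev.displacement(pts)
        return out

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.zeros_like(pts)
        for lev in self.levels:
            d += lev.displacement(pts)
        return d

    def invert_points(
        self, points_moving: np.ndarray, iters: int = 50, tol: float = 1e-6
    ) -> np.ndarray:
        """Numerically invert: solve apply(x) = y by fixed-point iteration
        x <- A^-1 (y - u(x)), which converges for moderate displacements."""
        y = np.atleast_2d(np.asarray(points_moving, dtype=float))
        ainv = self.affine.inverse()
        x = ainv.apply(y)
        for _ in range(iters):
            x_new = ainv.apply(y - self.displacement(x))
            if np.max(np.abs(x_new - x)) < tol:
                x = x_new
                break
            x = x_new
        return x

    def max_control_displacement(self) -> float:
        if not self.levels:
            return 0.0
        return max(float(np.abs(l.coeffs).max()) for l in self.levels)

    def to_dict(self) -> dict:
        return {
            "type": "ffd",
            "affine": self.affine.to_dict(),
            "levels": [
                {
                    "origin": l.origin.tolist(),
                    "spacing": l.spacing,
                    "shape": list(l.coeffs.shape[:3]),
                    "coeffs": l.coeffs.ravel().tolist(),
                }
                for l in self.levels
            ],
        }


def transform_from_dict(d: dict):
    if d["type"] == "rigid":
        return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"]))
    if d["type"] == "affine":
        return AffineTransform(np.asarray(d["matrix"]), np.asarray(d["translation"]))
    if d["type"] == "ffd":
        aff = transform_from_dict(d["affine"])
        levels = [
            BsplineLevel(
                np.asarray(l["origin"]),
                float(l["spacing"]),
                np.asarray(l["coeffs"]).reshape(tuple(l["shape"]) + (3,)),
            )
            for l in d["levels"]
        ]
        return FFDTransform(aff, levels)
    raise ValueError(f"unknown transform type {d['type']!r}")


@dataclass
class RegistrationConfig:
    """Settings of the image-based chain (declared defaults, see docs)."""

    smoothing_sigma_mm: float = 1.5
    control_spacings_mm: tuple[float, ...] = (20.0, 10.0, 5.0)
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    bending_weight: float = 1e-3
    max_iterations: int = 60
    gradient_tolerance: float = 1e-7
    channel_labels: tuple = ((MYOCARDIUM, SCAR), (CAVITY,), (SCAR,))
    seed: int = 0

    def __post_init__(self) -> None:
        sp = self.control_spacings_mm
        if any(sp[i] <= sp[i + 1] for i in range(len(sp) - 1)):
            raise ValueError("control spacings must be strictly decreasing")
        if self.bending_weight < 0:
            raise ValueError("bending weight must be >= 0")
        if len(self.pyramid_factors) != len(sp):
            raise ValueError("one pyramid factor per control spacing level")


# ---------------------------------------------------------------------------
# landmark rigid fit
# ---------------------------------------------------------------------------


def fit_rigid_landmarks(
    moving: LandmarkSet, fixed: LandmarkSet
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit over shared landmark names.

    Orthogonal Procrustes on centered coordinates with reflection correction;
    returns the transform mapping fixed-space points to moving-space points
    and the residual RMS in mm.
    """
    shared = [n for n in fixed.names if n in moving.names]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared landmark names")
    P = np.array([fixed.get(n) for n in shared])  # fixed
    Q = np.array([moving.get(n) for n in shared])  # moving
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    s = np.linalg.svd(Pc, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("rank deficient: landmarks are collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    tr = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((tr.apply(P) - Q) ** 2, axis=1))))
    return tr, rms


# ---------------------------------------------------------------------------
# metric machinery
# ---------------------------------------------------------------------------


@dataclass
class _ChannelImage:
    """Smoothed indicator channels of a label map at one pyramid level."""

    channels: np.ndarray  # (C, nx, ny, nz)
    voxel: float
    origin: np.ndarray

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Linear interpolation of all channels at world points -> (C, N)."""
        idx = (np.atleast_2d(points) - self.origin) / self.voxel
        return np.stack(
            [
                ndimage.map_coordinates(c, idx.T, order=1, mode="constant", cval=0.0)
                for c in self.channels
            ]
        )

    def sample_with_gradient(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Values (C, N) and spatial gradients (C, N, 3) in 1/mm."""
        idx = (np.atleast_2d(points) - self.origin) / self.voxel
        vals = []
        grads = []
        if not hasattr(self, "_grad_cache"):
            self._grad_cache = [np.gradient(c, self.voxel) for c in self.channels]
        for c, gc in zip(self.channels, self._grad_cache):
            vals.append(
                ndimage.map_coordinates(c, idx.T, order=1, mode="constant", cval=0.0)
            )
            grads.append(
                np.stack(
                    [
                        ndimage.map_coordinates(
                            g, idx.T, order=1, mode="constant", cval=0.0
                        )
                        for g in gc
                    ],
                    axis=-1,
                )
            )
        return np.stack(vals), np.stack(grads)


def _make_channels(
    labels: LabelMap, cfg: RegistrationConfig, factor: int = 1
) -> _ChannelImage:
    """Smoothed per-label indicator channels, optionally subsampled."""
    chans = []
    sigma_vox = cfg.smoothing_sigma_mm / labels.voxel_size_mm
    for labs in cfg.channel_labels:
        ind = np.isin(labels.data, labs).astype(float)
        # extra smoothing proportional to the subsampling factor (anti-alias)
        s = np.hypot(sigma_vox, 0.5 * max(factor - 1, 0))
        chans.append(ndimage.gaussian_filter(ind, s))
    arr = np.stack(chans)
    if factor > 1:
        arr = arr[:, ::factor, ::factor, ::factor]
    return _ChannelImage(
        channels=arr,
        voxel=labels.voxel_size_mm * factor,
        origin=labels.origin_mm.copy(),
    )


def _fixed_points_and_values(
    fixed: _ChannelImage, margin_vox: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed voxel centers inside the union support of the channels."""
    support = fixed.channels.max(axis=0) > 1e-4
    support = ndimage.binary_dilation(support, iterations=margin_vox)
    ii, jj, kk = np.nonzero(support)
    pts = fixed.origin + fixed.voxel * np.column_stack([ii, jj, kk]).astype(float)
    vals = fixed.channels[:, ii, jj, kk]
    return pts, vals


def _metric_value(
    moving: _ChannelImage, pts_fixed: np.ndarray, vals_fixed: np.ndarray, mapped: np.ndarray
) -> float:
    mvals = moving.sample(mapped)
    return float(np.mean((mvals - vals_fixed) ** 2))


# ---------------------------------------------------------------------------
# rigid / affine image registration
# ---------------------------------------------------------------------------


def _rotvec_to_matrix(r: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(r)
    if theta < 1e-12:
        K = _skew(r)
        return np.eye(3) + K
    k = r / theta
    K = _skew(k)
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    cos = np.clip((np.trace(R) - 1) / 2, -1.0, 1.0)
    theta = np.arccos(cos)
    if theta < 1e-8:
        return np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / 2
    axis = (
        np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        / (2 * np.sin(theta))
    )
    return axis * theta


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
    )


def _check_overlap(fixed: LabelMap, moving: LabelMap, init) -> None:
    """Error if the initialized fixed bounding box misses the moving image."""
    lo = fixed.origin_mm
    hi = fixed.origin_mm + np.asarray(fixed.shape) * fixed.voxel_size_mm
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    mapped = init.apply(corners)
    mlo = moving.origin_mm
    mhi = moving.origin_mm + np.asarray(moving.shape) * moving.voxel_size_mm
    if np.any(mapped.max(axis=0) < mlo) or np.any(mapped.min(axis=0) > mhi):
        raise ValueError("empty overlap of bounding boxes after initialization")


def register_rigid(
    fixed: LabelMap,
    moving: LabelMap,
    init: RigidTransform | None = None,
    cfg: RegistrationConfig | None = None,
) -> RigidTransform:
    """Six-parameter rigid refinement of the multi-channel SSD metric.

    Never degrades the metric relative to ``init`` (falls back to it)."""
    cfg = cfg or RegistrationConfig()
    init = init or RigidTransform.identity()
    _check_overlap(fixed, moving, init)
    center = fixed.origin_mm + np.asarray(fixed.shape) * fixed.voxel_size_mm / 2

    result = init
    for factor in cfg.pyramid_factors[:-1] if len(cfg.pyramid_factors) > 1 else cfg.pyramid_factors:
        fch = _make_channels(fixed, cfg, factor)
        mch = _make_channels(moving, cfg, factor)
        pts, vals = _fixed_points_and_values(fch)

        r0 = _matrix_to_rotvec(result.rotation)
        # parameterize about the image center for decorrelated parameters
        t0 = result.apply(center)[0] - center

        def loss(p: np.ndarray) -> float:
            R = _rotvec_to_matrix(p[3:])
            mapped = (pts - center) @ R.T + center + p[:3]
            return _metric_value(mch, pts, vals, mapped)

        x0 = np.concatenate([t0, r0])
        res = optimize.minimize(
            loss,
            x0,
            method="L-BFGS-B",
            options={"maxiter": cfg.max_iterations, "eps": 1e-4},
        )
        p = res.x if res.fun <= loss(x0) else x0
        R = _rotvec_to_matrix(p[3:])
        t = p[:3] + center - R @ center
        result = RigidTransform(R, t)
    return result


def register_affine(
    fixed: LabelMap,
    moving: LabelMap,
    init: RigidTransform | AffineTransform | None = None,
    cfg: RegistrationConfig | None = None,
) -> AffineTransform:
    """Twelve-parameter affine refinement (captures global anisotropic
    scaling such as the ex-vivo cavity shrinkage)."""
    cfg = cfg or RegistrationConfig()
    if init is None:
        init = AffineTransform.identity()
    if isinstance(init, RigidTransform):
        init = init.to_affine()
    _check_overlap(fixed, moving, init)
    center = fixed.origin_mm + np.asarray(fixed.shape) * fixed.voxel_size_mm / 2
    # matrix entries scaled so a unit parameter step moves points by ~1 mm
    mat_scale = float(np.asarray(fixed.shape).max() * fixed.voxel_size_mm / 2)

    result = init
    factors = list(cfg.pyramid_factors)
    # coarse levels do the work; a short full-resolution pass polishes the
    # global scales that the FFD cannot efficiently represent
    schedule = [(f, cfg.max_iterations) for f in factors[:-1]] or [
        (factors[0], cfg.max_iterations)
    ]
    if len(factors) > 1:
        schedule.append((factors[-1], min(15, cfg.max_iterations)))
    for factor, maxiter in schedule:
        fch = _make_channels(fixed, cfg, factor)
        mch = _make_channels(moving, cfg, factor)
        pts, vals = _fixed_points_and_values(fch)

        A0 = result.matrix
        t0 = result.apply(center)[0] - center

        def loss(p: np.ndarray) -> float:
            A = A0 + p[3:].reshape(3, 3) / mat_scale
            mapped = (pts - center) @ A.T + center + p[:3]
            return _metric_value(mch, pts, vals, mapped)

        x0 = np.zeros(12)
        x0[:3] = t0
        res = optimize.minimize(
            loss,
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "eps": 1e-4},
        )
        p = res.x if res.fun <= loss(x0) else x0
        A = A0 + p[3:].reshape(3, 3) / mat_scale
        if abs(np.linalg.det(A)) < 1e-8:
            warnings.warn("singular affine update rejected")
            continue
        t = p[:3] + center - A @ center
        result = AffineTransform(A, t)
    return result


# ---------------------------------------------------------------------------
# cubic B-spline FFD
# ---------------------------------------------------------------------------


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis weights for fractional offsets t in [0,1).

    Returns (4, N): weights of control points floor(g)-1 .. floor(g)+2.
    """
    t2 = t * t
    t3 = t2 * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ]
    )


def _lattice_coords(points: np.ndarray, origin: np.ndarray, spacing: float):
    g = (np.atleast_2d(points) - origin) / spacing
    i = np.floor(g).astype(int)
    t = g - i
    return i, t


def _bspline_eval(
    coeffs: np.ndarray, origin: np.ndarray, spacing: float, points: np.ndarray
) -> np.ndarray:
    """Evaluate the vector B-spline at world points -> (N, 3)."""
    n = coeffs.shape[:3]
    i, t = _lattice_coords(points, origin, spacing)
    w = [_bspline_weights(t[:, d]) for d in range(3)]
    out = np.zeros((len(i), 3))
    for a in range(4):
        ia = np.clip(i[:, 0] - 1 + a, 0, n[0] - 1)
        wa = w[0][a]
        for b in range(4):
            ib = np.clip(i[:, 1] - 1 + b, 0, n[1] - 1)
            wab = wa * w[1][b]
            for c in range(4):
                ic = np.clip(i[:, 2] - 1 + c, 0, n[2] - 1)
                out += (wab * w[2][c])[:, None] * coeffs[ia, ib, ic]
    return out


def _bspline_adjoint(
    shape: tuple[int, int, int],
    origin: np.ndarray,
    spacing: float,
    points: np.ndarray,
    vectors: np.ndarray,
) -> np.ndarray:
    """Adjoint of evaluation: scatter per-point vectors into coefficients."""
    n0, n1, n2 = shape
    i, t = _lattice_coords(points, origin, spacing)
    w = [_bspline_weights(t[:, d]) for d in range(3)]
    out = np.zeros((n0 * n1 * n2, 3))
    for a in range(4):
        ia = np.clip(i[:, 0] - 1 + a, 0, n0 - 1)
        wa = w[0][a]
        for b in range(4):
            ib = np.clip(i[:, 1] - 1 + b, 0, n1 - 1)
            wab = wa * w[1][b]
            base = (ia * n1 + ib) * n2
            for c in range(4):
                ic = np.clip(i[:, 2] - 1 + c, 0, n2 - 1)
                wabc = wab * w[2][c]
                idx = base + ic
                for d in range(3):
                    out[:, d] += np.bincount(
                        idx, weights=wabc * vectors[:, d], minlength=n0 * n1 * n2
                    )
    return out.reshape(n0, n1, n2, 3)


def _bending_value_grad(coeffs: np.ndarray) -> tuple[float, np.ndarray]:
    """Approximate bending energy via second differences of coefficients.

    Zero for any affine coefficient field (all second differences vanish).
    Normalized by the number of control points so the weight is
    lattice-size independent.
    """
    grad = np.zeros_like(coeffs)
    value = 0.0
    npts = float(np.prod(coeffs.shape[:3]))

    def second_diff(arr, axis):
        sl = [slice(None)] * 4
        sl_m = list(sl)
        sl_c = list(sl)
        sl_p = list(sl)
        sl_m[axis] = slice(0, -2)
        sl_c[axis] = slice(1, -1)
        sl_p[axis] = slice(2, None)
        return arr[tuple(sl_m)] - 2 * arr[tuple(sl_c)] + arr[tuple(sl_p)]

    def add_adjoint(target, d2, axis, w):
        sl = [slice(None)] * 4
        sl_m = list(sl)
        sl_c = list(sl)
        sl_p = list(sl)
        sl_m[axis] = slice(0, -2)
        sl_c[axis] = slice(1, -1)
        sl_p[axis] = slice(2, None)
        target[tuple(sl_m)] += w * d2
        target[tuple(sl_c)] += -2 * w * d2
        target[tuple(sl_p)] += w * d2

    def mixed_diff(arr, ax0, ax1):
        def d1(a, axis):
            sl_p = [slice(None)] * 4
            sl_m = [slice(None)] * 4
            sl_p[axis] = slice(1, None)
            sl_m[axis] = slice(0, -1)
            return a[tuple(sl_p)] - a[tuple(sl_m)]

        return d1(d1(arr, ax0), ax1)

    def add_mixed_adjoint(target, d2, ax0, ax1, w):
        def d1t(a, axis, full_shape):
            out = np.zeros(full_shape)
            sl_p = [slice(None)] * 4
            sl_m = [slice(None)] * 4
            sl_p[axis] = slice(1, None)
            sl_m[axis] = slice(0, -1)
            out[tuple(sl_p)] += a
            out[tuple(sl_m)] -= a
            return out

        shp1 = list(target.shape)
        shp1[ax0] -= 1
        tmp = d1t(d2, ax1, tuple(shp1))
        target += w * d1t(tmp, ax0, target.shape)

    for ax in range(3):
        d2 = second_diff(coeffs, ax)
        value += np.sum(d2**2)
        add_adjoint(grad, 2 * d2, ax, 1.0)
    for ax0, ax1 in ((0, 1), (0, 2), (1, 2)):
        d2 = mixed_diff(coeffs, ax0, ax1)
        value += 2.0 * np.sum(d2**2)
        add_mixed_adjoint(grad, 4 * d2, ax0, ax1, 1.0)
    return value / npts, grad / npts


def _make_lattice(
    fixed: LabelMap, spacing: float
) -> tuple[np.ndarray, tuple[int, int, int]]:
    lo = fixed.origin_mm - 2.0 * spacing
    hi = fixed.origin_mm + np.asarray(fixed.shape) * fixed.voxel_size_mm + 2.0 * spacing
    n = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 4 for d in range(3))
    return lo, n


def register_ffd(
    fixed: LabelMap,
    moving: LabelMap,
    init: AffineTransform | RigidTransform | None = None,
    cfg: RegistrationConfig | None = None,
) -> FFDTransform:
    """Multi-level FFD optimization of the channel metric plus bending energy.

    The metric is non-increasing across levels (each level starts from the
    previous state and L-BFGS-B only accepts decreases); reproducible given
    config (the method is deterministic; no stochastic sampling is used)."""
    cfg = cfg or RegistrationConfig()
    if init is None:
        init = AffineTransform.identity()
    if isinstance(init, RigidTransform):
        init = init.to_affine()
    result = FFDTransform(affine=init, levels=[])

    for spacing, factor in zip(cfg.control_spacings_mm, cfg.pyramid_factors):
        fch = _make_channels(fixed, cfg, factor)
        mch = _make_channels(moving, cfg, factor)
        pts, vals = _fixed_points_and_values(fch)
        base = result.apply(pts)  # affine + previously optimized levels
        lat_origin, lat_shape = _make_lattice(fixed, spacing)
        coeffs0 = np.zeros(lat_shape + (3,))
        nvox = len(pts)

        def value_and_grad(x: np.ndarray):
            coeffs = x.reshape(lat_shape + (3,))
            disp = _bspline_eval(coeffs, lat_origin, spacing, pts)
            mapped = base + disp
            mvals, mgrads = mch.sample_with_gradient(mapped)
            resid = mvals - vals  # (C, N)
            value = float(np.mean(resid**2))
            # dE/d(mapped) = 2/(C*N) * sum_c resid_c * grad_c
            pt_grad = np.einsum("cn,cnd->nd", resid, mgrads) * (
                2.0 / (resid.shape[0] * nvox)
            )
            g = _bspline_adjoint(lat_shape, lat_origin, spacing, pts, pt_grad)
            if cfg.bending_weight > 0:
                bv, bg = _bending_value_grad(coeffs)
                value += cfg.bending_weight * bv
                g = g + cfg.bending_weight * bg
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(
                    f"non-finite gradient at spacing {spacing} mm"
                )
            return value, g.ravel()

        res = optimize.minimize(
            value_and_grad,
            coeffs0.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": cfg.max_iterations,
                "gtol": cfg.gradient_tolerance,
                "maxcor": 10,
            },
        )
        coeffs = res.x.reshape(lat_shape + (3,))
        result.levels.append(BsplineLevel(lat_origin, spacing, coeffs))
    return result


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def apply_transform(
    source: Volume3D | LabelMap,
    transform,
    target_grid: Volume3D | LabelMap,
) -> Volume3D | LabelMap:
    """Resample ``source`` onto ``target_grid`` through a fixed->moving map.

    Scalar volumes use trilinear interpolation; label maps use per-label
    indicator interpolation followed by argmax with the fixed tie priority
    (scar > cavity > myocardium > aorta > background).  Out-of-domain points
    become background/0.
    """
    pts = _grid_points_of(target_grid)
    mapped = transform.apply(pts)
    idx = ((mapped - source.origin_mm) / source.voxel_size_mm).T
    if isinstance(source, LabelMap):
        stacked = np.stack(
            [
                ndimage.map_coordinates(
                    (source.data == lab).astype(float),
                    idx,
                    order=1,
                    mode="constant",
                    cval=1.0 if lab == BACKGROUND else 0.0,
                )
                for lab in LABEL_PRIORITY
            ]
        )
        out = np.asarray(LABEL_PRIORITY, dtype=source.data.dtype)[
            stacked.argmax(axis=0)
        ]
        return LabelMap(
            out.reshape(target_grid.shape),
            target_grid.voxel_size_mm,
            target_grid.origin_mm.copy(),
            dict(target_grid.meta),
        )
    out = ndimage.map_coordinates(
        np.asarray(source.data, dtype=float), idx, order=1, mode="constant", cval=0.0
    )
    return Volume3D(
        out.reshape(target_grid.shape),
        target_grid.voxel_size_mm,
        target_grid.origin_mm.copy(),
        dict(target_grid.meta),
    )


def _grid_points_of(grid: Volume3D) -> np.ndarray:
    ax = [grid.origin_mm[d] + grid.voxel_size_mm * np.arange(grid.shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
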