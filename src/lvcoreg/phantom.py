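"""Synthetic paired in-vivo / ex-vivo left-ventricle phantom.

The in-vivo LV is a truncated thick-walled ellipsoid: the cavity is the
interior of an endocardial ellipsoid (long axis along +z, apex at negative z),
the wall is the outward normal offset of that surface by a uniform thickness,
and an antero-septal scar sector with a prescribed transmural profile sits
inside the wall.  Everything is cut at a flat mitral-valve (MV) disc plane.

The ex-vivo pair is produced by an *analytic* deformation with an analytic
inverse, built in shell coordinates (endocardial foot point + normal offset):

* the endocardial surface is scaled anisotropically about the cavity centroid
  (defaults encode the measured ex-vivo/in-vivo axis ratios 0.83 long / 0.81
  short);
* the local wall thickness is multiplied by a region factor selected by the
  ground-truth scar transmurality (healthy 1.29, 0-50% transmural 1.05,
  50-100% transmural 0.98), blended smoothly over a 5 mm band.

Because outward normal offsets of a convex surface never fold, the map has a
positive Jacobian throughout the wall and labels on the fine ex-vivo grid can
be computed by exact geometric membership of the inverse-mapped point rather
than by interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import AORTA, BACKGROUND, CAVITY, MYOCARDIUM, SCAR, LabelMap, MVPlane, Volume3D

DEFAULT_LANDMARK_NAMES = (
    "LM_bifurcation",
    "RCA_ostium",
    "LV_apex",
    "papillary_1",
    "papillary_2",
)


@dataclass
class LandmarkSet:
    """Ordered list of named anatomical landmarks in world mm."""

    names: list[str]
    points: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.names) != len(self.points):
            raise ValueError("names and points length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if len(self.names) >= 3 and _collinear(self.points):
            raise ValueError("landmarks are collinear")

    def __len__(self) -> int:
        return len(self.names)

    def get(self, name: str) -> np.ndarray:
        return self.points[self.names.index(name)]


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    if len(points) < 3:
        return True
    d = points - points.mean(axis=0)
    s = np.linalg.svd(d, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


# ---------------------------------------------------------------------------
# intensity model
# ---------------------------------------------------------------------------

#: Default per-compartment intensity means/SDs.  In-vivo LGE: bright blood
#: pool and scar, dark remote myocardium.  Ex-vivo T1w: bright saline bath
#: (background and cavity) and scar, dark myocardium.
DEFAULT_INTENSITIES = {
    "invivo": {
        BACKGROUND: (10.0, 0.0),
        MYOCARDIUM: (30.0, 0.0),
        CAVITY: (120.0, 0.0),
        SCAR: (140.0, 0.0),
        AORTA: (120.0, 0.0),
    },
    "exvivo": {
        BACKGROUND: (120.0, 0.0),
        MYOCARDIUM: (40.0, 0.0),
        CAVITY: (120.0, 0.0),
        SCAR: (150.0, 0.0),
        AORTA: (120.0, 0.0),
    },
}

#: Lognormal scar enhancement texture (smooth, positively skewed); reflects
#: heterogeneous gadolinium accumulation within dense scar and keeps the
#: dim edge of the scar distribution above a mean-1SD threshold.  The
#: in-vivo texture is weaker: partial-volume averaging at 1.2 mm flattens
#: the heterogeneity that the 0.4 mm ex-vivo acquisition resolves.
SCAR_TEXTURE = {
    "invivo": {"amplitude": 15.0, "log_sigma": 0.5, "smooth_vox": 2.0},
    "exvivo": {"amplitude": 30.0, "log_sigma": 0.7, "smooth_vox": 2.0},
}


@dataclass
class PhantomSpec:
    """Full parameterization of the paired synthetic experiment.

    Lengths in mm, angles in degrees.  ``endo_semiaxes`` is (long, short,
    short); the long axis is mapped to world z with the apex at negative z and
    the MV plane at ``z = mv_plane_offset`` (ellipsoid centered at origin).
    """

    endo_semiaxes: tuple[float, float, float] = (60.0, 25.0, 25.0)
    wall_thickness: float = 9.95
    mv_plane_offset: float = 0.0
    scar_angular_extent: float = 90.0
    scar_long_extent: float = 0.4
    scar_center_angle: float = 0.0
    rim_transmurality: float = 0.5
    long_axis_ratio: float = 0.83
    short_axis_ratio: float = 0.81
    thick_mult_healthy: float = 1.29
    thick_mult_low: float = 1.05
    thick_mult_high: float = 0.98
    blend_band_mm: float = 5.0
    invivo_voxel: float = 1.2
    exvivo_voxel: float = 0.4
    pad_mm: float = 20.0
    intensity_model: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITIES.items()}
    )
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    noise_sigma_frac: float = 0.05  # fraction of wall-scar contrast
    papillary_muscles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        ax = np.asarray(self.endo_semiaxes, dtype=float)
        if np.any(ax <= 0) or self.wall_thickness <= 0:
            raise ValueError("all lengths must be positive")
        if not (0 < self.long_axis_ratio <= 1 and 0 < self.short_axis_ratio <= 1):
            raise ValueError("axis ratios must lie in (0, 1]")
        if min(self.thick_mult_healthy, self.thick_mult_low, self.thick_mult_high) <= 0:
            raise ValueError("thickness multipliers must be positive")
        if not 0 <= self.rim_transmurality <= 1:
            raise ValueError("transmurality values must lie in [0, 1]")
        if self.exvivo_voxel > self.invivo_voxel:
            raise ValueError("exvivo_voxel must not exceed invivo_voxel")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    # semiaxes ordered (x, y, z) = (short, short, long)
    @property
    def axes_xyz(self) -> np.ndarray:
        a, b, c = self.endo_semiaxes
        return np.array([b, c, a], dtype=float)

    @property
    def long_semiaxis(self) -> float:
        return float(self.endo_semiaxes[0])

    @property
    def z_mv(self) -> float:
        return float(self.mv_plane_offset)

    @property
    def cavity_centroid(self) -> np.ndarray:
        """Analytic centroid of the truncated (z <= z_mv) ellipsoid cavity."""
        a = self.long_semiaxis
        u = np.clip(self.z_mv / a, -1.0, 1.0)
        # z-centroid of ellipsoid slice z/a in [-1, u]:
        #   zbar = a * integral(z(1-z^2)) / integral(1-z^2) over [-1, u]
        num = (u**2 / 2 - u**4 / 4) - (1 / 2 - 1 / 4)
        den = (u - u**3 / 3) - (-1 + 1 / 3)
        return np.array([0.0, 0.0, a * num / den])

    @property
    def scale_xyz(self) -> np.ndarray:
        return np.array(
            [self.short_axis_ratio, self.short_axis_ratio, self.long_axis_ratio]
        )

    def jittered(self, rng: np.random.Generator, frac: float = 0.10) -> "PhantomSpec":
        """Replicate-level geometric jitter (uniform +/- frac) emulating
        inter-animal variability; deformation ratios are left untouched."""
        u = lambda: 1.0 + frac * (2 * rng.random() - 1)
        a, b, c = self.endo_semiaxes
        return replace(
            self,
            endo_semiaxes=(a * u(), b * u(), c * u()),
            wall_thickness=self.wall_thickness * u(),
            scar_angular_extent=self.scar_angular_extent * u(),
            scar_long_extent=min(0.9, self.scar_long_extent * u()),
        )


# ---------------------------------------------------------------------------
# ellipsoid geometry
# ---------------------------------------------------------------------------


def ellipsoid_closest_point(
    points: np.ndarray, center: np.ndarray, axes: np.ndarray, iters: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Foot point on an axis-aligned ellipsoid and signed offset distance.

    Solves, per point, the classic root problem
    ``sum((a_i y_i / (t + a_i^2))^2) = 1`` by safeguarded Newton iteration
    (the function is convex and decreasing, so Newton converges monotonically
    once on the left of the root).  Valid for exterior points and for
    near-surface interior points (which is all the phantom needs: wall
    membership and surface foot points).

    Returns ``(foot, d)`` with ``d = |y - foot|`` signed positive outside.
    """
    y = np.atleast_2d(points) - np.asarray(center, dtype=float)
    a2 = np.asarray(axes, dtype=float) ** 2
    ay2 = a2[None, :] * y**2  # (a_i y_i)^2
    t = np.zeros(len(y))
    tmin = -0.99 * a2.min()
    for _ in range(iters):
        denom = t[:, None] + a2[None, :]
        frac = ay2 / denom**2
        g = frac.sum(axis=1) - 1.0
        gp = -2.0 * (frac / denom).sum(axis=1)
        step = np.where(np.abs(gp) > 1e-300, g / gp, 0.0)
        t_new = np.maximum(t - step, tmin)
        if np.all(np.abs(t_new - t) < 1e-12 * (1.0 + np.abs(t))):
            t = t_new
            break
        t = t_new
    foot = a2[None, :] * y / (t[:, None] + a2[None, :])
    diff = y - foot
    d = np.linalg.norm(diff, axis=1)
    inside = (y**2 / a2[None, :]).sum(axis=1) < 1.0
    d = np.where(inside, -d, d)
    return foot + center, d


def ellipsoid_normal(points_on_surface: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Outward unit normal of the ellipsoid at (near-)surface points."""
    g = (np.atleast_2d(points_on_surface) - center) / np.asarray(axes) ** 2
    n = np.linalg.norm(g, axis=1, keepdims=True)
    return g / np.maximum(n, 1e-30)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    u = np.clip(x, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


class _ScarProfile:
    """Angular/longitudinal scar sector with a stepped transmural profile.

    Sector coordinates are evaluated at endocardial foot points: wrap-around
    circumferential angle about the long axis and the longitudinal (z)
    coordinate.  The *core* (inner half of the sector in both coordinates) is
    fully transmural; the surrounding rim carries ``rim_transmurality``.
    """

    def __init__(self, spec: PhantomSpec):
        self.theta0 = np.deg2rad(spec.scar_center_angle)
        self.half_ang = np.deg2rad(spec.scar_angular_extent) / 2.0
        a = spec.long_semiaxis
        self.z_center = -a / 2.0
        self.half_len = spec.scar_long_extent * a / 2.0
        self.rim_tau = spec.rim_transmurality
        self.spec = spec

    def _sector_coords(self, foot: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta = np.arctan2(foot[:, 1], foot[:, 0])
        dth = np.abs(np.angle(np.exp(1j * (theta - self.theta0))))
        dz = np.abs(foot[:, 2] - self.z_center)
        r_xy = np.hypot(foot[:, 0], foot[:, 1])
        return dth, dz, r_xy

    def transmurality(self, foot: np.ndarray) -> np.ndarray:
        dth, dz, _ = self._sector_coords(foot)
        if self.half_ang <= 0 or self.half_len <= 0:
            return np.zeros(len(foot))
        s = np.maximum(dth / self.half_ang, dz / self.half_len)
        tau = np.zeros(len(foot))
        tau[s <= 1.0] = self.rim_tau
        tau[s <= 0.5] = 1.0
        return tau

    def thickness_multiplier(self, foot: np.ndarray) -> np.ndarray:
        """Regional wall-thickness multiplier, blended over the 5 mm band."""
        sp = self.spec
        dth, dz, r_xy = self._sector_coords(foot)
        if self.half_ang <= 0 or self.half_len <= 0:
            return np.full(len(foot), sp.thick_mult_healthy)
        w = max(sp.blend_band_mm, 1e-6)
        # signed distances (mm, >0 outside) to the scar and core boxes in
        # (arc-length, z) coordinates
        d_scar = np.maximum((dth - self.half_ang) * r_xy, dz - self.half_len)
        d_core = np.maximum((dth - self.half_ang / 2) * r_xy, dz - self.half_len / 2)
        s_h = _smoothstep(0.5 + d_scar / w)
        s_low = _smoothstep(0.5 + d_core / w)
        inner = s_low * sp.thick_mult_low + (1.0 - s_low) * sp.thick_mult_high
        return s_h * sp.thick_mult_healthy + (1.0 - s_h) * inner


def ground_truth_transmurality(spec: PhantomSpec, endo_points: np.ndarray) -> np.ndarray:
    """Ground-truth transmural profile value at (near-)endocardial points.

    Oracle for the morphometry: returns the stepped profile (core 1.0,
    rim ``rim_transmurality``, healthy 0.0) at the angular/longitudinal
    position of each point's endocardial foot point.  Raises if any point
    lies above the MV truncation plane.
    """
    arr = np.asarray(endo_points, dtype=float)
    pts = np.atleast_2d(arr)
    foot, _ = ellipsoid_closest_point(pts, np.zeros(3), spec.axes_xyz)
    if np.any(foot[:, 2] > spec.z_mv + 1e-6):
        raise ValueError("point outside MV truncation")
    tau = _ScarProfile(spec).transmurality(foot)
    return tau if arr.ndim > 1 else float(tau[0])


# ---------------------------------------------------------------------------
# forward / inverse deformation
# ---------------------------------------------------------------------------


class GroundTruthWarp:
    """Analytic in-vivo -> ex-vivo map in shell coordinates.

    Cavity points are scaled anisotropically about the cavity centroid; a
    wall point at offset ``d`` along the endocardial normal maps to the
    scaled foot point offset by ``d * m(foot)`` along the scaled surface's
    normal, where ``m`` is the regional thickness multiplier.  Outward
    normal offsets of a convex surface never cross, so the map is bijective
    on the cavity's exterior and the inverse is again a closed-form
    foot-point decomposition (against the scaled ellipsoid).
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.axes = spec.axes_xyz
        self.center = np.zeros(3)
        self.c_cav = spec.cavity_centroid
        self.S = spec.scale_xyz
        self.axes_ex = self.axes * self.S
        # scaled ellipsoid center: c_cav + S(0 - c_cav)
        self.center_ex = self.c_cav + self.S * (self.center - self.c_cav)
        self.profile = _ScarProfile(spec)

    def forward(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rho = ((pts - self.center) ** 2 / self.axes**2).sum(axis=1)
        out = np.empty_like(pts)
        inside = rho < 1.0
        out[inside] = self.c_cav + self.S * (pts[inside] - self.c_cav)
        if np.any(~inside):
            p = pts[~inside]
            foot, d = ellipsoid_closest_point(p, self.center, self.axes)
            foot_ex = self.c_cav + self.S * (foot - self.c_cav)
            n_ex = ellipsoid_normal(foot_ex, self.center_ex, self.axes_ex)
            m = self.profile.thickness_multiplier(foot)
            out[~inside] = foot_ex + (d * m)[:, None] * n_ex
        return out

    def inverse(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rho = ((pts - self.center_ex) ** 2 / self.axes_ex**2).sum(axis=1)
        out = np.empty_like(pts)
        inside = rho < 1.0
        out[inside] = self.c_cav + (pts[inside] - self.c_cav) / self.S
        if np.any(~inside):
            y = pts[~inside]
            foot_ex, d_ex = ellipsoid_closest_point(y, self.center_ex, self.axes_ex)
            foot = self.c_cav + (foot_ex - self.c_cav) / self.S
            m = self.profile.thickness_multiplier(foot)
            n = ellipsoid_normal(foot, self.center, self.axes)
            out[~inside] = foot + (d_ex / m)[:, None] * n
        return out

    def shell_coords_exvivo(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For ex-vivo points: in-vivo endocardial foot point and in-vivo
        normal offset ``d_in`` (ex-vivo offset divided by the multiplier)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        foot_ex, d_ex = ellipsoid_closest_point(pts, self.center_ex, self.axes_ex)
        foot = self.c_cav + (foot_ex - self.c_cav) / self.S
        m = self.profile.thickness_multiplier(foot)
        return foot, d_ex / m


@dataclass
class DeformationField:
    """Dense per-voxel forward displacement (mm) on the in-vivo grid plus
    the analytic warp for exact inverse evaluation."""

    displacement: np.ndarray  # (nx, ny, nz, 3)
    grid: Volume3D  # geometry carrier (in-vivo grid)
    warp: GroundTruthWarp

    def forward_points(self, points: np.ndarray) -> np.ndarray:
        return self.warp.forward(points)

    def inverse_points(self, points: np.ndarray) -> np.ndarray:
        return self.warp.inverse(points)

    def jacobian_determinant(self, points: np.ndarray, eps: float = 1e-3) -> np.ndarray:
        """Central finite-difference Jacobian determinant of the forward map."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        J = np.empty((len(pts), 3, 3))
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = eps
            J[:, :, ax] = (self.warp.forward(pts + dp) - self.warp.forward(pts - dp)) / (
                2 * eps
            )
        return np.linalg.det(J)


# ---------------------------------------------------------------------------
# membership + rendering
# ---------------------------------------------------------------------------


def _membership_invivo(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Exact geometric labels of in-vivo world points (flat array)."""
    pts = np.atleast_2d(points)
    axes = spec.axes_xyz
    labels = np.zeros(len(pts), dtype=np.uint8)
    below = pts[:, 2] <= spec.z_mv
    rho = (pts**2 / axes**2).sum(axis=1)
    cavity = below & (rho < 1.0)
    labels[cavity] = CAVITY
    # wall: exterior points within one thickness of the endocardium;
    # restrict the (costly) foot-point solve to a generous shell
    cand = below & ~cavity & (rho < ((axes + spec.wall_thickness * 1.5) / axes).max() ** 2)
    if np.any(cand):
        foot, d = ellipsoid_closest_point(pts[cand], np.zeros(3), axes)
        wall = (d >= 0) & (d <= spec.wall_thickness)
        profile = _ScarProfile(spec)
        tau = profile.transmurality(foot)
        scar = wall & (tau > 0) & (d <= tau * spec.wall_thickness)
        sub = np.full(cand.sum(), BACKGROUND, dtype=np.uint8)
        sub[wall] = MYOCARDIUM
        sub[scar] = SCAR
        labels[cand] = sub
    if spec.papillary_muscles:
        labels = _add_papillary(spec, pts, labels)
    return labels


def _papillary_centers(spec: PhantomSpec) -> np.ndarray:
    axes = spec.axes_xyz
    centers = []
    for theta in (np.deg2rad(150.0), np.deg2rad(-150.0)):
        z = -0.55 * spec.long_semiaxis
        r = axes[0] * np.sqrt(max(0.0, 1 - (z / axes[2]) ** 2))
        centers.append([r * np.cos(theta), r * np.sin(theta), z])
    return np.asarray(centers)


def _add_papillary(spec: PhantomSpec, pts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two endocardial bumps labelled myocardium inside the cavity.

    Exercises the papillary convention: in the in-vivo condition the muscle
    body is separated from the wall (cavity contrast all around), so it is
    stored as myocardium protruding into the cavity label region.
    """
    radius = 4.0
    for c in _papillary_centers(spec):
        d = np.linalg.norm(pts - c, axis=1)
        bump = (d <= radius) & (labels == CAVITY)
        labels[bump] = MYOCARDIUM
    return labels


def _membership_exvivo(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Exact labels of ex-vivo points: in-vivo membership of the inverse map."""
    warp = GroundTruthWarp(spec)
    pts = np.atleast_2d(points)
    labels = np.zeros(len(pts), dtype=np.uint8)
    rho = ((pts - warp.center_ex) ** 2 / warp.axes_ex**2).sum(axis=1)
    # cavity region is mapped affinely; pull back and test directly
    inside = rho < 1.0
    x_in = warp.c_cav + (pts[inside] - warp.c_cav) / warp.S
    labels[inside] = np.where(x_in[:, 2] <= spec.z_mv, CAVITY, BACKGROUND)
    # wall candidates: exterior shell around the scaled endocardium
    max_th = spec.wall_thickness * max(
        spec.thick_mult_healthy, spec.thick_mult_low, spec.thick_mult_high
    )
    lim = ((warp.axes_ex + 1.5 * max_th) / warp.axes_ex).max() ** 2
    cand = ~inside & (rho < lim)
    if np.any(cand):
        foot, d_in = warp.shell_coords_exvivo(pts[cand])
        x = foot + d_in[:, None] * ellipsoid_normal(foot, warp.center, warp.axes)
        below = x[:, 2] <= spec.z_mv
        wall = below & (d_in >= 0) & (d_in <= spec.wall_thickness)
        tau = warp.profile.transmurality(foot)
        scar = wall & (tau > 0) & (d_in <= tau * spec.wall_thickness)
        sub = np.full(cand.sum(), BACKGROUND, dtype=np.uint8)
        sub[wall] = MYOCARDIUM
        sub[scar] = SCAR
        labels[cand] = sub
    if spec.papillary_muscles:
        # ex-vivo: papillary pushed against the wall but, by the segmentation
        # convention, kept in the cavity compartment -> no bump added
        pass
    return labels


def _render_intensities(
    spec: PhantomSpec, labels: LabelMap, condition: str, rng: np.random.Generator
) -> Volume3D:
    model = spec.intensity_model[condition]
    data = np.zeros(labels.shape, dtype=float)
    for lab, (mean, sd) in model.items():
        sel = labels.data == lab
        data[sel] = mean
        if sd > 0:
            data[sel] += sd * rng.standard_normal(sel.sum())
    # smooth lognormal enhancement texture inside scar
    scar_sel = labels.data == SCAR
    if np.any(scar_sel):
        tex = SCAR_TEXTURE[condition]
        g = rng.standard_normal(labels.shape)
        g = gaussian_filter(g, tex["smooth_vox"])
        g /= max(g[scar_sel].std(), 1e-12)
        g -= g[scar_sel].mean()
        lognorm = np.exp(tex["log_sigma"] * g)
        data[scar_sel] += tex["amplitude"] * lognorm[scar_sel] / np.exp(
            tex["log_sigma"] ** 2 / 2
        )
    # global acquisition noise
    wall_mean = model[MYOCARDIUM][0]
    scar_mean = model[SCAR][0]
    sigma = spec.noise_sigma_frac * abs(scar_mean - wall_mean)
    if sigma > 0:
        if spec.noise_model == "gaussian":
            data = data + sigma * rng.standard_normal(labels.shape)
        else:  # rician: magnitude of complex signal with gaussian channels
            re = data + sigma * rng.standard_normal(labels.shape)
            im = sigma * rng.standard_normal(labels.shape)
            data = np.hypot(re, im)
    return Volume3D(data, labels.voxel_size_mm, labels.origin_mm, dict(labels.meta))


def _make_grid(
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    voxel: float,
    snap_mm: float | None = None,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    # both acquisition grids are snapped to a common world frame (multiples
    # of the coarse voxel) so that integer-ratio downsampling lands the
    # ex-vivo voxel centers exactly on in-vivo centers: overlap metrics then
    # measure anatomy, not grid phase
    if snap_mm:
        bounds_lo = np.floor(bounds_lo / snap_mm) * snap_mm
    n = np.ceil((bounds_hi - bounds_lo) / voxel).astype(int)
    origin = bounds_lo + voxel / 2.0
    return origin, tuple(int(v) for v in n)


def _grid_points(origin: np.ndarray, shape: tuple[int, int, int], voxel: float) -> np.ndarray:
    ax = [origin[d] + voxel * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def default_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Analytically placed anatomical landmarks in the in-vivo condition."""
    axes = spec.axes_xyz
    T = spec.wall_thickness

    def epi_point(theta_deg: float, z: float) -> np.ndarray:
        r = axes[0] * np.sqrt(max(0.0, 1 - (z / axes[2]) ** 2))
        p = np.array([r * np.cos(np.deg2rad(theta_deg)), r * np.sin(np.deg2rad(theta_deg)), z])
        n = ellipsoid_normal(p[None], np.zeros(3), axes)[0]
        return p + T * n

    apex_endo = np.array([0.0, 0.0, -axes[2]])
    apex = apex_endo + T * np.array([0.0, 0.0, -1.0])
    pap = _papillary_centers(spec)
    return LandmarkSet(
        names=list(DEFAULT_LANDMARK_NAMES),
        points=np.array(
            [
                epi_point(140.0, spec.z_mv - 8.0),
                epi_point(-100.0, spec.z_mv - 8.0),
                apex,
                pap[0],
                pap[1],
            ]
        ),
    )


def make_invivo_phantom(
    spec: PhantomSpec,
) -> tuple[Volume3D, LabelMap, LandmarkSet]:
    """Generate the in-vivo volume, label map and landmark set.

    Deterministic given ``spec.seed``.  Raises if the wall is thinner than
    two in-vivo voxels (unresolvable wall).
    """
    if spec.wall_thickness < 2 * spec.invivo_voxel:
        raise ValueError("unresolvable wall: thickness below 2 voxels")
    axes = spec.axes_xyz
    T = spec.wall_thickness
    pad = spec.pad_mm
    lo = np.array([-(axes[0] + T + pad), -(axes[1] + T + pad), -(axes[2] + T + pad)])
    hi = np.array([axes[0] + T + pad, axes[1] + T + pad, spec.z_mv + pad / 2 + 2.0])
    origin, shape = _make_grid(lo, hi, spec.invivo_voxel, snap_mm=spec.invivo_voxel)
    pts = _grid_points(origin, shape, spec.invivo_voxel)
    labels_flat = _membership_invivo(spec, pts)
    meta = {"mv_plane": MVPlane(point=(0.0, 0.0, spec.z_mv), normal=(0.0, 0.0, 1.0))}
    labels = LabelMap(
        labels_flat.reshape(shape).astype(np.int16), spec.invivo_voxel, origin, meta
    )
    rng = np.random.default_rng(spec.seed)
    vol = _render_intensities(spec, labels, "invivo", rng)
    return vol, labels, default_landmarks(spec)


def make_exvivo_pair(
    spec: PhantomSpec, invivo_labels: LabelMap | None = None
) -> tuple[Volume3D, LabelMap, LandmarkSet, DeformationField]:
    """Generate the ex-vivo condition by the analytic ground-truth warp.

    Labels on the fine ex-vivo grid come from evaluating the analytic inverse
    at each voxel center (exact membership, no label interpolation); the
    landmark set is transported through the forward map; the returned
    ``DeformationField`` holds the dense forward displacement on the in-vivo
    grid plus the analytic warp itself.
    """
    mult_min = min(spec.thick_mult_healthy, spec.thick_mult_low, spec.thick_mult_high)
    if mult_min * spec.wall_thickness < 2 * spec.exvivo_voxel:
        raise ValueError("non-invertible parameters: multiplier collapses wall")
    warp = GroundTruthWarp(spec)
    max_th = spec.wall_thickness * max(
        spec.thick_mult_healthy, spec.thick_mult_low, spec.thick_mult_high
    )
    pad = 4.0
    lo = warp.center_ex - warp.axes_ex - max_th - pad
    z_mv_ex = float(warp.c_cav[2] + spec.scale_xyz[2] * (spec.z_mv - warp.c_cav[2]))
    hi = np.array(
        [
            warp.center_ex[0] + warp.axes_ex[0] + max_th + pad,
            warp.center_ex[1] + warp.axes_ex[1] + max_th + pad,
            z_mv_ex + pad,
        ]
    )
    origin, shape = _make_grid(lo, hi, spec.exvivo_voxel, snap_mm=spec.invivo_voxel)
    pts = _grid_points(origin, shape, spec.exvivo_voxel)
    labels_flat = _membership_exvivo(spec, pts)
    meta = {"mv_plane": MVPlane(point=(0.0, 0.0, z_mv_ex), normal=(0.0, 0.0, 1.0))}
    labels = LabelMap(
        labels_flat.reshape(shape).astype(np.int16), spec.exvivo_voxel, origin, meta
    )
    rng = np.random.default_rng(spec.seed + 1_000_003)
    vol = _render_intensities(spec, labels, "exvivo", rng)

    lms_in = default_landmarks(spec)
    lms_ex = LandmarkSet(list(lms_in.names), warp.forward(lms_in.points))

    if invivo_labels is None:
        _, invivo_labels, _ = make_invivo_phantom(spec)
    gpts = _grid_points(
        invivo_labels.origin_mm, invivo_labels.shape, invivo_labels.voxel_size_mm
    )
    disp = (warp.forward(gpts) - gpts).reshape(invivo_labels.shape + (3,))
    field = DeformationField(
        displacement=disp,
        grid=Volume3D(
            np.zeros(invivo_labels.shape, dtype=np.uint8),
            invivo_labels.voxel_size_mm,
            invivo_labels.origin_mm,
        ),
        warp=warp,
    )
    return vol, labels, lms_ex, field

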