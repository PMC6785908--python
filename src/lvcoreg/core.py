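"""Core grid containers shared by every pipeline stage.

Volumes and label maps live on axis-aligned isotropic grids: array axis 0/1/2
map to world x/y/z, and the world coordinate of voxel ``(i, j, k)`` is
``origin_mm + voxel_size_mm * (i, j, k)`` (voxel centers, no shear).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

# Label vocabulary. Scar supersedes myocardium in storage; the anatomical
# wall is the union of MYOCARDIUM and SCAR.
BACKGROUND = 0
MYOCARDIUM = 1
CAVITY = 2
SCAR = 3
AORTA = 4

LABELS = (BACKGROUND, MYOCARDIUM, CAVITY, SCAR, AORTA)

#: Tie-break priority used whenever fractional label occupancies compete
#: (downsampling, interpolating resampling). Highest priority first.
LABEL_PRIORITY = (SCAR, CAVITY, MYOCARDIUM, AORTA, BACKGROUND)


@dataclass
class Volume3D:
    """Scalar 3-D image on an isotropic axis-aligned grid."""

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("expected a 3-D array")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.origin_mm.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers as three broadcastable axes."""
        ax = [
            self.origin_mm[d] + self.voxel_size_mm * np.arange(self.shape[d])
            for d in range(3)
        ]
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points (N, 3)."""
        return (np.atleast_2d(points) - self.origin_mm) / self.voxel_size_mm

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.atleast_2d(idx) * self.voxel_size_mm

    def same_grid(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class LabelMap(Volume3D):
    """Integer-labelled grid sharing the Volume3D geometry contract."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap requires an integer array")
        bad = np.setdiff1d(np.unique(self.data), np.asarray(LABELS))
        if bad.size:
            raise ValueError(f"labels outside vocabulary: {bad.tolist()}")

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.data, labels)

    def wall_mask(self) -> np.ndarray:
        return self.mask(MYOCARDIUM, SCAR)

    def cavity_mask(self) -> np.ndarray:
        return self.mask(CAVITY)

    def scar_mask(self) -> np.ndarray:
        return self.mask(SCAR)

    @property
    def mv_plane(self) -> "MVPlane | None":
        return self.meta.get("mv_plane")


@dataclass(frozen=True)
class MVPlane:
    """Mitral-valve disc plane truncating the LV.

    ``normal`` points from apex toward base; tissue lies at
    ``(p - point) . normal <= 0``.
    """

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def depth_below(self, points: np.ndarray) -> np.ndarray:
        """Signed distance below the plane (positive toward the apex)."""
        p = np.atleast_2d(points)
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        return -(p - np.asarray(self.point, dtype=float)) @ n

    def to_dict(self) -> dict:
        return {"point": list(self.point), "normal": list(self.normal)}

    @classmethod
    def from_dict(cls, d: dict) -> "MVPlane":
        return cls(point=tuple(d["point"]), normal=tuple(d["normal"]))
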