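"""Standard-format I/O: NIfTI volumes/labels, CSV landmarks and node tables,
JSON transforms and reports, PLY/VTK meshes, YAML configs.

Grids are axis-aligned and isotropic; the NIfTI affine is diagonal with the
voxel size, and the MV-plane metadata travels in a JSON header extension so
that write/read round-trips preserve the full analysis context.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import LabelMap, MVPlane, Volume3D
from .mesh import SurfaceMesh
from .phantom import DEFAULT_LANDMARK_NAMES, LandmarkSet
from .registration import transform_from_dict

_NIFTI_EXT_CODE = 6  # "comment" extension carrying JSON metadata


def write_nifti(volume: Volume3D | LabelMap, path: str | Path) -> None:
    """Write a volume or label map as single-file NIfTI-1."""
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * volume.voxel_size_mm
    affine[:3, 3] = volume.origin_mm
    data = volume.data
    if isinstance(volume, LabelMap):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((volume.voxel_size_mm,) * 3)
    meta = {}
    plane = volume.meta.get("mv_plane")
    if plane is not None:
        meta["mv_plane"] = plane.to_dict()
    if meta:
        img.header.extensions.append(
            nib.nifti1.Nifti1Extension(_NIFTI_EXT_CODE, json.dumps(meta).encode())
        )
    nib.save(img, str(path))


def read_nifti(path: str | Path, as_labels: bool = False) -> Volume3D | LabelMap:
    """Read a NIfTI volume; rejects anisotropic voxels (stated contract)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-6:
        raise ValueError("isotropic voxels required")
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.eye(3) * zooms[0], atol=1e-6):
        raise ValueError("only axis-aligned grids without rotation are supported")
    origin = affine[:3, 3].astype(float)
    meta: dict = {}
    for ext in img.header.extensions:
        if ext.get_code() == _NIFTI_EXT_CODE:
            try:
                payload = json.loads(ext.get_content().decode())
            except (ValueError, UnicodeDecodeError):
                continue
            if "mv_plane" in payload:
                meta["mv_plane"] = MVPlane.from_dict(payload["mv_plane"])
    data = np.asanyarray(img.dataobj)
    if as_labels:
        return LabelMap(data.astype(np.int16), float(zooms[0]), origin, meta)
    return Volume3D(np.asarray(data, dtype=float), float(zooms[0]), origin, meta)


def write_deformation_field(field_arr: np.ndarray, voxel: float, origin: np.ndarray, path: str | Path) -> None:
    """Write a dense 3-component displacement field as 4-D NIfTI."""
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(field_arr, dtype=np.float32), affine), str(path))


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": lms.names,
            "x_mm": lms.points[:, 0],
            "y_mm": lms.points[:, 1],
            "z_mm": lms.points[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_landmarks(path: str | Path, allow_custom: bool = False) -> LandmarkSet:
    df = pd.read_csv(path)
    required = {"name", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV needs columns {sorted(required)}")
    names = [str(n) for n in df["name"]]
    if len(set(names)) != len(names):
        raise ValueError("duplicate landmark name")
    if not allow_custom:
        unknown = [n for n in names if n not in DEFAULT_LANDMARK_NAMES]
        if unknown:
            raise ValueError(
                f"unknown landmark names {unknown}; pass allow_custom=True to accept"
            )
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if len(names) < 3:
        # accepted at the I/O layer; geometric validity is enforced by the
        # registration operators that need >= 3 non-collinear points
        return _lenient_landmarks(names, pts)
    return LandmarkSet(names, pts)


def _lenient_landmarks(names, pts) -> LandmarkSet:
    obj = LandmarkSet.__new__(LandmarkSet)
    obj.names = list(names)
    obj.points = np.asarray(pts, dtype=float).reshape(-1, 3)
    return obj


def write_transform(transform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(transform.to_dict()))


def read_transform(path: str | Path):
    return transform_from_dict(json.loads(Path(path).read_text()))


def write_mesh_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    """Binary-free ASCII PLY with per-node attribute properties."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), file_type="ply", encoding="ascii")


def write_mesh_vtk(mesh: SurfaceMesh, path: str | Path) -> None:
    """Legacy ASCII VTK PolyData with POINT_DATA attribute arrays."""
    lines = [
        "# vtk DataFile Version 3.0",
        "lvcoreg surface mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(mesh.vertices)} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}")
    lines += ["3 " + " ".join(str(int(i)) for i in f) for f in mesh.faces]
    if mesh.attrs:
        lines.append(f"POINT_DATA {len(mesh.vertices)}")
        for name, vals in mesh.attrs.items():
            vals = np.asarray(vals, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6f}" for v in vals]
    Path(path).write_text("\n".join(lines) + "\n")


def write_node_table(mesh: SurfaceMesh, path: str | Path) -> None:
    """Per-node CSV: node_id, x, y, z plus every attribute column."""
    df = pd.DataFrame(
        {
            "node_id": np.arange(len(mesh)),
            "x": mesh.vertices[:, 0],
            "y": mesh.vertices[:, 1],
            "z": mesh.vertices[:, 2],
        }
    )
    for name, vals in mesh.attrs.items():
        df[name] = np.asarray(vals)
    df.to_csv(path, index=False)


def write_config(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
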