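"""Triangle surface models and STL exchange.

The bone mask is turned into a triangle mesh by marching cubes on the binary
occupancy field (isolevel 0.5, vertices scaled to mm).  Meshes are exchanged
as STL, the unit-less de facto format for surface models exported from
clinical segmentation software; this package fixes millimetres everywhere.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .segmentation import BoneMask

__all__ = ["TriangleMesh", "StlParseError", "extract_surface", "mesh_area", "read_stl", "write_stl"]


@dataclass(frozen=True)
class TriangleMesh:
    """Vertex/face surface in mm."""

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


class StlParseError(ValueError):
    """Malformed STL file; ``offset`` is the byte position of the inconsistency."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (byte offset {offset})")
        self.offset = offset


def _clean(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Merge duplicate vertices and drop degenerate (zero-area) faces."""
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=True)
    if len(tm.faces):
        cross = np.cross(
            tm.triangles[:, 1] - tm.triangles[:, 0], tm.triangles[:, 2] - tm.triangles[:, 0]
        )
        keep = np.linalg.norm(cross, axis=1) > 1e-12
        tm.update_faces(keep)
        tm.remove_unreferenced_vertices()
    return TriangleMesh(
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        faces=np.asarray(tm.faces, dtype=np.int64),
    )


def extract_surface(mask: BoneMask) -> TriangleMesh:
    """Marching-cubes isosurface of the binary bone field, in mm.

    The mask is zero-padded by one voxel so bone touching the grid boundary
    still yields a closed surface (needed downstream for rim detection).
    """
    if not mask.values.any():
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.values, 1).astype(np.uint8)
    verts, faces, _normals, _vals = measure.marching_cubes(
        padded, level=0.5, spacing=mask.spacing
    )
    verts = verts - np.asarray(mask.spacing)  # undo the one-voxel pad offset
    return _clean(verts, faces)


def mesh_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm^2: sum of 0.5 * |(v1-v0) x (v2-v0)| over faces."""
    if mesh.n_faces == 0:
        return 0.0
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _validate_binary_stl(data: bytes, path: Path) -> None:
    if len(data) < 84:
        raise StlParseError(f"{path}: binary STL truncated before triangle count", offset=len(data))
    (n,) = struct.unpack("<I", data[80:84])
    expected = 84 + 50 * n
    if len(data) != expected:
        raise StlParseError(
            f"{path}: header declares {n} triangles ({expected} bytes) but file has {len(data)}",
            offset=min(expected, len(data)),
        )


def read_stl(path: str | Path) -> TriangleMesh:
    """Read an ASCII or binary STL file into a TriangleMesh (coordinates taken as mm)."""
    path = Path(path)
    data = path.read_bytes()
    is_ascii = data.lstrip()[:5].lower() == b"solid" and b"facet" in data[:1024]
    if not is_ascii:
        _validate_binary_stl(data, path)
    try:
        tm = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on malformed input
        raise StlParseError(f"{path}: failed to parse STL ({exc})") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise StlParseError(f"{path}: STL contains no triangles")
    return TriangleMesh(
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        faces=np.asarray(tm.faces, dtype=np.int64),
    )


def write_stl(mesh: TriangleMesh, path: str | Path, format: str = "binary") -> None:
    """Write a mesh as binary (default) or ASCII STL."""
    if format not in ("binary", "ascii"):
        raise ValueError("format must be 'binary' or 'ascii'")
    path = Path(path)
    tm = mesh.to_trimesh()
    if format == "binary":
        data = trimesh.exchange.stl.export_stl(tm)
        path.write_bytes(data)
    else:
        text = trimesh.exchange.stl.export_stl_ascii(tm)
        path.write_text(text)
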