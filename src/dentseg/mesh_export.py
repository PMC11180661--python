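"""Binary mask -> watertight surface mesh -> binary STL.

The mask is padded by one background voxel layer before marching cubes so
surfaces close even where the mask touches the grid boundary, then the
pad offset is subtracted and vertices are scaled into mm by the voxel
spacing. STL files are binary (80-byte header, uint32 triangle count,
50-byte triangles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .volume_io import BinaryMask3D


class EmptyGeometryError(ValueError):
    pass


@dataclass
class SurfaceMesh:
    vertices: np.ndarray           # (n, 3) mm, world coordinates
    faces: np.ndarray              # (m, 3) vertex indices
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def enclosed_volume_mm3(self) -> float:
        """Signed-tetrahedron volume of the closed surface."""
        v = self.vertices
        t = v[self.faces]
        return float(abs(np.einsum("ij,ij->i", t[:, 0],
                                   np.cross(t[:, 1], t[:, 2])).sum()) / 6.0)


def mask_to_mesh(mask: BinaryMask3D, iso: float = 0.5,
                 source_id: str = "") -> SurfaceMesh:
    """Marching-cubes surface of a binary mask at the given iso level."""
    data = mask.data
    if not data.any():
        raise EmptyGeometryError("cannot mesh an empty mask")
    if data.all():
        raise EmptyGeometryError(
            "mask fills the whole grid; no surface exists without padding"
            " context")
    padded = np.pad(data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=iso, spacing=mask.spacing_mm)
    verts = verts - np.asarray(mask.spacing_mm)  # undo the 1-voxel pad
    return SurfaceMesh(verts, faces,
                       provenance=dict(source=source_id, iso=iso))


def is_watertight(mesh: SurfaceMesh) -> bool:
    """Every undirected edge shared by exactly two faces."""
    f = mesh.faces
    edges = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]],
                                    f[:, [2, 0]]]), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


def write_stl(mesh: SurfaceMesh, path) -> None:
    """Binary STL export; triangle count equals the face count."""
    if mesh.n_faces == 0:
        raise EmptyGeometryError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(str(Path(path)), file_type="stl")


def read_stl(path) -> SurfaceMesh:
    tm = trimesh.load(str(Path(path)), file_type="stl", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def stl_triangle_count(path) -> int:
    """Triangle count from a binary STL header (no full parse)."""
    with open(path, "rb") as fh:
        fh.seek(80)
        return int(np.frombuffer(fh.read(4), dtype="<u4")[0])
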