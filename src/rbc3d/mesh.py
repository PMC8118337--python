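"""Triangle meshes of closed cell surfaces.

Coordinates are in micrometres.  A mesh is conventionally stored with the
centre of its axis-aligned bounding box at the origin, which makes every
downstream descriptor translation invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class MeshError(ValueError):
    """Raised for structurally invalid meshes or unreadable mesh files."""


@dataclass
class TriangleMesh:
    vertices: np.ndarray  # (n, 3) float64, micrometres
    faces: np.ndarray  # (m, 3) int64 vertex indices
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")

    # ------------------------------------------------------------------ geometry

    def signed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (tetrahedron sum)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def volume(self) -> float:
        return abs(self.signed_volume())

    def area(self) -> float:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def sphericity(self) -> float:
        """pi^(1/3) (6V)^(2/3) / A; equals 1 for a perfect sphere."""
        return float(np.pi ** (1 / 3) * (6 * self.volume()) ** (2 / 3) / self.area())

    def is_closed(self) -> bool:
        """Every undirected edge must be shared by exactly two faces."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(len(e)) and bool((counts == 2).all())

    def volume_centroid(self) -> np.ndarray:
        """Centroid of the enclosed volume (rotation covariant, unlike the
        bounding-box centre)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        det = np.einsum("ij,ij->i", a, np.cross(b, c))
        vol6 = det.sum()
        if abs(vol6) < 1e-30:
            raise MeshError("degenerate mesh: zero volume")
        return (det[:, None] * (a + b + c)).sum(axis=0) / (4.0 * vol6)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def bbox_center(self) -> np.ndarray:
        lo, hi = self.bounding_box()
        return (lo + hi) / 2.0

    # ------------------------------------------------------------------ transforms

    def center_to_bbox(self) -> "TriangleMesh":
        """Translate so the bounding-box centre sits at the origin."""
        return TriangleMesh(self.vertices - self.bbox_center(), self.faces, self.provenance)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces, self.provenance)

    def rotated(self, rotation: np.ndarray) -> "TriangleMesh":
        """Apply a 3x3 rotation matrix about the origin."""
        return TriangleMesh(self.vertices @ np.asarray(rotation, float).T, self.faces, self.provenance)

    def ensure_outward(self) -> "TriangleMesh":
        """Flip face winding if the signed volume is negative."""
        if self.signed_volume() < 0:
            return TriangleMesh(self.vertices, self.faces[:, ::-1], self.provenance)
        return self

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.provenance)

    # ------------------------------------------------------------------ I/O

    def save_obj(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if self.provenance:
                fh.write(f"# {self.provenance}\n")
            for v in self.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")

    def save_ply(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            if self.provenance:
                fh.write(f"comment {self.provenance}\n")
            fh.write(f"element vertex {len(self.vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(self.faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".obj":
            self.save_obj(path)
        elif path.suffix.lower() == ".ply":
            self.save_ply(path)
        else:
            raise MeshError(f"unsupported mesh format: {path.suffix}")


def load_mesh(path) -> TriangleMesh:
    """Read an ASCII OBJ or PLY triangle mesh."""
    path = Path(path)
    if path.suffix.lower() == ".obj":
        return _load_obj(path)
    if path.suffix.lower() == ".ply":
        return _load_ply(path)
    raise MeshError(f"unsupported mesh format: {path.suffix}")


def _load_obj(path: Path) -> TriangleMesh:
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                faces.append([idx[0], idx[k], idx[k + 1]])
    if not verts or not faces:
        raise MeshError(f"no geometry in {path}")
    return TriangleMesh(np.array(verts), np.array(faces), provenance=f"loaded from {path.name}")


def _load_ply(path: Path) -> TriangleMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshError(f"not a ply file: {path}")
    n_vert = n_face = 0
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts and parts[0] == "format" and parts[1] != "ascii":
            raise MeshError("only ascii ply is supported")
        elif parts == ["end_header"]:
            i += 1
            break
        i += 1
    verts = np.array([[float(x) for x in lines[i + k].split()[:3]] for k in range(n_vert)])
    faces = []
    for k in range(n_face):
        parts = lines[i + n_vert + k].split()
        idx = [int(p) for p in parts[1 : 1 + int(parts[0])]]
        for j in range(1, len(idx) - 1):
            faces.append([idx[0], idx[j], idx[j + 1]])
    if n_vert == 0 or not faces:
        raise MeshError(f"no geometry in {path}")
    return TriangleMesh(verts, np.array(faces), provenance=f"loaded from {path.name}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
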