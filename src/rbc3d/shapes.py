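"""Parametric canonical red-blood-cell shapes, morphs and synthetic stacks.

Every canonical shape is defined as a radial function r(theta, phi)
sampled on a fixed UV sphere grid and triangulated into a closed mesh.
That shared star-shaped parameterization is also what makes linear
morphing between shapes well defined: both endpoint meshes are remeshed
onto the same grid and corresponding grid points are interpolated.

The geometry formulas are stand-ins chosen to satisfy the qualitative
morphological criteria of each class (biconcavity, cup depth, spike
count, trilobality, ...); they are not biophysical membrane models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mesh import TriangleMesh, random_rotation
from .sde import ALL_SHAPE_CLASSES, canonical_score, is_sde
from .stack import VoxelStack

_UNKNOWN_CLASS = "unknown"
GENERATABLE_CLASSES = ALL_SHAPE_CLASSES + (_UNKNOWN_CLASS,)


class InvalidSpecError(ValueError):
    """Raised when a ShapeSpec is outside its documented ranges."""


class MorphError(RuntimeError):
    """Raised when the shared spherical parameterization of a morph fails."""


class FieldOfViewError(ValueError):
    """Raised when a mesh does not fit the rasterization field of view."""


# --------------------------------------------------------------------------- spec

_DEFAULT_DIAMETER = {
    "spherocyte": 6.0,
    "stomatocyte_II": 6.8,
    "stomatocyte_I": 7.2,
    "discocyte": 7.8,
    "echinocyte_I": 7.6,
    "echinocyte_II": 7.0,
    "echinocyte_III": 6.4,
    "knizocyte": 7.8,
    "keratocyte": 7.4,
    "acanthocyte": 6.6,
    "multilobate": 7.4,
    "cell_cluster": 9.5,
    _UNKNOWN_CLASS: 7.0,
}


@dataclass
class ShapeSpec:
    """Recipe for one synthetic cell."""

    shape_class: str
    sde_score: float | None = None
    diameter_um: float | None = None
    geometry_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_class not in GENERATABLE_CLASSES:
            raise InvalidSpecError(f"unknown shape_class {self.shape_class!r}")
        if self.diameter_um is None:
            self.diameter_um = _DEFAULT_DIAMETER[self.shape_class]
        if self.diameter_um <= 0:
            raise InvalidSpecError("diameter_um must be positive")
        if is_sde(self.shape_class):
            if self.sde_score is None:
                self.sde_score = canonical_score(self.shape_class)
        elif self.sde_score is not None:
            raise InvalidSpecError(f"{self.shape_class} is not an SDE class; sde_score must be absent")
        if self.sde_score is not None and not -1.0 <= self.sde_score <= 1.0:
            raise InvalidSpecError("sde_score must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "shape_class": self.shape_class,
            "sde_score": self.sde_score,
            "diameter_um": self.diameter_um,
            "geometry_params": dict(self.geometry_params),
            "seed": self.seed,
        }


# --------------------------------------------------------------------------- sphere grid


class SphereGrid:
    """Fixed UV parameterization of the unit sphere with pole vertices.

    Vertices: north pole, (n_theta - 2) latitude rings of n_phi points,
    south pole.  Triangulation is a fan at each pole and split quads in
    between, which is closed by construction.
    """

    def __init__(self, n_theta: int = 49, n_phi: int = 96) -> None:
        if n_theta < 4 or n_phi < 6:
            raise ValueError("grid too coarse")
        self.n_theta = n_theta
        self.n_phi = n_phi
        ring_thetas = np.linspace(0.0, np.pi, n_theta)[1:-1]
        phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
        tt, pp = np.meshgrid(ring_thetas, phis, indexing="ij")
        self.theta = np.concatenate([[0.0], tt.ravel(), [np.pi]])
        self.phi = np.concatenate([[0.0], pp.ravel(), [0.0]])
        st, ct = np.sin(self.theta), np.cos(self.theta)
        self.dirs = np.column_stack([st * np.cos(self.phi), st * np.sin(self.phi), ct])
        self.faces = self._triangulate()

    @property
    def n_vertices(self) -> int:
        return 2 + (self.n_theta - 2) * self.n_phi

    def _triangulate(self) -> np.ndarray:
        nt, np_ = self.n_theta, self.n_phi
        ring = lambda i, j: 1 + i * np_ + (j % np_)  # noqa: E731
        faces = []
        for j in range(np_):  # north fan
            faces.append([0, ring(0, j), ring(0, j + 1)])
        for i in range(nt - 3):  # quad strips
            for j in range(np_):
                a, b = ring(i, j), ring(i, j + 1)
                c, d = ring(i + 1, j), ring(i + 1, j + 1)
                faces.append([a, c, b])
                faces.append([b, c, d])
        south = self.n_vertices - 1
        for j in range(np_):  # south fan
            faces.append([south, ring(nt - 3, j + 1), ring(nt - 3, j)])
        return np.array(faces, dtype=np.int64)

    def build_mesh(self, radii: np.ndarray, provenance: str = "") -> TriangleMesh:
        radii = np.asarray(radii, dtype=np.float64)
        if radii.shape != (self.n_vertices,):
            raise ValueError("radii must match grid vertex count")
        if (radii <= 0).any():
            raise ValueError("radial function must be strictly positive")
        mesh = TriangleMesh(self.dirs * radii[:, None], self.faces, provenance)
        return mesh.ensure_outward().center_to_bbox()


_DEFAULT_GRID = SphereGrid(49, 96)
_MORPH_GRID = SphereGrid(33, 64)


# --------------------------------------------------------------------------- radial profiles

# Biconcave disc-of-revolution coefficients (dimensionless, relative to
# the cell radius); chosen so the central thickness is well below the rim
# thickness, matching the classic biconcave profile.
_DISC_C0 = 0.207
_DISC_C2 = 2.003
_DISC_C4 = -1.123


def _disc_half_thickness(rho: np.ndarray, radius: float) -> np.ndarray:
    """Half thickness z(rho) of the biconcave disc, rho in [0, radius]."""
    x2 = np.clip((rho / radius) ** 2, 0.0, 1.0)
    return 0.5 * radius * np.sqrt(1.0 - x2) * (_DISC_C0 + _DISC_C2 * x2 + _DISC_C4 * x2 * x2)


def _disc_radial_profile(theta: np.ndarray, radius: float) -> np.ndarray:
    """Radial distance r(theta) of the biconcave disc surface from its centre.

    Solved by bisection on g(t) = |t cos(theta)| - z(t sin(theta)) = 0,
    which is valid because the disc is star shaped about its centre.
    """
    theta = np.asarray(theta, dtype=np.float64)
    st = np.abs(np.sin(theta))
    ct = np.abs(np.cos(theta))
    lo = np.full_like(theta, 1e-9)
    # upper bound: the surface lies inside the sphere of radius `radius`
    hi = np.full_like(theta, radius * 1.0001)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = mid * ct - _disc_half_thickness(np.minimum(mid * st, radius), radius)
        lo = np.where(g < 0, mid, lo)
        hi = np.where(g < 0, hi, mid)
    r = 0.5 * (lo + hi)
    # equatorial directions: intersect at the rim
    return np.where(st > 1.0 - 1e-12, radius, r)


def _fibonacci_directions(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Quasi-uniform unit directions (Fibonacci lattice, optional random spin)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * (np.pi * (3.0 - math.sqrt(5.0)))
    if rng is not None:
        phi = phi + rng.uniform(0, 2 * np.pi)
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _bump_field(dirs: np.ndarray, centers: np.ndarray, amps, widths) -> np.ndarray:
    """Sum of angular Gaussians: amp_k * exp(-(angle to center_k / width_k)^2)."""
    cosang = np.clip(dirs @ centers.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    amps = np.broadcast_to(np.asarray(amps, float), (centers.shape[0],))
    widths = np.broadcast_to(np.asarray(widths, float), (centers.shape[0],))
    return (amps * np.exp(-((ang / widths) ** 2))).sum(axis=1)


def _radial_function(spec: ShapeSpec, grid: SphereGrid) -> np.ndarray:
    """Radial distances of the canonical shape on the grid directions."""
    cls = spec.shape_class
    p = dict(spec.geometry_params)
    R = spec.diameter_um / 2.0
    theta, dirs = grid.theta, grid.dirs
    geo_rng = np.random.default_rng(np.random.SeedSequence([hash(cls) & 0xFFFF, spec.seed]))

    if cls == "spherocyte":
        return np.full(grid.n_vertices, R)

    if cls == "discocyte":
        return _disc_radial_profile(theta, R)

    if cls in ("stomatocyte_I", "stomatocyte_II"):
        depth = p.get("cup_depth", 0.35 if cls == "stomatocyte_I" else 0.62)
        width = p.get("cup_width", 0.75)
        body = R * (1.0 - 0.06 * np.sin(theta) ** 2)  # slightly prolate body
        dimple = depth * np.exp(-(((np.pi - theta) / width) ** 2))
        return body * (1.0 - dimple)

    if cls in ("echinocyte_I", "echinocyte_II", "echinocyte_III"):
        blend = {"echinocyte_I": 0.15, "echinocyte_II": 0.55, "echinocyte_III": 0.85}[cls]
        blend = p.get("body_blend", blend)
        n_spikes = int(p.get("spike_count", {"echinocyte_I": 14, "echinocyte_II": 20, "echinocyte_III": 36}[cls]))
        amp = p.get("spike_amplitude", {"echinocyte_I": 0.05, "echinocyte_II": 0.13, "echinocyte_III": 0.20}[cls])
        width = p.get("spike_width", {"echinocyte_I": 0.40, "echinocyte_II": 0.30, "echinocyte_III": 0.24}[cls])
        if n_spikes < 0:
            raise InvalidSpecError("spike_count must be >= 0")
        disc = _disc_radial_profile(theta, R)
        sphere = np.full(grid.n_vertices, 0.82 * R)
        base = (1.0 - blend) * disc + blend * sphere
        if n_spikes == 0:
            return base
        centers = _fibonacci_directions(n_spikes, geo_rng)
        return base * (1.0 + _bump_field(dirs, centers, amp, width))

    if cls == "knizocyte":
        lobes = int(p.get("lobe_count", 3))
        amp = p.get("lobe_amplitude", 0.28)
        disc = _disc_radial_profile(theta, R)
        mod = 1.0 + amp * np.cos(lobes * grid.phi) * np.sin(theta) ** 4
        # thicken the centre relative to a pure disc so lobes read as ridges
        bulge = 1.0 + 0.35 * np.exp(-((np.sin(theta) * R / (0.45 * R)) ** 2))
        return disc * mod * bulge

    if cls == "acanthocyte":
        n_spikes = int(p.get("spike_count", 7))
        if not 0 <= n_spikes:
            raise InvalidSpecError("spike_count must be >= 0")
        amp0 = p.get("spike_amplitude", 0.26)
        body = np.full(grid.n_vertices, 0.85 * R)
        if n_spikes == 0:
            return body
        centers = _fibonacci_directions(n_spikes, geo_rng)
        centers = centers + geo_rng.normal(scale=0.25, size=centers.shape)
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        amps = amp0 * geo_rng.uniform(0.6, 1.4, size=n_spikes)
        widths = geo_rng.uniform(0.28, 0.5, size=n_spikes)
        return body * (1.0 + _bump_field(dirs, centers, amps, widths))

    if cls == "keratocyte":
        # stand-in: dented sphere with two horn-like remnants beside the notch
        notch_depth = p.get("notch_depth", 0.45)
        body = np.full(grid.n_vertices, 0.9 * R)
        notch_dir = np.array([1.0, 0.0, 0.0])
        horn1 = np.array([0.35, 0.85, 0.0])
        horn2 = np.array([0.35, -0.85, 0.0])
        horn1 /= np.linalg.norm(horn1)
        horn2 /= np.linalg.norm(horn2)
        r = body * (1.0 - notch_depth * np.exp(-((np.arccos(np.clip(dirs @ notch_dir, -1, 1)) / 0.8) ** 2)))
        r = r * (1.0 + _bump_field(dirs, np.stack([horn1, horn2]), 0.22, 0.45))
        return r

    if cls == "multilobate":
        n_lobes = int(p.get("lobe_count", 4))
        amp = p.get("lobe_amplitude", 0.22)
        body = np.full(grid.n_vertices, 0.82 * R)
        centers = _fibonacci_directions(max(n_lobes, 1), geo_rng)
        return body * (1.0 + _bump_field(dirs, centers, amp, 0.62))

    if cls == "cell_cluster":
        f = p.get("fusion_offset", 0.6)
        if not 0.0 <= f < 1.0:
            raise InvalidSpecError("fusion_offset must be in [0, 1)")
        rho = spec.diameter_um / (2.0 * (1.0 + f))
        c = f * rho
        r = np.zeros(grid.n_vertices)
        for center in (np.array([c, 0, 0]), np.array([-c, 0, 0])):
            dc = dirs @ center
            disc = dc * dc - (center @ center) + rho * rho
            r = np.maximum(r, dc + np.sqrt(np.maximum(disc, 0.0)))
        return r

    if cls == _UNKNOWN_CLASS:
        # heterogeneous catch-all: random lumpy blobs
        n_bumps = int(geo_rng.integers(3, 9))
        centers = geo_rng.normal(size=(n_bumps, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        amps = geo_rng.uniform(-0.3, 0.35, size=n_bumps)
        widths = geo_rng.uniform(0.5, 1.1, size=n_bumps)
        body = np.full(grid.n_vertices, 0.75 * R)
        r = body * (1.0 + _bump_field(dirs, centers, amps, widths))
        return np.maximum(r, 0.25 * R)

    raise InvalidSpecError(f"unknown shape_class {cls!r}")  # pragma: no cover


def make_canonical_mesh(spec: ShapeSpec, grid: SphereGrid | None = None) -> TriangleMesh:
    """Build the closed, bounding-box-centred mesh of a canonical shape.

    Deterministic for a fixed ``spec.seed``.
    """
    grid = grid or _DEFAULT_GRID
    radii = _radial_function(spec, grid)
    prov = f"synthetic {spec.shape_class} d={spec.diameter_um:g}um seed={spec.seed}"
    return grid.build_mesh(radii, provenance=prov)


# --------------------------------------------------------------------------- morphing


def _raycast_radial(
    mesh: TriangleMesh, dirs: np.ndarray, chunk: int | None = None, dtype=np.float64
) -> np.ndarray:
    """Distance from the origin to the mesh surface along each direction.

    Vectorised Moller-Trumbore over all triangles; the farthest positive
    hit is taken (outer surface).  A direction with no hit means the mesh
    is not star shaped about the origin.
    """
    v = mesh.vertices.astype(dtype)
    dirs = np.asarray(dirs, dtype=dtype)
    a = v[mesh.faces[:, 0]]
    e1 = v[mesh.faces[:, 1]] - a
    e2 = v[mesh.faces[:, 2]] - a
    out = np.full(len(dirs), -1.0)
    eps = 1e-12 if dtype == np.float64 else 1e-7
    btol = 1e-9 if dtype == np.float64 else 1e-4
    if chunk is None:
        chunk = max(8, int(1.5e6 / max(len(mesh.faces), 1)))
    for start in range(0, len(dirs), chunk):
        d = dirs[start : start + chunk]  # (k, 3)
        p = np.cross(d[:, None, :], e2[None, :, :])  # (k, m, 3)
        det = np.einsum("mj,kmj->km", e1, p)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = -a[None, :, :]  # origin - a
        u = np.einsum("kmj,kmj->km", s, p) * inv
        q = np.cross(s, e1[None, :, :])
        w = np.einsum("kj,kmj->km", d, q) * inv
        t = np.einsum("mj,kmj->km", e2, q) * inv
        hit = ok & (u >= -btol) & (w >= -btol) & (u + w <= 1 + btol) & (t > eps)
        t = np.where(hit, t, -1.0)
        out[start : start + chunk] = t.max(axis=1)
    return out


def remesh_to_grid(mesh: TriangleMesh, grid: SphereGrid | None = None, name: str = "mesh") -> TriangleMesh:
    """Resample a closed mesh onto the shared spherical parameterization."""
    grid = grid or _MORPH_GRID
    centered = mesh.center_to_bbox()
    radii = _raycast_radial(centered, grid.dirs)
    if (radii <= 0).any():
        raise MorphError(
            f"{name} is not star shaped about its bounding-box centre; "
            f"{int((radii <= 0).sum())} rays missed the surface"
        )
    return grid.build_mesh(radii, provenance=f"remeshed {mesh.provenance or name}")


def morph_meshes(
    mesh_a: TriangleMesh,
    mesh_b: TriangleMesh,
    t: float,
    grid: SphereGrid | None = None,
) -> TriangleMesh:
    """Linear vertex-wise morph between two remeshed closed surfaces."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    grid = grid or _MORPH_GRID
    ra = remesh_to_grid(mesh_a, grid, name="mesh_a")
    rb = remesh_to_grid(mesh_b, grid, name="mesh_b")
    verts = (1.0 - t) * ra.vertices + t * rb.vertices
    mesh = TriangleMesh(verts, grid.faces, provenance=f"morph t={t:g}")
    return mesh.ensure_outward().center_to_bbox()


# --------------------------------------------------------------------------- rasterization


def _sample_surface_points(
    mesh: TriangleMesh, spacing_um: float, return_weights: bool = False
):
    """Deterministic dense point sampling of the surface (barycentric lattice).

    With ``return_weights`` each point also carries the share of its
    triangle's area, so the weights sum to the total surface area.
    """
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    tri_area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    edge = np.maximum(
        np.linalg.norm(b - a, axis=1),
        np.maximum(np.linalg.norm(c - b, axis=1), np.linalg.norm(a - c, axis=1)),
    )
    n_sub = np.clip(np.ceil(edge / spacing_um).astype(int), 1, 64)
    pts, wts = [], []
    for n in np.unique(n_sub):
        sel = n_sub == n
        ii, jj = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = ii + jj <= n
        u = (ii[keep] / n).ravel()
        w = (jj[keep] / n).ravel()
        bary = np.column_stack([1.0 - u - w, u, w])  # (p, 3)
        pts.append(
            (bary[:, 0][None, :, None] * a[sel][:, None, :]
             + bary[:, 1][None, :, None] * b[sel][:, None, :]
             + bary[:, 2][None, :, None] * c[sel][:, None, :]).reshape(-1, 3)
        )
        n_pts = bary.shape[0]
        wts.append(np.repeat(tri_area[sel] / n_pts, n_pts))
    points = np.concatenate(pts)
    if return_weights:
        return points, np.concatenate(wts)
    return points


def rasterize_to_stack(
    mesh: TriangleMesh,
    voxel_size_xyz: tuple[float, float, float] = (110.0, 110.0, 300.0),
    blur_sigma_nm: float = 150.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    fov_um: tuple[float, float, float] | None = None,
    margin_um: float = 1.2,
) -> VoxelStack:
    """Emulate a membrane-stained confocal acquisition of *mesh*.

    The surface-distance field is mapped through a Gaussian shell profile
    of width *blur_sigma_nm*; additive Gaussian noise of sd *noise_sd*
    (relative to the unit shell peak) is clipped at zero.
    """
    vs = tuple(float(v) for v in voxel_size_xyz)
    if any(v <= 0 for v in vs):
        raise ValueError("voxel sizes must be positive")
    centered = mesh.center_to_bbox()
    lo, hi = centered.bounding_box()
    extent = hi - lo
    if fov_um is None:
        fov = tuple(extent[i] + 2 * margin_um for i in range(3))
    else:
        fov = tuple(float(f) for f in fov_um)
        if any(extent[i] > fov[i] for i in range(3)):
            raise FieldOfViewError(
                f"mesh extent {tuple(np.round(extent, 2))} um exceeds field of view {fov} um"
            )
    pitch_um = np.array(vs) / 1000.0
    n_xyz = np.maximum(np.ceil(np.array(fov) / pitch_um).astype(int), 4)
    nx, ny, nz = (int(n) for n in n_xyz)
    shell = np.zeros((nz, ny, nx), dtype=bool)
    pts = _sample_surface_points(centered, spacing_um=float(pitch_um.min()) / 2.0)
    # voxel centres at (i + 0.5) * pitch - fov/2
    idx = np.floor((pts / pitch_um[None, :]) + n_xyz[None, :] / 2.0).astype(int)
    inside = ((idx >= 0) & (idx < n_xyz[None, :])).all(axis=1)
    idx = idx[inside]
    shell[idx[:, 2], idx[:, 1], idx[:, 0]] = True
    dist_nm = ndimage.distance_transform_edt(~shell, sampling=(vs[2], vs[1], vs[0]))
    intensity = np.exp(-(dist_nm**2) / (2.0 * blur_sigma_nm**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(scale=noise_sd, size=intensity.shape)
    return VoxelStack(np.clip(intensity, 0.0, None), vs)


def rasterize_scene(
    meshes: list[TriangleMesh],
    centers_um: list[tuple[float, float, float]],
    shape_xyz: tuple[int, int, int],
    voxel_size_xyz: tuple[float, float, float] = (110.0, 110.0, 300.0),
    blur_sigma_nm: float = 150.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelStack:
    """Rasterize several cells at given physical positions into one stack.

    *centers_um* are offsets from the stack's physical origin (corner at
    0,0,0).  Used to build multi-cell test scenes for the cropping stage.
    """
    vs = tuple(float(v) for v in voxel_size_xyz)
    nx, ny, nz = shape_xyz
    pitch_um = np.array(vs) / 1000.0
    shell = np.zeros((nz, ny, nx), dtype=bool)
    for mesh, center in zip(meshes, centers_um):
        centered = mesh.center_to_bbox()
        pts = _sample_surface_points(centered, spacing_um=float(pitch_um.min()) / 2.0) + np.asarray(center)
        idx = np.floor(pts / pitch_um[None, :]).astype(int)
        inside = (idx >= 0).all(axis=1) & (idx < np.array([nx, ny, nz])[None, :]).all(axis=1)
        idx = idx[inside]
        shell[idx[:, 2], idx[:, 1], idx[:, 0]] = True
    dist_nm = ndimage.distance_transform_edt(~shell, sampling=(vs[2], vs[1], vs[0]))
    intensity = np.exp(-(dist_nm**2) / (2.0 * blur_sigma_nm**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(scale=noise_sd, size=intensity.shape)
    return VoxelStack(np.clip(intensity, 0.0, None), vs)


# --------------------------------------------------------------------------- datasets

#: Relative jitter (sd) applied to geometry parameters by default.
DEFAULT_JITTER = {"diameter": 0.05, "spike_amplitude": 0.12, "cup_depth": 0.10,
                  "lobe_amplitude": 0.10, "spike_count": 0.08, "notch_depth": 0.10,
                  "fusion_offset": 0.10, "body_blend": 0.06}

_JITTERABLE = {
    "spherocyte": ["diameter"],
    "stomatocyte_I": ["diameter", "cup_depth"],
    "stomatocyte_II": ["diameter", "cup_depth"],
    "discocyte": ["diameter"],
    "echinocyte_I": ["diameter", "spike_amplitude", "spike_count", "body_blend"],
    "echinocyte_II": ["diameter", "spike_amplitude", "spike_count", "body_blend"],
    "echinocyte_III": ["diameter", "spike_amplitude", "spike_count", "body_blend"],
    "knizocyte": ["diameter", "lobe_amplitude"],
    "keratocyte": ["diameter", "notch_depth"],
    "acanthocyte": ["diameter", "spike_amplitude", "spike_count"],
    "multilobate": ["diameter", "lobe_amplitude"],
    "cell_cluster": ["diameter", "fusion_offset"],
    _UNKNOWN_CLASS: ["diameter"],
}

_CANONICAL_GEOMETRY = {
    "stomatocyte_I": {"cup_depth": 0.35}, "stomatocyte_II": {"cup_depth": 0.62},
    "echinocyte_I": {"spike_amplitude": 0.05, "spike_count": 14, "body_blend": 0.15},
    "echinocyte_II": {"spike_amplitude": 0.13, "spike_count": 20, "body_blend": 0.55},
    "echinocyte_III": {"spike_amplitude": 0.20, "spike_count": 36, "body_blend": 0.85},
    "knizocyte": {"lobe_amplitude": 0.28},
    "keratocyte": {"notch_depth": 0.45},
    "acanthocyte": {"spike_amplitude": 0.26, "spike_count": 7},
    "multilobate": {"lobe_amplitude": 0.22},
    "cell_cluster": {"fusion_offset": 0.6},
}


def default_specs(classes=None) -> list[ShapeSpec]:
    """Canonical ShapeSpec templates for the requested classes."""
    classes = list(classes) if classes is not None else list(GENERATABLE_CLASSES)
    return [
        ShapeSpec(shape_class=c, geometry_params=dict(_CANONICAL_GEOMETRY.get(c, {})))
        for c in classes
    ]


def generate_dataset(
    specs: list[ShapeSpec],
    n_per_class: int,
    jitter: dict | None = None,
    seed: int = 0,
    grid: SphereGrid | None = None,
) -> list[tuple[TriangleMesh, ShapeSpec]]:
    """Generate *n_per_class* jittered, randomly rotated meshes per spec.

    Deterministic for a fixed *seed*.  With an all-zero jitter map the
    instances of a class differ only by their random rotation.
    """
    if not specs:
        raise ValueError("specs must not be empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    jitter = DEFAULT_JITTER if jitter is None else jitter
    no_jitter = all(v == 0 for v in jitter.values()) if jitter else True
    grid = grid or _DEFAULT_GRID
    ss = np.random.SeedSequence(seed)
    out = []
    for template, child in zip(specs, ss.spawn(len(specs))):
        streams = child.spawn(n_per_class)
        for k in range(n_per_class):
            rng = np.random.default_rng(streams[k])
            params = dict(template.geometry_params)
            diameter = template.diameter_um
            for key in _JITTERABLE.get(template.shape_class, []):
                sd = jitter.get(key, 0.0)
                if sd <= 0:
                    continue
                if key == "diameter":
                    diameter = diameter * float(np.exp(rng.normal(scale=sd)))
                else:
                    base = params.get(key, _CANONICAL_GEOMETRY.get(template.shape_class, {}).get(key))
                    if base is None:
                        continue
                    if key == "spike_count":
                        params[key] = max(0, int(round(base * np.exp(rng.normal(scale=sd)))))
                    else:
                        params[key] = float(base * np.exp(rng.normal(scale=sd)))
            geo_seed = template.seed if no_jitter else int(rng.integers(0, 2**31 - 1))
            inst = ShapeSpec(
                shape_class=template.shape_class,
                sde_score=template.sde_score if is_sde(template.shape_class) else None,
                diameter_um=diameter,
                geometry_params=params,
                seed=geo_seed,
            )
            mesh = make_canonical_mesh(inst, grid)
            mesh = mesh.rotated(random_rotation(rng)).center_to_bbox()
            out.append((mesh, inst))
    return out


# --------------------------------------------------------------------------- analysis helpers


def count_spikes(
    mesh: TriangleMesh,
    min_prominence: float = 0.02,
    peak_radius: float = 0.15,
    ring_radius: tuple[float, float] = (0.25, 0.38),
    merge_radius: float = 0.30,
    grid: SphereGrid | None = None,
) -> int:
    """Count convex point protrusions (spikes) on a star-shaped mesh.

    The mesh is resampled to a radial field r(theta, phi).  A direction
    is a spike tip if it is the radial maximum within *peak_radius*
    radians AND stands at least ``min_prominence * median(r)`` above the
    maximum of the surrounding ring at *ring_radius* radians.  The ring
    condition rejects extended ridges (e.g. the rim of a biconcave
    disc), which are high along one direction of the ring.  Nearby tips
    within *merge_radius* are merged into one spike.
    """
    grid = grid or SphereGrid(40, 80)
    centered = mesh.center_to_bbox()
    r = _raycast_radial(centered, grid.dirs, dtype=np.float32)
    if (r <= 0).any():
        raise MorphError("mesh is not star shaped; cannot count spikes")
    dirs = grid.dirs.astype(np.float32)
    cos = np.clip(dirs @ dirs.T, -1.0, 1.0)
    r32 = r.astype(np.float32)
    neg = np.float32(-np.inf)
    near_max = np.where(cos > math.cos(peak_radius), r32[None, :], neg).max(axis=1)
    ring_mask = (cos > math.cos(ring_radius[1])) & (cos < math.cos(ring_radius[0]))
    ring_max = np.where(ring_mask, r32[None, :], neg).max(axis=1)
    rmed = float(np.median(r))
    tips = np.flatnonzero(
        (r32 >= near_max) & np.isfinite(ring_max) & (r32 - ring_max > min_prominence * rmed)
    ).tolist()
    merged: list[np.ndarray] = []
    order = sorted(tips, key=lambda i: -r[i])
    for i in order:
        d = grid.dirs[i]
        if any(float(d @ m) > math.cos(merge_radius) for m in merged):
            continue
        merged.append(d)
    return len(merged)
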