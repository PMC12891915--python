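"""Triangle-mesh primitives shared by both spine shape descriptors.

Covers mesh I/O, volumetric measures, the canonical spine orientation
(junction plane to the xz-plane, maximal residual variance to z), the
"internal center" used as the origin of the spherical coordinate system,
radial tabulation of the surface by ray casting, and the symmetric
Hausdorff distance used to score reconstructions.

All lengths pass through unchanged (no unit conversion); coordinates are
assumed consistent, e.g. micrometres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import trimesh
from skimage.morphology import skeletonize

__all__ = [
    "TriangleMesh",
    "Point3",
    "SphericalSample",
    "MeshFormatError",
    "EmptyMeshError",
    "NotWatertightError",
    "OrientationError",
    "TabulationError",
    "ResolutionError",
    "DecompositionError",
    "load_mesh",
    "save_mesh",
    "load_junction_sidecar",
    "mesh_volume",
    "center_of_mass",
    "internal_center",
    "orient_spine",
    "radial_tabulation",
    "hausdorff_symmetric",
    "ray_hit_distances",
    "point_mesh_distance",
    "point_in_mesh",
    "cartesian_to_spherical",
    "spherical_to_cartesian",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# errors


class MeshFormatError(ValueError):
    """The file could not be parsed as a triangle mesh."""


class EmptyMeshError(ValueError):
    """The mesh has no faces."""


class NotWatertightError(ValueError):
    """Operation requires a closed (watertight) mesh."""


class OrientationError(ValueError):
    """Canonical orientation is unavailable (e.g. no junction region)."""


class TabulationError(ValueError):
    """Radial tabulation failed (center outside mesh or too many misses)."""


class ResolutionError(ValueError):
    """Voxel pitch too coarse for the requested operation."""


class DecompositionError(RuntimeError):
    """A descriptor chain failed for this spine ("decomposition not possible")."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Point3:
    """A point in the mesh coordinate system."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("Point3 components must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Point3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class TriangleMesh:
    """Vertices and triangular faces of one spine surface.

    ``junction_region`` optionally holds the vertex indices of the rim where
    the spine attaches to its dendrite; it drives canonical orientation.
    """

    vertices: np.ndarray
    faces: np.ndarray
    junction_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) == 0:
            raise EmptyMeshError("mesh has no faces")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        if np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise ValueError("degenerate face (repeated vertex index)")
        if self.junction_region is not None:
            self.junction_region = np.asarray(self.junction_region, dtype=np.int64)
            if len(self.junction_region) and (
                self.junction_region.min() < 0
                or self.junction_region.max() >= len(self.vertices)
            ):
                raise ValueError("junction_region indices out of range")

    # -- conversion -----------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(
        cls, tm: trimesh.Trimesh, junction_region: np.ndarray | None = None
    ) -> "TriangleMesh":
        return cls(
            vertices=np.asarray(tm.vertices, dtype=float),
            faces=np.asarray(tm.faces, dtype=np.int64),
            junction_region=junction_region,
        )

    # -- basic properties -----------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Apply v -> rotation @ v + translation to every vertex."""
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, vertices=v)


@dataclass
class SphericalSample:
    """Tabular radial function f(theta, phi) of a star-shaped surface.

    ``directions`` are unit vectors from ``center``; ``radii`` are the
    distances to the surface along them.  ``multi_hit_fraction`` and
    ``miss_count`` record how far the surface is from being star-shaped
    with respect to the chosen center.
    """

    center: Point3
    directions: np.ndarray
    radii: np.ndarray
    multi_hit_fraction: float = 0.0
    miss_count: int = 0

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise ValueError("directions must be (n, 3)")
        if len(self.directions) != len(self.radii):
            raise ValueError("directions and radii must align")
        if len(self.radii) and (
            not np.all(np.isfinite(self.radii)) or np.any(self.radii <= 0)
        ):
            raise ValueError("radii must be strictly positive and finite")
        if not 0.0 <= self.multi_hit_fraction <= 1.0:
            raise ValueError("multi_hit_fraction must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def angles(self) -> tuple[np.ndarray, np.ndarray]:
        """(zenith theta, azimuth phi) of each direction."""
        theta, phi, _ = cartesian_to_spherical(self.directions)
        return theta, phi


# ---------------------------------------------------------------------------
# coordinates


def cartesian_to_spherical(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (theta, phi, r): zenith from +z in [0, pi], azimuth in [0, 2pi)."""
    xyz = np.asarray(xyz, dtype=float)
    r = np.linalg.norm(xyz, axis=-1)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(xyz[..., 2] / np.where(r > 0, r, 1.0), -1.0, 1.0))
    phi = np.mod(np.arctan2(xyz[..., 1], xyz[..., 0]), 2.0 * np.pi)
    return theta, phi, r


def spherical_to_cartesian(
    theta: np.ndarray, phi: np.ndarray, r: np.ndarray | float = 1.0
) -> np.ndarray:
    theta, phi = np.broadcast_arrays(np.asarray(theta, float), np.asarray(phi, float))
    st = np.sin(theta)
    out = np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)
    return out * np.asarray(r, dtype=float)[..., None] if np.ndim(r) else out * float(r)


# ---------------------------------------------------------------------------
# I/O


def load_mesh(
    path: str | Path,
    fmt: Literal["ply", "obj", "stl", "auto"] = "auto",
    junction: np.ndarray | None = None,
    merge_tol: float | None = None,
) -> TriangleMesh:
    """Load a triangle mesh from PLY / OBJ / STL.

    Duplicate vertices are merged and face winding is made consistent.
    A junction region may be passed explicitly, or is picked up from a PLY
    integer vertex property named ``junction`` (1 = junction vertex).
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    ftype = path.suffix.lstrip(".").lower() if fmt == "auto" else fmt
    try:
        tm = trimesh.load_mesh(str(path), file_type=ftype)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise MeshFormatError(f"could not parse {path} as {ftype}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path} contains no geometry")
        tm = trimesh.util.concatenate(geoms)
    if tm.faces is None or len(tm.faces) == 0:
        raise EmptyMeshError(f"{path} contains no faces")

    junction_mask = None
    ply_raw = tm.metadata.get("_ply_raw", {}) if hasattr(tm, "metadata") else {}
    vert_data = ply_raw.get("vertex", {}).get("data") if ply_raw else None
    if junction is None and vert_data is not None:
        if isinstance(vert_data, dict) and "junction" in vert_data:
            junction_mask = np.asarray(vert_data["junction"]).ravel().astype(bool)
        elif "junction" in (getattr(getattr(vert_data, "dtype", None), "names", None) or ()):
            junction_mask = np.asarray(vert_data["junction"]).ravel().astype(bool)

    if merge_tol is not None:
        tm.merge_vertices(digits_vertex=int(round(-np.log10(merge_tol))))
    else:
        tm.merge_vertices()
    trimesh.repair.fix_normals(tm)

    if junction_mask is not None:
        # merge_vertices can reorder; recover by nearest original junction vertex
        junction = np.flatnonzero(junction_mask)
    mesh = TriangleMesh.from_trimesh(tm)
    if junction is not None:
        junction = np.asarray(junction, dtype=np.int64)
        junction = junction[junction < mesh.n_vertices]
        mesh.junction_region = junction
    return mesh


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh in the format implied by the file suffix (.ply/.obj/.stl)."""
    mesh.to_trimesh().export(str(path))


def load_junction_sidecar(path: str | Path, spine_id: str) -> np.ndarray:
    """Read 0-based junction vertex indices from a ``{spine_id: [...]}`` JSON."""
    with open(path) as fh:
        table = json.load(fh)
    if spine_id not in table:
        raise KeyError(f"spine_id {spine_id!r} not in {path}")
    return np.asarray(table[spine_id], dtype=np.int64)


# ---------------------------------------------------------------------------
# volume / centroid


def mesh_volume(mesh: TriangleMesh, hull_fallback: bool = False) -> float:
    """Enclosed volume by the signed-tetrahedron sum over faces.

    Requires a watertight mesh; with ``hull_fallback`` an open mesh is
    replaced by its convex hull (a warning is emitted).
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        if not hull_fallback:
            raise NotWatertightError("mesh is not watertight; volume undefined")
        warnings.warn("open mesh: volume taken from the convex hull", stacklevel=2)
        tm = tm.convex_hull
    return float(abs(tm.volume))


def center_of_mass(mesh: TriangleMesh) -> Point3:
    """Uniform-density volumetric centroid (signed-tetrahedron weighting).

    Falls back to the area-weighted surface centroid for open meshes,
    with a warning.
    """
    tm = mesh.to_trimesh()
    if tm.is_watertight:
        return Point3.from_array(tm.center_mass)
    warnings.warn(
        "open mesh: using area-weighted surface centroid", stacklevel=2
    )
    tri = mesh.triangles()
    centroids = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return Point3.from_array((centroids * areas[:, None]).sum(0) / areas.sum())


# ---------------------------------------------------------------------------
# internal center (skeleton point nearest the center of mass)


@dataclass
class _SolidVoxels:
    matrix: np.ndarray  # bool (nx, ny, nz)
    origin: np.ndarray  # center of voxel (0, 0, 0)
    pitch: float

    def indices_to_points(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.pitch


def _voxelize_solid(mesh: TriangleMesh, pitch: float) -> _SolidVoxels:
    """Solid rasterization by vertical-column crossing parity.

    For every (x, y) voxel-column center the z-crossings with the surface
    are collected (barycentric point-in-triangle test on the projected
    faces) and voxels between alternate crossings are filled.  Exact for
    watertight meshes up to grid resolution.
    """
    v = mesh.vertices
    vmin = v.min(0)
    vmax = v.max(0)
    nx, ny, nz = (np.ceil((vmax - vmin) / pitch).astype(int) + 2)
    # grid centered on the bounding box; a tiny irrational sub-voxel shift
    # keeps column centers off exact triangle edges (parity robustness)
    origin = (vmin + vmax) / 2.0 - np.array([nx - 1, ny - 1, nz - 1]) * (pitch / 2.0)
    origin = origin + pitch * 1e-4 * np.array([np.sqrt(2) - 1, np.sqrt(3) - 1, np.sqrt(5) - 2])

    tri = mesh.triangles()
    ax, ay = tri[:, 0, 0], tri[:, 0, 1]
    bx, by = tri[:, 1, 0], tri[:, 1, 1]
    cx, cy = tri[:, 2, 0], tri[:, 2, 1]
    det = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)

    keep = np.abs(det) > 1e-14  # drop vertical faces: no transversal crossing
    xs = tri[:, :, 0]
    ys = tri[:, :, 1]
    i0 = np.clip(np.floor((xs.min(1) - origin[0]) / pitch).astype(int), 0, nx - 1)
    i1 = np.clip(np.ceil((xs.max(1) - origin[0]) / pitch).astype(int), 0, nx - 1)
    j0 = np.clip(np.floor((ys.min(1) - origin[1]) / pitch).astype(int), 0, ny - 1)
    j1 = np.clip(np.ceil((ys.max(1) - origin[1]) / pitch).astype(int), 0, ny - 1)
    cnt = np.where(keep, (i1 - i0 + 1) * (j1 - j0 + 1), 0)

    # flatten every (face, column) candidate pair in one pass
    face = np.repeat(np.arange(len(tri)), cnt)
    off = np.arange(cnt.sum()) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    wj = (j1 - j0 + 1)[face]
    gi = i0[face] + off // wj
    gj = j0[face] + off % wj
    px = origin[0] + gi * pitch
    py = origin[1] + gj * pitch
    detf = det[face]
    l1 = ((bx[face] - ax[face]) * (py - ay[face]) - (by[face] - ay[face]) * (px - ax[face])) / detf
    l2 = ((cy[face] - ay[face]) * (px - ax[face]) - (cx[face] - ax[face]) * (py - ay[face])) / detf
    inside = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)

    matrix = np.zeros((nx, ny, nz), dtype=bool)
    if inside.any():
        face, gi, gj, l1, l2 = face[inside], gi[inside], gj[inside], l1[inside], l2[inside]
        w = 1.0 - l1 - l2
        zs = w * tri[face, 0, 2] + l2 * tri[face, 1, 2] + l1 * tri[face, 2, 2]
        ids = gi * ny + gj
        order = np.lexsort((zs, ids))
        ids, zs = ids[order], zs[order]
        starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
        ends = np.r_[starts[1:], len(ids)]
        kz = np.arange(nz)
        ztol = 1e-9 * max(float(np.linalg.norm(vmax - vmin)), 1.0)
        for s, e in zip(starts, ends):
            crossings = zs[s:e]
            if len(crossings) > 1:  # merge duplicate crossings through shared edges
                crossings = crossings[np.r_[True, np.diff(crossings) > ztol]]
            if len(crossings) < 2:
                continue
            i, j = divmod(int(ids[s]), ny)
            # pair alternate crossings (entry/exit); odd leftovers are grazing
            for a in range(0, len(crossings) - 1, 2):
                z0, z1 = crossings[a], crossings[a + 1]
                k0 = int(np.ceil((z0 - origin[2]) / pitch))
                k1 = int(np.floor((z1 - origin[2]) / pitch))
                if k1 >= k0:
                    matrix[i, j, max(k0, 0) : min(k1, nz - 1) + 1] = True
    return _SolidVoxels(matrix=matrix, origin=origin, pitch=pitch)


def internal_center(mesh: TriangleMesh, voxel_pitch: float | None = None) -> Point3:
    """Skeleton point nearest the center of mass; origin for spherical coordinates.

    The solid is rasterized at ``voxel_pitch`` (default: bounding-box diagonal
    / 64), thinned to a 3D skeleton, and the skeleton voxel center nearest the
    volumetric centroid is returned.  Placing the spherical origin here keeps
    the surface as close to star-shaped as the geometry allows, minimising
    multi-intersection ambiguity during radial tabulation.
    """
    if voxel_pitch is None:
        extent = mesh.vertices.max(0) - mesh.vertices.min(0)
        voxel_pitch = float(np.linalg.norm(extent)) / 64.0
    vg = _voxelize_solid(mesh, voxel_pitch)
    filled = np.asarray(vg.matrix, dtype=bool)
    if filled.sum() < 8:
        raise ResolutionError(
            f"solid thinner than pitch {voxel_pitch:g}; try halving the pitch"
        )
    skel = skeletonize(filled)
    if skel.sum() == 0:
        # thinning can erase very small blobs entirely; fall back to the
        # filled voxel set so a center is still defined
        skel = filled
    candidates = vg.indices_to_points(np.argwhere(skel))
    com = center_of_mass(mesh).to_array()
    order = np.argsort(np.linalg.norm(candidates - com, axis=1))
    for idx in order[: min(len(order), 64)]:
        p = candidates[idx]
        if point_in_mesh(mesh, p):
            return Point3.from_array(p)
    raise ResolutionError(
        f"no skeleton voxel center lies inside the mesh at pitch {voxel_pitch:g};"
        " try halving the pitch"
    )


# ---------------------------------------------------------------------------
# canonical orientation


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < _EPS:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def orient_spine(
    mesh: TriangleMesh, mode: Literal["junction", "pca"] = "junction"
) -> TriangleMesh:
    """Rotate a spine into the canonical descriptor pose.

    The pose fixes the rotational ambiguity of the (non rotation-invariant)
    real harmonics: the best-fit plane of the dendrite-junction rim is made
    parallel to the xz-plane (its normal along y, spine body at positive y),
    and the residual rotation about y puts the direction of largest vertex
    variance in the xz-projection onto the z-axis.  The vertex centroid is
    moved to the origin.  ``mode="pca"`` orients by principal axes alone when
    no junction region is available (flagged fallback).
    """
    v = mesh.vertices
    centroid = v.mean(0)
    v = v - centroid

    if mode == "junction":
        if mesh.junction_region is None or len(mesh.junction_region) < 3:
            raise OrientationError(
                "junction_region missing or too small; pass mode='pca' to orient "
                "by principal axes only"
            )
        jv = v[mesh.junction_region]
        jc = jv.mean(0)
        # least-squares plane normal = smallest principal direction
        _, _, vt = np.linalg.svd(jv - jc, full_matrices=False)
        normal = vt[-1]
        body_ids = np.setdiff1d(np.arange(len(v)), mesh.junction_region)
        body_mean = v[body_ids].mean(0) if len(body_ids) else v.mean(0)
        if np.dot(normal, body_mean - jc) < 0:
            normal = -normal
        r1 = _rotation_between(normal, np.array([0.0, 1.0, 0.0]))
    elif mode == "pca":
        _, _, vt = np.linalg.svd(v - v.mean(0), full_matrices=False)
        warnings.warn("orienting by PCA only (no junction region)", stacklevel=2)
        r1 = vt  # rows are principal directions; y gets the 3rd, z the 1st below
        r1 = np.array([vt[1], vt[2], vt[0]])
        if np.linalg.det(r1) < 0:
            r1[0] = -r1[0]
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")

    v1 = v @ r1.T
    # residual rotation about y: largest xz variance onto z
    xz = v1[:, [0, 2]]
    xz = xz - xz.mean(0)
    cov = xz.T @ xz
    eigvals, eigvecs = np.linalg.eigh(cov)
    px, pz = eigvecs[:, -1]  # dominant direction in the (x, z) plane
    ang = np.arctan2(px, pz)  # rotate so it maps to +z
    ca, sa = np.cos(ang), np.sin(ang)
    r2 = np.array([[ca, 0.0, -sa], [0.0, 1.0, 0.0], [sa, 0.0, ca]])
    v2 = v1 @ r2.T

    # deterministic sign conventions: body at +y, z-skewness non-negative
    rot = r2 @ r1
    if v2[:, 1].mean() < 0 and mode == "pca":
        flip = np.diag([1.0, -1.0, -1.0])
        rot = flip @ rot
        v2 = v2 @ flip.T
    if np.sum(v2[:, 2] ** 3) < 0:
        flip = np.diag([-1.0, 1.0, -1.0])  # proper rotation (180 deg about y)
        rot = flip @ rot
        v2 = v2 @ flip.T

    out = replace(mesh, vertices=v2)
    # keep outward winding: a rotation preserves it, nothing else to fix
    return out


# ---------------------------------------------------------------------------
# ray casting (shared origin) and radial tabulation


def ray_hit_distances(
    mesh: TriangleMesh,
    origin: np.ndarray,
    directions: np.ndarray,
    chunk_floats: float = 4e6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distances from one origin to a mesh along many ray directions.

    Vectorized Möller–Trumbore over (ray, face) blocks.  Returns
    ``(n_hits, t_min, t_max)`` arrays over rays; misses have n_hits == 0 and
    NaN distances.
    """
    origin = np.asarray(origin, dtype=float)
    directions = np.asarray(directions, dtype=float)
    tri = mesh.triangles()
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    s = origin - v0  # (F, 3), shared by all rays
    q = np.cross(s, e1)  # (F, 3)
    # Möller–Trumbore with a shared origin reduces to three (rays, 3) @ (3, F)
    # products: a = -d.n,  u*a = d.(e2 x s),  v*a = d.q,  t*a = e2.q
    n_mat = np.cross(e1, e2).T  # (3, F)
    u_mat = np.cross(e2, s).T
    v_mat = q.T
    t_num = np.einsum("fi,fi->f", e2, q)  # (F,)

    n = len(directions)
    f = len(tri)
    chunk = max(1, int(chunk_floats / max(f, 1)))
    n_hits = np.zeros(n, dtype=np.int64)
    t_min = np.full(n, np.nan)
    t_max = np.full(n, np.nan)
    eps = 1e-12
    for start in range(0, n, chunk):
        d = directions[start : start + chunk]  # (c, 3)
        a = -(d @ n_mat)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_a = 1.0 / a
            u = (d @ u_mat) * inv_a
            vpar = (d @ v_mat) * inv_a
            t = t_num[None, :] * inv_a
            hit = (
                (np.abs(a) > eps)
                & (u >= -1e-9)
                & (vpar >= -1e-9)
                & (u + vpar <= 1.0 + 1e-9)
                & (t > 1e-9)
            )
        th = np.where(hit, t, np.nan)
        cnt = hit.sum(axis=1)
        sl = slice(start, start + len(d))
        n_hits[sl] = cnt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_min[sl] = np.nanmin(th, axis=1)
            t_max[sl] = np.nanmax(th, axis=1)
    return n_hits, t_min, t_max


def point_in_mesh(mesh: TriangleMesh, point: np.ndarray) -> bool:
    """Ray-parity inside test (odd number of distinct crossings = inside).

    A ray through a shared edge is reported by both adjacent triangles, so
    crossings are de-duplicated by distance and the parity is a majority
    vote over three skewed directions.
    """
    point = np.asarray(point, float)
    tri = mesh.triangles()
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    s = point - v0
    q = np.cross(s, e1)
    n_face = np.cross(e1, e2)
    t_num = np.einsum("fi,fi->f", e2, q)
    dirs = np.array(
        [
            [0.57735027, 0.57735027, 0.57735027],
            [-0.27602622, 0.62095512, 0.73370319],
            [0.80178373, -0.26726124, -0.53452248],
        ]
    )
    votes = 0
    for d in dirs:
        a = -(n_face @ d)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (np.cross(e2, s) @ d) / a
            v = (q @ d) / a
            t = t_num / a
            hit = (np.abs(a) > 1e-12) & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
        ts = np.sort(t[hit])
        distinct = 1 + int((np.diff(ts) > 1e-9).sum()) if len(ts) else 0
        votes += distinct % 2
    return votes >= 2


def radial_tabulation(
    mesh: TriangleMesh,
    center: Point3 | np.ndarray,
    directions: np.ndarray,
    multi_hit: Literal["farthest", "first"] = "farthest",
    max_miss_fraction: float = 0.5,
) -> SphericalSample:
    """Tabulate the surface radius f(theta, phi) by casting rays from ``center``.

    For directions where the ray crosses the surface more than once the
    farthest intersection is kept by default (outer envelope; preserves the
    head outline, which dominates spine morphology); ``multi_hit="first"``
    keeps the nearest.  Rays with no hit are dropped and counted.
    """
    c = center.to_array() if isinstance(center, Point3) else np.asarray(center, float)
    directions = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("directions must be unit vectors")
    if not point_in_mesh(mesh, c):
        raise TabulationError("center is outside the mesh")
    n_hits, t_min, t_max = ray_hit_distances(mesh, c, directions)
    hit = n_hits > 0
    miss_count = int((~hit).sum())
    if miss_count > max_miss_fraction * len(directions):
        raise TabulationError(
            f"{miss_count}/{len(directions)} rays missed the surface; "
            "tabulation degenerate"
        )
    radii = t_max[hit] if multi_hit == "farthest" else t_min[hit]
    multi = float((n_hits[hit] > 1).mean()) if hit.any() else 0.0
    return SphericalSample(
        center=Point3.from_array(c),
        directions=directions[hit],
        radii=radii,
        multi_hit_fraction=multi,
        miss_count=miss_count,
    )


# ---------------------------------------------------------------------------
# point-to-mesh distance and symmetric Hausdorff distance


def _closest_dist_to_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from each point to the nearest of all triangles.

    Vectorized closest-point-on-triangle (Ericson, Real-Time Collision
    Detection) over a (points, faces) block.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]  # (F, 3)
    ab = b - a
    ac = c - a
    bc = c - b
    # every dot product below is affine in the query point, so the whole
    # (P, F) block reduces to five BLAS products plus elementwise algebra
    pab = points @ ab.T
    pac = points @ ac.T
    d1 = pab - np.einsum("fi,fi->f", ab, a)  # ab.(p - a)
    d2 = pac - np.einsum("fi,fi->f", ac, a)
    d3 = pab - np.einsum("fi,fi->f", ab, b)
    d4 = pac - np.einsum("fi,fi->f", ac, b)
    d5 = pab - np.einsum("fi,fi->f", ab, c)
    d6 = pac - np.einsum("fi,fi->f", ac, c)
    p2 = np.einsum("pi,pi->p", points, points)[:, None]
    ap2 = p2 - 2.0 * (points @ a.T) + np.einsum("fi,fi->f", a, a)  # |p - a|^2
    bp2 = p2 - 2.0 * (points @ b.T) + np.einsum("fi,fi->f", b, b)
    cp2 = p2 - 2.0 * (points @ c.T) + np.einsum("fi,fi->f", c, c)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    len_ab2 = np.einsum("fi,fi->f", ab, ab)
    len_ac2 = np.einsum("fi,fi->f", ac, ac)
    len_bc2 = np.einsum("fi,fi->f", bc, bc)
    eps = 1e-300
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_in = vb / np.where(np.abs(denom) > eps, denom, 1.0)
        w_in = vc / np.where(np.abs(denom) > eps, denom, 1.0)
        d43 = d4 - d3
        sq = np.select(
            [
                (d1 <= 0) & (d2 <= 0),  # vertex a
                (d3 >= 0) & (d4 <= d3),  # vertex b
                (d6 >= 0) & (d5 <= d6),  # vertex c
                (vc <= 0) & (d1 >= 0) & (d3 <= 0),  # edge ab
                (vb <= 0) & (d2 >= 0) & (d6 <= 0),  # edge ac
                (va <= 0) & (d43 >= 0) & (d5 - d6 >= 0),  # edge bc
            ],
            [
                ap2,
                bp2,
                cp2,
                ap2 - d1 * d1 / np.maximum(len_ab2, eps),
                ap2 - d2 * d2 / np.maximum(len_ac2, eps),
                bp2 - d43 * d43 / np.maximum(len_bc2, eps),
            ],
            default=ap2 - v_in * d1 - w_in * d2,  # face interior
        )
    return np.sqrt(np.maximum(sq.min(axis=1), 0.0))


def point_mesh_distance(
    points: np.ndarray, mesh: TriangleMesh, chunk_floats: float = 2e6
) -> np.ndarray:
    """Exact Euclidean distance from each point to the mesh surface."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles()
    chunk = max(1, int(chunk_floats / max(len(tri), 1)))
    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        out[start : start + chunk] = _closest_dist_to_triangles(
            points[start : start + chunk], tri
        )
    return out


def _surface_samples(mesh: TriangleMesh, n: int, seed: int) -> np.ndarray:
    tm = mesh.to_trimesh()
    pts, _ = trimesh.sample.sample_surface(tm, n, seed=seed)
    return np.vstack([mesh.vertices, pts])


def hausdorff_symmetric(
    a: TriangleMesh, b: TriangleMesh, n_samples: int = 10_000, seed: int = 0
) -> float:
    """Symmetric Hausdorff distance between two surfaces.

    Each direction takes the max over a sample set (all vertices plus
    ``n_samples`` uniform area-weighted surface points) of the exact
    point-to-triangle-mesh distance.  Including the vertices makes the
    estimate monotone non-decreasing in ``n_samples`` for a fixed seed.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    pa = _surface_samples(a, n_samples, seed)
    pb = _surface_samples(b, n_samples, seed + 1)
    h_ab = float(point_mesh_distance(pa, b).max())
    h_ba = float(point_mesh_distance(pb, a).max())
    return max(h_ab, h_ba)
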