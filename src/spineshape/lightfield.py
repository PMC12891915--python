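"""Light-Field descriptor: Zernike moments of five mesh silhouettes.

The oriented spine is enclosed in a sphere of radius 2r (r = maximum vertex
radius about the internal center) carrying five fixed observation points:
the three principal orthogonal views (+z, +x, +y) and two diagonal views at
zenith pi/3 and 2*pi/3, azimuth pi/3.  Each view yields an orthographic
binary silhouette, inscribed into the unit disk and decomposed into complex
Zernike moments

    a_mn = sum_{x^2+y^2<=1} f(x, y) * V*_mn(r, theta) * dA

up to radial order M (default 10: 36 moments per view, 180 total).  Moment
moduli are invariant to in-plane rotation; real parts are not, so the
camera roll is fixed deterministically (world z projected onto the view
plane as image "up"; the +z view uses world x).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from skimage.draw import polygon

from .mesh_core import (
    DecompositionError,
    EmptyMeshError,
    Point3,
    TriangleMesh,
    internal_center,
    orient_spine,
    spherical_to_cartesian,
)

__all__ = [
    "Viewpoint",
    "Silhouette",
    "LightFieldDescriptor",
    "VIEW_ANGLES",
    "observation_points",
    "project_silhouette",
    "inscribe_unit_disk",
    "minimal_enclosing_circle",
    "zernike_radial",
    "zernike_basis",
    "zernike_indices",
    "encode_zernike",
    "encode_lightfield",
    "lf_real_features",
    "reconstruct_silhouette",
    "lightfield_frame",
]

DEFAULT_M = 10
DEFAULT_PX = 256

# (zenith, azimuth) of the five observation points: the three principal
# orthogonal views (+z, +x, +y) and two diagonal views in the phi = pi/3
# half-plane, above and below the equator
VIEW_ANGLES: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (np.pi / 2, 0.0),
    (np.pi / 2, np.pi / 2),
    (np.pi / 3, np.pi / 3),
    (2 * np.pi / 3, np.pi / 3),
)
VIEW_NAMES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class Viewpoint:
    zenith: float
    azimuth: float
    distance: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not 0.0 <= self.zenith <= np.pi:
            raise ValueError("zenith must be in [0, pi]")

    def to_cartesian(self) -> np.ndarray:
        return spherical_to_cartesian(self.zenith, self.azimuth, self.distance)


@dataclass
class Silhouette:
    """Binary orthographic projection of a mesh, optionally disk-normalized."""

    pixels: np.ndarray  # bool (H, W); row 0 = top of image (+up)
    resolution: float  # pixels per length unit
    disk_center: np.ndarray | None = None  # (col, row) of the unit-disk center
    disk_radius: float | None = None  # pixels

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D raster")

    @property
    def inscribed(self) -> bool:
        return self.disk_center is not None and self.disk_radius is not None

    def foreground_xy(self) -> np.ndarray:
        """Foreground pixel centers as (x=col, y=row-up) coordinates."""
        rows, cols = np.nonzero(self.pixels)
        return np.column_stack([cols.astype(float), (self.pixels.shape[0] - 1 - rows).astype(float)])

    def normalized_xy(self) -> np.ndarray:
        """Foreground pixel centers mapped into the unit disk."""
        if not self.inscribed:
            raise ValueError("silhouette not inscribed; call inscribe_unit_disk")
        return (self.foreground_xy() - self.disk_center) / self.disk_radius


@dataclass
class LightFieldDescriptor:
    """Per-viewpoint complex Zernike moments of one spine."""

    order_M: int
    viewpoints: tuple[Viewpoint, ...]
    moments: tuple[dict[tuple[int, int], complex], ...]  # keyed by (n, m), m >= 0
    mode: str = "complex"

    def __post_init__(self) -> None:
        if len(self.viewpoints) != len(self.moments):
            raise ValueError("one moment set per viewpoint required")

    @property
    def n_moments_per_view(self) -> int:
        return len(zernike_indices(self.order_M))

    def moment_matrix(self) -> np.ndarray:
        """(n_views, n_moments) complex array in zernike_indices order."""
        idx = zernike_indices(self.order_M)
        return np.array([[mv[nm] for nm in idx] for mv in self.moments])


# ---------------------------------------------------------------------------
# viewpoints


def observation_points(
    mesh: TriangleMesh, center: Point3 | np.ndarray | None = None
) -> tuple[Viewpoint, ...]:
    """The five fixed observation points on the enclosing sphere of radius 2r.

    ``center`` is the spherical-coordinate origin (the internal center of an
    oriented spine); r is the largest vertex radius about it.
    """
    c = (
        center.to_array()
        if isinstance(center, Point3)
        else np.zeros(3)
        if center is None
        else np.asarray(center, dtype=float)
    )
    r = float(np.linalg.norm(mesh.vertices - c, axis=1).max())
    if r <= 0:
        raise EmptyMeshError("mesh has zero radius")
    return tuple(Viewpoint(th, ph, 2.0 * r) for th, ph in VIEW_ANGLES)


def _view_basis(vp: Viewpoint) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(right, up, forward) for the orthographic camera at the viewpoint.

    forward looks from the viewpoint toward the center; up is the world
    z-axis projected onto the view plane (world x for the polar view).
    """
    pos = vp.to_cartesian()
    forward = -pos / np.linalg.norm(pos)
    z = np.array([0.0, 0.0, 1.0])
    up = z - np.dot(z, forward) * forward
    if np.linalg.norm(up) < 1e-8:
        up = np.array([1.0, 0.0, 0.0])
        up = up - np.dot(up, forward) * forward
    up /= np.linalg.norm(up)
    right = np.cross(forward, up)
    return right, up, forward


# ---------------------------------------------------------------------------
# silhouette


def project_silhouette(
    mesh: TriangleMesh,
    vp: Viewpoint,
    px: int = DEFAULT_PX,
    center: Point3 | np.ndarray | None = None,
    margin: float = 0.02,
) -> Silhouette:
    """Orthographic binary silhouette of the mesh seen from a viewpoint.

    Every face is rasterized as a filled triangle on a px-by-px grid; the
    union of fills is the silhouette.  The image frame is the symmetric
    bounding square of the projected vertices around the projection of
    ``center`` plus a small margin.
    """
    if px < 32:
        raise ValueError("px must be >= 32")
    c = (
        center.to_array()
        if isinstance(center, Point3)
        else np.zeros(3)
        if center is None
        else np.asarray(center, dtype=float)
    )
    right, up, _ = _view_basis(vp)
    rel = mesh.vertices - c
    u = rel @ right
    v = rel @ up
    half = float(max(np.abs(u).max(), np.abs(v).max())) * (1.0 + margin)
    if half <= 0:
        raise EmptyMeshError("degenerate projection")
    res = px / (2.0 * half)  # pixels per length unit
    # pixel (row, col): col = (u + half) * res, row counts down from +v
    cols = (u + half) * res - 0.5
    rows = (half - v) * res - 0.5
    img = np.zeros((px, px), dtype=bool)
    for f in mesh.faces:
        rr, cc = polygon(rows[f], cols[f], shape=img.shape)
        img[rr, cc] = True
    if not img.any():
        # extremely thin projections can miss all pixel centers; mark vertices
        r = np.clip(np.round(rows).astype(int), 0, px - 1)
        cclip = np.clip(np.round(cols).astype(int), 0, px - 1)
        img[r, cclip] = True
    return Silhouette(pixels=img, resolution=res)


# ---------------------------------------------------------------------------
# minimal enclosing circle (Welzl-style incremental, on hull points)


def minimal_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest circle containing all 2D points: (center, radius)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) == 0:
        raise ValueError("no points")
    if len(pts) == 1:
        return pts[0], 0.0
    if len(pts) > 16:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear input etc.: keep all points
            pass
    # deterministic shuffle keeps the incremental algorithm near O(n)
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.linalg.norm(a - c))

    def circle_three(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
        ctr = np.array([ux, uy])
        return ctr, float(np.linalg.norm(a - ctr))

    def inside(circ, p, tol=1e-9):
        ctr, r = circ
        return np.linalg.norm(p - ctr) <= r * (1 + 1e-12) + tol

    circ = circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if inside(circ, pts[i]):
            continue
        # circle must pass through pts[i]
        circ = circle_two(pts[0], pts[i])
        for j in range(1, i):
            if inside(circ, pts[j]):
                continue
            circ = circle_two(pts[j], pts[i])
            for k in range(j):
                if inside(circ, pts[k]):
                    continue
                c3 = circle_three(pts[j], pts[i], pts[k])
                if c3 is not None:
                    circ = c3
    return circ


def inscribe_unit_disk(sil: Silhouette) -> Silhouette:
    """Normalize a silhouette by its minimal enclosing circle.

    The disk mapping removes translation and scale: the same shape drawn at
    any size or position yields the same normalized foreground up to raster
    tolerance.
    """
    fg = sil.foreground_xy()
    if len(fg) == 0:
        raise ValueError("empty silhouette foreground")
    ctr, rad = minimal_enclosing_circle(fg)
    rad = max(rad, 0.5)  # single-pixel blobs still get a positive disk
    return Silhouette(
        pixels=sil.pixels.copy(),
        resolution=sil.resolution,
        disk_center=ctr,
        disk_radius=rad * (1.0 + 1e-9),
    )


# ---------------------------------------------------------------------------
# Zernike basis


def zernike_indices(M: int) -> list[tuple[int, int]]:
    """(n, m) pairs with 0 <= n <= M, 0 <= m <= n, n - m even."""
    return [(n, m) for n in range(M + 1) for m in range(n % 2, n + 1, 2)]


def zernike_radial(n: int, m: int, r: np.ndarray) -> np.ndarray:
    """Standard radial polynomial R_n^|m|(r)."""
    m = abs(m)
    if (n - m) % 2 or m > n:
        raise ValueError(f"invalid Zernike indices n={n}, m={m}")
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for k in range((n - m) // 2 + 1):
        coef = (
            (-1.0) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out = out + coef * r ** (n - 2 * k)
    return out


def zernike_basis(n: int, m: int, r, theta):
    """Complex Zernike polynomial V_mn(r, theta) = R_n^|m|(r) e^{i m theta}."""
    if abs(m) > n or (n - abs(m)) % 2:
        raise ValueError(f"invalid Zernike indices n={n}, m={m}")
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return zernike_radial(n, abs(m), r) * np.exp(1j * m * theta)


# ---------------------------------------------------------------------------
# moments


def encode_zernike(
    sil: Silhouette, M: int = DEFAULT_M, normalization: str = "standard"
) -> dict[tuple[int, int], complex]:
    """Complex Zernike moments of an inscribed silhouette up to order M.

    The pixel sum approximates the disk integral of f * V*; only m >= 0 is
    stored (a_{n,-m} is the conjugate).  ``normalization="standard"`` applies
    the (n+1)/pi factor that makes the synthesis sum_{nm} a_mn V_mn an
    orthogonal projection; ``"plain"`` leaves the bare area-weighted sum.
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    if normalization not in ("standard", "plain"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if not sil.inscribed:
        raise ValueError("silhouette must be inscribed into the unit disk first")
    xy = sil.normalized_xy()
    r = np.linalg.norm(xy, axis=1)
    keep = r <= 1.0
    xy, r = xy[keep], r[keep]
    theta = np.arctan2(xy[:, 1], xy[:, 0])
    d_area = (1.0 / sil.disk_radius) ** 2  # pixel area in disk coordinates
    out: dict[tuple[int, int], complex] = {}
    for n, m in zernike_indices(M):
        v_conj = zernike_radial(n, m, r) * np.exp(-1j * m * theta)
        a = complex(v_conj.sum() * d_area)
        if normalization == "standard":
            a *= (n + 1) / np.pi
        out[(n, m)] = a
    return out


def encode_lightfield(
    mesh: TriangleMesh,
    M: int = DEFAULT_M,
    px: int = DEFAULT_PX,
    orient: bool = True,
    normalization: str = "standard",
) -> LightFieldDescriptor:
    """Full light-field chain: orient, five silhouettes, Zernike moments.

    Any stage failure marks the spine "decomposition not possible"
    (DecompositionError).
    """
    try:
        oriented = orient_spine(mesh) if orient else mesh
        center = internal_center(oriented)
        vps = observation_points(oriented, center)
        moments = []
        for vp in vps:
            sil = project_silhouette(oriented, vp, px=px, center=center)
            sil = inscribe_unit_disk(sil)
            moments.append(encode_zernike(sil, M=M, normalization=normalization))
    except DecompositionError:
        raise
    except Exception as exc:
        raise DecompositionError(f"decomposition not possible: {exc}") from exc
    return LightFieldDescriptor(
        order_M=M, viewpoints=vps, moments=tuple(moments), mode="complex"
    )


def lf_real_features(desc: LightFieldDescriptor, mode: str = "modulus") -> np.ndarray:
    """Real feature vector: per-moment real parts or moduli over all views.

    Moduli (the default; the better-performing representation) are invariant
    to in-plane silhouette rotation, real parts are not.
    """
    if desc.mode != "complex":
        raise ValueError("descriptor must hold complex moments")
    mat = desc.moment_matrix()
    if mode == "modulus":
        return np.abs(mat).ravel()
    if mode == "real":
        return np.real(mat).ravel()
    raise ValueError(f"unknown mode {mode!r}")


def reconstruct_silhouette(
    moments: dict[tuple[int, int], complex],
    M: int | None = None,
    px: int = DEFAULT_PX,
    threshold: float = 0.5,
    normalization: str = "standard",
) -> Silhouette:
    """Binary approximation image from Zernike moments.

    Evaluates the real part of the synthesis sum (conjugate m < 0 terms
    included) on the px-by-px unit-disk grid and thresholds at ``threshold``
    of the maximum.
    """
    if M is None:
        M = max(n for n, _ in moments)
    lin = (np.arange(px) + 0.5) / px * 2.0 - 1.0
    xg, yg = np.meshgrid(lin, -lin)  # row 0 = top (+y)
    r = np.hypot(xg, yg)
    theta = np.arctan2(yg, xg)
    mask = r <= 1.0
    field = np.zeros((px, px))
    for (n, m), a in moments.items():
        if n > M:
            continue
        v = zernike_radial(n, m, np.where(mask, r, 0.0)) * np.exp(1j * m * theta)
        scale = 1.0 if normalization == "standard" else (n + 1) / np.pi
        term = np.real(a * v) * scale
        field += term if m == 0 else 2.0 * term
    field[~mask] = 0.0
    peak = field.max()
    img = field >= threshold * peak if peak > 0 else np.zeros_like(mask)
    img &= mask
    return Silhouette(
        pixels=img,
        resolution=px / 2.0,
        disk_center=np.array([(px - 1) / 2.0, (px - 1) / 2.0]),
        disk_radius=px / 2.0,
    )


# ---------------------------------------------------------------------------
# export


def lightfield_frame(
    descriptors: dict[str, LightFieldDescriptor], mode: str = "modulus"
) -> pd.DataFrame:
    """Wide table spine_id x (view, n, m) real features for model input."""
    if not descriptors:
        raise ValueError("no descriptors to export")
    rows = []
    for spine_id, d in descriptors.items():
        idx = zernike_indices(d.order_M)
        names = [
            f"{VIEW_NAMES[v]}_{mode[:3]}_{n}_{m}"
            for v in range(len(d.viewpoints))
            for n, m in idx
        ]
        rows.append(
            {"spine_id": spine_id, "M": d.order_M}
            | dict(zip(names, lf_real_features(d, mode=mode)))
        )
    return pd.DataFrame(rows)


def lightfield_long_frame(descriptors: dict[str, LightFieldDescriptor]) -> pd.DataFrame:
    """Long table: spine_id, view, n, m, re, im, modulus."""
    rows = []
    for spine_id, d in descriptors.items():
        for v, mv in enumerate(d.moments):
            for (n, m), a in mv.items():
                rows.append(
                    {
                        "spine_id": spine_id,
                        "view": VIEW_NAMES[v],
                        "n": n,
                        "m": m,
                        "re": a.real,
                        "im": a.imag,
                        "modulus": abs(a),
                    }
                )
    return pd.DataFrame(rows)
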