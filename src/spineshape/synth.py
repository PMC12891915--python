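"""Parametric synthetic dendritic spines and two-group populations.

Since no spine mesh dataset is deposited, the package generates its own:
each spine is a watertight lathe solid — a circular profile R(t) revolved
about the spine axis (+y, junction disk at y=0), with an optional lateral
"bend" shear and Gaussian vertex jitter along normals for within-class
variability.  The profiles emulate the classical morphological classes:

* mushroom — bulbous ellipsoidal head on a narrower neck
* thin — long neck, small head
* stubby — head sitting directly on the dendrite (no neck)
* filopodia — headless tapered protrusion (flagged; excluded from
  reconstruction comparisons, as is conventional)

A two-group population applies multiplicative treated-group effects
(smaller head, longer neck — the volume-reducing, elongating phenotype of
amyloid-beta exposure) on top of per-spine lognormal parameter jitter.

Because the bend is a pure shear of circular cross-sections, the solid
volume is exactly pi * integral R(t)^2 dt (Cavalieri), which doubles as an
analytic oracle for the mesh volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .mesh_core import TriangleMesh
from .sphharm import spine_seed

__all__ = [
    "SpineShapeParams",
    "PopulationSpec",
    "SpineRecord",
    "CLASS_DEFAULTS",
    "make_spine",
    "analytic_volume",
    "generate_population",
]

CLASS_NAMES = ("mushroom", "thin", "stubby", "filopodia")


@dataclass(frozen=True)
class SpineShapeParams:
    """Geometry of one synthetic spine (lengths in the same unit, e.g. um)."""

    class_name: str
    head_radius: float
    neck_radius: float
    neck_length: float
    head_eccentricity: float = 1.0  # head semi-axis along the spine axis / head_radius
    jitter_sd: float = 0.01
    bend: float = 0.15  # lateral tip offset as a fraction of total length
    mesh_resolution: int = 3  # ring vertex count = 12 * 2**(resolution - 1)

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if self.head_radius <= 0 or self.neck_radius <= 0:
            raise ValueError("radii must be positive")
        if self.neck_length < 0:
            raise ValueError("neck_length must be >= 0")
        if self.head_eccentricity < 1.0:
            raise ValueError("head_eccentricity must be >= 1")
        if self.jitter_sd < 0 or self.jitter_sd >= self.neck_radius / 2:
            raise ValueError("jitter_sd must be in [0, neck_radius / 2)")
        if self.mesh_resolution < 1:
            raise ValueError("mesh_resolution must be >= 1")


CLASS_DEFAULTS: dict[str, SpineShapeParams] = {
    "mushroom": SpineShapeParams("mushroom", 0.50, 0.16, 0.45, 1.1),
    "thin": SpineShapeParams("thin", 0.21, 0.11, 1.00, 1.1),
    "stubby": SpineShapeParams("stubby", 0.45, 0.38, 0.00, 1.0),
    "filopodia": SpineShapeParams("filopodia", 0.08, 0.13, 1.20, 1.0),
}


class TreatmentEffect(NamedTuple):
    """Multiplicative treated-group shifts (volume-reducing by construction)."""

    head_radius_factor: float = 0.7
    neck_length_factor: float = 1.4


@dataclass
class PopulationSpec:
    """Two-group population layout and effect sizes."""

    n_per_group: int = 100
    class_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "control": {"mushroom": 0.4, "thin": 0.3, "stubby": 0.2, "filopodia": 0.1},
            "treated": {"mushroom": 0.4, "thin": 0.3, "stubby": 0.2, "filopodia": 0.1},
        }
    )
    effect: TreatmentEffect = TreatmentEffect()
    param_jitter_sd: float = 0.08  # lognormal sigma of per-spine parameter scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g, mix in self.class_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class mixture for {g!r} sums to {total}, not 1")
            if any(c not in CLASS_NAMES for c in mix):
                raise ValueError(f"unknown class in mixture for {g!r}")
        if self.effect.head_radius_factor > 1.0:
            raise ValueError("head_radius_factor must be <= 1 (volume-reducing)")
        if self.effect.neck_length_factor < 1.0:
            raise ValueError("neck_length_factor must be >= 1 (elongating)")


class SpineRecord(NamedTuple):
    spine_id: str
    group: str
    class_name: str
    mesh: TriangleMesh


# ---------------------------------------------------------------------------
# profile geometry


def _profile(params: SpineShapeParams, t: np.ndarray) -> np.ndarray:
    """Cross-section radius R(t) along the axis, t in [0, total_length]."""
    hr, nr, nl = params.head_radius, params.neck_radius, params.neck_length
    ecc = params.head_eccentricity
    if params.class_name == "filopodia" or hr <= nr:
        # tapered shaft ending in a spherical tip cap of radius head_radius
        cap = ecc * hr
        shaft = np.interp(t, [0.0, nl], [nr, hr])
        u = np.clip((t - nl) / cap, 0.0, 1.0)
        tip = hr * np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0))
        return np.where(t <= nl, shaft, tip)
    # ellipsoidal head fused to a cylindrical neck where the head
    # cross-section equals the neck radius
    axis_semi = hr * ecc
    off = axis_semi * np.sqrt(1.0 - (nr / hr) ** 2)
    t_center = nl + off
    u = np.clip((t - t_center) / axis_semi, -1.0, 1.0)
    head = hr * np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0))
    return np.where(t <= nl, nr, head)


def _total_length(params: SpineShapeParams) -> float:
    hr, nr, nl = params.head_radius, params.neck_radius, params.neck_length
    ecc = params.head_eccentricity
    if params.class_name == "filopodia" or hr <= nr:
        return nl + ecc * hr
    return nl + hr * ecc * (1.0 + np.sqrt(1.0 - (nr / hr) ** 2))


def analytic_volume(params: SpineShapeParams, n_quad: int = 4096) -> float:
    """Exact solid volume pi * integral R(t)^2 dt (trapezoid at high n)."""
    total = _total_length(params)
    t = np.linspace(0.0, total, n_quad)
    return float(np.pi * np.trapezoid(_profile(params, t) ** 2, t))


# ---------------------------------------------------------------------------
# mesh construction


def _arc_length_stations(params: SpineShapeParams, n_rings: int) -> np.ndarray:
    """Axial stations equally spaced along the profile arc length."""
    total = _total_length(params)
    t_dense = np.linspace(0.0, total, 2048)
    r_dense = _profile(params, t_dense)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.hypot(np.diff(t_dense), np.diff(r_dense)))]
    )
    targets = np.linspace(0.0, arc[-1], n_rings + 1)  # last station = tip pole
    return np.interp(targets, arc, t_dense)


def make_spine(params: SpineShapeParams, seed: int = 0) -> TriangleMesh:
    """Build one watertight synthetic spine mesh.

    The junction disk sits in the y=0 plane (rim = ``junction_region``), the
    spine extends toward +y, and the bend shears ring centers toward +x.
    Jitter displaces every vertex except the junction disk along its normal;
    a jittered mesh that comes out non-watertight is retried with the jitter
    halved (three failures raise).
    """
    rng = np.random.default_rng(seed)
    n_theta = 12 * 2 ** (params.mesh_resolution - 1)
    n_rings = max(2 * n_theta // 3, 16)
    stations = _arc_length_stations(params, n_rings)
    radii = _profile(params, stations)
    total = _total_length(params)
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    ct, st = np.cos(theta), np.sin(theta)

    jitter = params.jitter_sd
    for _attempt in range(3):
        verts: list[np.ndarray] = []
        faces: list[tuple[int, int, int]] = []
        # bottom cap: center + rim ring at y=0
        verts.append(np.array([0.0, 0.0, 0.0]))
        ring_prev = None
        for i, (t, r) in enumerate(zip(stations, radii)):
            if i == len(stations) - 1 or r <= 1e-9:
                break
            shear = params.bend * total * (t / total) ** 2
            base = len(verts)
            ring = np.column_stack(
                [r * ct + shear, np.full(n_theta, t), r * st]
            )
            verts.extend(ring)
            idx = np.arange(base, base + n_theta)
            if ring_prev is None:
                # fan: junction disk (downward-facing -> wind for outward -y)
                for j in range(n_theta):
                    faces.append((0, idx[j], idx[(j + 1) % n_theta]))
            else:
                for j in range(n_theta):
                    a, b = ring_prev[j], ring_prev[(j + 1) % n_theta]
                    c, d = idx[j], idx[(j + 1) % n_theta]
                    faces.append((a, c, b))
                    faces.append((b, c, d))
            ring_prev = idx
        # tip pole
        tip_shear = params.bend * total
        tip = np.array([tip_shear, total, 0.0])
        tip_idx = len(verts)
        verts.append(tip)
        for j in range(n_theta):
            faces.append((ring_prev[j], tip_idx, ring_prev[(j + 1) % n_theta]))

        v = np.asarray(verts, dtype=float)
        f = np.asarray(faces, dtype=np.int64)
        junction = np.arange(1, 1 + n_theta)

        if jitter > 0:
            mesh = TriangleMesh(vertices=v, faces=f, junction_region=junction)
            tm = mesh.to_trimesh()
            normals = np.asarray(tm.vertex_normals)
            disp = rng.normal(0.0, jitter, size=len(v))
            fixed = np.zeros(len(v), dtype=bool)
            fixed[0] = True
            fixed[junction] = True
            disp[fixed] = 0.0
            v = v + normals * disp[:, None]

        mesh = TriangleMesh(vertices=v, faces=f, junction_region=junction)
        tm = mesh.to_trimesh()
        if tm.is_watertight and tm.volume > 0:
            return mesh
        jitter *= 0.5
        import warnings

        warnings.warn("jittered mesh not watertight; retrying with jitter halved")
    raise RuntimeError("could not build a watertight spine after 3 attempts")


# ---------------------------------------------------------------------------
# populations


def _jittered_params(
    base: SpineShapeParams, rng: np.random.Generator, sigma: float
) -> SpineShapeParams:
    def ln(x: float) -> float:
        return float(x * rng.lognormal(0.0, sigma)) if x > 0 else x

    ecc = max(1.0, base.head_eccentricity * rng.lognormal(0.0, sigma / 2))
    p = replace(
        base,
        head_radius=ln(base.head_radius),
        neck_radius=ln(base.neck_radius),
        neck_length=ln(base.neck_length),
        head_eccentricity=ecc,
    )
    # keep the jitter-vs-neck invariant after parameter scatter
    if p.jitter_sd >= p.neck_radius / 2:
        p = replace(p, jitter_sd=p.neck_radius / 4)
    return p


def generate_population(spec: PopulationSpec) -> list[SpineRecord]:
    """Draw a two-group spine population per the spec (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    records: list[SpineRecord] = []
    for group in ("control", "treated"):
        mix = spec.class_mixture[group]
        names = sorted(mix)
        probs = np.array([mix[c] for c in names])
        draws = rng.choice(len(names), size=spec.n_per_group, p=probs)
        for i, ci in enumerate(draws):
            cname = names[ci]
            sid = f"{group}_{i:04d}"
            p = _jittered_params(CLASS_DEFAULTS[cname], rng, spec.param_jitter_sd)
            if group == "treated":
                p = replace(
                    p,
                    head_radius=p.head_radius * spec.effect.head_radius_factor,
                    neck_length=p.neck_length * spec.effect.neck_length_factor,
                )
                if p.jitter_sd >= p.neck_radius / 2:
                    p = replace(p, jitter_sd=p.neck_radius / 4)
            mesh = make_spine(p, seed=spine_seed(spec.seed, sid))
            records.append(SpineRecord(sid, group, cname, mesh))
    return records
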