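"""Synthetic proximal femur with exactly known neck axis and head centre.

The phantom is the smooth union of analytic primitives in CT-like mm
coordinates (+x lateral, +y anterior, +z superior):

* a shaft capsule along +z,
* a tapered elliptical neck cone whose axis direction is set by the
  neck-shaft angle and anteversion,
* a head sphere centred on the neck axis or offset perpendicular to it
  by a controllable distance (the offset becomes the ground-truth DBHF),
* two compactly supported trochanter bumps whose apices define the
  greater- and lesser-trochanter landmarks.

The implicit field is isosurfaced by marching cubes, which guarantees a
watertight triangulation; surface noise (vertex jitter) and head-cap
flattening (collapse mimic) are optional stressors.  Ground truth is
recorded from the construction before meshing, so every fitted quantity
can be scored against a known axis and head centre.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import brentq
from skimage.measure import marching_cubes

from .exceptions import MeshResolutionError, NumericalError
from .geometry import Line3D, Vec3, point_line_distance, unit
from .model import (
    DEFAULT_SEED,
    FemoralNeckAxisModel,
    LandmarkSet,
    SectionConfig,
)

SMIN_K_MM = 6.0  # smooth-union blending radius at the head-neck junction


@dataclass(frozen=True)
class FemurSpec:
    """Parameters of the synthetic proximal femur (all lengths in mm)."""

    head_radius: float = 24.0
    head_offset: float = 0.0  # perpendicular offset of head centre from axis
    neck_length: float = 35.0
    neck_radius_head: float = 14.0
    neck_radius_base: float = 17.0
    neck_ellipticity: float = 0.85  # minor/major axis ratio of neck sections
    neck_shaft_angle: float = 130.0  # degrees
    anteversion: float = 15.0  # degrees
    shaft_radius: float = 14.0
    shaft_length: float = 80.0
    trochanter_bump_amp: float = 8.0
    vertex_noise_sigma: float = 0.0
    head_flatten_frac: float = 0.0  # fraction of head cap flattened
    voxel_pitch: float = 0.8
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        for name in (
            "head_radius",
            "neck_length",
            "neck_radius_head",
            "neck_radius_base",
            "shaft_radius",
            "shaft_length",
            "voxel_pitch",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.neck_ellipticity <= 1.0:
            raise ValueError("neck_ellipticity must be in [0, 1]")
        if not 0.0 <= self.head_flatten_frac < 0.5:
            raise ValueError("head_flatten_frac must be in [0, 0.5)")
        if self.head_offset < 0:
            raise ValueError("head_offset must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Construction-exact quantities the fit is scored against."""

    neck_axis: Line3D
    head_centre: Vec3
    landmarks: LandmarkSet
    head_vertex_tags: np.ndarray  # bool per mesh vertex


@dataclass(frozen=True)
class _Frame:
    """Analytic construction derived from a FemurSpec."""

    spec: FemurSpec
    neck_base: Vec3
    neck_dir: Vec3
    e1: Vec3  # in-section major-axis direction
    e2: Vec3  # in-section minor-axis direction (superiorly tilted)
    head_centre: Vec3
    shaft_a: Vec3
    shaft_b: Vec3
    gt_centre: Vec3
    lt_centre: Vec3
    flatten_dir: Vec3


# how far (mm) the neck primitive is extrapolated below its base so the
# intertrochanteric region is solid (no tunnel between neck and shaft)
_NECK_BASE_EXT = 16.0


def _build_frame(spec: FemurSpec) -> _Frame:
    gamma = np.radians(180.0 - spec.neck_shaft_angle)  # polar angle from +z
    alpha = np.radians(spec.anteversion)
    d = np.array(
        [-np.sin(gamma) * np.cos(alpha), np.sin(gamma) * np.sin(alpha), np.cos(gamma)]
    )
    d = unit(d)
    e1 = unit(np.cross(np.array([0.0, 0.0, 1.0]), d))
    e2 = np.cross(d, e1)
    neck_base = np.array([0.0, 0.0, 0.0])
    # the head centre sits past the neck tip so the head-neck junction
    # stays clear of the sliced neck span
    head_centre = (
        neck_base
        + (spec.neck_length + 0.3 * spec.head_radius) * d
        + spec.head_offset * e2
    )
    # the shaft cap stays well below the neck base so that sections
    # perpendicular to the neck axis clear the medial shaft (calcar)
    shaft_b = np.array([0.0, 0.0, -16.0 - spec.shaft_radius])
    shaft_a = np.array([0.0, 0.0, -spec.shaft_length])
    # trochanter bump centres sit inside the trochanteric mass so the bumps
    # raise distinct apices: greater trochanter superolateral (above the
    # neck base), lesser trochanter posteromedial on the upper shaft
    gt_centre = np.array([17.0, 2.0, 11.0])
    lt_centre = np.array([-11.6, -8.5, -16.0])
    return _Frame(
        spec=spec,
        neck_base=neck_base,
        neck_dir=d,
        e1=e1,
        e2=e2,
        head_centre=head_centre,
        shaft_a=shaft_a,
        shaft_b=shaft_b,
        gt_centre=gt_centre,
        lt_centre=lt_centre,
        flatten_dir=d,
    )


def _smin(a, b, k=SMIN_K_MM):
    """Polynomial smooth minimum; inflates by at most k/4 where a == b."""
    h = np.clip(k - np.abs(a - b), 0.0, None) / k
    return np.minimum(a, b) - 0.25 * k * h * h


def _capsule_dist(p, a, b, r):
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1) - r


def _neck_dist(p, fr: _Frame):
    spec = fr.spec
    q = p - fr.neck_base
    t_raw = q @ fr.neck_dir
    t = np.clip(t_raw, -_NECK_BASE_EXT, spec.neck_length)
    w = t_raw - t  # axial overshoot beyond the clipped segment (exact 0 inside)
    rel = p - (fr.neck_base + t[..., None] * fr.neck_dir)
    u = rel @ fr.e1
    v = rel @ fr.e2
    a = spec.neck_radius_base + (spec.neck_radius_head - spec.neck_radius_base) * (
        t / spec.neck_length
    )
    b = spec.neck_ellipticity * a
    d_trans = (np.sqrt((u / a) ** 2 + (v / b) ** 2) - 1.0) * b
    return np.where(
        w != 0.0,
        np.hypot(np.maximum(d_trans, 0.0), np.abs(w)),
        d_trans,
    )


def _head_dist(p, fr: _Frame):
    spec = fr.spec
    d = np.linalg.norm(p - fr.head_centre, axis=-1) - spec.head_radius
    if spec.head_flatten_frac > 0:
        cut = (p - fr.head_centre) @ fr.flatten_dir - spec.head_radius * (
            1.0 - 2.0 * spec.head_flatten_frac
        )
        d = np.maximum(d, cut)
    return d


def _bump(p, centre, radius):
    """Compactly supported quartic bump: 1 at the centre, 0 beyond radius.

    A hard support boundary (unlike a Gaussian tail) keeps the bumps from
    inflating the neck cross-sections, whose centroids must stay on the
    construction axis.
    """
    r2 = np.sum((p - centre) ** 2, axis=-1) / radius**2
    return np.clip(1.0 - r2, 0.0, None) ** 2


def femur_field(points, fr: _Frame) -> np.ndarray:
    """Signed implicit field of the phantom (negative inside)."""
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    spec = fr.spec
    d = _smin(_capsule_dist(p, fr.shaft_a, fr.shaft_b, spec.shaft_radius),
              _neck_dist(p, fr))
    d = _smin(d, _head_dist(p, fr))
    d = d - spec.trochanter_bump_amp * _bump(p, fr.gt_centre, 6.0)
    d = d - 0.75 * spec.trochanter_bump_amp * _bump(p, fr.lt_centre, 6.0)
    return d


def _surface_point(fr: _Frame, start, direction, max_mm=60.0) -> Vec3:
    """March from an interior point along a ray to the implicit surface."""
    start = np.asarray(start, dtype=float)
    u = unit(direction)

    def g(s):
        return float(femur_field(start + s * u, fr)[0])

    if g(0.0) >= 0:
        raise NumericalError("surface ray must start inside the solid")
    s_hi = None
    for s in np.arange(1.0, max_mm, 1.0):
        if g(s) > 0:
            s_hi = s
            break
    if s_hi is None:
        raise NumericalError("surface ray never left the solid")
    s_root = brentq(g, s_hi - 1.0, s_hi, xtol=1e-10)
    return start + s_root * u


def _landmarks(fr: _Frame) -> LandmarkSet:
    """Constructive landmark definitions on the phantom.

    The greater/lesser trochanter tips are the surface apices of the two
    bumps (surface crossing along each bump's outward ray); the
    intertrochanteric midpoint is the anterior surface point midway
    between the bumps.  These stand in for the anatomical definitions,
    as a simulation convention.
    """
    gt_dir = unit(fr.gt_centre - 0.3 * (fr.neck_base + fr.shaft_b))
    gt_tip = _surface_point(fr, fr.gt_centre, gt_dir)
    lt_dir = unit(fr.lt_centre - np.array([0.0, 0.0, fr.lt_centre[2]]))
    lt_tip = _surface_point(fr, fr.lt_centre, lt_dir)
    it_mid = _surface_point(
        fr, np.array([3.0, 0.0, -1.0]), np.array([0.15, 1.0, 0.0])
    )
    return LandmarkSet(
        gt_tip=gt_tip, lt_tip=lt_tip, it_mid=it_mid, head_hint=fr.head_centre
    )


def generate_femur(spec: FemurSpec | None = None) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Generate a watertight proximal-femur phantom and its ground truth.

    Deterministic for a given spec (including its seed): two calls with
    the same spec yield identical meshes.
    """
    spec = spec or FemurSpec()
    min_neck_r = spec.neck_ellipticity * min(spec.neck_radius_head, spec.neck_radius_base)
    if spec.voxel_pitch > min_neck_r / 4.0:
        raise MeshResolutionError(
            f"voxel_pitch {spec.voxel_pitch} mm too coarse to resolve a neck of "
            f"minimal radius {min_neck_r:.1f} mm (limit {min_neck_r / 4.0:.2f} mm)"
        )
    fr = _build_frame(spec)

    # domain margin: smooth-union inflation (k/4), jitter, and a few voxels;
    # the bump apices stay inside the primitive bounding boxes plus this
    margin = 8.0 + 3.0 * spec.voxel_pitch + 4.0 * spec.vertex_noise_sigma
    ref_pts = np.array(
        [
            fr.shaft_a,
            fr.shaft_b,
            fr.head_centre,
            fr.neck_base,
            fr.gt_centre,
            fr.lt_centre,
        ]
    )
    radii = np.array(
        [
            spec.shaft_radius,
            spec.shaft_radius,
            spec.head_radius,
            spec.neck_radius_base,
            0.0,
            0.0,
        ]
    )
    lo = (ref_pts - radii[:, None]).min(axis=0) - margin
    hi = (ref_pts + radii[:, None]).max(axis=0) + margin

    pitch = spec.voxel_pitch
    xs = np.arange(lo[0], hi[0] + pitch, pitch)
    ys = np.arange(lo[1], hi[1] + pitch, pitch)
    zs = np.arange(lo[2], hi[2] + pitch, pitch)
    # evaluate the field one x-slab at a time to keep temporaries small
    vol = np.empty((len(xs), len(ys), len(zs)))
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    slab = np.empty((len(ys) * len(zs), 3))
    slab[:, 1] = yy.ravel()
    slab[:, 2] = zz.ravel()
    for i, x in enumerate(xs):
        slab[:, 0] = x
        vol[i] = femur_field(slab, fr).reshape(len(ys), len(zs))

    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(pitch, pitch, pitch))
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    # marching cubes can emit isolated degenerate triangles at saddle
    # tangencies; keep the main closed surface
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    if not mesh.is_watertight:
        parts = mesh.split(only_watertight=False)
        mesh = max(parts, key=lambda m: len(m.faces))
    if not mesh.is_watertight:
        raise NumericalError("isosurfaced phantom unexpectedly not watertight")

    # tag head-sphere vertices before jitter (vertex order is preserved)
    v = mesh.vertices.view(np.ndarray)
    sphere_res = np.abs(
        np.linalg.norm(v - fr.head_centre, axis=1) - spec.head_radius
    )
    tags = sphere_res < 0.4
    if spec.head_flatten_frac > 0:
        cut = (v - fr.head_centre) @ fr.flatten_dir
        tags &= cut < spec.head_radius * (1.0 - 2.0 * spec.head_flatten_frac) - 0.5

    if spec.vertex_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        mesh.vertices = v + rng.normal(0.0, spec.vertex_noise_sigma, v.shape)

    truth = GroundTruth(
        neck_axis=Line3D(fr.neck_base, fr.neck_dir),
        head_centre=fr.head_centre,
        landmarks=_landmarks(fr),
        head_vertex_tags=tags,
    )
    # construction invariant: the head centre sits exactly head_offset off axis
    assert (
        abs(point_line_distance(truth.head_centre, truth.neck_axis) - spec.head_offset)
        < 1e-6
    )
    return mesh, truth


def perturb_landmarks(lm: LandmarkSet, sigma: float, seed: int) -> LandmarkSet:
    """Displace the three landmarks by isotropic Gaussian noise (std sigma).

    Emulates observer variability in picking the anatomical points; the
    orientation hint is left unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return lm
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, (3, 3))
    return LandmarkSet(
        gt_tip=lm.gt_tip + noise[0],
        lt_tip=lm.lt_tip + noise[1],
        it_mid=lm.it_mid + noise[2],
        head_hint=lm.head_hint,
    )


def simulate_reliability_study(
    spec: FemurSpec | None = None,
    n_cases: int = 10,
    n_raters: int = 1,
    n_reps: int = 3,
    sigma_rater: float = 0.5,
    seed: int = DEFAULT_SEED,
    case_offset_sd: float = 1.0,
    case_angle_sd: float = 2.0,
    config: SectionConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a repeated-measures DBHF study.

    Cases differ by jittered head offset (the dominant between-case DBHF
    variance) and mild neck-angle jitter; raters/repetitions differ by
    landmark perturbation of std ``sigma_rater``.  Returns the long-form
    table (case, rater, rep, dbhf) and a dict with the per-case true
    offsets and any failed runs (reported, not dropped).
    """
    if n_cases < 2 or n_raters < 1 or n_reps < 1:
        raise ValueError("need n_cases >= 2, n_raters >= 1, n_reps >= 1")
    spec = spec or FemurSpec()
    rng = np.random.default_rng(seed)
    rows = []
    offsets = []
    failures = []
    for case in range(n_cases):
        case_spec = replace(
            spec,
            head_offset=abs(spec.head_offset + rng.normal(0.0, case_offset_sd)),
            neck_shaft_angle=spec.neck_shaft_angle + rng.normal(0.0, case_angle_sd),
            anteversion=spec.anteversion + rng.normal(0.0, case_angle_sd),
            seed=int(rng.integers(2**31 - 1)),
        )
        offsets.append(case_spec.head_offset)
        mesh, truth = generate_femur(case_spec)
        for rater in range(n_raters):
            for rep in range(n_reps):
                lm = perturb_landmarks(
                    truth.landmarks, sigma_rater, seed=int(rng.integers(2**31 - 1))
                )
                try:
                    res = FemoralNeckAxisModel(mesh, lm, config).fit()
                    dbhf = res.dbhf
                except Exception as exc:  # noqa: BLE001 - reported, not dropped
                    failures.append({"case": case, "rater": rater, "rep": rep,
                                     "error": repr(exc)})
                    dbhf = np.nan
                rows.append(
                    {"case": case, "rater": rater, "rep": rep, "dbhf": dbhf}
                )
    table = pd.DataFrame(rows)
    info = {
        "case_head_offsets": np.array(offsets),
        "sigma_rater": sigma_rater,
        "failures": failures,
    }
    return table, info


def measurement_table(table: pd.DataFrame, by: str = "rep", rater: int = 0) -> pd.DataFrame:
    """Pivot a long study table into a subjects x columns grid for the ICC.

    ``by="rep"`` gives the intra-observer layout (one rater, repetitions
    as columns); ``by="rater"`` the inter-observer layout (first rep of
    each rater).
    """
    if by == "rep":
        sub = table[table["rater"] == rater]
        return sub.pivot(index="case", columns="rep", values="dbhf")
    if by == "rater":
        sub = table[table["rep"] == 0]
        return sub.pivot(index="case", columns="rater", values="dbhf")
    raise ValueError("by must be 'rep' or 'rater'")
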