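"""Centroid iterative fitting of the femoral neck axis (FNA).

The procedure: the plane through the greater-trochanter tip, the
lesser-trochanter tip and the midpoint of the intertrochanteric line is
the initial section.  Ten parallel sections at 1 mm spacing are taken
from it along the neck; each section's cross-sectional contour gives an
area-weighted polygon centroid; a total-least-squares line through the
ten centroids gives a new axis; sections are rebuilt perpendicular to
that axis, and after five iterations a cylinder is fitted to the final
centroid cloud.  The cylinder axis is the FNA.  A sphere fitted to the
femoral head gives the head centre, and the perpendicular distance
between head centre and FNA (DBHF, mm) is the accuracy metric: under
the mechanical-equilibrium assumption the ideal head centre lies on the
neck axis, so a small DBHF means an accurate axis.

:class:`FemoralNeckAxisModel` holds the inputs; :meth:`fit` runs the
procedure and returns :class:`FNAResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from . import __version__ as _version
from .exceptions import (
    DegenerateLandmarksError,
    HeadNotFoundError,
    StackTruncatedError,
    UndefinedRotationError,
)
from .fitting import Cylinder, Sphere, fit_cylinder, fit_line_tls, fit_sphere_robust
from .geometry import (
    Line3D,
    Plane,
    Vec3,
    angle_between_lines,
    plane_from_points,
    point_line_distance,
    points_line_distance,
    unit,
)
from .slicing import (
    SectionContour,
    select_neck_contour,
    slice_mesh,
    validate_watertight,
)

log = logging.getLogger("femaxis")

DEFAULT_SEED = 20190101


@dataclass(frozen=True)
class LandmarkSet:
    """The three anatomical landmarks seeding the initial section.

    ``head_hint`` is any point on the head side of the landmark plane; it
    only orients directions and needs no precision.
    """

    gt_tip: Vec3  # greater trochanter tip
    lt_tip: Vec3  # lesser trochanter tip
    it_mid: Vec3  # midpoint of the intertrochanteric line
    head_hint: Vec3

    def __post_init__(self):
        for name in ("gt_tip", "lt_tip", "it_mid", "head_hint"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
        plane = plane_from_points(self.gt_tip, self.lt_tip, self.it_mid)
        if abs(float(plane.signed_distance(self.head_hint))) < 1e-6:
            raise DegenerateLandmarksError("head_hint lies on the landmark plane")

    def transformed(self, matrix) -> "LandmarkSet":
        m = np.asarray(matrix, dtype=float)

        def tf(p):
            return (m[:3, :3] @ p) + m[:3, 3]

        return LandmarkSet(
            tf(self.gt_tip), tf(self.lt_tip), tf(self.it_mid), tf(self.head_hint)
        )


@dataclass(frozen=True)
class SectionConfig:
    """Protocol parameters for the section stacks.

    Defaults follow the published protocol: 10 sections, 1 mm apart,
    5 iterations.  ``early_stop_tol_deg`` optionally stops when successive
    axes differ by less than the tolerance (off by default for fidelity
    to the fixed-iteration protocol).
    """

    n_sections: int = 10
    spacing: float = 1.0
    n_iterations: int = 5
    early_stop_tol_deg: float | None = None
    cylinder_source: str = "centroids"  # "centroids" | "contours"
    accumulate_iterations: bool = False
    head_axial_margin: float = 14.0
    head_radial_factor: float = 1.5
    head_trim_mm: float = 0.75

    def __post_init__(self):
        if self.n_sections < 3:
            raise ValueError("n_sections must be >= 3")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.cylinder_source not in ("centroids", "contours"):
            raise ValueError("cylinder_source must be 'centroids' or 'contours'")


def initial_plane(landmarks: LandmarkSet) -> Plane:
    """Landmark plane with its normal oriented toward the femoral head."""
    plane = plane_from_points(landmarks.gt_tip, landmarks.lt_tip, landmarks.it_mid)
    if float(plane.signed_distance(landmarks.head_hint)) < 0:
        plane = Plane(plane.origin, -plane.normal)
    return plane


def build_section_stack(
    mesh: trimesh.Trimesh,
    base: Plane,
    cfg: SectionConfig,
    reference: Vec3,
) -> list[tuple[SectionContour, Vec3]]:
    """Parallel sections at offsets spacing, 2*spacing, ... along +normal.

    Each section's neck contour is selected by proximity to the previous
    section's centroid (the first uses ``reference``); the centroid of the
    chosen contour is the area-weighted polygon centroid mapped to 3-D.
    An empty slice truncates the stack; fewer than 3 completed sections
    is fatal.
    """
    ref = np.asarray(reference, dtype=float)
    out: list[tuple[SectionContour, Vec3]] = []
    for i in range(1, cfg.n_sections + 1):
        plane = base.translated(i * cfg.spacing)
        contours = slice_mesh(mesh, plane)
        if not contours:
            break
        contour = select_neck_contour(contours, ref)
        ref = contour.centroid3d
        out.append((contour, ref))
    if len(out) < cfg.n_sections:
        log.warning(
            "section stack truncated: %d of %d sections", len(out), cfg.n_sections
        )
    if len(out) < 3:
        raise StackTruncatedError(len(out), cfg.n_sections)
    return out


def select_head_vertices(
    mesh: trimesh.Trimesh,
    fna: Line3D,
    t_min: float,
    radial_factor: float = 1.5,
    min_count: int = 30,
) -> np.ndarray:
    """Mesh vertices on the head side of the final section stack.

    Keeps vertices whose axial coordinate along the (head-oriented) FNA
    exceeds ``t_min`` and whose radial distance is below ``radial_factor``
    times the 75th percentile of the selection's radial distances.
    """
    v = mesh.vertices.view(np.ndarray)
    t = (v - fna.point) @ fna.direction
    mask = t > t_min
    if mask.sum() < min_count:
        raise HeadNotFoundError(
            f"only {int(mask.sum())} vertices beyond the section stack; "
            "mesh may be truncated below the femoral head"
        )
    r = points_line_distance(v[mask], fna)
    mask2 = r <= radial_factor * np.quantile(r, 0.75)
    sel = v[mask][mask2]
    if len(sel) < min_count:
        raise HeadNotFoundError("head vertex selection collapsed to too few points")
    return sel


def deviated_axis(fna: Line3D, angle_deg: float, rotation_plane_normal) -> Line3D:
    """Rotate the FNA direction by ``angle_deg`` about a given normal.

    Models a mis-determined axis (e.g. a 20 deg deviation scenario); the
    rotated line passes through the same axis point.
    """
    if abs(angle_deg) >= 90.0:
        raise ValueError("deviation angle must satisfy |angle| < 90 deg")
    n = unit(rotation_plane_normal)
    if np.linalg.norm(np.cross(n, fna.direction)) < 1e-9:
        raise UndefinedRotationError(
            "rotation plane normal is parallel to the axis direction"
        )
    rot = Rotation.from_rotvec(np.radians(angle_deg) * n)
    return Line3D(fna.point, rot.apply(fna.direction))


@dataclass
class FNAResults:
    """Results of a centroid-iterative FNA fit.

    Attributes
    ----------
    fna : Line3D
        Final femoral neck axis (axis of the fitted cylinder), oriented
        toward the femoral head.
    cylinder : Cylinder
        Cylinder fitted to the final centroid cloud.
    head_sphere : Sphere
        Sphere fitted to the femoral-head vertices.
    dbhf : float
        Distance (mm) between the head-sphere centre and the FNA.
    per_iteration_axes : list of Line3D
        The TLS axis of each iteration, for convergence diagnostics.
    centroids : list of ndarray
        Per-iteration (n_sections, 3) section-centroid arrays.
    """

    model: "FemoralNeckAxisModel"
    config: SectionConfig
    fna: Line3D
    cylinder: Cylinder
    head_sphere: Sphere
    dbhf: float
    per_iteration_axes: list[Line3D]
    centroids: list[np.ndarray]
    final_contours: list[SectionContour]
    n_head_vertices: int

    def axis_at_iteration(self, i: int) -> Line3D:
        """Axis after iteration ``i`` (1-based)."""
        return self.per_iteration_axes[i - 1]

    def angle_to(self, other: Line3D) -> float:
        """Acute angle (deg) between the fitted FNA and another line."""
        return angle_between_lines(self.fna, other)

    def iteration_angles(self) -> np.ndarray:
        """Angles (deg) between successive iteration axes."""
        axes = self.per_iteration_axes
        return np.array(
            [angle_between_lines(a, b) for a, b in zip(axes[:-1], axes[1:])]
        )

    def to_dict(self) -> dict:
        c = self.config
        return {
            "tool": {"name": "femaxis", "version": _version},
            "config": {
                "n_sections": c.n_sections,
                "spacing_mm": c.spacing,
                "n_iterations": c.n_iterations,
                "cylinder_source": c.cylinder_source,
            },
            "fna": {
                "point": self.fna.point.tolist(),
                "direction": self.fna.direction.tolist(),
            },
            "cylinder": {"radius_mm": self.cylinder.radius},
            "head_sphere": {
                "centre": self.head_sphere.centre.tolist(),
                "radius_mm": self.head_sphere.radius,
            },
            "dbhf_mm": self.dbhf,
            "per_iteration_axes": [
                {"point": a.point.tolist(), "direction": a.direction.tolist()}
                for a in self.per_iteration_axes
            ],
            "iteration_angles_deg": self.iteration_angles().tolist(),
        }

    def summary(self) -> str:
        c = self.config
        p, d = self.fna.point, self.fna.direction
        s = self.head_sphere
        lines = [
            "Femoral neck axis fit (centroid iterative method)",
            "=" * 54,
            f"sections per stack     : {c.n_sections} @ {c.spacing:g} mm",
            f"iterations             : {len(self.per_iteration_axes)}"
            f" (requested {c.n_iterations})",
            f"FNA point [mm]         : ({p[0]: .3f}, {p[1]: .3f}, {p[2]: .3f})",
            f"FNA direction          : ({d[0]: .4f}, {d[1]: .4f}, {d[2]: .4f})",
            f"cylinder radius [mm]   : {self.cylinder.radius: .3f}",
            f"head centre [mm]       : ({s.centre[0]: .3f}, {s.centre[1]: .3f},"
            f" {s.centre[2]: .3f})",
            f"head radius [mm]       : {s.radius: .3f}  ({self.n_head_vertices}"
            " vertices)",
            f"DBHF [mm]              : {self.dbhf: .3f}",
            "successive axis angles : "
            + ", ".join(f"{a:.3f}" for a in self.iteration_angles())
            + " deg",
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Plot the angle between successive iteration axes (degrees)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        angles = self.iteration_angles()
        ax.plot(np.arange(2, len(angles) + 2), angles, "o-")
        ax.set_xlabel("iteration")
        ax.set_ylabel("angle to previous axis [deg]")
        ax.set_title("FNA convergence")
        return ax


class FemoralNeckAxisModel:
    """Centroid iterative FNA model for one proximal-femur mesh.

    Parameters
    ----------
    mesh : trimesh.Trimesh
        Watertight triangulated surface of the proximal femur, mm units.
    landmarks : LandmarkSet
        Greater-trochanter tip, lesser-trochanter tip, intertrochanteric
        midpoint, plus an orientation hint on the head side.
    config : SectionConfig, optional
        Section-stack protocol; defaults to 10 sections / 1 mm / 5
        iterations.
    """

    def __init__(self, mesh, landmarks: LandmarkSet, config: SectionConfig | None = None):
        validate_watertight(mesh)
        self.mesh = mesh
        self.landmarks = landmarks
        self.config = config or SectionConfig()

    @classmethod
    def from_files(cls, mesh_path, landmarks_path, config: SectionConfig | None = None):
        from .io import read_landmarks, read_mesh

        return cls(read_mesh(mesh_path), read_landmarks(landmarks_path), config)

    def fit(self) -> FNAResults:
        """Run the centroid iterative procedure and return results."""
        cfg = self.config
        lm = self.landmarks
        base = initial_plane(lm)
        # seed the neck-contour selection at the head hint projected onto
        # the landmark plane: that lands near where the neck axis crosses it
        reference = lm.head_hint - base.signed_distance(lm.head_hint) * base.normal

        axes: list[Line3D] = []
        cent_per_iter: list[np.ndarray] = []
        contours_final: list[SectionContour] = []
        for it in range(1, cfg.n_iterations + 1):
            stack = build_section_stack(self.mesh, base, cfg, reference)
            cents = np.array([c for _, c in stack])
            axis = fit_line_tls(cents, orient_hint=base.normal)
            axes.append(axis)
            cent_per_iter.append(cents)
            contours_final = [c for c, _ in stack]
            log.info(
                "iteration %d: %d sections, axis angle to previous %.3f deg",
                it,
                len(stack),
                angle_between_lines(axes[-2], axis) if len(axes) > 1 else float("nan"),
            )
            if (
                cfg.early_stop_tol_deg is not None
                and len(axes) > 1
                and angle_between_lines(axes[-2], axis) < cfg.early_stop_tol_deg
            ):
                break
            # re-anchor the next stack at this stack's first centroid,
            # perpendicular to the freshly fitted axis
            base = Plane(stack[0][1], axis.direction)
            reference = stack[0][1]

        if cfg.cylinder_source == "contours":
            pts = np.vstack([c.loop for c in contours_final])
        elif cfg.accumulate_iterations:
            pts = np.vstack(cent_per_iter)
        else:
            pts = cent_per_iter[-1]
        cylinder = fit_cylinder(pts, init=axes[-1])
        head_dir = lm.head_hint - cylinder.axis.point
        fna = cylinder.axis.oriented(head_dir)

        # head side: beyond the last section plane, plus a margin clearing
        # the head-neck junction
        t_last = float((cent_per_iter[-1][-1] - fna.point) @ fna.direction)
        head_pts = select_head_vertices(
            self.mesh,
            fna,
            t_min=t_last + cfg.head_axial_margin,
            radial_factor=cfg.head_radial_factor,
        )
        sphere = fit_sphere_robust(head_pts, trim_mm=cfg.head_trim_mm)
        dbhf = point_line_distance(sphere.centre, fna)

        return FNAResults(
            model=self,
            config=cfg,
            fna=fna,
            cylinder=cylinder,
            head_sphere=sphere,
            dbhf=dbhf,
            per_iteration_axes=axes,
            centroids=cent_per_iter,
            final_contours=contours_final,
            n_head_vertices=len(head_pts),
        )
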