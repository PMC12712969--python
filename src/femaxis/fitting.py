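"""Least-squares geometric fits: 3-D line (TLS), cylinder, sphere.

The line fit is total least squares (principal direction of the centred
cloud), which minimises the sum of squared orthogonal distances.  The
cylinder fit is a nonlinear least-squares refinement of axis and radius;
the sphere fit is the standard algebraic linear system, optionally
refined/robustified geometrically for partial, contaminated coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    AmbiguousDirectionError,
    FitFailureError,
    SingularSystemError,
    UnderdeterminedError,
)
from .geometry import Line3D, Vec3, points_line_distance, unit

# radial RMS below this means the cloud is a line, not a cylinder surface:
# section centroids scatter ~0.1-0.4 mm off the axis from mesh facets alone,
# and a cylinder radius is unidentifiable from such a cloud
COLLINEAR_RMS_MM = 0.5


@dataclass(frozen=True)
class Cylinder:
    axis: Line3D
    radius: float


@dataclass(frozen=True)
class Sphere:
    centre: Vec3
    radius: float


def fit_line_tls(points, orient_hint=None) -> Line3D:
    """Total-least-squares line through a 3-D point cloud.

    The line passes through the cloud mean along the principal direction
    of the centred cloud; this minimises the sum of squared perpendicular
    distances over all lines.  ``orient_hint`` fixes the direction sign.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(np.unique(p, axis=0)) < 2:
        raise UnderdeterminedError("need at least 2 distinct points for a line fit")
    mean = p.mean(axis=0)
    q = p - mean
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[0] - s[1] <= 1e-9 * max(1.0, s[0]):
        raise AmbiguousDirectionError(
            "leading principal values are equal; line direction is not unique"
        )
    line = Line3D(mean, vt[0])
    if orient_hint is not None:
        line = line.oriented(np.asarray(orient_hint, dtype=float))
    return line


def line_residual(points, line: Line3D) -> float:
    """Sum of squared perpendicular distances of points to a line."""
    return float(np.sum(points_line_distance(points, line) ** 2))


def _perp_basis(d: Vec3) -> tuple[Vec3, Vec3]:
    k = np.argmin(np.abs(d))
    e1 = np.zeros(3)
    e1[k] = 1.0
    e1 = unit(np.cross(d, e1))
    return e1, np.cross(d, e1)


def fit_cylinder(points, init: Line3D, max_nfev: int = 200) -> Cylinder:
    """Fit an infinite circular cylinder to points.

    Minimises ``sum((dist_i - r)^2)`` over axis point (2 dof transverse to
    the axis), axis direction (2 dof) and radius, starting from ``init``
    with the mean radial distance as the initial radius.

    A centroid cloud that is nearly collinear (radial RMS below
    ``COLLINEAR_RMS_MM``) carries no radius information; the fit then
    falls back to the TLS line as the axis, with the radial RMS as a
    nominal radius.  The axis is the only quantity used downstream.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if p.shape[0] < 6:
        raise UnderdeterminedError("need at least 6 points for a cylinder fit")

    tls = fit_line_tls(p, orient_hint=init.direction)
    rms = float(np.sqrt(np.mean(points_line_distance(p, tls) ** 2)))
    if rms < COLLINEAR_RMS_MM:
        return Cylinder(axis=tls, radius=max(rms, 1e-6))

    d0 = init.direction
    e1, e2 = _perp_basis(d0)
    mean = p.mean(axis=0)
    r0 = float(np.mean(points_line_distance(p, init)))

    def unpack(x):
        a, b, u, v, r = x
        d = unit(d0 + a * e1 + b * e2)
        c = mean + u * e1 + v * e2
        return Line3D(c, d), r

    def resid(x):
        line, r = unpack(x)
        return points_line_distance(p, line) - r

    x0 = np.array([0.0, 0.0, 0.0, 0.0, max(r0, 1e-3)])
    sol = least_squares(resid, x0, method="lm", max_nfev=max_nfev)
    if not sol.success:
        raise FitFailureError(
            f"cylinder fit did not converge: {sol.message}",
            residual=float(np.sum(sol.fun**2)),
        )
    line, r = unpack(sol.x)
    return Cylinder(axis=line.oriented(init.direction), radius=abs(float(r)))


def fit_sphere(points) -> Sphere:
    """Algebraic least-squares sphere through a point cloud.

    Solves ``|p|^2 = 2 c . p + (r^2 - |c|^2)`` linearly; exact on
    noiseless spherical data, including partial caps.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if p.shape[0] < 4:
        raise UnderdeterminedError("need at least 4 points for a sphere fit")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise SingularSystemError("points are coplanar; sphere is undetermined")
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise SingularSystemError("algebraic sphere fit produced a non-positive radius")
    return Sphere(centre=centre, radius=float(np.sqrt(r2)))


def refine_sphere(points, init: Sphere, max_nfev: int = 100) -> Sphere:
    """Geometric (orthogonal-distance) refinement of a sphere fit."""
    p = np.asarray(points, dtype=float).reshape(-1, 3)

    def resid(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    x0 = np.r_[init.centre, init.radius]
    sol = least_squares(resid, x0, method="lm", max_nfev=max_nfev)
    if not sol.success:
        raise FitFailureError(
            f"sphere refinement did not converge: {sol.message}",
            residual=float(np.sum(sol.fun**2)),
        )
    return Sphere(centre=sol.x[:3], radius=abs(float(sol.x[3])))


def fit_sphere_robust(points, trim_mm: float = 0.75, min_points: int = 30) -> Sphere:
    """Sphere fit with annealed residual trimming.

    The head selection can include blend-zone vertices at the head-neck
    junction and flattened collapse regions; trimming points whose
    absolute radial residual exceeds a threshold (annealed 4x -> 2x -> 1x
    ``trim_mm``) and refitting makes the centre estimate robust to them
    even when the initial algebraic fit is noticeably skewed.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    sphere = fit_sphere(p)
    for factor in (4.0, 2.0, 1.0, 1.0):
        res = np.abs(np.linalg.norm(p - sphere.centre, axis=1) - sphere.radius)
        keep = res <= factor * trim_mm
        if keep.sum() < min_points:
            break
        p = p[keep]
        sphere = fit_sphere(p)
    return sphere
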