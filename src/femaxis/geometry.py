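"""Exact geometric primitives: planes, lines, polygon centroids, distances.

All lengths are millimetres; angles returned in degrees.  Degeneracy
tolerances (triangle area 1e-6 mm^2, unit-norm 1e-9, polygon area
1e-9 mm^2) are fixed constants guarding numerical validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateContourError,
    DegenerateLandmarksError,
    NumericalError,
)

# fixed numerical guards, not modelling choices
UNIT_TOL = 1e-9
TRIANGLE_AREA_TOL = 1e-6  # mm^2
POLYGON_AREA_TOL = 1e-9  # mm^2

Vec3 = np.ndarray  # shape (3,), float64


def _as_vec3(v, name: str = "point") -> Vec3:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise NumericalError(f"{name} has non-finite coordinates: {a}")
    return a


def unit(v) -> Vec3:
    """Normalise ``v`` to unit length; raise on (near-)zero vectors."""
    a = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(a)
    if n < UNIT_TOL:
        raise NumericalError("cannot normalise a (near-)zero vector")
    return a / n


@dataclass(frozen=True)
class Plane:
    """Plane given by a point (``origin``) and a unit ``normal``."""

    origin: Vec3
    normal: Vec3

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "plane origin"))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance of one point (3,) or many points (N, 3)."""
        p = np.asarray(points, dtype=float)
        return (p - self.origin) @ self.normal

    def translated(self, offset: float) -> "Plane":
        """Parallel plane shifted ``offset`` mm along +normal."""
        return Plane(self.origin + offset * self.normal, self.normal)

    def basis(self) -> tuple[Vec3, Vec3]:
        """Right-handed orthonormal in-plane chart (e1, e2): e1 x e2 = normal."""
        n = self.normal
        # pick the coordinate axis least aligned with n for stability
        k = np.argmin(np.abs(n))
        e1 = np.zeros(3)
        e1[k] = 1.0
        e1 = unit(np.cross(n, e1))
        e2 = np.cross(n, e1)
        return e1, e2

    def project(self, points) -> np.ndarray:
        """Project points into the 2-D chart of :meth:`basis`."""
        e1, e2 = self.basis()
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.column_stack([p @ e1, p @ e2])

    def unproject(self, uv) -> np.ndarray:
        """Map 2-D chart coordinates back to 3-D points on the plane."""
        e1, e2 = self.basis()
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        pts = self.origin + uv[:, :1] * e1 + uv[:, 1:2] * e2
        return pts[0] if pts.shape[0] == 1 else pts


@dataclass(frozen=True)
class Line3D:
    """Line given by a ``point`` on it and a unit ``direction``."""

    point: Vec3
    direction: Vec3

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec3(self.point, "line point"))
        object.__setattr__(self, "direction", unit(self.direction))

    def at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.point + np.multiply.outer(t, self.direction)

    def oriented(self, hint: Vec3) -> "Line3D":
        """Flip direction if needed so ``direction . hint > 0``."""
        if float(self.direction @ np.asarray(hint, dtype=float)) < 0:
            return Line3D(self.point, -self.direction)
        return self


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    The normal follows the right-hand rule on ``cross(p2-p1, p3-p1)``; the
    origin is the centroid of the triangle.
    """
    p1, p2, p3 = (_as_vec3(p) for p in (p1, p2, p3))
    c = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(c)
    if area <= TRIANGLE_AREA_TOL:
        raise DegenerateLandmarksError(
            f"points are collinear or coincident (triangle area {area:.3g} mm^2)"
        )
    return Plane((p1 + p2 + p3) / 3.0, c)


def polygon_area(vertices) -> float:
    """Signed shoelace area of a simple polygon in 2-D chart coordinates."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(vertices) -> np.ndarray:
    """Area-weighted (lamina) centroid of a simple polygon.

    Shoelace form: with cross terms ``w_i = x_i y_{i+1} - x_{i+1} y_i``,
    ``A = sum(w_i)/2`` and ``C = sum((v_i + v_{i+1}) w_i) / (6A)``.  The
    result is independent of vertex winding and of the starting vertex.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise DegenerateContourError("polygon needs >= 3 two-dimensional vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    w = x * yn - xn * y
    a = 0.5 * np.sum(w)
    if abs(a) <= POLYGON_AREA_TOL:
        raise DegenerateContourError(f"polygon area {a:.3g} mm^2 is (near-)zero")
    cx = np.sum((x + xn) * w) / (6.0 * a)
    cy = np.sum((y + yn) * w) / (6.0 * a)
    return np.array([cx, cy])


def point_line_distance(p, line: Line3D) -> float:
    """Perpendicular distance (mm) from a point to a line."""
    d = _as_vec3(p) - line.point
    return float(np.linalg.norm(np.cross(d, line.direction)))


def points_line_distance(points, line: Line3D) -> np.ndarray:
    """Vectorised :func:`point_line_distance` for an (N, 3) array."""
    d = np.asarray(points, dtype=float) - line.point
    return np.linalg.norm(np.cross(d, line.direction), axis=-1)


def angle_between_vectors(u, v) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    u, v = unit(u), unit(v)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), u @ v)))


def angle_between_lines(l1: Line3D, l2: Line3D) -> float:
    """Acute angle between two lines, degrees in [0, 90].

    Symmetric in its arguments and invariant to direction sign flips.
    """
    d1, d2 = l1.direction, l2.direction
    c = abs(float(d1 @ d2))
    s = np.linalg.norm(np.cross(d1, d2))
    return float(np.degrees(np.arctan2(s, c)))
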