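"""Mesh-plane slicing: closed contour extraction and section centroids.

A slice intersects every mesh edge that crosses the plane, interpolates
the crossing point along the edge, and chains the per-triangle segments
into closed loops keyed by unique-edge identity (no coordinate rounding).
On a watertight mesh every crossing edge is shared by exactly two crossing
triangles, so every chain closes; an open chain is reported as an
:class:`~femaxis.exceptions.UnclosedContourError` with the gap size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .exceptions import DegenerateContourError, NoContourError, UnclosedContourError
from .geometry import POLYGON_AREA_TOL, Plane, Vec3, polygon_area, polygon_centroid

# vertices closer to the plane than this trigger the nudge-and-retry path
_ON_PLANE_TOL = 1e-12
_NUDGE_MM = 1e-7


@dataclass(frozen=True)
class SectionContour:
    """One closed intersection loop of mesh and plane.

    ``loop`` is an (N, 3) array of points on the plane, ordered CCW when
    viewed from the +normal side; the first vertex is not repeated.
    """

    plane: Plane
    loop: np.ndarray
    area: float
    centroid3d: Vec3


def _chain_loops(pairs: np.ndarray) -> list[list[int]]:
    """Chain segments (rows of two edge ids) into closed loops of edge ids."""
    neighbours: dict[int, list[int]] = {}
    for a, b in pairs:
        neighbours.setdefault(int(a), []).append(int(b))
        neighbours.setdefault(int(b), []).append(int(a))
    loops: list[list[int]] = []
    seen: set[int] = set()
    for start in neighbours:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev = None
        cur = start
        while True:
            nbrs = neighbours[cur]
            if len(nbrs) < 2:
                # open chain: only one incident crossing triangle
                raise _OpenChain(loop)
            cand = [e for e in nbrs if e != prev]
            nxt = cand[0] if cand else nbrs[0]
            if nxt == start:
                break
            if nxt in seen:
                # should not happen on a manifold mesh; treat as open
                raise _OpenChain(loop)
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        loops.append(loop)
    return loops


class _OpenChain(Exception):
    def __init__(self, loop):
        self.loop = loop


def slice_mesh(mesh: trimesh.Trimesh, plane: Plane) -> list[SectionContour]:
    """Intersect ``mesh`` with ``plane`` and return all closed contours.

    Returns an empty list when the plane misses the mesh.  Triangles lying
    exactly in the plane are a measure-zero event handled by nudging the
    plane 1e-7 mm along its normal and retrying once.
    """
    return _slice_mesh(mesh, plane, retry=True)


def _slice_mesh(mesh, plane, retry):
    verts = mesh.vertices.view(np.ndarray)
    d = (verts - plane.origin) @ plane.normal
    if np.any(np.abs(d) < _ON_PLANE_TOL):
        if not retry:
            raise DegenerateContourError(
                "mesh vertices lie exactly on the plane even after nudging"
            )
        return _slice_mesh(mesh, plane.translated(_NUDGE_MM), retry=False)

    edges = mesh.edges_unique
    pos = d > 0
    crossing = pos[edges[:, 0]] != pos[edges[:, 1]]
    if not crossing.any():
        return []

    # interpolated crossing point per unique edge (identical for both faces)
    cross_pts = np.full((len(edges), 3), np.nan)
    ce = edges[crossing]
    d0, d1 = d[ce[:, 0]], d[ce[:, 1]]
    t = (d0 / (d0 - d1))[:, None]
    cross_pts[crossing] = verts[ce[:, 0]] + t * (verts[ce[:, 1]] - verts[ce[:, 0]])

    face_edges = mesh.faces_unique_edges  # (F, 3) indices into edges_unique
    n_cross = crossing[face_edges].sum(axis=1)
    cross_faces = np.nonzero(n_cross == 2)[0]
    if len(cross_faces) == 0:
        return []

    fe = face_edges[cross_faces]
    fc = crossing[fe]
    # the two crossing edge ids of each crossing face
    pairs = fe[fc].reshape(-1, 2)

    try:
        loops = _chain_loops(pairs)
    except _OpenChain as oc:
        ends = cross_pts[[oc.loop[0], oc.loop[-1]]]
        raise UnclosedContourError(float(np.linalg.norm(ends[0] - ends[1]))) from None

    contours = []
    for loop in loops:
        pts = cross_pts[loop]
        if len(pts) < 3:
            continue  # degenerate sliver (two triangles sharing both edges)
        uv = plane.project(pts)
        a = polygon_area(uv)
        if abs(a) <= POLYGON_AREA_TOL:
            continue
        if a < 0:  # normalise winding to CCW viewed from +normal
            pts = pts[::-1]
            uv = uv[::-1]
            a = -a
        c3 = plane.unproject(polygon_centroid(uv))
        contours.append(SectionContour(plane=plane, loop=pts, area=float(a), centroid3d=c3))
    return contours


def select_neck_contour(contours: list[SectionContour], reference) -> SectionContour:
    """Pick the contour whose centroid is nearest the reference point.

    A plane through the femoral neck can also cut the trochanter or the
    head; chaining selection on the previous section's centroid keeps the
    stack on the neck.  Sliver loops below 1% of the largest loop's area
    (surface-noise artefacts) are ignored.  Ties within 1e-6 mm go to the
    larger area.
    """
    if not contours:
        raise NoContourError("no contours to select from")
    max_area = max(c.area for c in contours)
    contours = [c for c in contours if c.area >= 0.01 * max_area]
    ref = np.asarray(reference, dtype=float)
    dist = np.array([np.linalg.norm(c.centroid3d - ref) for c in contours])
    best = np.min(dist)
    tied = [c for c, dd in zip(contours, dist) if dd <= best + 1e-6]
    return max(tied, key=lambda c: c.area)


def section_centroid(contour: SectionContour) -> Vec3:
    """Area-weighted centroid of a contour, mapped back to 3-D.

    Projects the loop into the plane's orthonormal chart, applies the
    polygon centroid, and unprojects; the result lies on the plane.
    """
    uv = contour.plane.project(contour.loop)
    return contour.plane.unproject(polygon_centroid(uv))


def validate_watertight(mesh: trimesh.Trimesh) -> None:
    """Reject non-watertight meshes (holes corrupt contour centroids)."""
    if not mesh.is_watertight:
        from .exceptions import InputError

        raise InputError(
            "mesh is not watertight; repair it upstream before axis fitting"
        )
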