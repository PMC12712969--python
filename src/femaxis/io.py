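"""File formats: meshes (STL/PLY), landmark JSON, result JSON, CSV tables.

Coordinates stay in whatever frame the mesh is in (the CT scanner frame
for clinical data); the fitting pipeline is rigid-equivariant, so no
re-orientation is ever applied.  STL stores float32 vertices, so
round-trips are exact only to ~1e-6 relative; PLY is exported with
float64 vertices and round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import InputError
from .model import LandmarkSet

log = logging.getLogger("femaxis")

LANDMARK_SCHEMA_VERSION = 1
_LANDMARK_KEYS = ("gt_tip", "lt_tip", "it_mid", "head_hint")


def _check_binary_stl(path: Path) -> None:
    """Validate the length of a binary STL before parsing.

    A binary STL is an 80-byte header, a uint32 triangle count, and 50
    bytes per triangle; a mismatch pinpoints the truncation offset.
    """
    size = path.stat().st_size
    with open(path, "rb") as fh:
        head = fh.read(84)
    if len(head) < 84:
        raise InputError(
            f"{path}: binary STL truncated at byte {len(head)} (header needs 84)"
        )
    if head[:5] == b"solid":
        # might be ASCII; let the parser decide
        return
    (n_tri,) = struct.unpack("<I", head[80:84])
    expected = 84 + 50 * n_tri
    if size < expected:
        raise InputError(
            f"{path}: binary STL declares {n_tri} triangles "
            f"({expected} bytes) but ends at byte {size}"
        )


def read_mesh(path) -> trimesh.Trimesh:
    """Load an STL or PLY surface as a triangle mesh.

    Duplicate vertices are merged and zero-area faces dropped (with a
    logged count).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"mesh file not found: {path}")
    if path.suffix.lower() == ".stl":
        _check_binary_stl(path)
    try:
        mesh = trimesh.load(str(path), force="mesh", process=True)
    except Exception as exc:
        raise InputError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise InputError(f"mesh file {path} contains no triangles")
    n0 = len(mesh.faces)
    mesh.update_faces(mesh.nondegenerate_faces())
    dropped = n0 - len(mesh.faces)
    if dropped:
        log.info("dropped %d zero-area faces from %s", dropped, path.name)
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write STL (binary, float32) or PLY (ASCII, float64) by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        mesh.export(str(path))
    elif suffix == ".ply":
        # ASCII PLY with double-precision vertices (lossless round-trip)
        v = mesh.vertices.view(np.ndarray)
        f = mesh.faces.view(np.ndarray)
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(v)}\n"
                "property double x\nproperty double y\nproperty double z\n"
                f"element face {len(f)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for p3 in v:
                fh.write(f"{p3[0]:.17g} {p3[1]:.17g} {p3[2]:.17g}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    else:
        raise InputError(f"unsupported mesh format: {suffix!r} (use .stl or .ply)")


def read_landmarks(path) -> LandmarkSet:
    """Read the four named landmark points from a JSON file.

    Schema: ``{"schema_version": 1, "gt_tip": [x,y,z], "lt_tip": ...,
    "it_mid": ..., "head_hint": ...}`` with optional metadata keys.
    Collinear triplets are rejected at load time, not mid-pipeline.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"cannot parse landmark JSON {path}: {exc}") from exc
    missing = [k for k in _LANDMARK_KEYS if k not in doc]
    if missing:
        raise InputError(f"landmark file {path} missing keys: {missing}")
    pts = {}
    for k in _LANDMARK_KEYS:
        arr = np.asarray(doc[k], dtype=float)
        if arr.shape != (3,) or not np.all(np.isfinite(arr)):
            raise InputError(f"landmark {k!r} must be three finite coordinates")
        pts[k] = arr
    return LandmarkSet(**pts)


def write_landmarks(lm: LandmarkSet, path, metadata: dict | None = None) -> None:
    doc = {
        "schema_version": LANDMARK_SCHEMA_VERSION,
        **{k: getattr(lm, k).tolist() for k in _LANDMARK_KEYS},
    }
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_results(results, path) -> None:
    """Serialise an :class:`~femaxis.model.FNAResults` to JSON."""
    Path(path).write_text(json.dumps(results.to_dict(), indent=2) + "\n")


def read_results(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"results file not found: {path}")
    return json.loads(path.read_text())


def write_truth(truth, path) -> None:
    """Serialise a synthetic-femur ground truth to JSON."""
    doc = {
        "neck_axis": {
            "point": truth.neck_axis.point.tolist(),
            "direction": truth.neck_axis.direction.tolist(),
        },
        "head_centre": truth.head_centre.tolist(),
        "landmarks": {k: getattr(truth.landmarks, k).tolist() for k in _LANDMARK_KEYS},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_truth(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"truth file not found: {path}")
    return json.loads(path.read_text())


def write_contour_dump(contours_per_iteration, path) -> None:
    """Debug CSV of all section-contour vertices (iteration, section, x, y, z)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "section", "x", "y", "z"])
        for it, contours in enumerate(contours_per_iteration, start=1):
            for sec, contour in enumerate(contours, start=1):
                for p in contour.loop:
                    w.writerow([it, sec, f"{p[0]:.9g}", f"{p[1]:.9g}", f"{p[2]:.9g}"])
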