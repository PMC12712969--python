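"""Exception hierarchy.

Input/format problems derive from :class:`InputError`; numerical and
geometric failures derive from :class:`NumericalError`.  The CLI maps the
former to exit code 2 and the latter to exit code 3.
"""


class FemaxisError(Exception):
    """Base class for all package errors."""


class InputError(FemaxisError):
    """Unreadable, malformed or invalid input data."""


class DegenerateLandmarksError(InputError):
    """Landmark triplet is collinear or coincident."""


class NumericalError(FemaxisError):
    """Geometric or numerical failure during computation."""


class DegenerateContourError(NumericalError):
    """Section contour has (near-)zero area."""


class UnclosedContourError(NumericalError):
    """Mesh-plane intersection produced an open chain (non-watertight mesh)."""

    def __init__(self, gap_mm: float):
        self.gap_mm = float(gap_mm)
        super().__init__(
            f"open intersection chain: endpoints {gap_mm:.3g} mm apart "
            "(mesh is not watertight)"
        )


class NoContourError(NumericalError):
    """A slice produced no contour where one was required."""


class StackTruncatedError(NumericalError):
    """Too few sections of a stack produced contours."""

    def __init__(self, n_ok: int, n_requested: int):
        self.n_ok = int(n_ok)
        self.n_requested = int(n_requested)
        super().__init__(
            f"section stack truncated: only {n_ok} of {n_requested} sections "
            "intersect the mesh (at least 3 required)"
        )


class UnderdeterminedError(NumericalError):
    """Not enough distinct points for a fit."""


class AmbiguousDirectionError(NumericalError):
    """Principal direction of a point cloud is not unique."""


class FitFailureError(NumericalError):
    """Nonlinear optimiser failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class SingularSystemError(NumericalError):
    """Linear system for an algebraic fit is singular (e.g. coplanar points)."""


class HeadNotFoundError(NumericalError):
    """No femoral-head vertices found beyond the neck sections."""


class UndefinedRotationError(NumericalError):
    """Rotation axis parallel to the line being rotated."""


class UndefinedICCError(NumericalError):
    """ICC undefined because the table has zero total variance."""


class DesignError(InputError):
    """Factorial design invalid (empty or singleton cells)."""


class MeshResolutionError(InputError):
    """Voxel pitch too coarse to resolve the synthetic neck."""
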