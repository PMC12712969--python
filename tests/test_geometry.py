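import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from femaxis.exceptions import DegenerateContourError, DegenerateLandmarksError
from femaxis.geometry import (
    Line3D,
    Plane,
    angle_between_lines,
    plane_from_points,
    point_line_distance,
    points_line_distance,
    polygon_area,
    polygon_centroid,
)


def rasterized_centroid(vertices, h=1e-3):
    """Independent centroid oracle: area-weighted pixel mean on a fine grid."""
    import shapely

    poly = shapely.Polygon(vertices)
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + h / 2, maxx, h)
    ys = np.arange(miny + h / 2, maxy, h)
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
    pts = np.column_stack([xx.ravel(), yy.ravel()])[inside]
    return pts.mean(axis=0)


def star_polygon(rng, n=None, r_lo=0.5, r_hi=2.0):
    """Random simple (star-shaped) polygon."""
    n = n or rng.integers(5, 12)
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(r_lo, r_hi, n)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


class TestPlaneFromPoints:
    def test_axis_aligned(self):
        p = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(p.normal, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(p.origin, [1 / 3, 1 / 3, 0], atol=1e-12)

    def test_translated_plane(self):
        p = plane_from_points((0, 0, 5), (1, 0, 5), (0, 1, 5))
        assert abs(p.signed_distance(np.array([7.0, -3.0, 5.0]))) < 1e-12

    def test_contains_inputs(self, rng):
        for _ in range(50):
            pts = rng.uniform(-10, 10, (3, 3))
            try:
                plane = plane_from_points(*pts)
            except DegenerateLandmarksError:
                continue
            assert np.all(np.abs(plane.signed_distance(pts)) < 1e-9)

    def test_permutation_invariance_up_to_sign(self, rng):
        pts = rng.uniform(-5, 5, (3, 3))
        base = plane_from_points(*pts)
        for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
            other = plane_from_points(*pts[list(perm)])
            assert abs(abs(base.normal @ other.normal) - 1.0) < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateLandmarksError):
            plane_from_points((0, 0, 0), (1, 1, 1), (2, 2, 2))


class TestPolygonCentroid:
    @pytest.mark.parametrize(
        "vertices, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], (0.5, 0.5)),
            ([(0, 0), (3, 0), (0, 3)], (1.0, 1.0)),
        ],
    )
    def test_exact_shapes(self, vertices, expected):
        np.testing.assert_allclose(polygon_centroid(vertices), expected, atol=1e-12)

    def test_l_shape_matches_rasterization(self):
        verts = [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)]
        c = polygon_centroid(verts)
        np.testing.assert_allclose(c, (5 / 6, 5 / 6), atol=1e-12)
        oracle = rasterized_centroid(verts)
        assert np.linalg.norm(c - oracle) < 1e-3

    def test_random_polygons_match_rasterization(self, rng):
        for _ in range(5):
            verts = star_polygon(rng)
            assert np.linalg.norm(
                polygon_centroid(verts) - rasterized_centroid(verts)
            ) < 1e-3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 10))
    def test_invariant_to_reversal_and_cyclic_shift(self, seed, shift):
        verts = star_polygon(np.random.default_rng(seed))
        base = polygon_centroid(verts)
        np.testing.assert_allclose(polygon_centroid(verts[::-1]), base, atol=1e-12)
        np.testing.assert_allclose(
            polygon_centroid(np.roll(verts, shift % len(verts), axis=0)),
            base,
            atol=1e-12,
        )

    def test_convex_centroid_inside(self, rng):
        import shapely

        for _ in range(20):
            pts = rng.uniform(-3, 3, (12, 2))
            hull = shapely.MultiPoint(pts).convex_hull
            verts = np.asarray(hull.exterior.coords)[:-1]
            c = polygon_centroid(verts)
            assert hull.contains(shapely.Point(c))

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateContourError):
            polygon_centroid([(0, 0), (1, 1), (2, 2)])

    def test_signed_area_orientation(self):
        sq = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        assert polygon_area(sq) == pytest.approx(1.0)
        assert polygon_area(sq[::-1]) == pytest.approx(-1.0)


class TestPointLineDistance:
    def test_point_on_line(self):
        line = Line3D((1, 2, 3), (0, 0, 1))
        assert point_line_distance((1, 2, 10), line) == pytest.approx(0.0, abs=1e-12)

    def test_unit_offset_from_z_axis(self):
        assert point_line_distance((1, 0, 0), Line3D((0, 0, 0), (0, 0, 1))) == (
            pytest.approx(1.0)
        )

    def test_matches_1d_minimization_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(-20, 20, 3)
            line = Line3D(rng.uniform(-20, 20, 3), rng.normal(size=3))
            oracle = minimize_scalar(
                lambda t: np.linalg.norm(p - line.at(t)),
                bounds=(-200, 200),
                method="bounded",
                options={"xatol": 1e-12},
            ).fun
            assert abs(point_line_distance(p, line) - oracle) < 1e-9

    def test_vectorised_agrees_with_scalar(self, rng):
        line = Line3D((1, -2, 0.5), (3, 1, -2))
        pts = rng.uniform(-5, 5, (20, 3))
        vec = points_line_distance(pts, line)
        for p, d in zip(pts, vec):
            assert d == pytest.approx(point_line_distance(p, line), abs=1e-12)


class TestAngleBetweenLines:
    def test_identical_lines(self):
        l = Line3D((0, 0, 0), (1, 2, 3))
        assert angle_between_lines(l, l) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal(self):
        a = Line3D((0, 0, 0), (1, 0, 0))
        b = Line3D((5, 5, 5), (0, 1, 0))
        assert angle_between_lines(a, b) == pytest.approx(90.0)

    def test_closed_form_45deg(self):
        a = Line3D((0, 0, 0), (1, 1, 0))
        b = Line3D((0, 0, 0), (1, 0, 0))
        assert angle_between_lines(a, b) == pytest.approx(45.0)

    def test_symmetric_and_sign_invariant(self, rng):
        a = Line3D(rng.normal(size=3), rng.normal(size=3))
        b = Line3D(rng.normal(size=3), rng.normal(size=3))
        ab = angle_between_lines(a, b)
        assert ab == pytest.approx(angle_between_lines(b, a), abs=1e-12)
        flipped = Line3D(a.point, -a.direction)
        assert ab == pytest.approx(angle_between_lines(flipped, b), abs=1e-9)
        assert 0.0 <= ab <= 90.0


class TestPlaneChart:
    def test_project_unproject_roundtrip(self, rng):
        plane = Plane(rng.normal(size=3), rng.normal(size=3))
        pts = plane.origin + rng.normal(size=(10, 3))
        on_plane = pts - np.outer(plane.signed_distance(pts), plane.normal)
        back = plane.unproject(plane.project(on_plane))
        np.testing.assert_allclose(back, on_plane, atol=1e-9)

    def test_translated_keeps_normal(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        moved = plane.translated(2.5)
        np.testing.assert_allclose(moved.origin, [0, 0, 2.5])
        np.testing.assert_allclose(moved.normal, plane.normal)
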