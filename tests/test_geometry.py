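"""Geometry primitives against closed-form and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tibtorsion import (
    Plane,
    PlanarContour,
    PointSet,
    closest_surface_points,
    contour_centroid,
    fit_circle_2d,
    fit_plane,
    kmeans2,
    pca_axes,
    project_direction,
    sample_surface,
    signed_angle_about,
    slice_mesh,
    wrap_angle,
)
from tibtorsion.errors import (
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)
from tibtorsion.geometry import plane_rms_residual
from tibtorsion.io import SurfaceMesh

from conftest import make_cylinder


# ---------------------------------------------------------------------------
# PCA


class TestPCA:
    def test_box_corners_closed_form(self):
        """Corners of a 20x10x4 box: variances are the squared half-sides."""
        corners = np.array(list(itertools.product([-10, 10], [-5, 5], [-2, 2])), float)
        center, comps, variances = pca_axes(PointSet(corners))
        assert np.allclose(center, 0)
        assert np.allclose(variances, [100.0, 25.0, 4.0])
        assert np.allclose(np.abs(comps), np.eye(3), atol=1e-12)
        # sign convention: positive dot with +x / +y / +z
        assert comps[0][0] > 0 and comps[1][1] > 0 and comps[2][2] > 0

    def test_collinear_points(self):
        pts = np.linspace([0, 0, 0], [10, 0, 0], 20)
        _, comps, variances = pca_axes(PointSet(pts))
        assert np.allclose(comps[0], [1, 0, 0])
        assert variances[1] < 1e-12 and variances[2] < 1e-12

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 3)) * [5.0, 2.0, 1.0]
        _, comps, var = pca_axes(PointSet(pts))
        R = Rotation.random(random_state=rng).as_matrix()
        _, comps_r, var_r = pca_axes(PointSet(pts @ R.T))
        assert np.allclose(var, var_r)
        for c, cr in zip(comps, comps_r):
            assert abs(abs((R @ c) @ cr) - 1.0) < 1e-9  # equal up to sign convention

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            pca_axes(PointSet([[0, 0, 0], [1, 1, 1]]))


# ---------------------------------------------------------------------------
# plane fit


class TestFitPlane:
    def test_exact_plane(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-5, 5, 9), rng.uniform(-5, 5, 9), np.zeros(9)])
        plane = fit_plane(PointSet(pts), reference_direction=(0, 0, 1))
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert np.allclose(plane.point, pts.mean(axis=0))

    def test_symmetric_residuals(self):
        """Alternating +-1 offsets at square corners: best plane is z = 0."""
        pts = np.array([[2, 2, 1], [-2, 2, -1], [-2, -2, 1], [2, -2, -1]], float)
        plane = fit_plane(PointSet(pts), reference_direction=(0, 0, 1))
        assert abs(plane.normal @ np.array([0, 0, 1.0])) > 0.999999

    def test_total_least_squares_tilted(self):
        """Points near z = 0.1 x + 5: normal within 0.5 deg of the true one."""
        rng = np.random.default_rng(11)
        x = rng.uniform(-20, 20, 9)
        yy = rng.uniform(-20, 20, 9)
        z = 0.1 * x + 5 + rng.normal(0, 0.1, 9)
        plane = fit_plane(PointSet(np.column_stack([x, yy, z])), reference_direction=(0, 0, 1))
        truth = np.array([-0.1, 0, 1.0])
        truth /= np.linalg.norm(truth)
        ang = np.degrees(np.arccos(np.clip(plane.normal @ truth, -1, 1)))
        assert ang < 0.5

    def test_residual_optimality_vs_random_planes(self):
        """TLS residual beats 1000 random candidate planes."""
        rng = np.random.default_rng(5)
        pts = PointSet(rng.normal(size=(30, 3)) * [6, 4, 0.5])
        plane = fit_plane(pts)
        best = plane_rms_residual(plane, pts)
        centroid = pts.points.mean(axis=0)
        for _ in range(1000):
            n = rng.normal(size=3)
            cand = Plane(centroid + rng.normal(0, 0.2, 3), n / np.linalg.norm(n))
            assert best <= plane_rms_residual(cand, pts) + 1e-12

    def test_collinear_degenerate(self):
        pts = np.linspace([0, 0, 0], [5, 5, 5], 9)
        with pytest.raises(DegenerateFitError):
            fit_plane(PointSet(pts))


# ---------------------------------------------------------------------------
# k-means


def brute_force_wcss(points: np.ndarray) -> tuple[float, frozenset]:
    """Best 2-partition by exhaustive enumeration."""
    n = len(points)
    best = (np.inf, None)
    for mask in range(1, 2 ** (n - 1)):
        idx = [(mask >> i) & 1 for i in range(n)]
        a = points[np.array(idx) == 1]
        b = points[np.array(idx) == 0]
        if len(a) == 0 or len(b) == 0:
            continue
        wcss = ((a - a.mean(0)) ** 2).sum() + ((b - b.mean(0)) ** 2).sum()
        if wcss < best[0]:
            best = (wcss, frozenset(np.flatnonzero(np.array(idx) == 1)))
    return best


class TestKMeans2:
    def test_two_blobs(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 2, (100, 3))
        b = rng.normal(0, 2, (100, 3)) + [50, 0, 0]
        pts = np.vstack([a, b])
        labels, centers = kmeans2(PointSet(pts), seed=0)
        assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1
        assert labels[0] != labels[100]
        means = np.array([a.mean(0), b.mean(0)])
        d = min(
            np.linalg.norm(centers - means, axis=1).max(),
            np.linalg.norm(centers[::-1] - means, axis=1).max(),
        )
        assert d < 1.0

    def test_matches_brute_force_small(self):
        """Exact WCSS optimum on the 4-point line and random <=8 point sets."""
        pts = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0], [11, 0, 0]], float)
        labels, centers = kmeans2(PointSet(pts), seed=1)
        wcss = sum(
            ((pts[labels == k] - centers[k]) ** 2).sum() for k in (0, 1)
        )
        assert abs(wcss - 1.0) < 1e-12
        assert labels[0] == labels[1] and labels[2] == labels[3]
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.normal(size=(rng.integers(4, 9), 3)) * 5
            labels, centers = kmeans2(PointSet(p), seed=3)
            wcss = sum(((p[labels == k] - p[labels == k].mean(0)) ** 2).sum() for k in (0, 1))
            best, _ = brute_force_wcss(p)
            assert wcss <= best + 1e-9

    def test_seed_invariance_separated(self):
        pts = np.vstack(
            [np.random.default_rng(1).normal(0, 1, (50, 3)),
             np.random.default_rng(2).normal(0, 1, (50, 3)) + [30, 0, 0]]
        )
        l1, _ = kmeans2(PointSet(pts), seed=10)
        l2, _ = kmeans2(PointSet(pts), seed=99)
        assert np.array_equal(l1, l2)

    def test_identical_points(self):
        with pytest.raises(DegenerateFitError):
            kmeans2(PointSet(np.ones((5, 3))), seed=0)


# ---------------------------------------------------------------------------
# circle fit


class TestCircleFit:
    def test_exact_circle(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([3 + 7 * np.cos(t), -2 + 7 * np.sin(t)])
        center, radius = fit_circle_2d(pts)
        assert np.allclose(center, [3, -2], atol=1e-9)
        assert abs(radius - 7) < 1e-9

    def test_circumcircle(self):
        center, radius = fit_circle_2d([[0, 0], [2, 0], [1, 1]])
        assert np.allclose(center, [1, 0], atol=1e-9)
        assert abs(radius - 1) < 1e-9

    def test_half_arc(self):
        t = np.linspace(0, np.pi, 30)
        pts = np.column_stack([5 + 4 * np.cos(t), 1 + 4 * np.sin(t)])
        center, radius = fit_circle_2d(pts)
        assert np.allclose(center, [5, 1], atol=1e-6)
        assert abs(radius - 4) < 1e-6

    def test_collinear(self):
        with pytest.raises(DegenerateFitError):
            fit_circle_2d([[0, 0], [1, 0], [2, 0], [3, 0]])


# ---------------------------------------------------------------------------
# slicing / centroids


class TestSliceMesh:
    def test_cylinder_cross_section_area(self):
        mesh = make_cylinder(radius=10.0, height=100.0, sections=256)
        plane = Plane([0, 5.0, 0], [0, 1, 0])
        contours = slice_mesh(mesh, plane)
        assert len(contours) == 1
        area = contours[0].area()
        assert abs(area - np.pi * 100) / (np.pi * 100) < 0.005
        assert contours[0].signed_area() >= 0

    def test_area_converges_with_refinement(self):
        errs = []
        for sections in (64, 256):
            mesh = make_cylinder(radius=10.0, height=100.0, sections=sections)
            area = slice_mesh(mesh, Plane([0, 0, 0], [0, 1, 0]))[0].area()
            errs.append(abs(area - np.pi * 100))
        assert errs[1] < errs[0] / 4

    def test_plane_misses_mesh(self):
        mesh = make_cylinder()
        assert slice_mesh(mesh, Plane([0, 500.0, 0], [0, 1, 0])) == []

    def test_multi_component_count(self, default_bones):
        """At the plafond level + prong level the tibia has one component;
        1 mm below it only the malleolar prong remains."""
        tibia = default_bones.tibia
        y_plafond = -360.0
        plane_above = Plane([0, y_plafond + 1.0, 0], [0, 1, 0])
        plane_below = Plane([0, y_plafond - 1.0, 0], [0, 1, 0])
        assert len(slice_mesh(tibia, plane_above)) == 1
        assert len(slice_mesh(tibia, plane_below)) == 1  # prong only


class TestContourCentroid:
    def test_unit_square(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        c = PlanarContour(plane, [[0, 0], [1, 0], [1, 1], [0, 1]])
        world = contour_centroid(c)
        assert np.allclose(plane.to_plane_coords(world)[0], [0.5, 0.5])

    def test_l_shape_matches_shoelace(self):
        poly = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], float)
        # shoelace-centroid oracle
        x, y = poly[:, 0], poly[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        area = cross.sum() / 2
        cx = ((x + xn) * cross).sum() / (6 * area)
        cy = ((y + yn) * cross).sum() / (6 * area)
        plane = Plane([0, 0, 0], [0, 0, 1])
        world = contour_centroid(PlanarContour(plane, poly))
        assert np.allclose(plane.to_plane_coords(world)[0], [cx, cy], atol=1e-12)
        assert np.allclose([cx, cy], [5 / 6, 5 / 6])

    def test_translation_equivariance(self):
        plane = Plane([3, -1, 2], [0, 1, 0])
        poly = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float)
        c0 = contour_centroid(PlanarContour(plane, poly))
        c1 = contour_centroid(PlanarContour(plane, poly + [10, -3]))
        u, v = plane.basis()
        assert np.allclose(c1 - c0, 10 * u - 3 * v)

    def test_open_contour_rejected(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        c = PlanarContour(plane, [[0, 0], [1, 0], [1, 1]], closed=False)
        with pytest.raises(ValidationError):
            contour_centroid(c)


# ---------------------------------------------------------------------------
# closest point / sampling


class TestClosestSurfacePoints:
    def test_matches_exhaustive_search(self, tetrahedron):
        """50 random queries agree with a brute-force scan over all faces."""
        import trimesh as tm

        rng = np.random.default_rng(7)
        queries = rng.uniform(-3, 3, (50, 3))
        result = closest_surface_points(PointSet(queries), tetrahedron)
        tris = tetrahedron.trimesh.triangles
        for q, r in zip(queries, result.points):
            best = np.inf
            for tri in tris:
                p = tm.triangles.closest_point(tri[None], q[None])[0]
                best = min(best, np.linalg.norm(p - q))
            assert abs(np.linalg.norm(r - q) - best) < 1e-9

    def test_projection_onto_flat_triangle(self):
        v = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]], float)
        f = np.array([[0, 1, 2], [1, 3, 2], [0, 2, 1], [1, 2, 3]])
        mesh = SurfaceMesh(v, f, "tibia")
        res = closest_surface_points(PointSet([[2.0, 3.0, 5.0]]), mesh)
        assert np.allclose(res.points[0], [2, 3, 0], atol=1e-12)

    def test_beyond_edge_maps_to_edge(self):
        v = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]], float)
        f = np.array([[0, 1, 2], [1, 3, 2], [0, 2, 1], [1, 2, 3]])
        mesh = SurfaceMesh(v, f, "tibia")
        res = closest_surface_points(PointSet([[-4.0, 3.0, 2.0]]), mesh)
        assert np.allclose(res.points[0], [0, 3, 0], atol=1e-12)


class TestSampleSurface:
    def test_two_triangle_split(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        f = np.array([[0, 1, 2], [0, 2, 3], [0, 2, 1], [0, 3, 2]])
        mesh = SurfaceMesh(v, f, "tibia")
        pts = sample_surface(mesh, 10000, seed=4).points
        below = (pts[:, 1] < pts[:, 0]).sum()  # lower-right triangle (x > y)
        assert abs(below - 5000) < 400  # 4 sd of Binomial(10000, 1/2), doubled faces

    def test_dominant_face_share(self):
        v = np.array([[0, 0, 0], [100, 0, 0], [100, 100, 0], [100.1, 0, 0.1]], float)
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 1], [0, 3, 1]])
        mesh = SurfaceMesh(v, f, "tibia")
        pts = sample_surface(mesh, 10000, seed=4).points
        big = (pts[:, 1] > 0.5).sum()
        assert big >= 9700

    def test_determinism(self, tetrahedron):
        a = sample_surface(tetrahedron, 500, seed=9).points
        b = sample_surface(tetrahedron, 500, seed=9).points
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# projections / angles


class TestAngles:
    def test_project_direction(self):
        assert np.allclose(project_direction([1, 0, 0], [0, 1, 0]), [1, 0, 0])
        assert np.allclose(project_direction([1, 1, 0], [0, 1, 0]), [1, 0, 0])
        v = project_direction([0.3, 0.5, 0.8], [0, 1, 0])
        assert np.allclose(project_direction(v, [0, 1, 0]), v)  # idempotent
        with pytest.raises(DegenerateFitError):
            project_direction([0, 2, 0], [0, 1, 0])

    def test_signed_angle_right_hand_rule(self):
        assert signed_angle_about([1, 0, 0], [1, 0, 0], [0, 1, 0]) == 0.0
        assert abs(signed_angle_about([1, 0, 0], [0, 0, 1], [0, -1, 0]) - 90.0) < 1e-12

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            a = project_direction(rng.normal(size=3), axis)
            b = project_direction(rng.normal(size=3), axis)
            assert abs(
                signed_angle_about(a, b, axis) + signed_angle_about(b, a, axis)
            ) % 360.0 < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 359), st.integers(0, 359), st.integers(0, 359))
    def test_additivity_mod_360(self, ia, ib, ic):
        axis = np.array([0.0, 1.0, 0.0])

        def vec(deg):
            r = np.radians(deg)
            return np.array([np.cos(r), 0.0, np.sin(r)])

        ab = signed_angle_about(vec(ia), vec(ib), axis)
        bc = signed_angle_about(vec(ib), vec(ic), axis)
        ac = signed_angle_about(vec(ia), vec(ic), axis)
        assert abs(wrap_angle(ab + bc - ac)) < 1e-9
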