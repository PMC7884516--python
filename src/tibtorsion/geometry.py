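"""Geometry primitives shared by every pipeline stage.

All coordinates are millimetres. Angles are degrees. The transverse azimuth of
a direction ``v`` is ``atan2(v_z, v_x)`` — the in-plane angle about the
proximal (+y) axis — and is the single angular convention used to state
ground truths and report torsion.

The primitives here are deliberately small and deterministic:

* PCA eigenvectors get a fixed sign convention (positive dot with +x, then
  +y, then +z, first non-zero wins) so axes never flip between runs.
* k-means is k = 2 only, k-means++ initialised, best of 10 seeded restarts.
* Mesh queries (sampling, slicing, closest-point) delegate to trimesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from shapely.geometry import Polygon
from sklearn.cluster import KMeans

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)

_UNIT_TOL = 1e-9


def _as_unit(v, name: str = "direction") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(v).all() or n < _UNIT_TOL:
        raise ValidationError(f"{name} must be a finite non-zero vector")
    return v / n


@dataclass(frozen=True)
class Axis:
    """Oriented line: anchor point plus unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", _as_unit(self.direction))

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "direction": self.direction.tolist()}


@dataclass(frozen=True)
class Plane:
    """Oriented plane: anchor point plus unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _as_unit(self.normal, "normal"))

    def signed_distance(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane orthonormal basis (u, v).

        u is the world axis least parallel to the normal, projected into the
        plane; v = normal x u, so (u, v, normal) is right-handed.
        """
        n = self.normal
        k = int(np.argmin(np.abs(n)))
        e = np.zeros(3)
        e[k] = 1.0
        u = _as_unit(e - (e @ n) * n)
        v = np.cross(n, u)
        return u, v

    def to_plane_coords(self, points) -> np.ndarray:
        u, v = self.basis()
        d = np.atleast_2d(np.asarray(points, dtype=float)) - self.point
        return np.column_stack([d @ u, d @ v])

    def to_world(self, coords2d) -> np.ndarray:
        u, v = self.basis()
        c = np.atleast_2d(np.asarray(coords2d, dtype=float))
        return self.point + np.outer(c[:, 0], u) + np.outer(c[:, 1], v)

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}


@dataclass
class PointSet:
    """Bag of 3D points with optional positive weights."""

    points: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            raise ValidationError("PointSet must be non-empty")
        if not np.isfinite(self.points).all():
            raise ValidationError("PointSet contains non-finite coordinates")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape[0] != self.points.shape[0]:
                raise ValidationError("weights length must match point count")
            if not (self.weights > 0).all():
                raise ValidationError("weights must be positive")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class PlanarContour:
    """Closed or open polyline living in a plane, stored in plane coordinates."""

    plane: Plane
    polygon: np.ndarray  # (n, 2) in the plane's (u, v) basis
    closed: bool = True
    label: str = ""

    def __post_init__(self):
        self.polygon = np.atleast_2d(np.asarray(self.polygon, dtype=float))
        if self.closed and self.polygon.shape[0] < 3:
            raise ValidationError("closed contour needs at least 3 points")

    def world_points(self) -> np.ndarray:
        return self.plane.to_world(self.polygon)

    def signed_area(self) -> float:
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())


# ---------------------------------------------------------------------------
# PCA / fits


def pca_axes(points: PointSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted PCA of a 3D point set.

    Returns (center, components, variances) with components as rows ordered
    by descending variance, orthonormal, sign-fixed by the package convention:
    each component is flipped so its dot product with +x (then +y, then +z,
    first non-zero wins) is positive.
    """
    pts = points.points
    if len(points) < 3:
        raise InsufficientDataError("PCA needs at least 3 points")
    w = points.weights
    if w is None:
        center = pts.mean(axis=0)
        cov = np.cov(pts.T, bias=True)
    else:
        wn = w / w.sum()
        center = wn @ pts
        d = pts - center
        cov = (d * wn[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    variances = np.clip(evals[order], 0.0, None)
    components = evecs[:, order].T.copy()
    for i in range(3):
        components[i] = fix_sign(components[i])
    return center, components, variances


def fix_sign(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministic sign for an undirected unit vector (see pca_axes)."""
    for k in range(3):
        if abs(v[k]) > tol:
            return -v if v[k] < 0 else v
    return v


def fit_plane(points: PointSet, reference_direction=(0.0, 1.0, 0.0)) -> Plane:
    """Total-least-squares plane: centroid + smallest-variance PCA component.

    The normal is flipped, if needed, toward the supplied reference direction
    (default +y, i.e. proximal).
    """
    center, components, variances = pca_axes(points)
    if variances[1] < 1e-12 * max(variances[0], 1e-30):
        raise DegenerateFitError("plane fit is degenerate: points are collinear")
    normal = components[2]
    ref = np.asarray(reference_direction, dtype=float)
    if normal @ ref < 0:
        normal = -normal
    return Plane(center, normal)


def plane_rms_residual(plane: Plane, points: PointSet) -> float:
    d = plane.signed_distance(points.points)
    return float(np.sqrt(np.mean(d**2)))


def kmeans2(points: PointSet, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-cluster k-means (k-means++ init, 10 restarts, 300-iteration cap).

    Deterministic given ``seed``. Returns (labels in {0, 1}, centers (2, 3)).
    Cluster 0 is the one whose center has the smaller sign-fixed ordering key
    (lexicographic by x, y, z) so labels are reproducible.
    """
    pts = points.points
    if len(points) < 2 or np.allclose(pts, pts[0]):
        raise DegenerateFitError("k-means needs at least 2 distinct points")
    km = KMeans(
        n_clusters=2, init="k-means++", n_init=10, max_iter=300, random_state=seed
    ).fit(pts)
    labels, centers = km.labels_, km.cluster_centers_
    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))
    if order[0] == 1:
        labels = 1 - labels
        centers = centers[::-1]
    return labels, centers


def fit_circle_2d(points) -> tuple[np.ndarray, float]:
    """Least-squares circle in 2D: Pratt-style algebraic fit plus one
    Gauss-Newton refinement pass on geometric distance.

    Works on partial arcs; raises on collinear input.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise InsufficientDataError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    # Algebraic (Pratt) fit: minimise |A(x^2+y^2) + Bx + Cy + D| subject to
    # the Pratt normalisation B^2 + C^2 - 4AD = 1.
    z = x**2 + y**2
    M = np.column_stack([z, x, y, np.ones_like(x)])
    # Constraint matrix for Pratt normalisation.
    N = np.array(
        [
            [0.0, 0.0, 0.0, -2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-2.0, 0.0, 0.0, 0.0],
        ]
    )
    S = M.T @ M
    try:
        from scipy.linalg import eig

        evals, evecs = eig(S, N)
    except Exception as exc:  # pragma: no cover
        raise DegenerateFitError(f"circle fit failed: {exc}") from exc
    evals = np.real(evals)
    evecs = np.real(evecs)
    # smallest non-negative generalized eigenvalue (0 for an exact circle)
    tol = 1e-9 * max(np.trace(S), 1.0)
    good = np.isfinite(evals) & (evals >= -tol)
    if not good.any():
        raise DegenerateFitError("circle fit is degenerate: collinear points")
    sol = evecs[:, np.where(good, evals, np.inf).argmin()]
    A, B, C, D = sol
    if abs(A) < 1e-14 * max(1.0, abs(B), abs(C)):
        raise DegenerateFitError("circle fit is degenerate: collinear points")
    cx, cy = -B / (2 * A), -C / (2 * A)
    r = float(np.sqrt(max(cx**2 + cy**2 - D / A, 0.0)))
    # One Gauss-Newton pass on geometric distance.
    for _ in range(1):
        dx, dy = x - cx, y - cy
        di = np.hypot(dx, dy)
        if (di < 1e-12).any():
            break
        J = np.column_stack([-dx / di, -dy / di, -np.ones_like(di)])
        res = di - r
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        cx, cy, r = cx + step[0], cy + step[1], r + step[2]
    return np.array([cx, cy]), float(r)


# ---------------------------------------------------------------------------
# Mesh queries


def slice_mesh(mesh, plane: Plane) -> list[PlanarContour]:
    """All closed intersection polygons of a surface mesh with a plane.

    Every returned contour is oriented counter-clockwise about the plane
    normal (signed area >= 0). Returns an empty list when the plane misses
    the mesh.
    """
    tm = mesh.trimesh if hasattr(mesh, "trimesh") else mesh
    section = tm.section(plane_origin=plane.point, plane_normal=plane.normal)
    if section is None:
        return []
    contours: list[PlanarContour] = []
    label = getattr(mesh, "name", "")
    for loop in section.discrete:
        loop = np.asarray(loop, dtype=float)
        closed = bool(np.allclose(loop[0], loop[-1]))
        if closed:
            loop = loop[:-1]
        if loop.shape[0] < 3:
            continue
        poly2 = plane.to_plane_coords(loop)
        contour = PlanarContour(plane, poly2, closed=closed, label=label)
        if closed and contour.signed_area() < 0:
            contour.polygon = contour.polygon[::-1].copy()
        contours.append(contour)
    return contours


def contour_centroid(contour: PlanarContour) -> np.ndarray:
    """Area centroid of a closed planar contour, in world coordinates."""
    if not contour.closed:
        raise ValidationError("centroid requires a closed contour")
    c = Polygon(contour.polygon).centroid
    return contour.plane.to_world([[c.x, c.y]])[0]


def closest_surface_points(query: PointSet, mesh) -> PointSet:
    """Nearest point on the triangulated surface (faces, not vertices only)
    for each query point; order preserved.

    Exact: a KD-tree on face centroids supplies an upper bound from a few
    nearby faces, then every face whose centroid ball could beat that bound
    is tested with the exact point-triangle distance.
    """
    from scipy.spatial import cKDTree

    tm = mesh.trimesh if hasattr(mesh, "trimesh") else mesh
    triangles = tm.triangles  # (f, 3, 3)
    centroids = triangles.mean(axis=1)
    # per-face bounding radius about the centroid
    radii = np.linalg.norm(triangles - centroids[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(centroids)
    q = query.points
    k = min(8, len(centroids))
    _, nearby = tree.query(q, k=k)
    nearby = np.atleast_2d(nearby)

    def exact(face_idx: np.ndarray, pts: np.ndarray) -> np.ndarray:
        on_tri = trimesh.triangles.closest_point(triangles[face_idx], pts)
        return on_tri

    # upper bound from the k nearest-centroid faces
    flat_faces = nearby.ravel()
    flat_pts = np.repeat(q, k, axis=0)
    cand = exact(flat_faces, flat_pts).reshape(len(q), k, 3)
    d_cand = np.linalg.norm(cand - q[:, None, :], axis=2)
    best_j = d_cand.argmin(axis=1)
    best_pts = cand[np.arange(len(q)), best_j]
    d_upper = d_cand[np.arange(len(q)), best_j]

    # exhaustive check of every face that could possibly be closer
    for i in range(len(q)):
        candidates = tree.query_ball_point(q[i], d_upper[i] + radii.max())
        candidates = np.asarray(candidates, dtype=np.int64)
        if len(candidates) == 0:
            continue
        keep = np.linalg.norm(centroids[candidates] - q[i], axis=1) - radii[candidates] <= d_upper[i]
        candidates = candidates[keep]
        if len(candidates) == 0:
            continue
        pts_i = exact(candidates, np.repeat(q[i][None, :], len(candidates), axis=0))
        d_i = np.linalg.norm(pts_i - q[i], axis=1)
        j = d_i.argmin()
        if d_i[j] < d_upper[i]:
            d_upper[i] = d_i[j]
            best_pts[i] = pts_i[j]
    return PointSet(best_pts)


def sample_surface(mesh, n: int, seed: int) -> PointSet:
    """Area-uniform surface samples; deterministic given the seed."""
    if n < 1:
        raise ValidationError("sample count must be >= 1")
    tm = mesh.trimesh if hasattr(mesh, "trimesh") else mesh
    pts, _ = trimesh.sample.sample_surface(tm, n, seed=int(seed))
    return PointSet(np.asarray(pts, dtype=float))


# ---------------------------------------------------------------------------
# Angles


def project_direction(v, normal) -> np.ndarray:
    """Unit projection of v into the plane perpendicular to ``normal``."""
    v = np.asarray(v, dtype=float)
    n = _as_unit(normal, "normal")
    w = v - (v @ n) * n
    nw = np.linalg.norm(w)
    if nw < 1e-9 * max(np.linalg.norm(v), 1e-30):
        raise DegenerateFitError("cannot project: vector is parallel to the normal")
    return w / nw


def signed_angle_about(a, b, axis) -> float:
    """Signed angle (degrees, (-180, 180]) rotating a onto b about ``axis``,
    positive counter-clockwise by the right-hand rule."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.linalg.norm(a) < _UNIT_TOL or np.linalg.norm(b) < _UNIT_TOL:
        raise ValidationError("zero-length vector in signed_angle_about")
    ax = _as_unit(axis, "axis")
    ang = float(np.degrees(np.arctan2(np.cross(a, b) @ ax, a @ b)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def transverse_azimuth(v) -> float:
    """Azimuth (degrees) of a direction in the transverse (x, z) plane:
    atan2(v_z, v_x), the in-plane angle about the proximal +y axis."""
    v = np.asarray(v, dtype=float)
    return float(np.degrees(np.arctan2(v[2], v[0])))


def wrap_angle(angle: float, period: float = 360.0) -> float:
    """Wrap into (-period/2, period/2]."""
    a = (angle + period / 2.0) % period - period / 2.0
    if a == -period / 2.0:
        a = period / 2.0
    return a


def angle_difference(a: float, b: float, period: float = 360.0) -> float:
    """Smallest-magnitude circular difference a - b modulo ``period``."""
    return wrap_angle(a - b, period)


__all__ = [
    "Axis",
    "Plane",
    "PointSet",
    "PlanarContour",
    "pca_axes",
    "fix_sign",
    "fit_plane",
    "plane_rms_residual",
    "kmeans2",
    "fit_circle_2d",
    "slice_mesh",
    "contour_centroid",
    "closest_surface_points",
    "sample_surface",
    "project_direction",
    "signed_angle_about",
    "transverse_azimuth",
    "wrap_angle",
    "angle_difference",
]
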