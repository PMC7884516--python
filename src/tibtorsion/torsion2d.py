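"""2D reference methods for tibial torsion, computed on axial slices.

Both methods share the proximal axis: a tangent along the posterior cortex
of the tibial head in the axial slice 1.0 mm proximal to the fibular head
apex. They differ distally:

* Jakob — circles fitted to the tibial and fibular contours in the slice
  1.0 mm proximal to the tibial articular surface of the ankle; the distal
  axis joins the two circle centres.
* Goutallier — tangents to the articular aspects of the medial and lateral
  malleoli in the slice 1.0 mm below the talar surface (approximated here by
  the distal tibia joint plane level); the distal axis joins the centres of
  the two tangents.

Torsion is the signed angle from the proximal to the distal line in the
axial (x, z) plane, external positive, reported in (-90, 90] after resolving
each line's 180-degree direction ambiguity toward the smaller magnitude.

Slices are exact planes in the aligned frame — the 1.0 mm offsets mirror the
CT slice spacing of the acquisition the method was designed for; slice
thickness itself is not simulated. Tangent placement, done by eye in the
original technique, is operationalised reproducibly: the posterior tangent
is the convex-hull supporting line whose outward normal is most posterior,
and a malleolar "articular aspect" is the contour arc whose outward normals
point toward the inter-malleolar midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .config import RunConfig
from .errors import SliceError, ValidationError
from .geometry import (
    Axis,
    Plane,
    PointSet,
    fit_circle_2d,
    pca_axes,
    slice_mesh,
    wrap_angle,
)
from .io import BoneSet, SurfaceMesh
from .torsion3d import TorsionResult, align_to_reference, fit_dtjp

METHODS_2D = ("jakob", "goutallier")


@dataclass(frozen=True)
class Line2D:
    """Line in the axial (x, z) plane: point plus unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValidationError("Line2D direction must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    @property
    def azimuth_deg(self) -> float:
        """atan2(z, x) of the direction — same convention as 3D axes."""
        return float(np.degrees(np.arctan2(self.direction[1], self.direction[0])))

    def as_axis(self, y_level: float) -> Axis:
        return Axis(
            point=np.array([self.point[0], y_level, self.point[1]]),
            direction=np.array([self.direction[0], 0.0, self.direction[1]]),
        )


def axial_contours(mesh: SurfaceMesh, y_level: float) -> list[np.ndarray]:
    """Closed contours of a mesh at the axial plane y = y_level, each as an
    ordered (n, 2) array of (x, z) coordinates."""
    plane = Plane(np.array([0.0, y_level, 0.0]), np.array([0.0, 1.0, 0.0]))
    out = []
    for contour in slice_mesh(mesh, plane):
        if not contour.closed:
            continue
        w = contour.world_points()
        out.append(np.column_stack([w[:, 0], w[:, 2]]))
    return out


def _largest_contour(contours: list[np.ndarray]) -> np.ndarray:
    def shoelace(c):
        x, z = c[:, 0], c[:, 1]
        return abs(0.5 * np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z))

    return max(contours, key=shoelace)


def fibular_head_apex_y(fibula: SurfaceMesh) -> float:
    return float(fibula.vertices[:, 1].max())


def proximal_axis_2d(
    tibia: SurfaceMesh,
    fibula: SurfaceMesh,
    config: RunConfig | None = None,
    diagnostics: dict | None = None,
) -> Line2D:
    """Posterior tangent of the tibial head, one slice (1.0 mm) proximal to
    the fibular head apex.

    The tangent is the convex-hull edge of the tibial contour whose outward
    normal is closest to -z (posterior).
    """
    cfg = config or RunConfig()
    y_star = fibular_head_apex_y(fibula) + cfg.slice_offset_mm
    contours = axial_contours(tibia, y_star)
    if not contours:
        raise SliceError(
            f"no tibial contour at y = {y_star:.1f} mm (fibular head apex + "
            f"{cfg.slice_offset_mm:.1f} mm)",
            stage="proximal_axis_2d",
        )
    contour = _largest_contour(contours)
    hull = ConvexHull(contour)
    hv = contour[hull.vertices]  # counter-clockwise in (x, z)
    edges = []
    for i in range(len(hv)):
        p1, p2 = hv[i], hv[(i + 1) % len(hv)]
        e = p2 - p1
        le = np.linalg.norm(e)
        if le < 1e-12:
            continue
        e = e / le
        outward = np.array([e[1], -e[0]])  # outward normal of a CCW hull
        score = outward @ np.array([0.0, -1.0])  # alignment with posterior
        edges.append((score, le, p1, p2, e))
    # a manual tangent hugs the flat cortex, not a short tessellation edge at
    # the posterior-most corner: consider only edges of substantial length
    max_len = max(le for _, le, *_ in edges)
    candidates = [t for t in edges if t[1] >= 0.25 * max_len]
    _, _, p1, p2, e = max(candidates, key=lambda t: t[0])
    if diagnostics is not None:
        diagnostics["proximal_slice_y_mm"] = y_star
        diagnostics["posterior_tangent"] = {"p1": p1, "p2": p2}
    return Line2D(point=(p1 + p2) / 2.0, direction=e)


def jakob_distal_axis(
    tibia: SurfaceMesh,
    fibula: SurfaceMesh,
    dtjp: Plane,
    config: RunConfig | None = None,
    diagnostics: dict | None = None,
) -> Line2D:
    """Line through the centres of circles fitted to the tibial and fibular
    contours, one slice (1.0 mm) proximal to the articular surface."""
    cfg = config or RunConfig()
    y_level = float(dtjp.point[1]) + cfg.slice_offset_mm
    tib = axial_contours(tibia, y_level)
    fib = axial_contours(fibula, y_level)
    if not tib:
        raise SliceError(
            f"no tibial contour at y = {y_level:.1f} mm", stage="jakob_distal_axis"
        )
    if not fib:
        raise SliceError(
            f"no fibular contour at y = {y_level:.1f} mm", stage="jakob_distal_axis"
        )
    c_tib, r_tib = fit_circle_2d(_largest_contour(tib))
    c_fib, r_fib = fit_circle_2d(_largest_contour(fib))
    if diagnostics is not None:
        diagnostics["jakob_slice_y_mm"] = y_level
        diagnostics["jakob_circles"] = {
            "tibia": {"center": c_tib, "radius": r_tib},
            "fibula": {"center": c_fib, "radius": r_fib},
        }
    return Line2D(point=(c_tib + c_fib) / 2.0, direction=c_fib - c_tib)


def _resample_smooth(contour: np.ndarray, n_out: int = 256, window_mm: float = 2.0) -> np.ndarray:
    """Uniform arc-length resampling plus a circular moving average.

    Malleolar contours from noisy segmentations have jagged 1-mm edges whose
    normals are meaningless; a reader's tangent responds to the smooth cortex
    outline. Smoothing at ~2 mm leaves flat facets and large-radius arcs
    unchanged.
    """
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total < 1e-9:
        return contour
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, total, n_out, endpoint=False)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    pts = np.column_stack([x, y])
    half = max(1, int(round(window_mm / (total / n_out) / 2)))
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    sm = np.column_stack(
        [
            np.convolve(np.concatenate([pts[-half:, k], pts[:, k], pts[:half, k]]), kernel, mode="valid")
            for k in (0, 1)
        ]
    )
    return sm


def _articular_arc(
    contour: np.ndarray, midpoint: np.ndarray, trim_half_angle_deg: float = 45.0
) -> np.ndarray:
    """Ordered contour arc forming the 'articular aspect' of a malleolus.

    Two steps: (1) the longest contiguous run of edges whose outward normals
    face the inter-malleolar midpoint (dot > 0); (2) a trim to the subrun
    whose normals lie within ``trim_half_angle_deg`` of the centroid-to-
    midpoint direction (a noise-stable reference that on clean geometry is
    the facet normal). The trim anchors the arc ends where the normal
    direction turns quickly, so noise cannot slide them along the contour;
    on a flat facet it reduces the arc to exactly the facet.
    """
    n = len(contour)
    centroid = contour.mean(axis=0)
    nxt = np.roll(contour, -1, axis=0)
    edges = nxt - contour
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 1e-12
    # edge directions over a ~2 mm central stencil: single-edge directions on
    # a finely resampled noisy contour are meaningless
    mean_len = max(float(lengths[keep].mean()) if keep.any() else 1.0, 1e-9)
    k = int(np.clip(round(2.0 / mean_len), 1, max(1, n // 8)))
    idx = np.arange(n)
    stencil = contour[(idx + k) % n] - contour[(idx - k + 1) % n]
    slen = np.linalg.norm(stencil, axis=1)
    ok = slen > 1e-12
    dirs = np.where(ok[:, None], stencil, edges)
    dlen = np.where(ok, slen, np.maximum(lengths, 1e-12))
    normals = np.column_stack([dirs[:, 1], -dirs[:, 0]]) / dlen[:, None]
    mids = (contour + nxt) / 2.0
    # orient normals outward (away from the contour centroid)
    flip = np.sum(normals * (mids - centroid), axis=1) < 0
    normals[flip] *= -1.0
    facing = (np.sum(normals * (midpoint - mids), axis=1) > 0) & keep
    if not facing.any():
        return np.empty((0, 2))
    # longest circular run of facing edges
    idx = np.arange(n)
    runs = []
    visited = np.zeros(n, bool)
    for start in idx[facing]:
        if visited[start]:
            continue
        run = []
        i = start
        # rewind to run start
        while facing[(i - 1) % n] and (i - 1) % n != start:
            i = (i - 1) % n
        j = i
        while facing[j] and not visited[j]:
            visited[j] = True
            run.append(j)
            j = (j + 1) % n
        runs.append(run)
    best = max(runs, key=len)
    # trim to the subrun whose normals cluster around the stable reference
    n_ref = midpoint - centroid
    n_ref /= max(np.linalg.norm(n_ref), 1e-12)
    cos_min = np.cos(np.radians(trim_half_angle_deg))
    within = [normals[i] @ n_ref >= cos_min for i in best]
    if any(within):
        # span first to last cone-satisfying edge: interior dropouts from
        # residual normal noise must not split the facet
        first = within.index(True)
        last = len(within) - 1 - within[::-1].index(True)
        best = best[first : last + 1]
    # arc points: edge start points plus final edge end point
    pts = [contour[i] for i in best] + [nxt[best[-1]]]
    return np.asarray(pts)


def _arc_tangent_center(arc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares tangent to an arc and its 'centre': the arc
    midpoint (by arc length) projected onto the tangent."""
    if len(arc) == 2:
        d = arc[1] - arc[0]
        return d / np.linalg.norm(d), (arc[0] + arc[1]) / 2.0
    pts3 = np.column_stack([arc[:, 0], np.zeros(len(arc)), arc[:, 1]])
    _, components, _ = pca_axes(PointSet(pts3))
    d3 = components[0]
    direction = np.array([d3[0], d3[2]])
    direction /= np.linalg.norm(direction)
    seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        mid = arc[0]
    else:
        t = (half - cum[k - 1]) / max(cum[k] - cum[k - 1], 1e-12)
        mid = arc[k - 1] + t * (arc[k] - arc[k - 1])
    anchor = arc.mean(axis=0)
    center = anchor + ((mid - anchor) @ direction) * direction
    return direction, center


def goutallier_distal_axis(
    tibia: SurfaceMesh,
    fibula: SurfaceMesh,
    dtjp: Plane,
    config: RunConfig | None = None,
    diagnostics: dict | None = None,
) -> Line2D:
    """Line through the centres of tangents to the medial and lateral
    malleolar articular aspects, one slice (1.0 mm) below the talar surface
    (taken as the distal tibia joint plane level)."""
    cfg = config or RunConfig()
    y_level = float(dtjp.point[1]) - cfg.slice_offset_mm
    tib = axial_contours(tibia, y_level)
    fib = axial_contours(fibula, y_level)
    if not tib:
        raise SliceError(
            f"no medial malleolar (tibial) contour at y = {y_level:.1f} mm",
            stage="goutallier_distal_axis",
        )
    if not fib:
        raise SliceError(
            f"no lateral malleolar (fibular) contour at y = {y_level:.1f} mm",
            stage="goutallier_distal_axis",
        )
    medial = _resample_smooth(_largest_contour(tib))
    lateral = _resample_smooth(_largest_contour(fib))
    midpoint = (medial.mean(axis=0) + lateral.mean(axis=0)) / 2.0
    centers = []
    for name, contour in (("medial", medial), ("lateral", lateral)):
        arc = _articular_arc(contour, midpoint)
        if len(arc) < 2:
            raise SliceError(
                f"no articular aspect found on the {name} malleolus",
                stage="goutallier_distal_axis",
            )
        direction, center = _arc_tangent_center(arc)
        centers.append(center)
        if diagnostics is not None:
            diagnostics[f"goutallier_{name}"] = {
                "tangent_direction": direction,
                "center": center,
                "arc_points": len(arc),
            }
    if diagnostics is not None:
        diagnostics["goutallier_slice_y_mm"] = y_level
    return Line2D(point=(centers[0] + centers[1]) / 2.0, direction=centers[1] - centers[0])


def measure_torsion_2d(
    bones: BoneSet,
    method: str = "jakob",
    seed: int = 0,
    config: RunConfig | None = None,
) -> TorsionResult:
    """Full 2D torsion measurement by the Jakob or Goutallier technique.

    Torsion = signed angle from the proximal tangent direction to the distal
    line direction in the axial plane, wrapped to (-90, 90] (axes are lines,
    defined only up to 180 degrees).
    """
    if method not in METHODS_2D:
        raise ValidationError(f"unknown 2D method {method!r}; expected {METHODS_2D}")
    cfg = config or RunConfig()
    bones.require("fibula", f"the {method} method")
    diag: dict = {"method": method, "seed": int(seed)}
    aligned, frame = align_to_reference(bones)
    proximal = proximal_axis_2d(aligned.tibia, aligned.fibula, cfg, diag)
    dtjp = fit_dtjp(aligned.landmarks, diag)
    if method == "jakob":
        distal = jakob_distal_axis(aligned.tibia, aligned.fibula, dtjp, cfg, diag)
    else:
        distal = goutallier_distal_axis(aligned.tibia, aligned.fibula, dtjp, cfg, diag)
    angle = wrap_angle(distal.azimuth_deg - proximal.azimuth_deg, period=180.0)
    y_prox = diag["proximal_slice_y_mm"]
    y_dist = diag.get("jakob_slice_y_mm", diag.get("goutallier_slice_y_mm", 0.0))
    return TorsionResult(
        angle_deg=float(angle),
        variant=method,
        pta=proximal.as_axis(y_prox),
        dta=distal.as_axis(y_dist),
        anatomical_axis=None,
        frame=frame,
        diagnostics=diag,
    )


__all__ = [
    "Line2D",
    "METHODS_2D",
    "axial_contours",
    "fibular_head_apex_y",
    "proximal_axis_2d",
    "jakob_distal_axis",
    "goutallier_distal_axis",
    "measure_torsion_2d",
]
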