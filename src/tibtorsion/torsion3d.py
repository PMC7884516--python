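"""The 3D tibial-torsion measurement.

Torsion in 3D is the angle between the proximal tibia axis (PTA) and the
distal tibia axis (DTA), both projected onto the plane perpendicular to the
anatomical axis of the tibia. The DTA comes in two adaptations: from the
distal tibia alone (3D-T) or additionally including the distal fibula
(3D-TF).

Pipeline stages (each an importable function):

1. ``align_to_reference`` — mirror left legs, map the mechanical axis
   (knee centre -> ankle centre) onto +y, rotate the anterior reference into
   the y-z plane.
2. ``compute_pta`` — k-means condyle detection on the distal 25 mm of the
   femur, 1 mm condylar tip clusters, closest-point mapping onto the tibial
   plateau (tibiofemoral contact areas), PCA first component.
3. ``fit_dtjp`` — least-squares plane through the nine distal articular
   points (distal tibia joint plane).
4. ``extract_distal_slab`` — the 10 mm metaphyseal surface band adjacent to
   the DTJP, optionally including the fibula at equal sample density.
5. ``compute_dta`` — PCA of the slab; by default the second principal
   component (configurable, and reported, because variance ordering depends
   on slab shape).
6. ``compute_anatomical_axis`` — tibial plateau plane from eight points,
   whole-bone PCA for the slicing normal, six cross-section centroids every
   20 mm from 40 mm below the plateau plane centre, total-least-squares line.
7. ``measure_torsion_3d`` — the full chain plus the projected signed angle.

Sign convention: external torsion positive — the right-hand rule about the
distally pointing anatomical axis, with +x lateral and +y proximal; left
sides are mirrored (x -> -x) before alignment so both sides are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import (
    CoverageError,
    DegenerateFitError,
    GeometryError,
    InsufficientDataError,
    TorsionError,
    ValidationError,
    stage_wrap,
)
from .geometry import (
    Axis,
    Plane,
    PointSet,
    closest_surface_points,
    contour_centroid,
    fit_plane,
    fix_sign,
    kmeans2,
    pca_axes,
    plane_rms_residual,
    project_direction,
    sample_surface,
    signed_angle_about,
    slice_mesh,
)
from .io import BoneSet, LandmarkSet, SurfaceMesh

VARIANTS_3D = ("3D-T", "3D-TF")


@dataclass
class ReferenceFrame:
    """Rigid map from input coordinates to the measurement frame.

    ``apply`` computes ``R @ (M p) + t`` where M is the x-mirror when the
    input is a left leg. The rotation is proper (det +1); mirroring is
    recorded separately.
    """

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    side_mirrored: bool = False

    def apply_points(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self.side_mirrored:
            p = p.copy()
            p[:, 0] *= -1.0
        return p @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "side_mirrored": self.side_mirrored,
        }


@dataclass
class TorsionResult:
    """One torsion angle plus every intermediate axis for audit."""

    angle_deg: float
    variant: str  # 3D-T | 3D-TF | jakob | goutallier
    pta: Axis
    dta: Axis
    anatomical_axis: Axis | None
    frame: ReferenceFrame
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "variant": self.variant,
            "axes": {
                "PTA": self.pta.to_dict(),
                "DTA": self.dta.to_dict(),
                "anatomical": (
                    self.anatomical_axis.to_dict() if self.anatomical_axis else None
                ),
            },
            "frame": self.frame.to_dict(),
            "diagnostics": _jsonable(self.diagnostics),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Stage 1: alignment


def align_to_reference(bones: BoneSet) -> tuple[BoneSet, ReferenceFrame]:
    """Bring a leg into the measurement frame.

    The mechanical axis of the tibia — the line from the knee centre to the
    ankle centre (by default the centroid of the nine distal articular
    points) — is aligned with +y (proximal up); the leg is then rotated
    about y until the anterior reference point lies in the y-z plane with
    z > 0. Left legs are mirrored (x -> -x) first, so +x is lateral for both
    sides. The knee centre maps to the origin.
    """
    lm = bones.landmarks
    _validate_landmarks_on_surface(lm, bones.tibia)
    mirrored = lm.side == "left"
    if mirrored:
        lm = lm.mirrored_x()

    knee = lm.knee_center
    ankle = lm.ankle_center
    axis_vec = knee - ankle
    if np.linalg.norm(axis_vec) < 1.0:
        raise DegenerateFitError(
            "knee_center within 1 mm of ankle_center: mechanical axis undefined",
            stage="align_to_reference",
        )
    y_new = axis_vec / np.linalg.norm(axis_vec)
    t_ant = lm.anterior_ref - knee
    t_perp = t_ant - (t_ant @ y_new) * y_new
    if np.linalg.norm(t_perp) < 1e-9:
        raise DegenerateFitError(
            "anterior_ref lies on the mechanical axis: anterior direction undefined",
            stage="align_to_reference",
        )
    z_new = t_perp / np.linalg.norm(t_perp)
    x_new = np.cross(y_new, z_new)
    # rows of R are the new basis expressed in (mirrored) input coordinates
    rotation = np.vstack([x_new, y_new, z_new])
    translation = -rotation @ knee
    frame = ReferenceFrame(rotation=rotation, translation=translation, side_mirrored=mirrored)

    def tf_mesh(mesh: SurfaceMesh | None) -> SurfaceMesh | None:
        if mesh is None:
            return None
        m = mesh.mirrored_x() if mirrored else mesh
        return m.transformed(rotation, translation)

    lm_aligned = lm.transformed(rotation, translation)
    aligned = BoneSet(
        tibia=tf_mesh(bones.tibia),
        landmarks=lm_aligned,
        femur=tf_mesh(bones.femur),
        fibula=tf_mesh(bones.fibula),
    )
    return aligned, frame


def _validate_landmarks_on_surface(
    lm: LandmarkSet, tibia: SurfaceMesh, tol_mm: float = 5.0, tol_anterior_mm: float = 60.0
) -> None:
    """Landmarks must lie on (near) the tibia: within 5 mm, except the
    anterior reference, which may sit on the patella or tuberosity (60 mm)."""
    groups = {
        "distal_articular": (lm.distal_articular, tol_mm),
        "plateau": (lm.plateau, tol_mm),
        "knee_center": (lm.knee_center[None, :], tol_mm),
        "ankle_center": (lm.ankle_center[None, :], tol_mm),
        "anterior_ref": (lm.anterior_ref[None, :], tol_anterior_mm),
    }
    for name, (pts, tol) in groups.items():
        nearest = closest_surface_points(PointSet(pts), tibia).points
        d = np.linalg.norm(nearest - pts, axis=1)
        if (d > tol).any():
            raise ValidationError(
                f"landmark '{name}' lies {d.max():.1f} mm from the tibia surface "
                f"(limit {tol:.0f} mm)",
                stage="align_to_reference",
            )


# ---------------------------------------------------------------------------
# Stage 2: proximal tibia axis


def compute_pta(
    femur: SurfaceMesh,
    tibia: SurfaceMesh,
    seed: int,
    config: RunConfig | None = None,
    diagnostics: dict | None = None,
) -> Axis:
    """PTA: first principal component of the tibiofemoral contact areas.

    The two femoral condyles are found by k-means on area-uniform surface
    samples of the most distal 25 mm of the femur; each condylar tip cluster
    (CTC) is the points within 1 mm of its condyle's most distal point; the
    CTC points are mapped to their closest points on the tibial surface,
    yielding the tibiofemoral contact areas (TFCA) whose first principal
    component, anchored at the TFCA centroid, is the PTA.
    """
    cfg = config or RunConfig()
    diag = diagnostics if diagnostics is not None else {}
    y_cut = float(femur.vertices[:, 1].min()) + cfg.condyle_band_mm
    band_mesh = _submesh_below(femur, y_cut)
    samples = sample_surface(band_mesh, cfg.pta_sample_count, seed)
    band = samples.points[samples.points[:, 1] <= y_cut]
    if len(band) < 10:
        raise InsufficientDataError(
            "too few femoral samples in the distal condyle band", stage="compute_pta"
        )
    labels, centers = kmeans2(PointSet(band), seed)
    separation = float(np.linalg.norm(centers[0] - centers[1]))
    diag["condyle_separation_mm"] = separation
    if separation < cfg.min_condyle_separation_mm:
        raise GeometryError(
            f"condyle detection failed: cluster separation {separation:.1f} mm "
            f"< {cfg.min_condyle_separation_mm:.0f} mm",
            stage="compute_pta",
        )
    ctc_points = []
    for k in (0, 1):
        cluster = band[labels == k]
        # robust minimum: a 0.5th-percentile floor instead of the single
        # lowest sample, so one deep noise vertex cannot recentre the tip
        # band sideways (identical to the minimum on smooth meshes)
        y_floor = float(np.percentile(cluster[:, 1], 0.5))
        tips = cluster[cluster[:, 1] <= y_floor + cfg.tip_band_mm]
        if len(tips) == 0:
            raise GeometryError(f"empty condylar tip cluster {k}", stage="compute_pta")
        ctc_points.append(tips)
    diag["ctc_point_counts"] = [len(c) for c in ctc_points]
    tfca = closest_surface_points(PointSet(np.vstack(ctc_points)), tibia)
    center, components, variances = pca_axes(tfca)
    diag["tfca_point_count"] = len(tfca)
    diag["tfca_variances"] = variances
    direction = _sign_positive_x(components[0])
    return Axis(center, direction)


def _sign_positive_x(direction: np.ndarray) -> np.ndarray:
    """Directional sign rule for transverse axes: positive x-component."""
    if abs(direction[0]) > 1e-9:
        return -direction if direction[0] < 0 else direction
    return fix_sign(direction)


def _submesh_below(mesh: SurfaceMesh, y_cut: float) -> SurfaceMesh:
    """Faces with at least one vertex at y <= y_cut (band candidates)."""
    vy = mesh.vertices[:, 1]
    mask = vy[mesh.faces].min(axis=1) <= y_cut
    if mask.sum() < 4:
        return mesh
    return SurfaceMesh(mesh.vertices, mesh.faces[mask], mesh.name)


def _band_submesh(mesh: SurfaceMesh, plane: Plane, thickness: float) -> SurfaceMesh | None:
    """Faces whose vertex distance range overlaps [0, thickness] from plane."""
    eps = 1e-6
    d = plane.signed_distance(mesh.vertices)
    dmin = d[mesh.faces].min(axis=1)
    dmax = d[mesh.faces].max(axis=1)
    mask = (dmin <= thickness + eps) & (dmax >= -eps)
    if mask.sum() < 4:
        return None
    return SurfaceMesh(mesh.vertices, mesh.faces[mask], mesh.name)


# ---------------------------------------------------------------------------
# Stage 3: distal tibia joint plane


def fit_dtjp(landmarks: LandmarkSet, diagnostics: dict | None = None) -> Plane:
    """Least-squares plane through the nine distal articular points,
    normal oriented proximally (+y)."""
    pts = PointSet(landmarks.distal_articular)
    try:
        plane = fit_plane(pts, reference_direction=(0.0, 1.0, 0.0))
    except TorsionError as exc:
        raise stage_wrap("fit_dtjp", exc)
    if diagnostics is not None:
        diagnostics["dtjp_rms_residual_mm"] = plane_rms_residual(plane, pts)
    return plane


# ---------------------------------------------------------------------------
# Stage 4: distal metaphyseal slab


def extract_distal_slab(
    tibia: SurfaceMesh,
    fibula: SurfaceMesh | None,
    dtjp: Plane,
    include_fibula: bool,
    thickness: float = 10.0,
    seed: int = 0,
    config: RunConfig | None = None,
    diagnostics: dict | None = None,
) -> PointSet:
    """Area-uniform surface samples of the metaphyseal band adjacent to the
    DTJP (on its proximal side by default; see ``RunConfig.slab_side``).

    When ``include_fibula`` is set, the corresponding fibular band is added
    at the same sample density (points per mm^2).
    """
    cfg = config or RunConfig()
    if include_fibula and fibula is None:
        raise ValidationError(
            "3D-TF slab requires a fibula mesh, none given", stage="extract_distal_slab"
        )
    normal = dtjp.normal if cfg.slab_side == "proximal" else -dtjp.normal
    band_plane = Plane(dtjp.point, normal)

    eps = 1e-6  # numerical skin: the articular surface sits exactly at d = 0

    def band_points(band_mesh: SurfaceMesh, n: int, sub_seed: int) -> np.ndarray:
        pts = sample_surface(band_mesh, n, sub_seed).points
        d = band_plane.signed_distance(pts)
        return pts[(d >= -eps) & (d <= thickness + eps)]

    tib_band = _band_submesh(tibia, band_plane, thickness)
    if tib_band is None:
        raise InsufficientDataError(
            "no tibial surface within the metaphyseal band", stage="extract_distal_slab"
        )
    n_tibia = cfg.slab_sample_count
    density = n_tibia / tib_band.area  # points per mm^2 of candidate band faces
    parts = [band_points(tib_band, n_tibia, seed)]
    if include_fibula and fibula is not None:
        fib_band = _band_submesh(fibula, band_plane, thickness)
        if fib_band is not None:
            # equal sample density (points per mm^2) for both bones
            n_fib = max(1, int(round(density * fib_band.area)))
            parts.append(band_points(fib_band, n_fib, seed + 1))
        else:
            parts.append(np.empty((0, 3)))
    slab = np.vstack([p for p in parts if len(p)]) if any(len(p) for p in parts) else np.empty((0, 3))
    if diagnostics is not None:
        diagnostics["slab_point_count"] = int(len(slab))
        diagnostics["slab_tibia_points"] = int(len(parts[0]))
        if include_fibula:
            diagnostics["slab_fibula_points"] = int(len(parts[1]))
    if len(slab) < cfg.min_slab_points:
        raise InsufficientDataError(
            f"only {len(slab)} surface samples in the {thickness:.1f} mm "
            f"metaphyseal band (need {cfg.min_slab_points})",
            stage="extract_distal_slab",
        )
    return PointSet(slab)


# ---------------------------------------------------------------------------
# Stage 5: distal tibia axis


def compute_dta(
    slab: PointSet,
    component_index: int = 2,
    diagnostics: dict | None = None,
) -> Axis:
    """DTA: a principal component of the metaphyseal slab (default: the
    second, as the method defines; configurable to the first).

    When the selected component's variance is within 5% of an adjacent
    component's, an ambiguity warning is recorded in the diagnostics — the
    selection is then unstable under resampling.
    """
    if component_index not in (1, 2):
        raise ValidationError("component_index must be 1 or 2", stage="compute_dta")
    center, components, variances = pca_axes(slab)
    i = component_index - 1
    ratios = []
    if i > 0 and variances[i] > 0:
        ratios.append(variances[i - 1] / variances[i])
    if i < 2 and variances[i + 1] > 0:
        ratios.append(variances[i] / variances[i + 1])
    ambiguous = any(r < RunConfig().dta_ambiguity_ratio for r in ratios)
    if diagnostics is not None:
        diagnostics["dta_component_index"] = component_index
        diagnostics["slab_variances"] = variances
        diagnostics["dta_ambiguous"] = bool(ambiguous)
        if ambiguous:
            diagnostics["dta_warning"] = (
                "compute_dta: near-isotropic slab — principal component "
                "selection is ambiguous (adjacent variance ratio < 1.05)"
            )
    direction = _sign_positive_x(components[i])
    return Axis(center, direction)


# ---------------------------------------------------------------------------
# Stage 6: anatomical axis


def compute_anatomical_axis(
    tibia: SurfaceMesh,
    landmarks: LandmarkSet,
    seed: int,
    config: RunConfig | None = None,
    diagnostics: dict | None = None,
) -> Axis:
    """Anatomical axis: total-least-squares line through the centroids of
    six tibial cross-sections.

    The tibial plateau plane (TPP) is fitted to the eight plateau points;
    whole-bone PCA (on area-uniform surface samples) gives the slicing
    normal; six planes are placed every 20 mm starting 40 mm distal of the
    TPP centre; the largest-area intersection contour of each plane yields a
    centroid; the axis is the first principal component through the six
    centroids, oriented proximally (+y).
    """
    cfg = config or RunConfig()
    diag = diagnostics if diagnostics is not None else {}
    try:
        tpp = fit_plane(PointSet(landmarks.plateau), reference_direction=(0.0, 1.0, 0.0))
    except TorsionError as exc:
        raise stage_wrap("compute_anatomical_axis", exc)
    diag["tpp_rms_residual_mm"] = plane_rms_residual(tpp, PointSet(landmarks.plateau))
    samples = sample_surface(tibia, cfg.sample_count, seed)
    _, components, _ = pca_axes(samples)
    long_dir = components[0]
    # orient the slicing direction distally: from the TPP centre toward the bone
    to_bone = samples.points.mean(axis=0) - tpp.point
    if long_dir @ to_bone < 0:
        long_dir = -long_dir
    centroids = []
    for offset in cfg.anat_offsets():
        plane = Plane(tpp.point + offset * long_dir, long_dir)
        contours = [c for c in slice_mesh(tibia, plane) if c.closed]
        if not contours:
            raise CoverageError(
                f"no tibial cross-section at offset {offset:.0f} mm distal of the "
                "plateau plane (truncated shaft?)",
                stage="compute_anatomical_axis",
            )
        largest = max(contours, key=lambda c: c.area())
        centroids.append(contour_centroid(largest))
    centroids = np.asarray(centroids)
    diag["anat_centroids"] = centroids
    center, components, _ = pca_axes(PointSet(centroids))
    direction = components[0]
    if direction[1] < 0:
        direction = -direction
    return Axis(center, direction)


# ---------------------------------------------------------------------------
# Stage 7: full measurement


def measure_torsion_3d(
    bones: BoneSet,
    variant: str = "3D-TF",
    seed: int = 0,
    config: RunConfig | None = None,
) -> TorsionResult:
    """Full 3D torsion measurement (variant '3D-T' or '3D-TF')."""
    if variant not in VARIANTS_3D:
        raise ValidationError(f"unknown 3D variant {variant!r}; expected {VARIANTS_3D}")
    cfg = config or RunConfig()
    include_fibula = variant == "3D-TF"
    if include_fibula:
        bones.require("fibula", "variant 3D-TF")
    femur = bones.require("femur", "the 3D proximal tibia axis")

    diag: dict = {"variant": variant, "seed": int(seed)}
    aligned, frame = align_to_reference(bones)
    pta = compute_pta(aligned.femur, aligned.tibia, seed, cfg, diag)
    dtjp = fit_dtjp(aligned.landmarks, diag)
    slab = extract_distal_slab(
        aligned.tibia,
        aligned.fibula,
        dtjp,
        include_fibula=include_fibula,
        thickness=cfg.slab_thickness_mm,
        seed=seed,
        config=cfg,
        diagnostics=diag,
    )
    dta = compute_dta(slab, cfg.dta_component, diag)
    anat = compute_anatomical_axis(aligned.tibia, aligned.landmarks, seed, cfg, diag)
    try:
        pta_proj = project_direction(pta.direction, anat.direction)
        dta_proj = project_direction(dta.direction, anat.direction)
    except TorsionError as exc:
        raise stage_wrap("measure_torsion_3d", exc)
    angle = signed_angle_about(pta_proj, dta_proj, -anat.direction)
    return TorsionResult(
        angle_deg=angle,
        variant=variant,
        pta=pta,
        dta=dta,
        anatomical_axis=anat,
        frame=frame,
        diagnostics=diag,
    )


__all__ = [
    "ReferenceFrame",
    "TorsionResult",
    "align_to_reference",
    "compute_pta",
    "fit_dtjp",
    "extract_distal_slab",
    "compute_dta",
    "compute_anatomical_axis",
    "measure_torsion_3d",
    "VARIANTS_3D",
]
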