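"""Parametric synthetic bone phantom with analytic ground truth.

The phantom emulates the geometry the measurement method relies on, one
feature per pipeline stage, with every defining azimuth a free parameter:

* tibia — a watertight loft of convex cross-sections along y: a tibial-head
  ellipse with a posterior flat facet (proximal 2D tangent), a circular
  shaft, and a distal 10-mm elliptic-cylinder band over a flat plafond
  (distal 3D axis); a small medial-malleolar prong with a flat articular
  facet sits just below the plafond as a second closed component;
* femur — two condylar spheres hovering just above the flat plateau, their
  centre line at ``condyle_azimuth`` (proximal 3D axis via the tibiofemoral
  contact areas);
* fibula — a cylinder with a small flat-capped head apex (2D proximal slice
  level) and a distal lateral-malleolar facet.

Ground truth is defined relative to the pipeline's stated axis definitions,
not to any anatomical "true torsion": the phantom tests internal
consistency, which is what those definitions support. The distal slab's
second principal component is the ellipse minor axis by construction
(default semi-axes 25 x 18 mm over a 10 mm band keep the variance ordering
major > minor > height unambiguous); with the fibula placed on the distal
major axis (the default) the 3D-T and 3D-TF truths coincide, and the truth
for any fibula placement is obtained from the analytic surface covariance.

All azimuths are transverse angles atan2(z, x) in degrees; torsion truths
follow the package convention torsion = azimuth(distal axis) - azimuth
(proximal axis), wrapped per axis type (360 for directed 3D projections
after the positive-x sign rule, 180 for 2D lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import ValidationError
from .geometry import wrap_angle
from .io import BoneSet, LandmarkSet, SurfaceMesh

ALL_METHODS = ("3D-T", "3D-TF", "jakob", "goutallier")


@dataclass
class PhantomSpec:
    """Construction parameters of the synthetic leg (mm, degrees)."""

    side: str = "right"
    shaft_length: float = 360.0
    plateau_halfwidth: float = 38.0
    plateau_halfdepth: float = 34.0
    condyle_azimuth: float = 0.0
    condyle_spacing: float = 44.0
    condyle_radius: float = 22.0
    posterior_facet_azimuth: float = 0.0
    posterior_facet_cut: float = 26.0  # chord distance from head centre
    distal_major_azimuth: float = 115.0
    distal_semi_axes: tuple[float, float] = (25.0, 18.0)
    fibula_azimuth: float | None = None  # default: on the distal major axis
    fibula_offset: float = 48.0
    fibula_radius: float = 8.0
    malleolus_offset: float = 20.0
    malleolus_radius: float = 7.0
    facet_cut: float = 4.0  # malleolar facet chord distance from centre
    shaft_tilt: float = 0.0  # degrees about x (anterior-posterior shear)
    noise_sd: float = 0.0
    mesh_density: float = 2.5  # target edge length, mm
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.shaft_length < 160.0:
            raise ValidationError("shaft_length must be >= 160 mm")
        a, b = self.distal_semi_axes
        if not (a > b > 0):
            raise ValidationError("distal_semi_axes must be positive with major > minor")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.mesh_density <= 0:
            raise ValidationError("mesh_density must be positive")
        if self.fibula_azimuth is None:
            self.fibula_azimuth = self.distal_major_azimuth - 180.0
        # condylar contact patches must land on the plateau, clear of the
        # posterior facet cut
        patch_reach = self.condyle_spacing / 2.0 + np.sqrt(
            2.0 * self.condyle_radius + 1.0
        )
        rel = np.radians(self.condyle_azimuth - self.posterior_facet_azimuth)
        if patch_reach > min(self.plateau_halfwidth, self.plateau_halfdepth) - 2.0:
            raise ValidationError("condyle_spacing too large for the plateau")
        if (self.condyle_spacing / 2.0) * abs(np.sin(rel)) + np.sqrt(
            2.0 * self.condyle_radius + 1.0
        ) > self.posterior_facet_cut:
            raise ValidationError(
                "condylar contact patches would overhang the posterior facet cut"
            )


@dataclass
class PhantomTruth:
    """Closed-form / analytic ground truth for every estimated axis."""

    pta_azimuth: float
    posterior_tangent_azimuth: float
    dta_azimuth_t: float
    dta_azimuth_tf: float
    distal_line_azimuth: float  # tibia-centre -> fibula-centre (Jakob line)
    anatomical_direction: np.ndarray
    torsion: dict = field(default_factory=dict)  # method -> degrees

    def to_dict(self) -> dict:
        return {
            "pta_azimuth": self.pta_azimuth,
            "posterior_tangent_azimuth": self.posterior_tangent_azimuth,
            "dta_azimuth_t": self.dta_azimuth_t,
            "dta_azimuth_tf": self.dta_azimuth_tf,
            "distal_line_azimuth": self.distal_line_azimuth,
            "anatomical_direction": self.anatomical_direction.tolist(),
            "torsion": dict(self.torsion),
        }


# ---------------------------------------------------------------------------
# cross-section profiles (2D, in the transverse (x, z) plane)


def _unit(azimuth_deg: float) -> np.ndarray:
    a = np.radians(azimuth_deg)
    return np.array([np.cos(a), np.sin(a)])


def _rot2(azimuth_deg: float) -> np.ndarray:
    a = np.radians(azimuth_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _ellipse(t: np.ndarray, a: float, b: float, azimuth: float, center) -> np.ndarray:
    # parameter t is a world angle: evaluating at t - azimuth keeps the same
    # parameter near the same world direction for every section, so lofts
    # between differently rotated sections do not twist
    tl = t - np.radians(azimuth)
    local = np.column_stack([a * np.cos(tl), b * np.sin(tl)])
    return local @ _rot2(azimuth).T + np.asarray(center)


def _faceted_ellipse(
    t: np.ndarray, a: float, b: float, azimuth: float, center, cut: float
) -> np.ndarray:
    """Ellipse with a flat chord facet: local -eta coordinates clamped at
    -cut (the facet faces local azimuth -90, i.e. posterior before the
    section is rotated by ``azimuth``)."""
    tl = t - np.radians(azimuth)
    local = np.column_stack([a * np.cos(tl), np.maximum(b * np.sin(tl), -cut)])
    return local @ _rot2(azimuth).T + np.asarray(center)


def _faceted_circle(
    t: np.ndarray, r: float, facet_azimuth: float, center, cut: float
) -> np.ndarray:
    """Circle with a flat chord facet whose outward normal points along
    ``facet_azimuth``: local +xi coordinates clamped at +cut."""
    tl = t - np.radians(facet_azimuth)
    local = np.column_stack([np.minimum(r * np.cos(tl), cut), r * np.sin(tl)])
    return local @ _rot2(facet_azimuth).T + np.asarray(center)


# ---------------------------------------------------------------------------
# lofting


def _loft(rings: list[np.ndarray], ys: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Closed loft: rings (each (N, 2) in (x, z), same N, same parameter
    order, CCW as produced by the profile functions) at strictly decreasing
    y levels; flat cap fans at both ends. Outward normals by construction."""
    n = rings[0].shape[0]
    verts = []
    for ring, y in zip(rings, ys):
        verts.append(np.column_stack([ring[:, 0], np.full(n, y), ring[:, 1]]))
    verts = np.vstack(verts)
    faces = []
    for k in range(len(rings) - 1):
        base0, base1 = k * n, (k + 1) * n
        for i in range(n):
            j = (i + 1) % n
            a, b = base0 + i, base0 + j
            d, c = base1 + i, base1 + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    top_center = len(verts)
    bottom_center = len(verts) + 1
    centers = np.array(
        [
            [rings[0][:, 0].mean(), ys[0], rings[0][:, 1].mean()],
            [rings[-1][:, 0].mean(), ys[-1], rings[-1][:, 1].mean()],
        ]
    )
    verts = np.vstack([verts, centers])
    last = (len(rings) - 1) * n
    for i in range(n):
        j = (i + 1) % n
        faces.append([top_center, j, i])
        faces.append([bottom_center, last + i, last + j])
    return verts, np.asarray(faces, dtype=np.int64)


def _level_plan(breaks: list[tuple[float, object]], step: float) -> list[tuple[float, object, object, float]]:
    """Expand profile breakpoints into ring levels.

    ``breaks`` maps y (descending) to a profile callable; between two
    breakpoints rings interpolate linearly between the bounding profiles.
    Returns (y, profile_a, profile_b, blend fraction toward b).
    """
    levels = []
    for (y_hi, f_hi), (y_lo, f_lo) in zip(breaks[:-1], breaks[1:]):
        span = y_hi - y_lo
        n_seg = max(1, int(np.ceil(span / step)))
        for i in range(n_seg):
            frac = i / n_seg
            levels.append((y_hi - frac * span, f_hi, f_lo, frac))
    y_end, f_end = breaks[-1]
    levels.append((y_end, f_end, f_end, 0.0))
    return levels


def _build_loft(breaks, step: float, n_ring: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    rings, ys = [], []
    for y, f_hi, f_lo, frac in _level_plan(breaks, step):
        ring = (1.0 - frac) * f_hi(t) + frac * f_lo(t)
        rings.append(ring)
        ys.append(y)
    return _loft(rings, ys)


# ---------------------------------------------------------------------------
# phantom generation


def generate_phantom(spec: PhantomSpec) -> tuple[BoneSet, PhantomTruth]:
    """Build the phantom leg and its analytic ground truth.

    Deterministic given the spec (including its seed): identical specs give
    byte-identical meshes.
    """
    L = spec.shaft_length
    ap, bp = spec.plateau_halfwidth, spec.plateau_halfdepth
    ad, bd = spec.distal_semi_axes
    u_fib = _unit(spec.fibula_azimuth)
    fib_center = spec.fibula_offset * u_fib
    mal_center = -spec.malleolus_offset * u_fib
    tan_tilt = np.tan(np.radians(spec.shaft_tilt))

    def shear(verts: np.ndarray) -> np.ndarray:
        out = verts.copy()
        out[:, 2] += out[:, 1] * tan_tilt
        return out

    step = max(1.5, spec.mesh_density)

    # --- tibia main loft ---------------------------------------------------
    def head(t):
        return _faceted_ellipse(
            t, ap, bp, spec.posterior_facet_azimuth, (0.0, 0.0), spec.posterior_facet_cut
        )

    def head_plain(t):
        return _ellipse(t, ap, bp, spec.posterior_facet_azimuth, (0.0, 0.0))

    def shaft(t):
        return _ellipse(t, 16.0, 16.0, 0.0, (0.0, 0.0))

    def distal(t):
        return _ellipse(t, ad, bd, spec.distal_major_azimuth, (0.0, 0.0))

    n_ring = max(32, int(np.ceil(2.0 * np.pi * max(ap, bp) / spec.mesh_density)))
    tibia_breaks = [
        (0.0, head),
        (-36.0, head),
        (-39.5, head_plain),
        (-58.0, shaft),
        (-L + 26.0, shaft),
        (-L + 12.0, distal),
        (-L, distal),
    ]
    tv, tf = _build_loft(tibia_breaks, step, n_ring)

    # --- medial malleolar prong (second closed component of the tibia) ----
    def prong(t):
        return _faceted_circle(
            t, spec.malleolus_radius, spec.fibula_azimuth, mal_center, spec.facet_cut
        )

    n_small = max(24, int(np.ceil(2.0 * np.pi * 10.0 / spec.mesh_density)))
    pv, pf = _build_loft([(-L - 0.2, prong), (-L - 12.0, prong)], step, n_small)
    tibia_v = np.vstack([tv, pv])
    tibia_f = np.vstack([tf, pf + len(tv)])

    # --- fibula ------------------------------------------------------------
    def fib_head(t):
        return _ellipse(t, 2.0, 2.0, 0.0, fib_center)

    def fib_shaft(t):
        return _ellipse(t, spec.fibula_radius, spec.fibula_radius, 0.0, fib_center)

    def fib_facet(t):
        return _faceted_circle(
            t, spec.fibula_radius, spec.fibula_azimuth + 180.0, fib_center, spec.facet_cut
        )

    fibula_breaks = [
        (-28.0, fib_head),
        (-34.0, fib_shaft),
        (-L - 0.3, fib_shaft),
        (-L - 0.8, fib_facet),
        (-L - 12.0, fib_facet),
    ]
    fv, ff = _build_loft(fibula_breaks, step, n_small)

    # --- femur: two condylar spheres ---------------------------------------
    u_con = _unit(spec.condyle_azimuth)
    gap = 4.0
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=spec.condyle_radius)
    fem_parts = []
    for s in (+1.0, -1.0):
        c = s * (spec.condyle_spacing / 2.0) * u_con
        offset = np.array([c[0], gap + spec.condyle_radius, c[1]])
        fem_parts.append((sphere.vertices + offset, sphere.faces))
    fem_v = np.vstack([p[0] for p in fem_parts])
    fem_f = np.vstack([fem_parts[0][1], fem_parts[1][1] + len(fem_parts[0][0])])

    # --- shear (shaft tilt), landmarks, noise, side ------------------------
    tibia_v, fv, fem_v = shear(tibia_v), shear(fv), shear(fem_v)

    plafond_center = shear(np.array([[0.0, -L, 0.0]]))[0]
    ring8 = np.array(
        [
            [12.0 * np.cos(a), 0.0, 12.0 * np.sin(a)]
            for a in np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
        ]
    )
    distal_points = plafond_center + np.vstack([np.zeros(3), ring8])
    plateau_points = np.array(
        [
            [15.0 * np.cos(a), 0.0, 15.0 * np.sin(a)]
            for a in np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
        ]
    )
    knee_center = np.zeros(3)
    anterior_ref = shear(np.array([[0.0, -15.0, bp + 6.0]]))[0]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        tibia_v = tibia_v + rng.normal(0.0, spec.noise_sd, tibia_v.shape)
        fem_v = fem_v + rng.normal(0.0, spec.noise_sd, fem_v.shape)
        fv = fv + rng.normal(0.0, spec.noise_sd, fv.shape)

    tibia = SurfaceMesh(tibia_v, tibia_f, "tibia")
    femur = SurfaceMesh(fem_v, fem_f, "femur")
    fibula = SurfaceMesh(fv, ff, "fibula")
    landmarks = LandmarkSet(
        distal_articular=distal_points,
        plateau=plateau_points,
        knee_center=knee_center,
        anterior_ref=anterior_ref,
        side="right",
        ankle_center=plafond_center,
    )
    if spec.side == "left":
        tibia = tibia.mirrored_x()
        femur = femur.mirrored_x()
        fibula = fibula.mirrored_x()
        landmarks = landmarks.mirrored_x()
        landmarks.side = "left"
    bones = BoneSet(tibia=tibia, landmarks=landmarks, femur=femur, fibula=fibula)
    return bones, _ground_truth(spec)


# ---------------------------------------------------------------------------
# analytic ground truth


def _axis_azimuth(azimuth: float) -> float:
    """Azimuth of an undirected transverse axis after the positive-x sign
    rule, in (-90, 90]."""
    return wrap_angle(azimuth, 180.0)


def _part_moments_ellipse_band(a, b, azimuth, center, y0, y1, weight_scale=1.0):
    """Mean/covariance/weight of an area-uniform elliptic cylinder band."""
    m = 20000
    t = (np.arange(m) + 0.5) * (2.0 * np.pi / m)
    pts = _ellipse(t, a, b, azimuth, center)
    # arc-length weights (derivative at the shifted parameter, see _ellipse)
    tl = t - np.radians(azimuth)
    d = np.column_stack([-a * np.sin(tl), b * np.cos(tl)]) @ _rot2(azimuth).T
    w = np.linalg.norm(d, axis=1)
    w = w / w.sum()
    mean2 = w @ pts
    dd = pts - mean2
    cov2 = (dd * w[:, None]).T @ dd
    h = y1 - y0
    mean = np.array([mean2[0], (y0 + y1) / 2.0, mean2[1]])
    cov = np.zeros((3, 3))
    cov[np.ix_([0, 2], [0, 2])] = cov2
    cov[1, 1] = h * h / 12.0
    # perimeter of the ellipse (same quadrature)
    perim = np.linalg.norm(np.column_stack([-a * np.sin(t), b * np.cos(t)]), axis=1).sum() * (
        2.0 * np.pi / m
    )
    return perim * h * weight_scale, mean, cov


def _part_moments_ellipse_disk(a, b, azimuth, center, y):
    """Mean/covariance/weight of a flat elliptical disk (area-uniform)."""
    R = _rot2(azimuth)
    cov2 = R @ np.diag([a * a / 4.0, b * b / 4.0]) @ R.T
    mean = np.array([center[0], y, center[1]])
    cov = np.zeros((3, 3))
    cov[np.ix_([0, 2], [0, 2])] = cov2
    return np.pi * a * b, mean, cov


def _combine_parts(parts):
    wsum = sum(w for w, _, _ in parts)
    mean = sum(w * m for w, m, _ in parts) / wsum
    cov = np.zeros((3, 3))
    for w, m, c in parts:
        d = (m - mean)[:, None]
        cov += w * (c + d @ d.T)
    return cov / wsum


def analytic_dta_azimuth(spec: PhantomSpec, include_fibula: bool, component_index: int = 2) -> float:
    """Azimuth of the slab principal component from the analytic surface
    covariance of the distal band (elliptic cylinder + plafond disk,
    optionally + fibular cylinder band), independent of any mesh."""
    ad, bd = spec.distal_semi_axes
    fib_center = spec.fibula_offset * _unit(spec.fibula_azimuth)
    parts = [
        _part_moments_ellipse_band(ad, bd, spec.distal_major_azimuth, (0.0, 0.0), 0.0, 10.0),
        _part_moments_ellipse_disk(ad, bd, spec.distal_major_azimuth, (0.0, 0.0), 0.0),
    ]
    if include_fibula:
        parts.append(
            _part_moments_ellipse_band(
                spec.fibula_radius, spec.fibula_radius, 0.0, fib_center, 0.0, 10.0
            )
        )
    cov = _combine_parts(parts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    v = evecs[:, order[component_index - 1]]
    return _axis_azimuth(float(np.degrees(np.arctan2(v[2], v[0]))))


def _ground_truth(spec: PhantomSpec) -> PhantomTruth:
    pta_az = _axis_azimuth(spec.condyle_azimuth)
    dta_t = analytic_dta_azimuth(spec, include_fibula=False)
    dta_tf = analytic_dta_azimuth(spec, include_fibula=True)
    line_az = _axis_azimuth(spec.fibula_azimuth)
    post_az = _axis_azimuth(spec.posterior_facet_azimuth)
    tan_tilt = np.tan(np.radians(spec.shaft_tilt))
    anat = np.array([0.0, 1.0, tan_tilt])
    anat = anat / np.linalg.norm(anat)
    torsion = {
        "3D-T": wrap_angle(dta_t - pta_az),
        "3D-TF": wrap_angle(dta_tf - pta_az),
        "jakob": wrap_angle(line_az - post_az, 180.0),
        "goutallier": wrap_angle(line_az - post_az, 180.0),
    }
    return PhantomTruth(
        pta_azimuth=pta_az,
        posterior_tangent_azimuth=post_az,
        dta_azimuth_t=dta_t,
        dta_azimuth_tf=dta_tf,
        distal_line_azimuth=line_az,
        anatomical_direction=anat,
        torsion=torsion,
    )


def closed_form_dta_azimuth_t(spec: PhantomSpec, component_index: int = 2) -> float:
    """Closed-form tibia-only DTA azimuth: the distal ellipse minor axis for
    the second component, the major axis for the first."""
    if component_index == 1:
        return _axis_azimuth(spec.distal_major_azimuth)
    return _axis_azimuth(spec.distal_major_azimuth + 90.0)


def torsion_family_spec(true_torsion_deg: float, **overrides) -> PhantomSpec:
    """Spec with 3D construction torsion ``true_torsion_deg``: condylar line
    at azimuth 0, distal minor axis at the requested torsion, fibula on the
    distal major axis (so 3D-T and 3D-TF truths coincide)."""
    tau = float(true_torsion_deg)
    params = dict(
        condyle_azimuth=0.0,
        posterior_facet_azimuth=0.0,
        distal_major_azimuth=tau + 90.0,
        fibula_azimuth=tau - 90.0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def ground_truth_table(
    specs: list[PhantomSpec],
    methods: tuple[str, ...] = ALL_METHODS,
    measure: bool = False,
    seed: int = 0,
    config=None,
):
    """One row per spec x method with the construction truth and, when
    ``measure`` is set, the pipeline's measured angle and the circular
    recovery error (period 360 for 3D methods, 180 for 2D line methods)."""
    import pandas as pd

    from .torsion2d import measure_torsion_2d
    from .torsion3d import measure_torsion_3d

    if not specs:
        raise ValidationError("ground_truth_table needs at least one spec")
    if not methods:
        raise ValidationError("ground_truth_table needs at least one method")
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    rows = []
    for i, spec in enumerate(specs):
        bones, truth = generate_phantom(spec)
        for method in methods:
            row = {
                "phantom": i,
                "side": spec.side,
                "noise_sd": spec.noise_sd,
                "method": method,
                "true_deg": truth.torsion[method],
            }
            if measure:
                if method in ("3D-T", "3D-TF"):
                    res = measure_torsion_3d(bones, method, seed=seed, config=config)
                    period = 360.0
                else:
                    res = measure_torsion_2d(bones, method, seed=seed, config=config)
                    period = 180.0
                row["measured_deg"] = res.angle_deg
                row["error_deg"] = abs(
                    wrap_angle(res.angle_deg - truth.torsion[method], period)
                )
            rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "ALL_METHODS",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "analytic_dta_azimuth",
    "closed_form_dta_azimuth_t",
    "torsion_family_spec",
    "ground_truth_table",
]
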