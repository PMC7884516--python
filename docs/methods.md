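# Methods

This note records the models, conventions, numerical choices and known
limitations of `tibtorsion`, in the order the pipeline runs. Units are
millimetres and degrees throughout.

## Coordinate conventions

All angular quantities reduce to one convention: the **transverse azimuth**
of a direction `v` is `atan2(v_z, v_x)`, the in-plane angle about the
proximal (+y) axis of the reference frame. Torsion is the signed angle from
the projected proximal axis to the projected distal axis about the
*distally pointing* anatomical axis, which equals
`azimuth(DTA) − azimuth(PTA)`; external rotation is positive. Transverse
axes from PCA are sign-ambiguous, so every estimated axis direction is
flipped to positive x-component (falling back to the global PCA sign rule —
positive dot with +x, then +y, then +z — when the x-component vanishes).
Left legs are mirrored (x → −x, with face winding reversed) before
alignment, which makes a left leg and its mirrored right twin numerically
identical inputs; left/right torsion values are therefore directly
comparable, and the mirror-consistency test holds to float precision rather
than statistically.

The reference frame itself is defined by landmarks: the mechanical axis is
operationalised as the knee-centre → ankle-centre line (ankle centre
defaulting to the centroid of the nine distal articular points). Torsion is
a projected angle about the long axis and is insensitive to small changes
in this choice; a landmark definition also keeps the tool independent of
the femoral head, which short knee/ankle CT protocols do not cover. The
frame's rotation, translation and mirror flag are recorded in every result.

## Alignment-independence

Every stage operates in the aligned frame, and all stochastic stages
(surface sampling, k-means) are seeded. Surface sampling is exactly
equivariant under rigid motion (face areas and the random stream are both
invariant), so a rigidly moved input realigns to bit-identical geometry and
the measured angle is invariant to ~1e-13 degrees, not merely within a
statistical tolerance. One subtlety mattered: the distal articular surface
lies exactly on the DTJP (signed distance 0), so the slab filter uses a
1e-6 mm numerical skin — without it, float jitter after realignment
includes a spatially correlated half of the plafond face and rotates the
slab PCA by over a degree.

## Stage parameters

| Parameter | Default | Meaning |
|---|---|---|
| `condyle_band_mm` | 25 | distal femur band fed to k-means |
| `tip_band_mm` | 1 | condylar tip cluster height |
| `min_condyle_separation_mm` | 10 | below this, condyle detection fails |
| `slab_thickness_mm` | 10 | metaphyseal band adjacent to the DTJP |
| `slab_side` | proximal | side of the DTJP the band is taken from |
| `dta_component` | 2 | principal component used as the DTA (1 or 2) |
| `anat_start_mm`, `anat_step_mm`, `anat_n_planes` | 40, 20, 6 | shaft cross-section ladder |
| `sample_count` | 20 000 | whole-bone PCA samples |
| `pta_sample_count` | 150 000 | samples on the distal-femur band |
| `slab_sample_count` | 400 000 | samples on the metaphyseal band |
| `slice_offset_mm` | 1.0 | axial slice offsets of the 2D methods |

The band constants are the method's published values. The two local sample
counts are much larger than the whole-bone count because those PCA
directions rest on modest variance gaps: for an elliptic 25 × 18 mm band
the leading in-plane variances are ≈312 and 162 mm², and the eigenvector
direction error is ≈ √(λ₁λ₂)/((λ₁−λ₂)√n) radians — about 2.4° at n = 20 000
but 0.14° at n = 400 000. Sampling is restricted to the band submeshes
(faces overlapping the band), so the large counts cost ≈2 s per 3D
measurement. PCA runs on area-uniform surface samples, not raw vertices:
vertex density varies with segmentation, and STL-style duplication would
otherwise weight dense patches arbitrarily (meshes are also
duplicate-merged at 1e-6 mm on load, idempotently).

Two robustness choices inside the stages, both inert on clean meshes:

* the condylar tip band is anchored at a 0.5th-percentile floor of the
  cluster's y values rather than the single minimum, so one deep noise
  vertex cannot recentre the tip cluster sideways;
* when a slicing plane meets several cross-section components, the
  largest-area contour is used (the shaft has a single cross-section; the
  rule resolves segmentation debris deterministically).

The DTA uses the **second** principal component of the slab by default.
On an elliptic band the ordering major > minor > height makes this the
ellipse minor axis; the geometric rationale for the second rather than the
first component is not obvious (the first is the major/blob-connecting
axis, which is also what the 2D techniques' inter-malleolar line follows),
so the component index is configurable, always reported in the result, and
a diagnostics warning is raised when an adjacent variance ratio around the
selected component falls below 1.05 — there the selection is unstable under
resampling. Likewise, the slab is taken *proximal* of the DTJP (distal of
the plafond there is little tibial bone) but the side is switchable.

## 2D techniques

The 1.0 mm slice offsets are exact plane offsets in the aligned frame —
they mirror the slice spacing of the CT protocol the techniques were
designed on; slice thickness itself is not simulated. The Goutallier
"talar surface" level is approximated by the DTJP centre level, as no talus
mesh is in scope.

Manual tangent placement is operationalised reproducibly:

* the **posterior tangent** is the convex-hull edge of the tibial-head
  contour whose outward normal is most posterior, considering only edges at
  least a quarter of the longest hull edge — a reader's tangent hugs the
  flat cortex, and without the length rule a short tessellation edge at the
  posterior-most corner wins whenever the cortex facet is rotated;
* a **malleolar articular aspect** is found on an arc-length-resampled,
  ~2 mm-smoothed contour with ~2 mm-stencil edge normals, as the contiguous
  arc facing the inter-malleolar midpoint (outward normal · direction to
  midpoint > 0), trimmed to the span of edges whose normals lie within 45°
  of the centroid-to-midpoint direction. On clean geometry the trim reduces
  the arc to exactly the flat facet; under noise it anchors the arc ends in
  fast-turning-normal zones so they cannot slide along the contour (without
  it, arc-extent jitter moved the tangent centre millimetres along the
  facet and produced 3–5° torsion errors). The tangent is the
  total-least-squares line through the arc, and its "centre" is the arc
  midpoint (by arc length) projected onto it.

Axial axes are lines, defined only up to 180°; the reported 2D torsion is
wrapped to (−90°, 90°].

## The phantom

The generator builds the minimal geometry each stage relies on, with every
defining azimuth a free parameter: a lofted tibia (head ellipse 38 × 34 mm
with a posterior facet, circular shaft r = 16, distal 25 × 18 mm
elliptic-cylinder band over a flat plafond, length 360 mm), a floating
medial-malleolar prong just below the plafond, two condylar spheres
(r = 22, 44 mm apart) hovering 4 mm above the flat plateau, and a fibula
cylinder (r = 8, offset 48 mm) with a flat-capped head apex and a distal
facet. Landmarks are placed by rule (8 + centre on the plafond, 8 on the
plateau circle), so they are exact; Gaussian vertex noise (seeded) is the
only corruption and can be studied separately from landmark error. Loft
profiles are evaluated at world angles so sections with different rotations
blend without twist; meshes are watertight (the tibia as two closed
components) and self-intersection-free at the default 2.5 mm density, and
identical specs produce byte-identical meshes.

Ground truth is defined **relative to the pipeline's axis definitions**,
not to an anatomical "true torsion" — the phantom tests internal
consistency, which is all those definitions support. The tibia-only DTA
truth is the distal minor axis in closed form; the tibia + fibula truth
comes from the analytic surface covariance of the band (elliptic cylinder +
plafond disk + fibular cylinder), and the two routes agree within 0.5°.
With the fibula on the distal major axis (the default, and the anatomical
configuration) the 3D-T and 3D-TF truths coincide. A consequence of the
idealised elliptic band: the second-component DTA is *perpendicular* to
the inter-malleolar line, so the phantom's 2D and 3D truths differ by ~90°
and each method is validated against its own construction truth. Real
distal tibiae are not elliptic cylinders — cohort studies find similar 2D
and 3D means — which is precisely why the component index is kept
switchable.

What the phantom does not emulate: cortical thickness, plateau concavity,
surface curvature texture, segmentation artefacts with spatially correlated
error, or anatomical shape variation. Passing the phantom study shows the
pipeline reproduces its defining geometry under white vertex noise; it does
not certify accuracy on patient anatomy.

## Noise sensitivity

At white vertex noise sd 0.3 mm (the order of a 0.4 mm in-plane CT
resolution) the measured recovery errors across noise realisations are
typically ≤1° for Jakob/Goutallier and 3D-TF and ≤2° for 3D-T, with an
occasional 4–5° outlier for 3D-T. The dominant residual mechanism is the
slab's d = 0 boundary coinciding with the plafond face: noise includes or
excludes cap samples in patches the size of a mesh face, perturbing the
covariance cross-terms against a ~100 mm² eigengap. The 3D-TF variant is
tighter because the fibula widens the eigengap. Seed-to-seed (sampling
only) variation is ≈0.1°.

## Statistics

ICC estimates come from the two-way ANOVA mean squares (MSR subjects, MSC
raters, MSE residual): absolute agreement of single measures
`(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))` and of average measures
`(MSR − MSE)/(MSR + (MSC − MSE)/n)`. Confidence intervals use the McGraw &
Wong (1996) F-based procedure with Satterthwaite degrees of freedom for the
single-measures form and Spearman–Brown-stepped bounds for the average
form — the standard construction behind clinical statistics packages, which
name the model but not the interval. Estimates and intervals match
`pingouin`'s ICC(A,1)/ICC(A,k) to machine precision (cross-checked in the
test suite, where a from-scratch ANOVA with explicit loops is the second,
independent oracle). t-tests and Shapiro–Wilk delegate to scipy; the paired
test additionally reports the mean difference ± sd and range that
method-comparison tables print. Tests are two-sided, α = 0.05; complete
cases are required, with no imputation.

## Problem sizes

The default study sizes are chosen so a full validation runs on one CPU in
minutes: seven phantoms per noise condition for recovery, 20 rigid
transforms for invariance, 100 seeded tables for the ICC oracle, and
150 000 / 400 000 band samples per 3D measurement (≈2 s each). All sizes
are configuration values.

## Known limitations

* Consumes segmented meshes only; DICOM reading and segmentation are out of
  scope, as is femoral torsion or a whole-leg rotational profile.
* The nine + eight landmark points are accepted anywhere on the respective
  surfaces (validated to lie within 5 mm of the tibia; the anterior
  reference within 60 mm); the placement rule is the operator's.
* The Goutallier talar-surface level and the operational definitions of
  "tangent" and "tangent centre" are documented approximations of a human
  reader's judgement, configurable where reasonable.
* Validation is phantom-based; no patient data ships with the package.
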