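# tibtorsion

Measurement of **tibial torsion** — the axial rotation of the distal tibia
relative to the proximal tibia about the bone's long axis — from CT-derived,
segmented bone surface meshes.

Pathological tibial torsion affects lower-limb function and is a target of
corrective osteotomy, but the classic CT measurements are two-dimensional:
angles drawn on single axial slices, sensitive to slice selection and to the
highly variable position of the fibula. `tibtorsion` implements a fully
three-dimensional technique that uses the whole bone surface, alongside the
two standard 2D techniques for comparison, a parametric bone phantom with
analytic ground truth for validation, and the agreement statistics
(intraclass correlation, t-tests, mean absolute differences) used in
reliability studies. It is aimed at musculoskeletal imaging researchers and
3D surgical-planning developers who already have segmented STL/PLY bone
models.

## The measurement

All bones are first aligned in a reference frame: the mechanical axis of the
tibia (knee centre → ankle centre) is mapped onto **+y** (proximal up) and
the leg is rotated about y until the anterior reference landmark faces +z;
left legs are mirrored (x → −x) first so +x is lateral for both sides.

**3D torsion** is the angle between the proximal tibia axis (PTA) and the
distal tibia axis (DTA), projected onto the plane perpendicular to the
anatomical axis â of the tibia:

    torsion = ∠(P⊥ PTA, P⊥ DTA)  about  −â,   P⊥ v = v − (v·â)â

with external rotation positive (right-hand rule about the distally
pointing anatomical axis). The axes are constructed from the surface
geometry:

* **PTA** — k-means (k = 2, k-means++ init) detects the two condyles in the
  most distal 25 mm of the femur; each condylar tip cluster (CTC) is the
  surface within 1 mm of the condyle's most distal point; CTC points are
  mapped to their closest points on the tibial plateau, giving the
  tibiofemoral contact areas (TFCA); the PTA is the first principal
  component of the TFCA.
* **DTA** — a least-squares plane through nine points on the distal
  articular surface defines the distal tibia joint plane (DTJP); the 10 mm
  metaphyseal surface band adjacent to it is extracted and PCA applied; the
  DTA is the second principal component. Two adaptations: tibia only
  (**3D-T**) or with the corresponding fibular band (**3D-TF**).
* **Anatomical axis** — a plane through eight tibial-plateau points (TPP),
  whole-bone PCA for the slicing direction, six cross-section centroids
  every 20 mm starting 40 mm below the TPP centre, and a total-least-squares
  line through them.

**2D torsion** (Jakob and Goutallier techniques) uses a posterior tangent to
the tibial head 1 mm proximal to the fibular head, and distally either the
line through circle centres fitted to the tibia and fibula at the ankle
(Jakob) or the line through the centres of tangents to the two malleolar
articular facets (Goutallier).

## Worked example

`examples/01_measure_phantom_leg.py` builds a synthetic leg whose
construction 3D torsion is 30° and measures it with all four methods:

```
method        measured     truth
3D-T            29.77     30.00
3D-TF           29.89     30.00
jakob          -60.00    -60.00
goutallier     -59.92    -60.00

condyle separation: 44.1 mm
metaphyseal slab:   430407 surface samples
DTJP fit residual:  0.000 mm RMS
```

The 3D methods read back the construction torsion within a third of a
degree. The 2D values are *correct for their own definitions*: on this
phantom the distal ellipse's major axis (which carries the inter-malleolar
line that Jakob and Goutallier measure) is perpendicular to its minor axis
(which the second principal component, i.e. the 3D DTA, follows), so the 2D
ground truth is 90° away from the 3D one — each method is validated against
its own construction truth. The diagnostics lines are the per-stage quality
measures every result carries.

The same measurement from a shell, on files:

```sh
tibtorsion phantom --out leg/ --torsion 30 --seed 7
tibtorsion measure --tibia leg/tibia.stl --femur leg/femur.stl \
    --fibula leg/fibula.stl --landmarks leg/landmarks.json \
    --variant all --seed 1 --out result.json
```

`result.json` contains all four angles, every intermediate axis (point +
direction), the resolved configuration, and SHA-256 checksums of the
inputs. See `examples/` for the parameter-recovery study and the agreement
statistics, and run `tibtorsion --help` for the CLI.

For real data you supply the segmented meshes (STL or PLY, millimetres) and
one landmark JSON per leg with the nine distal articular points, eight
plateau points, knee centre, anterior reference and side (schema in
`tibtorsion.io`).

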