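"""Reading and writing bone meshes, landmark files and result reports.

Units are millimetres everywhere and are never inferred from file headers:
CT segmentation exports are mm by convention and silent rescaling is a
classic failure mode. Meshes are cleaned on load — duplicate vertices merged
at 1e-6 mm, zero-area faces dropped — because STL stores each triangle with
its own vertices, which would triple-weight every point in any PCA.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from ._version import __version__ as _pkg_version
from .errors import FormatError, IOErrorTorsion, ValidationError

MERGE_TOL_MM = 1e-6
BONE_LABELS = ("femur", "tibia", "fibula", "patella")


@dataclass
class SurfaceMesh:
    """Triangulated bone surface in millimetre coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    name: str = "tibia"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if not np.isfinite(self.vertices).all():
            raise ValidationError(f"mesh '{self.name}': non-finite vertex coordinates")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError(f"mesh '{self.name}': vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError(f"mesh '{self.name}': faces must be (m, 3)")
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise ValidationError(
                f"mesh '{self.name}': needs at least 4 vertices and 4 faces"
            )
        if self.faces.max() >= len(self.vertices) or self.faces.min() < 0:
            raise ValidationError(f"mesh '{self.name}': face index out of range")
        self._trimesh: trimesh.Trimesh | None = None

    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @property
    def area(self) -> float:
        return float(self.trimesh.area)

    def bounds_y(self) -> tuple[float, float]:
        y = self.vertices[:, 1]
        return float(y.min()), float(y.max())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        v = self.vertices @ np.asarray(rotation, dtype=float).T + translation
        return SurfaceMesh(v, self.faces.copy(), self.name)

    def mirrored_x(self) -> "SurfaceMesh":
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        # reverse winding so outward normals stay outward
        return SurfaceMesh(v, self.faces[:, ::-1].copy(), self.name)


def clean_mesh(vertices, faces, name: str = "tibia", tol: float = MERGE_TOL_MM) -> SurfaceMesh:
    """Merge duplicate vertices at ``tol`` mm and drop degenerate faces.

    Idempotent: cleaning a cleaned mesh is a no-op.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if not np.isfinite(vertices).all():
        raise ValidationError(f"mesh '{name}': non-finite vertex coordinates")
    key = np.round(vertices / tol).astype(np.int64)
    _, first_idx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[np.sort(first_idx)]
    # remap inverse to the sorted-first-occurrence ordering
    rank = np.empty(len(first_idx), dtype=np.int64)
    rank[np.argsort(first_idx)] = np.arange(len(first_idx))
    remap = rank[inverse]
    new_faces = remap[faces]
    # drop faces with repeated indices or (near) zero area
    distinct = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[distinct]
    if len(new_faces):
        a = new_vertices[new_faces[:, 1]] - new_vertices[new_faces[:, 0]]
        b = new_vertices[new_faces[:, 2]] - new_vertices[new_faces[:, 0]]
        area2 = np.linalg.norm(np.cross(a, b), axis=1)
        new_faces = new_faces[area2 > 1e-14]
    return SurfaceMesh(new_vertices, new_faces, name)


def read_mesh(path, label: str = "tibia") -> SurfaceMesh:
    """Read an STL (binary or ASCII) or PLY surface mesh and clean it."""
    path = Path(path)
    if not path.exists():
        raise IOErrorTorsion(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise FormatError(f"could not read mesh file {path}: {exc}") from exc
    if tm is None or not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise FormatError(f"mesh file {path} contains no faces")
    return clean_mesh(np.asarray(tm.vertices), np.asarray(tm.faces), name=label)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write STL (by .stl suffix, binary) or PLY (ASCII) to disk."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".ply":
            # ASCII PLY with double-precision vertices: the round-trip
            # contract is 1e-6 mm, beyond single precision at bone scale
            header = (
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(mesh.vertices)}\n"
                "property double x\nproperty double y\nproperty double z\n"
                f"element face {len(mesh.faces)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            body = "\n".join(
                f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices
            )
            faces = "\n".join(f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces)
            data = header + body + "\n" + faces + "\n"
        elif path.suffix.lower() == ".stl":
            data = trimesh.exchange.stl.export_stl(mesh.trimesh)
        else:
            raise FormatError(f"unsupported mesh format: {path.suffix}")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    except OSError as exc:
        raise IOErrorTorsion(f"could not write mesh to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Landmarks


@dataclass
class LandmarkSet:
    """The manually selected points the measurement method requires.

    Nine points on the distal articular surface (plafond), eight on the
    tibial plateau, the knee and ankle centres and one anterior reference
    point (patella centroid or tibial tuberosity). The ankle centre defaults
    to the centroid of the nine distal articular points.
    """

    distal_articular: np.ndarray  # (9, 3)
    plateau: np.ndarray  # (8, 3)
    knee_center: np.ndarray
    anterior_ref: np.ndarray
    side: str = "right"
    ankle_center: np.ndarray | None = None

    N_DISTAL = 9
    N_PLATEAU = 8

    def __post_init__(self):
        self.distal_articular = _check_points(
            self.distal_articular, self.N_DISTAL, "distal_articular"
        )
        self.plateau = _check_points(self.plateau, self.N_PLATEAU, "plateau")
        self.knee_center = _check_points(self.knee_center, 1, "knee_center")[0]
        self.anterior_ref = _check_points(self.anterior_ref, 1, "anterior_ref")[0]
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.ankle_center is None:
            self.ankle_center = self.distal_articular.mean(axis=0)
        else:
            self.ankle_center = _check_points(self.ankle_center, 1, "ankle_center")[0]

    def transformed(self, rotation, translation) -> "LandmarkSet":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)

        def tf(p):
            return np.atleast_2d(p) @ R.T + t

        return LandmarkSet(
            distal_articular=tf(self.distal_articular),
            plateau=tf(self.plateau),
            knee_center=tf(self.knee_center)[0],
            anterior_ref=tf(self.anterior_ref)[0],
            side=self.side,
            ankle_center=tf(self.ankle_center)[0],
        )

    def mirrored_x(self) -> "LandmarkSet":
        def mir(p):
            q = np.array(p, dtype=float, copy=True)
            q[..., 0] *= -1.0
            return q

        return LandmarkSet(
            distal_articular=mir(self.distal_articular),
            plateau=mir(self.plateau),
            knee_center=mir(self.knee_center),
            anterior_ref=mir(self.anterior_ref),
            side=self.side,
            ankle_center=mir(self.ankle_center),
        )

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "distal_articular": self.distal_articular.tolist(),
            "plateau": self.plateau.tolist(),
            "knee_center": self.knee_center.tolist(),
            "ankle_center": self.ankle_center.tolist(),
            "anterior_ref": self.anterior_ref.tolist(),
        }


def _check_points(value, n: int, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(value, dtype=float))
    if arr.shape != (n, 3):
        raise ValidationError(
            f"landmark field '{name}': expected {n} point(s) of 3 coordinates, "
            f"got shape {arr.shape}"
        )
    if not np.isfinite(arr).all():
        raise ValidationError(f"landmark field '{name}': non-finite coordinates")
    return arr


def read_landmarks(path) -> LandmarkSet:
    """Read the single-JSON-document landmark schema (one file per leg)."""
    path = Path(path)
    if not path.exists():
        raise IOErrorTorsion(f"landmark file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"landmark file {path} is not valid JSON: {exc}") from exc
    for key in ("side", "distal_articular", "plateau", "knee_center", "anterior_ref"):
        if key not in doc:
            raise ValidationError(f"landmark file {path}: missing field '{key}'")
    return LandmarkSet(
        distal_articular=doc["distal_articular"],
        plateau=doc["plateau"],
        knee_center=doc["knee_center"],
        anterior_ref=doc["anterior_ref"],
        side=doc["side"],
        ankle_center=doc.get("ankle_center"),
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# Bone set


@dataclass
class BoneSet:
    """One leg's meshes plus landmarks, in a common coordinate frame."""

    tibia: SurfaceMesh
    landmarks: LandmarkSet
    femur: SurfaceMesh | None = None
    fibula: SurfaceMesh | None = None

    def require(self, bone: str, context: str) -> SurfaceMesh:
        mesh = getattr(self, bone, None)
        if mesh is None:
            raise ValidationError(f"{context} requires a {bone} mesh, none given")
        return mesh

    def transformed(self, rotation, translation) -> "BoneSet":
        """Apply one rigid transform to every mesh and landmark."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return BoneSet(
            tibia=self.tibia.transformed(R, t),
            landmarks=self.landmarks.transformed(R, t),
            femur=self.femur.transformed(R, t) if self.femur else None,
            fibula=self.fibula.transformed(R, t) if self.fibula else None,
        )


# ---------------------------------------------------------------------------
# Result reports


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_result(result, path, *, input_checksums: dict | None = None, config=None) -> None:
    """JSON report for a TorsionResult (or a list of them); CSV for tables."""
    import pandas as pd

    path = Path(path)
    if isinstance(result, pd.DataFrame):
        try:
            result.to_csv(path, index=False)
        except OSError as exc:
            raise IOErrorTorsion(f"could not write table to {path}: {exc}") from exc
        return
    results = result if isinstance(result, (list, tuple)) else [result]
    doc = {
        "software": {"name": "tibtorsion", "version": _pkg_version},
        "units": "mm, degrees",
        "sign_convention": (
            "external torsion positive; right-hand rule about the distally "
            "pointing anatomical axis with +x lateral, +y proximal; left "
            "sides mirrored (x -> -x) before alignment"
        ),
        "input_checksums": input_checksums or {},
        "config": config.to_dict() if config is not None else None,
        "results": [r.to_dict() for r in results],
    }
    try:
        path.write_text(json.dumps(doc, indent=1))
    except OSError as exc:
        raise IOErrorTorsion(f"could not write report to {path}: {exc}") from exc


def read_result(path) -> dict:
    return json.loads(Path(path).read_text())
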