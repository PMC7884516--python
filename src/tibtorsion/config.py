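"""Run configuration: every tunable constant of the measurement pipeline.

Defaults are the method's published constants (condyle band 25 mm, condylar
tip band 1 mm, metaphyseal slab 10 mm, six shaft planes every 20 mm starting
40 mm below the plateau plane centre, 1.0 mm axial slice offsets for the 2D
methods). All lengths in mm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    # proximal tibia axis (PTA)
    condyle_band_mm: float = 25.0  # distal femur band fed to k-means
    tip_band_mm: float = 1.0  # condylar tip cluster height
    min_condyle_separation_mm: float = 10.0
    # distal tibia axis (DTA)
    slab_thickness_mm: float = 10.0
    slab_side: str = "proximal"  # 'proximal' or 'distal' of the DTJP
    dta_component: int = 2  # 1-based principal-component index
    dta_ambiguity_ratio: float = 1.05
    min_slab_points: int = 100
    # anatomical axis
    anat_start_mm: float = 40.0
    anat_step_mm: float = 20.0
    anat_n_planes: int = 6
    # sampling: whole-bone PCA vs the two local PCA stages. The local stages
    # use far more points because their principal-axis directions are set by
    # modest variance gaps (condyle caps; elliptic slab, variance ratio ~2)
    # and the direction's sampling error scales as 1/sqrt(n).
    sample_count: int = 20000
    pta_sample_count: int = 150000
    slab_sample_count: int = 400000
    seed: int = 0
    # 2D methods
    slice_offset_mm: float = 1.0

    def __post_init__(self):
        positive = (
            "condyle_band_mm",
            "tip_band_mm",
            "min_condyle_separation_mm",
            "slab_thickness_mm",
            "anat_start_mm",
            "anat_step_mm",
            "slice_offset_mm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be positive")
        if self.slab_side not in ("proximal", "distal"):
            raise ValidationError("config: slab_side must be 'proximal' or 'distal'")
        if self.dta_component not in (1, 2):
            raise ValidationError("config: dta_component must be 1 or 2")
        if self.anat_n_planes < 2:
            raise ValidationError("config: anat_n_planes must be >= 2")
        for name in ("sample_count", "pta_sample_count", "slab_sample_count"):
            if getattr(self, name) < 100:
                raise ValidationError(f"config: {name} must be >= 100")

    def anat_offsets(self) -> list[float]:
        return [
            self.anat_start_mm + i * self.anat_step_mm for i in range(self.anat_n_planes)
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load overrides from a TOML or YAML file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            doc = yaml.safe_load(text) or {}
        else:
            import tomllib

            doc = tomllib.loads(text)
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"config file {path}: unknown keys {sorted(unknown)}")
        return cls(**doc)
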