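"""Pipeline configuration: one validated YAML/JSON document, hashed.

All defaults of the whole pipeline live here.  The config hash covers every
semantic field (sorted-key JSON of the model dump), so two runs share a hash
exactly when they are configured identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError  # noqa: F401


class GeometryConfig(BaseModel):
    n_residues: int = 8
    n_unimers: int = 8
    radius: float = 4.0          # angstrom
    amide_offset: float = 0.6    # angstrom
    spacing: float = 4.85        # angstrom
    antiparallel: bool = True
    registry_rotation: float | None = None  # degrees; None -> 360/n_residues


class UnbindingConfig(BaseModel):
    enabled: bool = False
    event_frame: int = 500
    displacement: float = 10.0   # angstrom
    tilt: float = 15.0           # degrees


class TrajectoryConfig(BaseModel):
    n_frames: int = 1000
    frame_dt: float = 0.1        # ns
    sigma: float = 0.2           # angstrom thermal jitter
    seed: int = 0
    unbinding: UnbindingConfig = UnbindingConfig()


class KineticsConfig(BaseModel):
    n_cap_bonds: int = 16
    n_core_bonds: int = 40
    k_break_cap: float = 0.05    # ns^-1
    k_break_core: float = 0.005  # ns^-1
    k_reform: float = 5.0        # ns^-1
    frame_dt: float = 0.1        # ns
    n_frames: int = 10000
    seed: int = 1


class CriteriaConfig(BaseModel):
    d_max: float = 3.5           # angstrom N...O
    theta_min: float = 120.0     # degrees N-H...O


class MetricsConfig(BaseModel):
    flicker_window: int = 0      # frames
    drop_threshold: float = 6.0  # bonds
    persistence: int = 50        # frames
    median_window: int = 11      # frames
    spacing_nm: float = 0.485    # stacking period for length conversion


class SANSParamsConfig(BaseModel):
    r_core: float = 10.0
    t_shell: float = 40.0
    length: float = 1000.0
    sld_core: float = 2.0
    sld_shell: float = 0.8
    sld_solvent: float = 6.36
    scale: float = 1.0
    background: float = 0.001


class SANSConfig(BaseModel):
    params: SANSParamsConfig = SANSParamsConfig()
    rel_noise: float = 0.05
    q_min: float = 3e-3
    q_max: float = 0.5
    n_q: int = 100
    seed: int = 2
    fit_free: list[str] = Field(
        default_factory=lambda: ["r_core", "t_shell", "scale", "background"])
    init_perturbation: float = 1.5


class PipelineConfig(BaseModel):
    geometry: GeometryConfig = GeometryConfig()
    trajectory: TrajectoryConfig = TrajectoryConfig()
    kinetics: KineticsConfig = KineticsConfig()
    criteria: CriteriaConfig = CriteriaConfig()
    metrics: MetricsConfig = MetricsConfig()
    sans: SANSConfig = SANSConfig()
    output_dir: str = "cptube_run"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML (or JSON) config; defaults when path is None."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
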