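"""Run configuration: a single declarative YAML file, validated before any stage runs.

Unknown keys are rejected so typos fail fast rather than silently running
defaults.  Each enabled stage is a sub-model; a stage is run when its section
is present.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pydantic
import yaml

from .errors import ConfigError


class _StrictModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class SurfaceStage(_StrictModel):
    structure: str
    model_index: int = 0
    chains_a: list[str] = ["A"]
    chains_b: list[str] = ["B"]
    probe_radius: float = 1.4
    n_points: int = 960
    interface_cutoff: float = 0.1
    salt_bridge_cutoff: float = 4.0


class EnsembleStage(_StrictModel):
    structure: str
    ordered_region: list[tuple[int, int]] | None = None  # native numbering
    chains: list[str] | None = None


class GeometryStage(_StrictModel):
    structure: str
    model_index: int = 0
    chain: str = "A"


class CSPStage(_StrictModel):
    free: str
    bound: str
    threshold: float = 0.05
    nitrogen_weight: float = 0.14
    formula_variant: str = "weight_squared_with_shift"
    structure: str | None = None  # enables mapping onto coordinates
    region: tuple[int, int] | None = None  # native numbering


class FitStage(_StrictModel):
    titration: str | None = None
    binding_model: str = "hyperbolic"
    tracer_conc_um: float = 0.010
    melt: str | None = None
    urea: str | None = None


class ConservationStage(_StrictModel):
    alignment: str
    reference_id: str
    threshold: float = 0.80
    reference_start: int = 1


class RunConfig(_StrictModel):
    """Validated pipeline configuration."""

    seed: int = 0
    output_dir: str = "protodimer_out"
    numbering_offset: int = 0
    surface: SurfaceStage | None = None
    ensemble: EnsembleStage | None = None
    geometry: GeometryStage | None = None
    csp: CSPStage | None = None
    fit: FitStage | None = None
    conservation: ConservationStage | None = None

    def enabled_stages(self) -> list[str]:
        return [
            name
            for name in ("surface", "ensemble", "geometry", "csp", "fit", "conservation")
            if getattr(self, name) is not None
        ]

    def input_paths(self) -> list[Path]:
        paths = []
        for stage in (self.surface, self.ensemble, self.geometry, self.csp,
                      self.fit, self.conservation):
            if stage is None:
                continue
            for field in ("structure", "free", "bound", "titration", "melt", "urea", "alignment"):
                val = getattr(stage, field, None)
                if val:
                    paths.append(Path(val))
        return paths


def load_config(path: str | Path) -> RunConfig:
    """Load + validate a YAML config; every referenced input file must exist."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path.name}: invalid YAML: {exc}") from exc
    try:
        config = RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ConfigError(f"{path.name}: {exc}") from exc
    if not config.enabled_stages():
        raise ConfigError(f"{path.name}: no stage enabled")
    missing = [str(p) for p in config.input_paths() if not p.exists()]
    if missing:
        raise ConfigError(f"{path.name}: input file(s) not found: {missing}")
    return config


def config_hash(config: RunConfig) -> str:
    """Stable hash of the resolved configuration (for provenance)."""
    blob = config.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:16]
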