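"""Validated run configuration for every pipeline stage.

Configs are YAML (or JSON — YAML is a superset) mappings with a ``stage``
selector, a ``seed``, an output directory and per-stage parameters.  Unknown
keys are rejected so typos fail loudly, and configs round-trip losslessly
through ``RunConfig.to_dict`` / ``load_config``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "SurfaceParams",
    "CurveParams",
    "KineticsParams",
    "ImmobileParams",
    "RunConfig",
    "ConfigError",
    "load_config",
]


class ConfigError(ValueError):
    """Raised for missing files or schema violations, naming offending keys."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SpecParams(_Strict):
    name: str
    span_nm: float = Field(ge=0)
    lever_length_nm: float = Field(default=32.0, ge=0)
    her2_length_nm: float = Field(default=8.0, ge=0)
    her2_terms: int = Field(default=2, ge=0)


class SurfaceParams(_Strict):
    side_nm: float = Field(default=2400.0, gt=0)
    in_radius_nm: float = Field(default=2.5, gt=0)
    mean_distance_nm: float = Field(default=100.0, gt=0)


class CurveParams(_Strict):
    specs: list[str] = ["441", "841", "mAb_combo"]
    custom_specs: list[SpecParams] = []
    distances_nm: list[float] = [50.0, 100.0, 200.0]
    n_surfaces: int = Field(default=10, ge=1)
    n_repeats: int = Field(default=10, ge=1)
    side_nm: Optional[float] = Field(default=None, gt=0)
    in_radius_nm: float = Field(default=2.5, gt=0)


class KineticsParams(_Strict):
    k_on: float = Field(default=1e5, gt=0)
    k_off: float = Field(default=1e-3, ge=0)
    concentration_M: float = Field(default=20e-9, gt=0)
    t_assoc_s: float = Field(default=300.0, gt=0)
    t_diss_s: float = Field(default=3600.0, gt=0)
    n_points: int = Field(default=300, ge=2)
    noise_sd: float = Field(default=0.01, ge=0)
    phases: Literal["auto", "1", "2"] = "auto"
    with_offset: bool = False


class ImmobileParams(_Strict):
    n_mobile: int = Field(default=80, ge=0)
    n_immobile: int = Field(default=120, ge=0)
    D_um2_s: float = Field(default=0.1, ge=0)
    dt_s: float = Field(default=0.03, gt=0)
    n_frames: int = Field(default=100, ge=1)
    precision_nm: float = Field(default=20.0, gt=0)
    field_nm: tuple[float, float] = (20_000.0, 20_000.0)
    eps_nm: Optional[float] = Field(default=None, gt=0)
    min_samples: int = Field(default=10, ge=1)
    min_frame_span: int = Field(default=10, ge=1)


class RunConfig(_Strict):
    """Top-level run configuration; defaults fill every omitted stage block."""

    stage: Literal["surface", "curve", "kinetics", "immobile"]
    seed: int = 0
    out_dir: str = "results"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"
    surface: SurfaceParams = SurfaceParams()
    curve: CurveParams = CurveParams()
    kinetics: KineticsParams = KineticsParams()
    immobile: ImmobileParams = ImmobileParams()

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config.

    Raises :class:`ConfigError` when the file is missing or the schema is
    violated; the message lists the offending keys.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid config ({fields}): {exc}") from exc
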