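"""Validated parameter models for every pipeline stage.

All tunables live here so that a run is fully described by one
:class:`PipelineConfig`, which round-trips losslessly through YAML and is
hashed into the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigError


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=False, extra="forbid")


class SynthParams(_Frozen):
    """Parameters of the synthetic fluorescence-scene generator.

    Defaults emulate the live-cell mislocalization assay this package
    quantifies: 512x512 EMCCD fields, 15 fields per condition with 3-4
    cells each (~50 cells/condition), a perinuclear Golgi arc, a spread-out
    mitochondrial filament network, lognormal marker expression with an
    untransfected subpopulation, a smooth background plane, Poisson shot
    noise and Gaussian read noise.

    ``misloc_fraction`` (theta) is the single generative knob for
    mislocalization: the fraction of each cell's reporter photon mass placed
    on the mitochondrial mask, the remainder going to the Golgi mask.
    """

    image_height: int = Field(512, ge=64)
    image_width: int = Field(512, ge=64)
    n_fields: int = Field(15, ge=0)
    cells_per_field: Tuple[int, int] = (3, 4)

    nucleus_radius_range: Tuple[float, float] = (9.0, 14.0)
    cell_radius_range: Tuple[float, float] = (34.0, 46.0)

    mito_filament_count: int = Field(7, gt=0)
    mito_filament_length: int = Field(70, gt=0)
    mito_filament_width: int = Field(3, gt=0)

    golgi_span_degrees: float = Field(120.0, gt=0, le=360)
    golgi_thickness_px: float = Field(7.0, gt=0)
    golgi_offset_px: float = Field(4.0, ge=0)

    misloc_fraction: float = Field(0.3, ge=0.0, le=1.0)
    #: Optional (low, high) theta range; when set, each transfected cell's
    #: theta follows its expression level monotonically within this range.
    theta_coupling: Optional[Tuple[float, float]] = None

    transfected_prob: float = Field(0.75, ge=0.0, le=1.0)
    marker_lognormal_mu: float = 5.7
    marker_lognormal_sigma: float = Field(0.6, gt=0)

    nuclei_intensity: float = Field(400.0, gt=0)
    mito_intensity: float = Field(500.0, gt=0)
    reporter_mass: float = Field(2.5e5, gt=0)

    #: Background plane per channel: offset + bx*(x/W) + by*(y/H).
    background_plane_coeffs: Tuple[float, float, float] = (30.0, 8.0, 5.0)
    read_noise_sd: float = Field(3.0, ge=0)
    shot_noise: bool = True
    n_z: int = Field(1, ge=1)

    seed: int = 0

    @field_validator("nucleus_radius_range", "cell_radius_range")
    @classmethod
    def _radii_positive_ordered(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        lo, hi = v
        if lo <= 0 or hi <= 0:
            raise ValueError("radii must be strictly positive")
        if lo > hi:
            raise ValueError("radius range must satisfy low <= high")
        return v

    @field_validator("cells_per_field")
    @classmethod
    def _cells_range(cls, v: Tuple[int, int]) -> Tuple[int, int]:
        lo, hi = v
        if lo < 0 or lo > hi:
            raise ValueError("cells_per_field must satisfy 0 <= low <= high")
        return v

    @field_validator("theta_coupling")
    @classmethod
    def _coupling_range(cls, v):
        if v is None:
            return v
        lo, hi = v
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("theta_coupling must satisfy 0 <= low <= high <= 1")
        return v

    @model_validator(mode="after")
    def _nucleus_fits_cell(self) -> "SynthParams":
        if self.nucleus_radius_range[1] + 4 >= self.cell_radius_range[0]:
            raise ValueError(
                "largest nucleus must fit inside the smallest cell with margin"
            )
        return self


class PreprocessParams(_Frozen):
    """Projection and background-correction options."""

    background_method: Literal["opening", "polynomial"] = "opening"
    background_radius_px: int = Field(50, gt=0)
    background_poly_order: int = Field(2, ge=0, le=3)


class SegmentationParams(_Frozen):
    """Nucleus detection, cell propagation, gating and pseudo-cell options."""

    nucleus_threshold: Union[Literal["otsu"], float] = "otsu"
    nucleus_min_area: int = Field(120, gt=0)
    nucleus_max_area: int = Field(6000, gt=0)
    declump: bool = False
    declump_min_distance: int = Field(10, gt=0)

    guidance_channel: str = "mito"
    guidance_smooth_sigma: float = Field(8.0, ge=0)
    guidance_threshold: Union[Literal["otsu"], float] = "otsu"
    guidance_threshold_scale: float = Field(0.5, gt=0)
    propagation_lambda: float = Field(0.05, ge=0)

    mito_threshold: Union[Literal["otsu"], float] = "otsu"
    closing_radius_px: int = Field(10, gt=0)
    nucleus_dilation_px: int = Field(0, ge=0)

    #: The transfection gate on integrated marker intensity. Deliberately has
    #: no default: it mirrors a manually chosen threshold and must be set
    #: explicitly (see segment.suggest_marker_threshold for a helper).
    marker_gate_threshold: Optional[float] = None

    @field_validator("nucleus_threshold", "guidance_threshold", "mito_threshold")
    @classmethod
    def _threshold_nonneg(cls, v):
        if isinstance(v, (int, float)) and v < 0:
            raise ValueError("fixed thresholds must be >= 0")
        return v

    @field_validator("marker_gate_threshold")
    @classmethod
    def _gate_nonneg(cls, v):
        if v is not None and v < 0:
            raise ValueError("marker_gate_threshold must be >= 0")
        return v


class ColocParams(_Frozen):
    """Per-cell colocalization options."""

    min_pixels: int = Field(50, gt=1)


class StatsParams(_Frozen):
    """Condition-level statistics options."""

    expression_corr_method: Literal["spearman", "pearson"] = "spearman"
    exact_max_total: int = Field(16, gt=1)


class ConditionSpec(_Frozen):
    """One experimental condition: either simulated or loaded from files.

    Exactly one of ``synth`` and ``fields`` must be given. ``fields`` is a
    list of per-field channel-role -> TIFF-path mappings (or a single path
    per field when the file is multi-channel).
    """

    name: str
    synth: Optional[SynthParams] = None
    fields: Optional[List[Dict[str, str]]] = None

    @model_validator(mode="after")
    def _one_source(self) -> "ConditionSpec":
        if (self.synth is None) == (self.fields is None):
            raise ValueError(
                f"condition {self.name!r}: give exactly one of 'synth' or 'fields'"
            )
        return self


class PipelineConfig(_Frozen):
    """Complete description of an end-to-end run."""

    conditions: List[ConditionSpec]
    preprocess: PreprocessParams = PreprocessParams()
    segmentation: SegmentationParams = SegmentationParams()
    colocalization: ColocParams = ColocParams()
    statistics: StatsParams = StatsParams()
    output_dir: str = "mitoloc_out"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _nonempty(self) -> "PipelineConfig":
        if not self.conditions:
            raise ValueError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        return self


def config_hash(config: BaseModel) -> str:
    """Stable SHA-256 over the canonical JSON form of any config model."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def save_config(config: BaseModel, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )


def load_config(path, model=PipelineConfig):
    try:
        data = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    return model.model_validate(data)
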