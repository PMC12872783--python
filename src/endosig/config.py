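"""Run configuration: validated, default-filled, persisted with every run.

A run is described by one YAML file whose top level selects the stage
(``simulate``, ``imaging``, ``silac`` or ``stats``) and provides the matching
section.  Unknown keys are rejected, every numeric parameter is range-checked
before any I/O happens, and the fully resolved configuration (defaults
filled in) is written alongside the outputs for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneConfig(_Strict):
    """Synthetic-scene parameters (see :class:`endosig.synth.SceneSpec`)."""

    n_cells: int = Field(20, ge=0)
    field_height: int = Field(1024, ge=16)
    field_width: int = Field(1024, ge=16)
    pixel_size: float = Field(0.65, gt=0)
    nucleus_area_mean: float = Field(1661.078, gt=0)  # um^2, wild-type-like
    nucleus_area_sd: float = Field(416.71, ge=0)
    nc_ratio_mean: float = Field(2.0, gt=0)
    nc_ratio_sd: float = Field(0.2, ge=0)
    background_level: float = Field(50.0, ge=0)
    marker_cyto_level: float = Field(100.0, ge=0)
    dapi_level: float = Field(400.0, ge=0)
    cyto_width: float = Field(8.0, ge=1)
    noise: Literal["none", "gaussian", "poisson"] = "none"
    noise_sigma: float = Field(0.0, ge=0)
    crowded: bool = False
    n_fields: int = Field(1, ge=1)
    group: str = "group1"

    def to_spec(self, seed: int):
        from .synth import SceneSpec

        return SceneSpec(
            n_cells=self.n_cells,
            field_size=(self.field_height, self.field_width),
            pixel_size=self.pixel_size,
            nucleus_area_um2=(self.nucleus_area_mean, self.nucleus_area_sd),
            nc_ratio=(self.nc_ratio_mean, self.nc_ratio_sd),
            background_level=self.background_level,
            marker_cyto_level=self.marker_cyto_level,
            dapi_level=self.dapi_level,
            cyto_width=self.cyto_width,
            noise=self.noise,
            noise_sigma=self.noise_sigma,
            crowded=self.crowded,
            seed=seed,
        )


class TableConfig(_Strict):
    """Synthetic SILAC table parameters (see :class:`endosig.synth.TableSpec`)."""

    n_sites: int = Field(5000, ge=0)
    fraction_shifted: float = Field(0.05, ge=0, le=1)
    shift_magnitude: float = Field(0.9, ge=0)
    ratio_noise_sd: float = Field(0.3, ge=0)
    missing_rate: float = Field(0.1, ge=0, le=1)
    n_decoy_reverse: int = Field(25, ge=0)
    n_contaminants: int = Field(25, ge=0)
    n_low_peptide: int = Field(50, ge=0)

    def to_spec(self, seed: int):
        from .synth import TableSpec

        return TableSpec(seed=seed, **self.model_dump())


class SimulateConfig(_Strict):
    scenes: list[SceneConfig] = Field(default_factory=lambda: [SceneConfig()])
    table: Optional[TableConfig] = Field(default_factory=TableConfig)


class SegmentationConfig(_Strict):
    median_radius: int = Field(2, ge=1)
    min_area_px: Optional[float] = Field(None, gt=0)
    max_area_px: Optional[float] = Field(None, gt=0)
    exclude_border: bool = True

    @model_validator(mode="after")
    def _ordered(self):
        if (self.min_area_px is not None and self.max_area_px is not None
                and self.max_area_px < self.min_area_px):
            raise ValueError("max_area_px must be >= min_area_px")
        return self


class RingConfig(_Strict):
    gap: float = Field(1.0, ge=0)
    ring_width: float = Field(4.0, ge=1)
    contested: Literal["exclude", "nearest"] = "exclude"


class QCConfig(_Strict):
    min_area_px: float = Field(0.0, ge=0)
    max_area_px: float = Field(1e9, gt=0)
    min_ring_pixels: int = Field(10, ge=0)
    min_solidity: float = Field(0.90, ge=0, le=1)


class FieldInput(_Strict):
    dapi: str
    marker: str
    group: str
    experiment: Optional[str] = None
    channel_dapi: Optional[int] = None  # for multi-channel TIFF inputs
    channel_marker: Optional[int] = None


class ImagingConfig(_Strict):
    fields: list[FieldInput]
    pixel_size: Optional[float] = Field(None, gt=0)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    ring: RingConfig = Field(default_factory=RingConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    mode_bin_width: Optional[float] = Field(None, gt=0)
    stats_unit: Literal["cell", "experiment"] = "cell"
    export_labels: bool = False


class SilacRunConfig(_Strict):
    forward: str
    reverse: str
    mutant_channel_forward: Literal["heavy", "light"]  # required, no default
    min_unique: int = Field(2, ge=0)
    min_loc_prob: float = Field(0.75, ge=0, le=1)
    center: Literal["median", "mean"] = "median"
    n_sd: float = Field(2.0, gt=0)
    impute_constant: float = Field(0.1, ge=0)
    gene_sets: Optional[str] = None  # GMT path for over-representation


class StatsConfig(_Strict):
    cells_csv: str
    value_col: str = "nc_ratio"
    group_col: str = "group"
    unit: Literal["cell", "experiment"] = "cell"
    experiment_col: Optional[str] = None
    welch: bool = False
    plot: bool = False


class RunConfig(_Strict):
    """Top-level run description; exactly the section for ``stage`` is used."""

    stage: Literal["simulate", "imaging", "silac", "stats"]
    seed: int = Field(0, ge=0, lt=2**31)
    outdir: str = "results"
    simulate: Optional[SimulateConfig] = None
    imaging: Optional[ImagingConfig] = None
    silac: Optional[SilacRunConfig] = None
    stats: Optional[StatsConfig] = None

    @model_validator(mode="after")
    def _stage_section_present(self):
        if getattr(self, self.stage) is None:
            raise ValueError(f"stage {self.stage!r} requires a {self.stage!r} section")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.model_validate(raw)

    def write_resolved(self, outdir: str | Path) -> Path:
        """Persist the fully resolved config (defaults filled) for provenance."""
        out = Path(outdir) / "resolved_config.yaml"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                      sort_keys=False))
        return out
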