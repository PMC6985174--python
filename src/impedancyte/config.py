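"""YAML experiment configuration with strict schema validation.

One config drives the whole experiment (simulate -> detect -> features ->
population analysis).  Unknown keys are rejected; numeric keys carry their
units in the name.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .circuit import (
    DEFAULT_FREQUENCIES,
    ChannelGeometry,
    FrequencyPanel,
    MappingParams,
    SystemCircuit,
)
from .detect import DetectionParams
from .errors import SchemaError
from .synth import AcquisitionSpec, LogNormalSpec, PopulationSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CircuitConfig(_Strict):
    r_sol_ohm: float = 7.8e4
    c_sol_farad: float = 5.7e-15
    c_dl_electrode_farad: float = 1.2e-10
    c_dl_cell_farad: float = 1e-9
    gain_v: float = 1.0
    k_geo: float = 1.5
    g_ref_s_per_m2: float = 200.0
    medium_conductivity_s_per_m: float = 1.6
    ion_exchange: bool = True
    channel_width_um: float = 30.0
    channel_height_um: float = 8.0
    electrode_gap_um: float = 30.0

    def system(self) -> SystemCircuit:
        return SystemCircuit(
            r_sol=self.r_sol_ohm,
            c_sol=self.c_sol_farad,
            c_dl_electrode=self.c_dl_electrode_farad,
            gain=self.gain_v,
        )

    def geometry(self) -> ChannelGeometry:
        return ChannelGeometry(
            width_um=self.channel_width_um,
            height_um=self.channel_height_um,
            electrode_gap_um=self.electrode_gap_um,
        )

    def mapping(self) -> MappingParams:
        return MappingParams(
            medium_conductivity=self.medium_conductivity_s_per_m,
            k_geo=self.k_geo,
            g_ref=self.g_ref_s_per_m2,
            c_dl_cell=self.c_dl_cell_farad,
            ion_exchange=self.ion_exchange,
        )


class PanelConfig(_Strict):
    frequencies_hz: list[float] = Field(default_factory=lambda: list(DEFAULT_FREQUENCIES))
    reference_index: int = 0

    def panel(self) -> FrequencyPanel:
        return FrequencyPanel(tuple(self.frequencies_hz), self.reference_index)


class AcquisitionConfig(_Strict):
    sampling_rate_hz: float = 57600.0
    duration_s: float | None = None
    event_rate_hz: float = 10.0
    transit_time_s: float = 1e-3
    noise_sigma_rel: float = 3.4e-4
    drift_amplitude_rel: float = 2e-3
    drift_period_s: float = 7.3
    baseline_volts: float | list[float] = 1.0
    min_separation_factor: float = 3.0

    def acquisition(self) -> AcquisitionSpec:
        b = self.baseline_volts
        return AcquisitionSpec(
            sampling_rate=self.sampling_rate_hz,
            duration=self.duration_s,
            event_rate=self.event_rate_hz,
            transit_time=self.transit_time_s,
            noise_sigma=self.noise_sigma_rel,
            drift_amplitude=self.drift_amplitude_rel,
            drift_period=self.drift_period_s,
            baseline_volts=tuple(b) if isinstance(b, list) else b,
            min_separation_factor=self.min_separation_factor,
        )


class LogNormalConfig(_Strict):
    median: float
    sigma: float = 0.0

    def dist(self) -> LogNormalSpec:
        return LogNormalSpec(self.median, self.sigma)


class PopulationConfig(_Strict):
    group: str
    n_cells: int
    diameter_um: LogNormalConfig = LogNormalConfig(median=4.6, sigma=0.04)
    g_mem_s_per_m2: LogNormalConfig = LogNormalConfig(median=5.0, sigma=0.25)
    sigma_cyto_s_per_m: LogNormalConfig = LogNormalConfig(median=0.6, sigma=0.08)
    c_mem_spec_f_per_m2: float = 0.01
    eps_cyto: float = 60.0
    outlier_fraction: float = 0.0
    outlier_shift_diameter: float = 1.3
    outlier_shift_g_mem: float = 10.0
    bead: bool = False

    def spec(self) -> PopulationSpec:
        if self.bead:
            return PopulationSpec(
                n_cells=self.n_cells,
                group=self.group,
                diameter_um=self.diameter_um.dist(),
                g_mem=LogNormalSpec(1e-6),
                sigma_cyto=LogNormalSpec(1e-6),
                c_mem_spec=1e-6,
                eps_cyto=2.6,
            )
        return PopulationSpec(
            n_cells=self.n_cells,
            group=self.group,
            diameter_um=self.diameter_um.dist(),
            g_mem=self.g_mem_s_per_m2.dist(),
            sigma_cyto=self.sigma_cyto_s_per_m.dist(),
            c_mem_spec=self.c_mem_spec_f_per_m2,
            eps_cyto=self.eps_cyto,
            outlier_fraction=self.outlier_fraction,
            outlier_shift=(self.outlier_shift_diameter, self.outlier_shift_g_mem),
        )


class DetectionConfig(_Strict):
    baseline_window_samples: int = 201
    k_mad: float = 5.0
    max_baseline_shift_rel: float = 0.02
    saturation_volts: float | None = None

    def params(self, sampling_rate: float, transit_time: float) -> DetectionParams:
        return DetectionParams.from_acquisition(
            sampling_rate,
            transit_time,
            baseline_window_samples=self.baseline_window_samples,
            k_mad=self.k_mad,
            max_baseline_shift_rel=self.max_baseline_shift_rel,
            saturation_volts=self.saturation_volts,
        )


class FeatureConfig(_Strict):
    transparency_freqs_hz: list[float] = Field(default_factory=lambda: [5e6, 2e7])
    calibrate_size: bool = True
    calibration_fraction: float = 0.2


class AnalysisConfig(_Strict):
    transparency_freq_hz: float = 2e7
    n_size_bins: int = 10
    outlier_size_quantile: float = 0.90
    outlier_permeability_quantile: float = 0.10
    compare_feature: str | None = None
    make_figures: bool = False


class ExperimentConfig(_Strict):
    """Top-level experiment description (one YAML file)."""

    seed: int = 0
    output_dir: str = "results/run"
    circuit: CircuitConfig = CircuitConfig()
    panel: PanelConfig = PanelConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    populations: list[PopulationConfig] = Field(default_factory=list)
    detection: DetectionConfig = DetectionConfig()
    feature: FeatureConfig = FeatureConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @field_validator("populations")
    @classmethod
    def _unique_groups(cls, v: list[PopulationConfig]):
        names = [p.group for p in v]
        if len(set(names)) != len(names):
            raise ValueError("population group labels must be unique")
        return v


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and schema-validate a YAML experiment config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - malformed files
        raise SchemaError(f"cannot parse YAML config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    try:
        return ExperimentConfig.model_validate(raw)
    except Exception as exc:
        raise SchemaError(f"invalid config {path}: {exc}") from exc


def dump_config(cfg: ExperimentConfig) -> str:
    """Canonical YAML serialization (stable key order for hashing)."""
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
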