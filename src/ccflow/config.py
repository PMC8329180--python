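"""Pipeline configuration: validated, YAML round-trippable.

One top-level seed feeds every stochastic stage through named substreams,
so a config plus a seed pins the entire demo bit-for-bit. Unknown keys
are rejected to catch typos early.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import FieldGeometry
from .synth.dye import PulseModel
from .synth.presets import SimulationPreset


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSettings(_Strict):
    width_mm: float = 3.0
    height_mm: float = 3.0
    grid_nx: int = 256
    grid_ny: int = 256
    disc_center_mm: Tuple[float, float] = (-1.0, 1.5)
    n_arterioles: int = 25
    n_venules: int = 25
    min_spacing_um: float = 300.0
    fps: float = 15.0
    duration_s: float = 10.0
    noise_sigma: float = 0.7
    mobility: float = 0.55
    pulse_period_s: float = 1.0
    pulse_modulation_depth: float = 0.7
    pulse_modulation_decay_tau_s: float = 4.5
    bolus_peak_s: float = 2.0
    bolus_decay_tau_s: float = 30.0
    radial_onset_delay_s_per_mm: float = 1.0
    dispersion_gain: float = 3.5


class RegistrationSettings(_Strict):
    reference: Literal["first", "middle", "previous"] = "first"
    mode: Literal["full", "rigid"] = "full"
    control_spacing_px: float = 32.0


class SubtractionSettings(_Strict):
    smooth_sigma_px: float = 0.7
    negative_handling: Literal["clip_zero", "signed"] = "clip_zero"
    remap_scope: Literal["global", "per_frame"] = "global"
    output_depth: int = 8


class AveragingSettings(_Strict):
    n_frames: int = 9
    min_signal_strength: int = 9
    vessel_density_target: float = 0.55
    repeat_max_shift_px: float = 5.0
    repeat_max_rot_deg: float = 2.0
    repeat_noise_sigma: float = 10.0


class AnalysisSettings(_Strict):
    min_unit_area_um2: float = 3000.0
    arrival_threshold_frac: float = 0.10
    cycle_prominence_frac: float = 0.86
    cycle_roi: Tuple[int, int, int, int] = (96, 8, 64, 48)
    split_merged_units: bool = True
    split_min_distance_px: int = 14
    zone_percentile: float = 80.0


class PipelineConfig(_Strict):
    """Full demo configuration; defaults reproduce the frozen preset."""

    seed: int = 42
    output_dir: str = "ccflow_out"
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    registration: RegistrationSettings = Field(default_factory=RegistrationSettings)
    subtraction: SubtractionSettings = Field(default_factory=SubtractionSettings)
    averaging: AveragingSettings = Field(default_factory=AveragingSettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)

    # -- conversions -------------------------------------------------------
    def to_preset(self) -> SimulationPreset:
        s, a = self.simulation, self.analysis
        return SimulationPreset(
            geometry=FieldGeometry(
                width_mm=s.width_mm,
                height_mm=s.height_mm,
                grid_nx=s.grid_nx,
                grid_ny=s.grid_ny,
                disc_center_mm=tuple(s.disc_center_mm),
            ),
            n_arterioles=s.n_arterioles,
            n_venules=s.n_venules,
            min_spacing_um=s.min_spacing_um,
            fps=s.fps,
            duration_s=s.duration_s,
            pulse=PulseModel(
                period_s=s.pulse_period_s,
                modulation_depth=s.pulse_modulation_depth,
                modulation_decay_tau_s=s.pulse_modulation_decay_tau_s,
                bolus_peak_s=s.bolus_peak_s,
                bolus_decay_tau_s=s.bolus_decay_tau_s,
                radial_onset_delay_s_per_mm=s.radial_onset_delay_s_per_mm,
                dispersion_gain=s.dispersion_gain,
            ),
            seed=self.seed,
            noise_sigma=s.noise_sigma,
            mobility=s.mobility,
            zone_percentile=a.zone_percentile,
            min_unit_area_um2=a.min_unit_area_um2,
            arrival_threshold_frac=a.arrival_threshold_frac,
            cycle_prominence_frac=a.cycle_prominence_frac,
            cycle_roi=tuple(a.cycle_roi),
            split_merged_units=a.split_merged_units,
            split_min_distance_px=a.split_min_distance_px,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )
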