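"""Frozen default simulation configuration.

``preset_reference_default`` is the package's reference study condition: a
3 x 3 mm field sampled at 256 x 256, 25 arterioles and 25 venules with at
least 300 um spacing, the optic disc 1 mm beyond the nasal (left) border,
15 frames per second for 10 s, a 1.0 s cardiac period, seed 42. The
remaining knobs (Darcy mobility, onset-delay rate, bolus shape, noise,
segmentation thresholds) are calibration parameters of the preset, fixed
once so the simulated sequence reproduces the qualitative filling
behaviour: a radial peripapillary-to-peripheral wave spanning several
seconds, discrete lobules separated by 50-200 um slow zones, and a few
decaying cardiac refilling cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ..geometry import FieldGeometry
from .dye import AngioSequence, PulseModel, simulate_dye
from .pressure import PerfusionField, solve_pressure
from .vessels import VascularMap, place_vessels


@dataclass(frozen=True)
class SimulationPreset:
    """Complete, frozen configuration for one synthetic acquisition."""

    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    n_arterioles: int = 25
    n_venules: int = 25
    min_spacing_um: float = 300.0
    fps: float = 15.0
    duration_s: float = 10.0
    pulse: PulseModel = field(default_factory=PulseModel)
    seed: int = 42
    noise_sigma: float = 0.7
    mobility: float = 0.55
    zone_percentile: float = 80.0
    # analysis calibration
    min_unit_area_um2: float = 3000.0
    arrival_threshold_frac: float = 0.10
    cycle_prominence_frac: float = 0.86
    cycle_roi: tuple[int, int, int, int] = (96, 8, 64, 48)
    split_merged_units: bool = True
    split_min_distance_px: int = 14

    def place(self) -> VascularMap:
        return place_vessels(
            self.geometry,
            self.n_arterioles,
            self.n_venules,
            self.min_spacing_um,
            seed=self.seed,
        )

    def solve(self, vmap: VascularMap | None = None) -> PerfusionField:
        if vmap is None:
            vmap = self.place()
        return solve_pressure(vmap, self.geometry, mobility=self.mobility)

    def simulate(self, perfusion: PerfusionField | None = None) -> AngioSequence:
        if perfusion is None:
            perfusion = self.solve()
        return simulate_dye(
            perfusion,
            self.pulse,
            duration_s=self.duration_s,
            fps=self.fps,
            geometry=self.geometry,
            seed=self.seed,
            noise_sigma=self.noise_sigma,
            zone_percentile=self.zone_percentile,
        )

    def with_(self, **kwargs) -> "SimulationPreset":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def preset_reference_default() -> SimulationPreset:
    """Return the frozen default configuration (identical on every call)."""
    return SimulationPreset()
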