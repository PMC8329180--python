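import numpy as np
import pytest
import scipy.ndimage as ndi

from ccflow.geometry import FieldGeometry
from ccflow.pipeline import analyze_sequence
from ccflow.synth import render_octa
from ccflow.synth.presets import SimulationPreset


@pytest.fixture(scope="session")
def reference_preset() -> SimulationPreset:
    """The frozen default study configuration."""
    return SimulationPreset()


@pytest.fixture(scope="session")
def reference_run(reference_preset):
    """Full frozen-preset run: placement, solve, simulation, analysis.

    Session-scoped because the chain costs a few seconds and many tests
    consume different pieces of it.
    """
    vmap = reference_preset.place()
    perfusion = reference_preset.solve(vmap)
    sequence = reference_preset.simulate(perfusion)
    report, sub = analyze_sequence(sequence, reference_preset, vascular_map=vmap)
    return {
        "preset": reference_preset,
        "vmap": vmap,
        "perfusion": perfusion,
        "sequence": sequence,
        "report": report,
        "sub": sub,
    }


@pytest.fixture(scope="session")
def small_preset() -> SimulationPreset:
    """A desk-scale configuration for fast functional tests."""
    return SimulationPreset(
        geometry=FieldGeometry(grid_nx=96, grid_ny=96),
        n_arterioles=6,
        n_venules=6,
        duration_s=4.0,
        fps=10.0,
        cycle_roi=(32, 4, 24, 16),
        seed=7,
    )


@pytest.fixture(scope="session")
def octa_texture():
    """Smooth mesh texture suited to subpixel registration tests."""
    base = render_octa(FieldGeometry(), 0.45, seed=3).astype(np.float32)
    return ndi.gaussian_filter(base, 1.0)
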