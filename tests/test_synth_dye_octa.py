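"""Dye-filling simulation and synthetic OCTA textures."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from ccflow.errors import TooShortError
from ccflow.geometry import FieldGeometry
from ccflow.synth import make_octa_repeats, render_octa, simulate_dye
from ccflow.synth.dye import PulseModel
from ccflow.synth.pressure import UNPERFUSED, trace_streamline


class TestPulseModel:
    def test_envelope_zero_before_onset_and_rises(self):
        pm = PulseModel()
        tau = np.linspace(-2, 10, 500)
        env = pm.bolus_envelope(tau)
        assert np.all(env[tau <= 0] == 0)
        assert env[tau > 0].max() <= 1.0 + 1e-9
        rise = env[(tau > 0) & (tau < pm.bolus_peak_s)]
        assert np.all(np.diff(rise) >= 0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PulseModel(modulation_depth=1.5)
        with pytest.raises(ValueError):
            PulseModel(period_s=0.0)
        with pytest.raises(ValueError):
            PulseModel(dispersion_gain=-1.0)


class TestSimulateDye:
    def test_too_short_raises(self, small_preset):
        field = small_preset.solve()
        with pytest.raises(TooShortError):
            simulate_dye(
                field,
                small_preset.pulse,
                duration_s=0.05,
                fps=10.0,
                geometry=small_preset.geometry,
                seed=1,
            )

    def test_no_modulation_gives_monotone_plateau_trace(self, small_preset):
        """With no cardiac pulse and no noise the fill is monotone."""
        field = small_preset.solve()
        pulse = PulseModel(
            modulation_depth=0.0,
            bolus_decay_tau_s=1e6,
            bolus_peak_s=1.0,
            dispersion_gain=0.0,
        )
        seq = simulate_dye(
            field, pulse, 4.0, 10.0, small_preset.geometry, seed=1, noise_sigma=0.0
        )
        trace = seq.frames[:, 30:60, 30:60].mean(axis=(1, 2))
        assert np.all(np.diff(trace) >= -0.51)  # quantisation only
        peaks, _ = find_peaks(trace, prominence=0.05 * trace.max())
        assert len(peaks) == 0

    def test_arrival_nondecreasing_along_streamlines(self, reference_run):
        field = reference_run["perfusion"]
        arrival = reference_run["sequence"].ground_truth["arrival_s"]
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 100:
            r = int(rng.integers(0, arrival.shape[0]))
            c = int(rng.integers(0, arrival.shape[1]))
            if field.ownership[r, c] == UNPERFUSED:
                continue
            path = trace_streamline(field, (r, c))
            vals = arrival[path[:, 0], path[:, 1]][::-1]  # arteriole outward
            vals = vals[np.isfinite(vals)]
            assert np.all(np.diff(vals) >= -1e-9)
            checked += 1

    def test_first_dye_appears_peripapillarily(self, reference_run):
        """Earliest arrival sits on the disc side of the field."""
        seq = reference_run["sequence"]
        g = seq.geometry
        arr = seq.ground_truth["arrival_s"]
        r, c = np.unravel_index(np.nanargmin(np.where(np.isfinite(arr), arr, np.nan)),
                                arr.shape)
        X, Y = g.pixel_centers_mm()
        disc = np.asarray(g.disc_center_mm)
        dist = np.hypot(X - disc[0], Y - disc[1])
        assert dist[r, c] < np.percentile(dist, 25)

    def test_bit_identical_for_same_seed(self, small_preset):
        a = small_preset.simulate()
        b = small_preset.simulate()
        assert np.array_equal(a.frames, b.frames)

    def test_ground_truth_populated(self, small_preset):
        seq = small_preset.simulate()
        gt = seq.ground_truth
        assert set(gt) >= {"arrival_s", "ownership", "zone_mask"}
        assert gt["zone_mask"].dtype == bool
        assert 0.0 < gt["zone_mask"].mean() < 0.5


class TestRenderOcta:
    def test_density_hits_target(self):
        img = render_octa(FieldGeometry(), 0.55, seed=4)
        frac = (img > 127).mean()
        assert 0.53 <= frac <= 0.57

    def test_identical_seed_identical_texture(self):
        g = FieldGeometry()
        assert np.array_equal(render_octa(g, 0.4, seed=9), render_octa(g, 0.4, seed=9))

    def test_isotropic_spectrum(self):
        """No preferred orientation: angular power is nearly uniform."""
        img = render_octa(FieldGeometry(), 0.5, seed=2).astype(float)
        spec = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean()))) ** 2
        ny, nx = spec.shape
        yy, xx = np.indices(spec.shape)
        ang = np.arctan2(yy - ny // 2, xx - nx // 2) % np.pi
        rad = np.hypot(yy - ny // 2, xx - nx // 2)
        band = (rad > 10) & (rad < 100)
        bins = np.linspace(0, np.pi, 13)
        power = np.array([
            spec[band & (ang >= lo) & (ang < hi)].mean()
            for lo, hi in zip(bins[:-1], bins[1:])
        ])
        assert power.max() / power.min() < 1.5

    def test_density_validation(self):
        with pytest.raises(ValueError):
            render_octa(FieldGeometry(), 1.2, seed=0)


class TestMakeOctaRepeats:
    def test_single_repeat_is_identity_with_noise(self):
        base = render_octa(FieldGeometry(grid_nx=64, grid_ny=64), 0.5, seed=1)
        reps = make_octa_repeats(base, 1, 3.0, 1.0, 5.0, seed=2)
        assert len(reps.images) == 1
        assert reps.true_transforms[0] == (0.0, 0.0, 0.0)
        resid = reps.images[0].astype(float) - base.astype(float)
        assert 3.5 < resid.std() < 6.5

    def test_noise_std_recovered_without_jitter(self):
        """With identity transforms the per-pixel std across repeats is sigma."""
        base = render_octa(FieldGeometry(grid_nx=128, grid_ny=128), 0.5, seed=1)
        reps = make_octa_repeats(base, 9, 0.0, 0.0, 10.0, seed=3)
        stack = np.stack([i.astype(float) for i in reps.images])
        per_pixel_std = stack.std(axis=0, ddof=1)
        # pool across pixels; quantisation adds ~1/12 variance
        assert abs(np.median(per_pixel_std) - 10.0) < 1.5

    def test_recorded_transforms_within_bounds(self):
        base = render_octa(FieldGeometry(grid_nx=64, grid_ny=64), 0.5, seed=1)
        reps = make_octa_repeats(base, 8, 4.0, 2.5, 1.0, seed=5)
        assert reps.true_transforms[0] == (0.0, 0.0, 0.0)
        for dx, dy, th in reps.true_transforms:
            assert abs(dx) <= 4.0 and abs(dy) <= 4.0 and abs(th) <= 2.5
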