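"""Sequential subtraction, grayscale remap, 3-D Gaussian smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from ccflow.errors import TooShortError
from ccflow.subtraction import (
    SubtractionParams,
    gaussian_smooth_3d,
    remap_grayscale,
    run_subtraction_pipeline,
    sequential_subtract,
)


class TestSequentialSubtract:
    def test_constant_stack_all_zero(self):
        stack = np.full((5, 4, 4), 17, dtype=np.uint8)
        assert np.all(sequential_subtract(stack) == 0)

    def test_uniform_values_arithmetic(self):
        stack = np.stack([np.full((3, 3), v) for v in (0, 10, 30)])
        out = sequential_subtract(stack)
        assert np.all(out[0] == 10) and np.all(out[1] == 20)

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            sequential_subtract(np.zeros((1, 4, 4)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        hnp.arrays(
            np.uint8,
            st.tuples(
                st.integers(2, 8), st.integers(2, 6), st.integers(2, 6)
            ),
        )
    )
    def test_telescoping_identity(self, stack):
        """Sum of differences equals last minus first, exactly, per pixel."""
        out = sequential_subtract(stack)
        total = out.sum(axis=0)
        expected = stack[-1].astype(np.float64) - stack[0].astype(np.float64)
        assert np.array_equal(total, expected)


class TestRemap:
    def test_endpoints_forced(self):
        stack = np.array([[[10.0, 20.0]]])
        out = remap_grayscale(stack, SubtractionParams(negative_handling="signed"))
        assert out.min() == 0 and out.max() == 255

    def test_constant_maps_to_zero(self):
        out = remap_grayscale(np.full((3, 4, 4), 7.0), SubtractionParams())
        assert np.all(out == 0)

    def test_midpoint_rounds_half_up(self):
        stack = np.array([[[10.0, 15.0, 20.0]]])
        out = remap_grayscale(stack, SubtractionParams(negative_handling="signed"))
        assert out[0, 0, 1] == 128  # round(255 * 0.5) with half-up

    def test_clip_zero_removes_negatives(self):
        stack = np.array([[[-5.0, 0.0, 5.0]]])
        out = remap_grayscale(stack, SubtractionParams())
        assert out[0, 0, 0] == 0 and out[0, 0, 1] == 0 and out[0, 0, 2] == 255

    def test_per_frame_scope_stretches_each_frame(self):
        stack = np.stack([np.array([[0.0, 1.0]]), np.array([[0.0, 10.0]])])
        params = SubtractionParams(remap_scope="per_frame", negative_handling="signed")
        out = remap_grayscale(stack, params)
        assert out[0].max() == 255 and out[1].max() == 255


class TestGaussianSmooth:
    def test_sigma_zero_is_identity(self):
        stack = np.random.default_rng(0).integers(0, 255, (4, 8, 8)).astype(np.uint8)
        assert np.array_equal(gaussian_smooth_3d(stack, 0.0), stack)

    def test_impulse_kernel_normalised(self):
        stack = np.zeros((9, 9, 9))
        stack[4, 4, 4] = 1.0
        out = gaussian_smooth_3d(stack, 0.7)
        assert abs(out.sum() - 1.0) < 1e-6

    def test_matches_brute_force_convolution(self):
        """Separable implementation equals direct 3-D convolution."""
        rng = np.random.default_rng(3)
        stack = rng.random((5, 8, 8))
        sigma = 0.7
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        # edge-repeating reflection (np.pad calls it "symmetric")
        padded = np.pad(stack, radius, mode="symmetric")
        brute = np.zeros_like(stack)
        for i in range(stack.shape[0]):
            for j in range(stack.shape[1]):
                for k in range(stack.shape[2]):
                    block = padded[
                        i : i + 2 * radius + 1,
                        j : j + 2 * radius + 1,
                        k : k + 2 * radius + 1,
                    ]
                    brute[i, j, k] = (block * kernel).sum()
        out = gaussian_smooth_3d(stack, sigma)
        assert np.abs(out - brute).max() < 1e-6

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        stack = rng.random((6, 16, 16)) * 100
        out = gaussian_smooth_3d(stack, 0.7)
        assert abs(out.mean() - stack.mean()) < 1e-3 * stack.mean()


class TestPipeline:
    def test_frame_count_contract(self, small_preset):
        seq = small_preset.simulate()
        sub = run_subtraction_pipeline(seq)
        assert sub.n_frames == seq.n_frames - 1
        assert sub.frames.dtype == np.uint8

    def test_deterministic_rerun(self, small_preset):
        seq = small_preset.simulate()
        a = run_subtraction_pipeline(seq)
        b = run_subtraction_pipeline(seq)
        assert np.array_equal(a.frames, b.frames)
        assert a.provenance["input_sha256"] == b.provenance["input_sha256"]

    def test_subtraction_is_linear_in_contrast(self):
        """Doubling the dye-front contrast doubles pre-remap differences."""
        rng = np.random.default_rng(0)
        ramp = np.cumsum(rng.random((6, 5, 5)), axis=0)
        d1 = sequential_subtract(100 + ramp)
        d2 = sequential_subtract(100 + 2 * ramp)
        assert np.allclose(d2, 2 * d1)

    def test_steady_flow_goes_dark(self, small_preset):
        """After fill completes without pulse, subtracted frames are near zero."""
        from ccflow.synth.dye import PulseModel
        from ccflow.synth import simulate_dye, solve_pressure

        # high mobility so even boundary-zone transit completes well inside
        # the acquisition
        field = solve_pressure(
            small_preset.place(), small_preset.geometry, mobility=4.0
        )
        pulse = PulseModel(
            modulation_depth=0.0,
            bolus_peak_s=0.4,
            bolus_decay_tau_s=1e6,
            radial_onset_delay_s_per_mm=0.1,
            dispersion_gain=0.0,
        )
        seq = simulate_dye(
            field, pulse, 6.0, 10.0, small_preset.geometry, seed=2, noise_sigma=0.0
        )
        sub = run_subtraction_pipeline(seq)
        early = sub.frames[: sub.n_frames // 3].mean()
        late = sub.frames[-5:].mean()
        assert late < 0.05 * early
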