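"""Tests for TIE initialization and multi-height phase retrieval."""

import numpy as np
import pytest

from holorec.classical import (
    MultiHeightParams,
    TIEInput,
    multiheight_recover,
    recover_subset,
    tie_phase,
)
from holorec.classical import _amplitude_update
from holorec.optics import ComplexField, IntensityImage, OpticalConfig, propagate
from holorec.phantom import default_heights, generate_phantom, generate_stack


def gaussian_beam_intensity_and_phase(z, n=256, w0=20.0, lam=0.532, pitch=1.0):
    """Closed-form Gaussian beam at distance z from the waist."""
    zr = np.pi * w0**2 / lam
    k = 2 * np.pi / lam
    y, x = np.mgrid[0:n, 0:n] * pitch
    c = (n - 1) / 2 * pitch
    r2 = (x - c) ** 2 + (y - c) ** 2
    w = w0 * np.sqrt(1 + (z / zr) ** 2)
    amp = (w0 / w) * np.exp(-r2 / w**2)
    R = z * (1 + (zr / z) ** 2)
    phase = k * r2 / (2 * R)
    return amp**2, phase


@pytest.fixture
def tissue_stack(cfg_periodic):
    p = generate_phantom("tissue", 128, seed=3, target_rms_ratio=0.28, config=cfg_periodic)
    return p, generate_stack(p, default_heights(300.0))


class TestTIEInput:
    def test_height_ordering(self, cfg):
        im = IntensityImage(np.ones((8, 8)), cfg, 0.0)
        with pytest.raises(ValueError):
            TIEInput(im, im, im, 100.0, 100.0, 180.0)

    def test_shape_mismatch(self, cfg):
        im = IntensityImage(np.ones((8, 8)), cfg, 0.0)
        im2 = IntensityImage(np.ones((16, 16)), cfg, 0.0)
        with pytest.raises(ValueError):
            TIEInput(im, im2, im, 100.0, 190.0, 280.0)


class TestTIEPhase:
    def test_identical_intensities_zero_phase(self, cfg):
        im = IntensityImage(np.ones((64, 64)), cfg, 0.0)
        inp = TIEInput(im, im, im, 300.0, 390.0, 480.0)
        phi = tie_phase(inp, cfg)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_gaussian_beam_quadratic_phase(self, cfg):
        # closed-form oracle: three-plane intensities of an analytic Gaussian
        # beam recover its quadratic phase at the middle plane
        z1, z7, z8 = 300.0, 390.0, 480.0
        I1, _ = gaussian_beam_intensity_and_phase(z1)
        I7, phase7 = gaussian_beam_intensity_and_phase(z7)
        I8, _ = gaussian_beam_intensity_and_phase(z8)
        inp = TIEInput(
            IntensityImage(I1, cfg, z1),
            IntensityImage(I7, cfg, z7),
            IntensityImage(I8, cfg, z8),
            z1,
            z7,
            z8,
        )
        phi = tie_phase(inp, cfg)
        mask = I7 > 0.01 * I7.max()
        r = np.corrcoef(phi[mask], phase7[mask])[0, 1]
        assert r > 0.95

    def test_weak_phase_phantom(self, cfg_periodic):
        # weak pure-phase object, smooth enough that the (I8 - I1) finite
        # difference is a faithful axial derivative
        from scipy import ndimage

        from holorec.optics import simulate_hologram

        rng = np.random.default_rng(6)
        phase = ndimage.gaussian_filter(rng.standard_normal((128, 128)), 6.0)
        phase = 0.15 * phase / phase.std()
        t = np.exp(1j * phase)
        fld = ComplexField(t - 1.0, cfg_periodic)
        z1, z7, z8 = 100.0, 190.0, 280.0
        holos = [simulate_hologram(fld, 1.0, z) for z in (z1, z7, z8)]
        inp = TIEInput(holos[0], holos[1], holos[2], z1, z7, z8)
        phi = tie_phase(inp, cfg_periodic)
        truth7 = propagate(ComplexField(t, cfg_periodic), z7)
        true_phase = np.angle(truth7.values)
        r = np.corrcoef(phi.ravel(), (true_phase - true_phase.mean()).ravel())[0, 1]
        assert r > 0.9

    def test_zero_mean_output(self, cfg):
        I1, _ = gaussian_beam_intensity_and_phase(300.0, n=64)
        I7, _ = gaussian_beam_intensity_and_phase(390.0, n=64)
        I8, _ = gaussian_beam_intensity_and_phase(480.0, n=64)
        inp = TIEInput(
            IntensityImage(I1, cfg, 300.0),
            IntensityImage(I7, cfg, 390.0),
            IntensityImage(I8, cfg, 480.0),
            300.0,
            390.0,
            480.0,
        )
        assert abs(tie_phase(inp, cfg).mean()) < 1e-12


class TestAmplitudeUpdate:
    def test_phase_preserved(self, rng):
        vals = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        intensity = rng.uniform(0.5, 2.0, (32, 32))
        new_vals, _ = _amplitude_update(vals, intensity)
        np.testing.assert_allclose(np.angle(new_vals), np.angle(vals), atol=1e-12)

    def test_amplitude_is_average(self, rng):
        vals = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        intensity = rng.uniform(0.5, 2.0, (16, 16))
        new_vals, _ = _amplitude_update(vals, intensity)
        expected = 0.5 * (np.abs(vals) + np.sqrt(intensity))
        np.testing.assert_allclose(np.abs(new_vals), expected, atol=1e-12)

    def test_consistent_data_zero_residual(self, rng):
        vals = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        new_vals, res = _amplitude_update(vals, np.abs(vals) ** 2)
        assert res == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(new_vals, vals, atol=1e-12)


class TestMultiHeightRecover:
    def test_ground_truth_is_fixed_point(self, tissue_stack, cfg_periodic):
        p, stack = tissue_stack
        truth7 = propagate(ComplexField(1.0 + p.scattered, cfg_periodic), stack.heights[6])
        params = MultiHeightParams(n_iterations=3)
        rec = multiheight_recover(stack, np.angle(truth7.values), params, cfg_periodic)
        drift = np.sqrt(np.mean(np.abs(rec.values - p.transmittance) ** 2))
        assert drift < 1e-6
        assert all(res < 1e-10 for (_, _, res) in params.convergence_log)

    def test_defaults_echo_protocol(self):
        params = MultiHeightParams()
        assert params.n_iterations == 50
        assert default_heights(0.0) == (0, 15, 30, 45, 60, 75, 90, 180)

    def test_residual_decreases_on_noiseless_data(self, tissue_stack, cfg_periodic):
        _, stack = tissue_stack
        params = MultiHeightParams(n_iterations=20)
        multiheight_recover(stack, np.zeros((128, 128)), params, cfg_periodic)
        residuals = [r for (_, _, r) in params.convergence_log]
        assert residuals[-1] <= residuals[0]

    def test_refuses_single_height(self, tissue_stack, cfg_periodic):
        _, stack = tissue_stack
        params = MultiHeightParams(n_iterations=1, subset=(0,))
        with pytest.raises(ValueError, match=">= 2"):
            multiheight_recover(stack, np.zeros((128, 128)), params, cfg_periodic)

    def test_init_shape_mismatch(self, tissue_stack, cfg_periodic):
        _, stack = tissue_stack
        with pytest.raises(ValueError, match="shape"):
            multiheight_recover(stack, np.zeros((64, 64)), MultiHeightParams(), cfg_periodic)


class TestRecoverSubset:
    def test_nholo_bounds(self, tissue_stack, cfg_periodic):
        _, stack = tissue_stack
        with pytest.raises(ValueError):
            recover_subset(stack, 1, config=cfg_periodic)
        with pytest.raises(ValueError):
            recover_subset(stack, 9, config=cfg_periodic)

    def test_consistency_with_multiheight(self, tissue_stack, cfg_periodic):
        p, stack = tissue_stack
        from holorec.classical import TIEInput, tie_phase

        inp = TIEInput(
            stack.images[0], stack.images[6], stack.images[7],
            stack.heights[0], stack.heights[6], stack.heights[7],
        )
        init = tie_phase(inp, cfg_periodic)
        params_a = MultiHeightParams(n_iterations=5)
        a = recover_subset(stack, 8, params_a, cfg_periodic)
        params_b = MultiHeightParams(n_iterations=5)
        b = multiheight_recover(stack, init, params_b, cfg_periodic)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_two_heights_worse_than_eight(self, tissue_stack, cfg_periodic):
        _, stack = tissue_stack
        p2 = MultiHeightParams(n_iterations=50)
        recover_subset(stack, 2, p2, cfg_periodic)
        p8 = MultiHeightParams(n_iterations=50)
        recover_subset(stack, 8, p8, cfg_periodic)
        final2 = p2.convergence_log[-1][2]
        final8 = p8.convergence_log[-1][2]
        assert final2 >= final8


class TestParameterRecovery:
    def test_phase_rmse_over_seeds(self, cfg_periodic):
        # noiseless 8-height recovery: phase RMSE < 0.05 rad over 5 seeds
        errs = []
        for seed in range(5):
            p = generate_phantom("tissue", 128, seed=20 + seed, target_rms_ratio=0.28,
                                 config=cfg_periodic)
            stack = generate_stack(p, default_heights(300.0))
            rec = recover_subset(stack, 8, MultiHeightParams(n_iterations=50), cfg_periodic)
            dphi = np.angle(rec.values * np.conj(p.transmittance))
            dphi -= dphi.mean()
            errs.append(np.sqrt(np.mean(dphi**2)))
        assert max(errs) < 0.05
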