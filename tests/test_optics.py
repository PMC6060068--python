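"""Unit and property tests for the scalar diffraction engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holorec.optics import (
    ComplexField,
    IntensityImage,
    OpticalConfig,
    back_propagate,
    propagate,
    simulate_hologram,
)


def _gaussian_spot(n=32, sigma=3.0, cfg=None):
    cfg = cfg or OpticalConfig()
    y, x = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    vals = np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2 * sigma**2)).astype(complex)
    return ComplexField(values=vals, config=cfg, z=0.0)


def rayleigh_sommerfeld(values, pitch, wavelength, dz):
    """Brute-force Rayleigh-Sommerfeld (first kind) point-by-point summation."""
    n = values.shape[0]
    k = 2 * np.pi / wavelength
    yy, xx = np.mgrid[0:n, 0:n] * pitch
    out = np.zeros_like(values, dtype=complex)
    for i in range(n):
        for j in range(n):
            r = np.sqrt((xx - xx[i, j]) ** 2 + (yy - yy[i, j]) ** 2 + dz**2)
            h = dz * (1 - 1j * k * r) * np.exp(1j * k * r) / (2 * np.pi * r**3)
            out[i, j] = np.sum(values * h) * pitch**2
    return out


class TestOpticalConfig:
    def test_defaults(self):
        cfg = OpticalConfig()
        assert cfg.wavelength == 0.532
        assert cfg.pixel_pitch == 1.0
        assert cfg.pad_factor == 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"wavelength": 0.0},
            {"wavelength": -1.0},
            {"pixel_pitch": 0.0},
            {"medium_index": 0.9},
            {"pad_factor": 0},
            {"evanescent_policy": "reflect"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            OpticalConfig(**kwargs)


class TestFieldTypes:
    def test_nonfinite_rejected(self, cfg):
        vals = np.ones((4, 4), complex)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            ComplexField(values=vals, config=cfg)

    def test_negative_intensity_rejected(self, cfg):
        vals = np.ones((4, 4))
        vals[1, 1] = -0.1
        with pytest.raises(ValueError):
            IntensityImage(values=vals, config=cfg)

    def test_empty_rejected(self, cfg):
        with pytest.raises(ValueError):
            ComplexField(values=np.empty((0, 4), complex), config=cfg)


class TestPropagate:
    def test_dz_zero_identity(self, random_field):
        out = propagate(random_field, 0.0)
        np.testing.assert_array_equal(out.values, random_field.values)

    def test_nonfinite_dz(self, random_field):
        with pytest.raises(ValueError):
            propagate(random_field, np.nan)

    def test_constant_field_eigenfunction(self, cfg):
        fld = ComplexField(values=np.full((32, 32), 1.5 - 0.5j), config=cfg)
        out = propagate(fld, 77.0)
        # plane wave along the axis: modulus unchanged, uniform phase
        np.testing.assert_allclose(np.abs(out.values), np.abs(fld.values), atol=1e-12)
        assert np.ptp(np.angle(out.values * np.conj(fld.values))) < 1e-12

    def test_z_bookkeeping(self, random_field):
        out = propagate(random_field, 12.5)
        assert out.z == random_field.z + 12.5
        assert out.shape == random_field.shape
        assert out.config is random_field.config

    def test_matches_rayleigh_sommerfeld(self):
        # 32x32 Gaussian spot, dz = 50 um, lambda = 0.532 um, pitch = 1 um;
        # oracle evaluated on the padded grid, compared on the inner window
        cfg = OpticalConfig(pad_factor=2, evanescent_policy="zero")
        spot = _gaussian_spot(32, 3.0, cfg)
        asm = propagate(spot, 50.0)
        padded = np.pad(spot.values, 16, mode="edge")
        rs = rayleigh_sommerfeld(padded, 1.0, 0.532, 50.0)[16:48, 16:48]
        # remove the on-axis plane-wave gauge used by the transfer function
        asm_abs = asm.values * np.exp(1j * 2 * np.pi / 0.532 * 50.0)
        err = np.sqrt(np.mean(np.abs(asm_abs - rs) ** 2) / np.mean(np.abs(rs) ** 2))
        assert err < 1e-3

    def test_round_trip_unitary(self, cfg_keep, rng):
        vals = rng.standard_normal((48, 48)) + 1j * rng.standard_normal((48, 48))
        fld = ComplexField(values=vals, config=cfg_keep)
        out = propagate(propagate(fld, 41.0), -41.0)
        err = np.sqrt(np.mean(np.abs(out.values - vals) ** 2) / np.mean(np.abs(vals) ** 2))
        assert err < 1e-10

    @settings(max_examples=10, deadline=None)
    @given(
        z1=st.floats(-80, 80),
        z2=st.floats(-80, 80),
        seed=st.integers(0, 2**16),
    )
    def test_additivity(self, z1, z2, seed):
        cfg = OpticalConfig(pad_factor=1)
        r = np.random.default_rng(seed)
        vals = r.standard_normal((32, 32)) + 1j * r.standard_normal((32, 32))
        fld = ComplexField(values=vals, config=cfg)
        a = propagate(propagate(fld, z1), z2).values
        b = propagate(fld, z1 + z2).values
        assert np.sqrt(np.mean(np.abs(a - b) ** 2) / np.mean(np.abs(vals) ** 2)) < 1e-10

    def test_power_non_increasing_with_zero_policy(self, rng):
        cfg = OpticalConfig(pad_factor=1, evanescent_policy="zero", pixel_pitch=0.25)
        vals = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        fld = ComplexField(values=vals, config=cfg)
        p0 = fld.power()
        for dz in (5.0, 20.0, 100.0):
            assert propagate(fld, dz).power() <= p0 + 1e-9 * p0

    def test_gaussian_beam_width(self):
        # beam width after propagation matches the analytic w(z) to < 1%
        lam, w0 = 0.532, 6.0
        zr = np.pi * w0**2 / lam
        z = 150.0
        w_true = w0 * np.sqrt(1 + (z / zr) ** 2)
        cfg = OpticalConfig(pad_factor=2)
        n = 512
        y, x = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        r2 = (x - c) ** 2 + (y - c) ** 2
        fld = ComplexField(np.exp(-r2 / w0**2).astype(complex), cfg)
        out = propagate(fld, z)
        intensity = np.abs(out.values) ** 2
        # second-moment width: <r^2> = w^2/2 for I ~ exp(-2 r^2 / w^2)
        total = intensity.sum()
        mean_r2 = (r2 * intensity).sum() / total
        w_est = np.sqrt(2 * mean_r2)
        assert abs(w_est - w_true) / w_true < 0.01


class TestSimulateHologram:
    def test_no_scatterer(self, cfg):
        fld = ComplexField(values=np.zeros((16, 16), complex), config=cfg)
        holo = simulate_hologram(fld, 1.0, 42.0)
        np.testing.assert_allclose(holo.values, 1.0, atol=1e-12)

    def test_single_pixel_cross_terms_cancel(self, cfg):
        vals = np.zeros((16, 16), complex)
        vals[8, 8] = 0.1j
        fld = ComplexField(values=vals, config=cfg)
        holo = simulate_hologram(fld, 1.0, 0.0)
        assert holo.values[8, 8] == pytest.approx(1.01, abs=1e-12)

    def test_energy_conservation(self, cfg_periodic, rng):
        # zero-mean scattered field: mean(I) = |A|^2 + mean(|a_z|^2)
        vals = rng.standard_normal((128, 128)) + 1j * rng.standard_normal((128, 128))
        vals *= 0.1
        vals -= vals.mean()
        fld = ComplexField(values=vals, config=cfg_periodic)
        holo = simulate_hologram(fld, 1.0, 300.0)
        a_z = propagate(fld, 300.0)
        expected = 1.0 + np.mean(np.abs(a_z.values) ** 2)
        assert abs(holo.values.mean() - expected) / expected < 1e-6

    def test_bad_reference(self, cfg):
        fld = ComplexField(values=np.zeros((8, 8), complex), config=cfg)
        with pytest.raises(ValueError):
            simulate_hologram(fld, 0.0, 10.0)

    def test_global_phase_invariance(self, cfg_periodic, rng):
        # rotating a and the reference together leaves the intensity unchanged
        vals = 0.2 * (rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32)))
        theta = 0.7
        i1 = simulate_hologram(ComplexField(vals, cfg_periodic), 1.0, 90.0).values
        rot = ComplexField(vals * np.exp(1j * theta), cfg_periodic)
        a_z = propagate(rot, 90.0)
        i2 = np.abs(np.exp(1j * theta) * 1.0 + a_z.values) ** 2
        np.testing.assert_allclose(i1, i2, atol=1e-10)

    def test_output_real_nonnegative(self, cfg_periodic, rng):
        vals = 0.3 * (rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32)))
        holo = simulate_hologram(ComplexField(vals, cfg_periodic), 2.0, 55.0)
        assert holo.values.dtype == np.float64
        assert np.all(holo.values >= 0)


class TestBackPropagate:
    def test_pure_reference_constant_modulus(self, cfg):
        holo = IntensityImage(values=np.full((32, 32), 4.0), config=cfg, z=100.0)
        out = back_propagate(holo, 100.0, reference_amplitude=2.0)
        np.testing.assert_allclose(np.abs(out.values), 2.0, atol=1e-10)

    def test_round_trip_reference(self, cfg):
        fld = ComplexField(values=np.zeros((32, 32), complex), config=cfg)
        holo = simulate_hologram(fld, 1.5, 80.0)
        out = back_propagate(holo, 80.0, 1.5)
        np.testing.assert_allclose(np.abs(out.values), 1.5, atol=1e-9)
        assert out.z == pytest.approx(0.0)

    def test_bad_reference_amplitude(self, cfg):
        holo = IntensityImage(values=np.ones((8, 8)), config=cfg, z=10.0)
        with pytest.raises(ValueError):
            back_propagate(holo, 10.0, reference_amplitude=-1.0)

    def test_weak_phase_correlation_with_twin(self, cfg_periodic):
        # back-propagation correlates with truth but keeps twin artifacts
        from holorec.phantom import generate_phantom, twin_energy

        p = generate_phantom("tissue", 128, seed=5, target_rms_ratio=0.1, config=cfg_periodic)
        fld = ComplexField(values=p.scattered, config=cfg_periodic)
        holo = simulate_hologram(fld, 1.0, 300.0)
        bp = back_propagate(holo, 300.0)
        r = np.corrcoef(bp.values.real.ravel(), p.transmittance.real.ravel())[0, 1]
        assert r > 0.5
        assert twin_energy(bp, p, baseline=bp) == pytest.approx(1.0)
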