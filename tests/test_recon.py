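import numpy as np
import pytest

from holostain.optics import OpticalConfig
from holostain.recon import (
    ComplexField,
    ReconSettings,
    angular_spectrum_propagate,
    autofocus,
    correct_aberration,
    demodulate_offaxis,
    reconstruct_pair,
)
from holostain.simulate import (
    CellPopulationSpec,
    polynomial_aberration,
    random_aberration,
    sample_cell_field,
    synthesize_hologram,
    synthesize_reference_hologram,
)


def _band_limit(phase: np.ndarray, radius: float) -> np.ndarray:
    """Low-pass a map to the demodulation band (the information that an
    off-axis hologram can carry)."""
    h, w = phase.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    keep = np.hypot(fx, fy) <= radius
    return np.fft.ifft2(np.fft.fft2(phase) * keep).real


def _random_band_limited_field(shape=(128, 128), seed=0, radius=0.2) -> ComplexField:
    rng = np.random.default_rng(seed)
    data = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    F = np.fft.fft2(data)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    F[np.hypot(fx, fy) > radius] = 0
    return ComplexField(np.fft.ifft2(F), pitch=0.275e-6, wavelength=532e-9)


class TestDemodulation:
    def test_pure_carrier_recovers_flat_field(self, small_cfg):
        h, w = small_cfg.sensor_shape
        y = np.arange(h)[:, None]
        x = np.arange(w)[None, :]
        fx, fy = small_cfg.carrier
        holo = 2.0 + 2.0 * np.cos(2 * np.pi * (fx * x + fy * y))
        field = demodulate_offaxis(holo, small_cfg)
        interior = np.s_[16:-16, 16:-16]
        phase = np.angle(field.data)[interior]
        assert np.sqrt(np.mean(phase**2)) < 1e-6
        np.testing.assert_allclose(np.abs(field.data)[interior], 1.0, atol=1e-6)

    def test_roundtrip_recovers_phase_within_band(self, small_cfg, small_field):
        holo = synthesize_hologram(small_field, small_cfg, None, 0.0)
        field = demodulate_offaxis(holo, small_cfg)
        recovered = np.angle(field.data)
        expected = _band_limit(small_field.phase, small_cfg.band_radius)
        rmse = np.sqrt(np.mean((recovered - expected) ** 2))
        assert rmse < 0.01

    def test_explicit_carrier_matches_auto_peak(self, small_cfg, small_field):
        holo = synthesize_hologram(small_field, small_cfg, None, 0.0)
        auto = demodulate_offaxis(holo, small_cfg, ReconSettings(carrier_mode="auto-peak"))
        expl = demodulate_offaxis(holo, small_cfg, ReconSettings(carrier_mode="explicit"))
        # 0.25 cycles/px is an exact FFT bin of a 256-px frame, so the two
        # code paths select the identical spectral region
        np.testing.assert_allclose(auto.data, expl.data, atol=1e-9)

    def test_constant_hologram_rejected(self, small_cfg):
        with pytest.raises(ValueError, match="constant"):
            demodulate_offaxis(np.ones((64, 64)), small_cfg)

    def test_no_carrier_found(self, small_cfg):
        rng = np.random.default_rng(0)
        noise = rng.uniform(0.9, 1.1, size=(256, 256))
        with pytest.raises(ValueError, match="no carrier"):
            demodulate_offaxis(noise, small_cfg)


class TestAngularSpectrum:
    def test_zero_distance_is_identity(self):
        f = _random_band_limited_field(seed=1)
        out = angular_spectrum_propagate(f, 0.0)
        np.testing.assert_array_equal(out.data, f.data)

    def test_unitarity_on_propagating_band(self):
        f = _random_band_limited_field(seed=2)
        out = angular_spectrum_propagate(f, 83e-6)
        assert abs(out.energy() - f.energy()) / f.energy() < 1e-10

    def test_forward_backward_roundtrip(self):
        f = _random_band_limited_field(seed=3)
        back = angular_spectrum_propagate(angular_spectrum_propagate(f, 37e-6), -37e-6)
        assert np.abs(back.data - f.data).max() < 1e-10

    def test_semigroup_property(self):
        f = _random_band_limited_field(seed=4)
        once = angular_spectrum_propagate(f, 41e-6)
        twice = angular_spectrum_propagate(angular_spectrum_propagate(f, 15e-6), 26e-6)
        assert np.abs(once.data - twice.data).max() < 1e-10

    def test_plane_wave_accumulates_global_phase(self):
        pw = ComplexField(np.ones((64, 64), complex), pitch=0.275e-6, wavelength=532e-9)
        z = 13e-6
        out = angular_spectrum_propagate(pw, z)
        np.testing.assert_allclose(
            out.data, np.exp(2j * np.pi * z / 532e-9), atol=1e-12
        )

    def test_z_offset_bookkeeping(self):
        f = _random_band_limited_field(seed=5)
        f.z_offset = 50e-6
        out = angular_spectrum_propagate(f, 20e-6)
        assert out.z_offset == pytest.approx(30e-6)

    def test_matches_fresnel_quadrature_oracle(self):
        """Independent oracle: direct Fresnel-integral quadrature of a
        smooth (paraxial) aperture."""
        n = 64
        pitch = 0.275e-6
        lam = 532e-9
        yy, xx = np.mgrid[0:n, 0:n]
        r2 = (yy - n / 2) ** 2 + (xx - n / 2) ** 2
        aperture = np.exp(-r2 / (2 * 4.0**2))  # sigma=4 px, band << NA
        f = ComplexField(aperture.astype(complex), pitch, lam)
        z = 30e-6
        out = angular_spectrum_propagate(f, z)

        # brute-force Fresnel diffraction integral
        coords = np.arange(n) * pitch
        X, Y = np.meshgrid(coords, coords)
        src = aperture.ravel()
        sx, sy = X.ravel(), Y.ravel()
        k = 2 * np.pi / lam
        U = np.zeros((n, n), complex)
        for i in range(n):
            dx2 = (X[i][:, None] - sx[None, :]) ** 2
            dy2 = (Y[i][:, None] - sy[None, :]) ** 2
            U[i] = (dx2 + dy2) @ np.zeros_like(src)  # placeholder shape
            kernel = np.exp(1j * k / (2 * z) * (dx2 + dy2))
            U[i] = kernel @ src
        U *= pitch**2 / (1j * lam * z)

        ia = np.abs(out.data[8:-8, 8:-8]) ** 2
        ib = np.abs(U[8:-8, 8:-8]) ** 2
        corr = np.corrcoef(ia.ravel(), ib.ravel())[0, 1]
        assert corr > 0.999


class TestAutofocus:
    def test_recovers_known_defocus(self):
        cfg = OpticalConfig(sensor_shape=(256, 256), defocus_z=50e-6)
        spec = CellPopulationSpec(cells_per_field=50)
        field = sample_cell_field(spec, cfg, seed=5)
        holo = synthesize_hologram(field, cfg, None, 0.0)
        obj = demodulate_offaxis(holo, cfg)
        settings = ReconSettings(z_search=(-200e-6, 200e-6, 10e-6, 1))
        z_best, curve = autofocus(obj, settings)
        # refocusing inverts the recording defocus
        assert abs(z_best - (-50e-6)) <= 1e-6

    def test_in_focus_field_stays_near_zero(self, small_cfg, small_field):
        holo = synthesize_hologram(small_field, small_cfg, None, 0.0)
        obj = demodulate_offaxis(holo, small_cfg)
        settings = ReconSettings(z_search=(-100e-6, 100e-6, 10e-6, 0))
        z_best, _ = autofocus(obj, settings)
        assert abs(z_best) <= 10e-6

    def test_curve_bookkeeping(self, small_cfg, small_field):
        holo = synthesize_hologram(small_field, small_cfg, None, 0.0)
        obj = demodulate_offaxis(holo, small_cfg)
        settings = ReconSettings(z_search=(-50e-6, 50e-6, 10e-6, 1))
        _, curve = autofocus(obj, settings)
        assert len(curve) == 11 + 21  # coarse points + one refinement scan

    def test_boundary_warning(self, small_cfg, small_field):
        cfg = OpticalConfig(sensor_shape=(256, 256), defocus_z=90e-6)
        field = sample_cell_field(CellPopulationSpec(cells_per_field=50), cfg, seed=5)
        holo = synthesize_hologram(field, cfg, None, 0.0)
        obj = demodulate_offaxis(holo, cfg)
        with pytest.warns(UserWarning, match="boundary"):
            autofocus(obj, ReconSettings(z_search=(-50e-6, 50e-6, 10e-6, 0)))

    def test_median_recovery_over_random_defocus(self):
        """Over 20 random defocus values in +-150 um the median error is
        within the refinement step (1 um)."""
        spec = CellPopulationSpec(cells_per_field=50)
        rng = np.random.default_rng(42)
        errors = []
        for i in range(20):
            d = float(rng.uniform(-150e-6, 150e-6))
            cfg = OpticalConfig(sensor_shape=(256, 256), defocus_z=d)
            field = sample_cell_field(spec, cfg, seed=100 + i)
            holo = synthesize_hologram(field, cfg, None, 0.005, seed=i)
            obj = demodulate_offaxis(holo, cfg)
            z_best, _ = autofocus(obj, ReconSettings(z_search=(-200e-6, 200e-6, 10e-6, 1)))
            errors.append(abs(z_best + d))
        assert np.median(errors) <= 1e-6


class TestAberrationCorrection:
    def test_identity_pair_gives_zero_phase(self):
        f = _random_band_limited_field(seed=6)
        pm = correct_aberration(f, f)
        assert np.abs(pm.phase).max() < 1e-12

    def test_shape_mismatch_rejected(self):
        a = _random_band_limited_field(shape=(64, 64), seed=1)
        b = _random_band_limited_field(shape=(128, 128), seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            correct_aberration(a, b)

    def test_aberration_only_pair_is_flat(self, small_cfg):
        ab = polynomial_aberration((256, 256), tilt=(0.4, -0.3), defocus=0.2)
        holo = synthesize_reference_hologram(small_cfg, ab, 0.0)
        ref = synthesize_reference_hologram(small_cfg, ab, 0.0)
        pm = correct_aberration(
            demodulate_offaxis(holo, small_cfg), demodulate_offaxis(ref, small_cfg)
        )
        assert pm.phase.std() < 0.01

    def test_simulator_pair_recovers_truth(self, small_cfg):
        """Sparse field so the check isolates aberration correction from
        band-limit truncation at smear density."""
        spec = CellPopulationSpec(cells_per_field=10)
        field = sample_cell_field(spec, small_cfg, seed=21)
        ab = polynomial_aberration(
            (256, 256), tilt=(0.5, -0.4), defocus=0.3, astigmatism=(0.2, -0.1)
        )
        holo = synthesize_hologram(field, small_cfg, ab, 0.0)
        ref = synthesize_reference_hologram(small_cfg, ab, 0.0)
        pm = correct_aberration(
            demodulate_offaxis(holo, small_cfg), demodulate_offaxis(ref, small_cfg)
        )
        rmse = np.sqrt(np.mean((pm.phase - field.phase) ** 2))
        assert rmse < 0.02


class TestFullPipeline:
    @pytest.mark.parametrize("ratio,seed", [(10, 1), (10, 2), (10, 3), (10, 4),
                                            (50, 5), (50, 6), (50, 7),
                                            (1000, 8), (1000, 9), (1000, 10)])
    def test_phase_recovery_across_ratios(self, ratio, seed):
        """Simulate -> demodulate -> autofocus -> propagate -> correct:
        RMSE < 0.05 rad at full smear density, 10 seeded fields."""
        defocus = float(np.random.default_rng(seed).uniform(-40e-6, 40e-6))
        cfg = OpticalConfig(sensor_shape=(256, 256), defocus_z=defocus)
        spec = CellPopulationSpec(ratio_pbmc_to_tumor=ratio, cells_per_field=50)
        field = sample_cell_field(spec, cfg, seed=seed)
        ab = random_aberration((256, 256), seed + 500)
        holo = synthesize_hologram(field, cfg, ab, 0.01, seed=seed)
        ref = synthesize_reference_hologram(cfg, ab, 0.01, seed=seed + 1000)
        pm = reconstruct_pair(holo, ref, cfg, run_autofocus=True)
        rmse = np.sqrt(np.mean((pm.phase - field.phase) ** 2))
        assert rmse < 0.05
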