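"""Smoothing, spectral filters, directional decomposition, phase gradient."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from tomoelast import (ComplexWaveField, butterworth_lowpass, curl_highpass,
                       directional_decompose, gaussian_smooth,
                       phase_gradient_wavenumber)
from tomoelast.preproc import (MOUSE_FILTERS, direction_windows_2d,
                               direction_windows_3d, fibonacci_directions)
from conftest import on_grid_wavenumber, plane_wave

SPACING = (0.18, 0.18)


def random_field(shape=(40, 30), seed=0, spacing=SPACING):
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return ComplexWaveField(u, 1000.0, spacing)


class TestGaussianSmooth:
    def test_sigma_zero_is_identity(self):
        f = random_field()
        out = gaussian_smooth(f, 0.0)
        assert np.array_equal(out.values, f.values)

    def test_constant_field_unchanged(self):
        f = ComplexWaveField(np.full((30, 30), 2.0 + 1.0j), 1000.0, SPACING)
        out = gaussian_smooth(f, 0.15)
        assert np.allclose(out.values, 2.0 + 1.0j, rtol=1e-10)

    def test_impulse_matches_dense_convolution_oracle(self):
        """Smoothing a unit impulse reproduces the sampled-Gaussian kernel
        applied by direct dense convolution."""
        u = np.zeros((41, 41), dtype=complex)
        u[20, 20] = 1.0
        f = ComplexWaveField(u, 1000.0, SPACING)
        out = gaussian_smooth(f, 0.15)
        sigma_vox = 0.15 / 0.18
        r = int(4 * sigma_vox + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-x ** 2 / (2 * sigma_vox ** 2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        oracle = fftconvolve(u.real, kernel, mode="same")
        assert np.allclose(out.values.real, oracle, atol=1e-8)

    def test_mask_aware_normalised_convolution(self):
        """A constant field with an invalid hole stays constant on the mask."""
        u = np.full((30, 30), 3.0 + 0j)
        mask = np.ones((30, 30), bool)
        mask[10:15, 10:15] = False
        u[~mask] = 100.0  # garbage that must not leak
        f = ComplexWaveField(u, 1000.0, SPACING, mask=mask)
        out = gaussian_smooth(f, 0.3)
        assert np.allclose(out.values[mask], 3.0, rtol=1e-9)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(random_field(), -0.1)


class TestButterworth:
    def test_dc_unchanged(self):
        f = ComplexWaveField(np.full((32, 32), 5.0 + 0j), 1000.0, SPACING)
        out = butterworth_lowpass(f, 600.0, 1)
        assert np.allclose(out.values, 5.0, rtol=1e-10)

    @pytest.mark.parametrize("mult,gain", [(1.0, 1 / np.sqrt(2)),
                                           (2.0, 1 / np.sqrt(5))])
    def test_on_grid_sinusoid_gain(self, mult, gain):
        """A pure sinusoid at m*cutoff is scaled by 1/sqrt(1+m^2)."""
        shape = (64, 64)
        cycles = 8
        k = on_grid_wavenumber(shape, SPACING, cycles)
        cutoff = k / (2 * np.pi) / mult  # cycles/m so that |xi| = mult*cutoff
        f = plane_wave(shape, SPACING, k)
        out = butterworth_lowpass(f, cutoff, 1)
        assert np.allclose(out.values, gain * f.values, atol=1e-9)

    def test_matches_fft_oracle_on_random_field(self):
        f = random_field((32, 24), seed=3)
        out = butterworth_lowpass(f, 600.0, 1)
        # independent oracle: explicit FFT filtering
        xi0 = np.fft.fftfreq(32, d=0.18e-3)
        xi1 = np.fft.fftfreq(24, d=0.18e-3)
        rad = np.sqrt(xi0[:, None] ** 2 + xi1[None, :] ** 2)
        h = 1.0 / np.sqrt(1.0 + (rad / 600.0) ** 2)
        oracle = np.fft.ifft2(np.fft.fft2(f.values) * h)
        assert np.allclose(out.values, oracle, atol=1e-12)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(random_field(), 0.0)


class TestDirectionalDecompose:
    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_partition_of_unity_2d(self, n):
        f = random_field((48, 36), seed=1)
        comps = directional_decompose(f, n)
        total = np.sum([c.values for c in comps], axis=0)
        assert np.max(np.abs(total - f.values)) < 1e-10 * np.max(np.abs(f.values))

    def test_partition_of_unity_3d(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal((12, 10, 8)) + 1j * rng.standard_normal((12, 10, 8))
        f = ComplexWaveField(u, 30.0, (2.0, 2.0, 2.0))
        comps = directional_decompose(f, 20)
        total = np.sum([c.values for c in comps], axis=0)
        assert np.max(np.abs(total - u)) < 1e-10 * np.max(np.abs(u))

    def test_windows_sum_to_one_everywhere(self):
        w2 = direction_windows_2d((32, 32), (1.8e-4, 1.8e-4), 8)
        assert np.allclose(np.sum(w2, axis=0), 1.0, atol=1e-12)
        w3 = direction_windows_3d((8, 8, 8), (2e-3,) * 3, 20)
        assert np.allclose(np.sum(w3, axis=0), 1.0, atol=1e-12)

    def test_plane_wave_energy_concentrated(self):
        shape = (64, 64)
        k = on_grid_wavenumber(shape, SPACING, 8, axis=0)
        f = plane_wave(shape, SPACING, k, angle_rad=0.0)  # travels along axis 0
        comps = directional_decompose(f, 8)
        energies = [np.sum(np.abs(c.values) ** 2) for c in comps]
        assert np.argmax(energies) == 0  # window centred on theta=0
        # orthogonal and opposing windows carry essentially nothing
        assert energies[2] < 1e-20 * energies[0]
        assert energies[4] < 1e-20 * energies[0]

    def test_standing_wave_split_closed_form(self):
        """cos(kx) splits exactly into two opposing travelling half-waves."""
        shape = (64, 64)
        k = on_grid_wavenumber(shape, SPACING, 8, axis=0)
        fwd = plane_wave(shape, SPACING, k, angle_rad=0.0)
        standing = fwd.with_values(np.cos(np.angle(fwd.values)))
        comps = directional_decompose(standing, 8)
        assert np.allclose(comps[0].values, 0.5 * fwd.values, atol=1e-10)
        assert np.allclose(comps[4].values, 0.5 * np.conj(fwd.values),
                           atol=1e-10)

    def test_symmetrised_direction_set(self):
        dirs = fibonacci_directions(20)
        assert dirs.shape == (20, 3)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        assert np.allclose(dirs[:10], -dirs[10:])

    def test_too_few_directions(self):
        with pytest.raises(ValueError):
            directional_decompose(random_field(), 1)


class TestCurlHighpass:
    def test_curl_of_discrete_gradient_vanishes(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        psi = gaussian_filter(rng.standard_normal((16, 16, 16)), 2.0)
        grads = np.gradient(psi, 2e-3)
        comps = [ComplexWaveField(g.astype(complex), 30.0, (2.0, 2.0, 2.0))
                 for g in grads]
        curl = curl_highpass(comps)
        scale = max(np.max(np.abs(g)) for g in grads) / 2e-3
        inner = (slice(2, -2),) * 3
        for c in curl:
            assert np.max(np.abs(c.values[inner])) < 1e-8 * scale

    def test_transverse_plane_wave_preserves_wavenumber(self):
        shape = (24, 24, 24)
        sp = (2.0, 2.0, 2.0)
        k = on_grid_wavenumber(shape, sp, 4, axis=0)
        axes = [np.arange(n) * s * 1e-3 for n, s in zip(shape, sp)]
        z = axes[0][:, None, None]
        wave = np.exp(1j * k * z) * np.ones(shape)
        zero = np.zeros(shape, complex)
        # polarisation along axis 1, propagation along axis 0
        comps = [ComplexWaveField(zero, 30.0, sp),
                 ComplexWaveField(wave, 30.0, sp),
                 ComplexWaveField(zero.copy(), 30.0, sp)]
        curl = curl_highpass(comps)
        kmap, _ = phase_gradient_wavenumber(curl[2])
        interior = kmap.eroded(2).masked_values()
        assert np.nanmedian(interior) == pytest.approx(k, rel=1e-3)

    def test_divergence_of_curl_vanishes(self):
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter

        comps = [ComplexWaveField(
            gaussian_filter(rng.standard_normal((14, 14, 14)), 1.5).astype(complex),
            30.0, (2.0, 2.0, 2.0)) for _ in range(3)]
        curl = curl_highpass(comps)
        div = sum(np.gradient(c.values, 2e-3, axis=i)
                  for i, c in enumerate(curl))
        scale = max(np.max(np.abs(c.values)) for c in curl) / 2e-3
        inner = (slice(2, -2),) * 3
        assert np.max(np.abs(div[inner])) < 1e-8 * scale

    def test_requires_three_components(self):
        with pytest.raises(ValueError):
            curl_highpass([random_field(), random_field()])


class TestPhaseGradient:
    def test_known_wavelength(self):
        """lambda = 2 mm gives k = 2 pi / 0.002 = 3141.59 rad/m."""
        shape = (64, 64)
        sp = (0.25, 0.25)  # 2 mm = 8 voxels, exactly periodic
        k = 2 * np.pi / 2e-3
        f = plane_wave(shape, sp, k)
        kmap, amp = phase_gradient_wavenumber(f)
        interior = kmap.eroded(2).masked_values()
        assert np.allclose(interior, 3141.5927, rtol=1e-6)
        assert np.allclose(amp.masked_values(), 1.0)

    def test_constant_field_zero_wavenumber(self):
        f = ComplexWaveField(np.full((20, 20), 1.0 + 1.0j), 1000.0, SPACING)
        kmap, _ = phase_gradient_wavenumber(f)
        assert np.allclose(kmap.masked_values(), 0.0)

    def test_decaying_plane_wave_within_half_percent(self):
        """Attenuation up to gamma = 0.2 k biases the estimate < 0.5 %."""
        sp = (0.1, 0.1)
        k = 2 * np.pi / 1.4e-3  # k h ~ 0.45
        for frac in (0.05, 0.1, 0.2):
            f = plane_wave((80, 40), sp, k, decay_rad_m=frac * k)
            kmap, _ = phase_gradient_wavenumber(f)
            med = np.nanmedian(kmap.eroded(2).masked_values())
            assert med == pytest.approx(k, rel=0.005)

    def test_dispersion_correction_exact_on_coarse_grid(self):
        """At k h ~ 0.8 the raw central-difference estimate is ~10 % low;
        the arcsin correction recovers k to float precision."""
        sp = (0.18, 0.18)
        k = 2 * np.pi * 1400.0 / 2.0  # 1400 Hz at 2 m/s
        f = plane_wave((60, 40), sp, k)
        raw, _ = phase_gradient_wavenumber(f, dispersion_correction=False)
        fixed, _ = phase_gradient_wavenumber(f, dispersion_correction=True)
        kh = k * 0.18e-3
        assert np.nanmedian(raw.eroded(2).masked_values()) == pytest.approx(
            np.sin(kh) / 0.18e-3, rel=1e-6)
        assert np.nanmedian(fixed.eroded(2).masked_values()) == pytest.approx(
            k, rel=1e-9)

    def test_invariance_to_global_phase_and_scale(self):
        f = plane_wave((40, 40), SPACING, 3000.0, angle_rad=0.4)
        kmap, _ = phase_gradient_wavenumber(f)
        g = f.with_values(5.7 * np.exp(1.3j) * f.values)
        kmap2, _ = phase_gradient_wavenumber(g)
        assert np.allclose(kmap.values, kmap2.values, equal_nan=True)

    def test_zero_field_rejected(self):
        f = ComplexWaveField(np.zeros((10, 10), complex), 1000.0, SPACING)
        with pytest.raises(ValueError):
            phase_gradient_wavenumber(f)

    def test_amplitude_floor_masks_nodes(self):
        """Near-zero-amplitude voxels are masked, not reported as garbage."""
        f = plane_wave((40, 40), SPACING, 3000.0)
        u = f.values.copy()
        u[20, 20] *= 1e-6
        kmap, _ = phase_gradient_wavenumber(f.with_values(u))
        assert not kmap.mask[20, 20]


class TestLinearityAndPipelineOrder:
    @pytest.mark.parametrize("op", [
        lambda f: gaussian_smooth(f, 0.2),
        lambda f: butterworth_lowpass(f, 600.0, 1),
        lambda f: directional_decompose(f, 8)[3],
    ])
    def test_operations_are_linear(self, op):
        u = random_field((32, 24), seed=7)
        v = random_field((32, 24), seed=8)
        a, b = 2.0 - 1.0j, 0.3 + 0.7j
        combo = u.with_values(a * u.values + b * v.values)
        lhs = op(combo).values
        rhs = a * op(u).values + b * op(v).values
        assert np.allclose(lhs, rhs, atol=1e-10 * np.max(np.abs(lhs)))

    def test_mouse_chain_preserves_plane_wave_wavenumber(self):
        """smooth -> lowpass -> decompose -> phase gradient returns the same
        wavenumber as the single-op estimate on a clean plane wave."""
        shape = (60, 60)
        k = on_grid_wavenumber(shape, SPACING, 6, axis=0)
        f = plane_wave(shape, SPACING, k)
        direct, _ = phase_gradient_wavenumber(f)
        chained = gaussian_smooth(f, MOUSE_FILTERS.gauss_sigma_mm)
        chained = butterworth_lowpass(chained,
                                      MOUSE_FILTERS.butterworth_cutoff_inv_m, 1)
        comp = directional_decompose(chained, 8)[0]
        kmap, _ = phase_gradient_wavenumber(comp)
        d = np.nanmedian(direct.eroded(2).masked_values())
        c = np.nanmedian(kmap.eroded(2).masked_values())
        # the smoother's reflect boundary perturbs the interior at the 1e-4
        # level; the phase estimate itself is exact
        assert c == pytest.approx(d, rel=2e-4)
        assert c == pytest.approx(k, rel=2e-4)
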