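import numpy as np
import pytest

from emgvmd import (
    DegenerateModeError,
    VmdConfig,
    make_triharmonic,
    update_center_frequency,
    update_mode,
    vmd_decompose,
)

FS = 1000.0
TRI_FREQS = (10.0, 60.0, 200.0)


def _fft_peak_hz(x, fs):
    spec = np.abs(np.fft.rfft(x))
    return np.fft.rfftfreq(x.size, 1.0 / fs)[np.argmax(spec)]


class TestUpdateMode:
    def test_alpha_to_zero_returns_input_spectrum(self):
        grid = np.linspace(0, 0.5, 64)
        f = np.exp(1j * grid * 7) * (1 + grid)
        lam = np.zeros_like(grid, dtype=complex)
        out = update_mode(f, None, lam, grid, omega_n=0.2, alpha=1e-300)
        assert np.allclose(out, f, atol=1e-12)

    def test_far_off_band_attenuation_bound(self):
        grid = np.linspace(0, 0.5, 64)
        f = np.zeros(64, dtype=complex)
        f[60] = 10.0  # energy far from omega_n
        lam = np.zeros_like(f)
        out = update_mode(f, None, lam, grid, omega_n=0.01, alpha=2000.0)
        bound = np.abs(f[60]) / (1 + 2 * 2000.0 * (grid[60] - 0.01) ** 2)
        assert np.abs(out[60]) <= bound * (1 + 1e-12)

    def test_matches_elementwise_formula_oracle(self):
        rng = np.random.default_rng(123)
        F = 41
        grid = np.fft.rfftfreq(80)
        f = rng.standard_normal(F) + 1j * rng.standard_normal(F)
        others = rng.standard_normal((2, F)) + 1j * rng.standard_normal((2, F))
        lam = rng.standard_normal(F) + 1j * rng.standard_normal(F)
        omega_n, alpha = 0.17, 2000.0
        out = update_mode(f, others, lam, grid, omega_n, alpha)
        # independent element-wise evaluation of the Wiener update
        for i in range(F):
            num = f[i] - (others[0][i] + others[1][i]) + lam[i] / 2
            den = 1 + 2 * alpha * (grid[i] - omega_n) ** 2
            assert out[i] == pytest.approx(num / den, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            update_mode(
                np.zeros(4, complex),
                None,
                np.zeros(5, complex),
                np.linspace(0, 0.5, 4),
                0.1,
                2000.0,
            )


class TestUpdateCenterFrequency:
    def test_single_bin(self):
        grid = np.linspace(0, 0.5, 11)
        spec = np.zeros(11, complex)
        spec[4] = 3.0 - 1j
        assert update_center_frequency(spec, grid) == pytest.approx(grid[4])

    def test_symmetric_pair_returns_midpoint(self):
        grid = np.linspace(0, 0.5, 11)
        spec = np.zeros(11, complex)
        spec[2] = spec[8] = 1.0
        assert update_center_frequency(spec, grid) == pytest.approx(
            (grid[2] + grid[8]) / 2
        )

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(7)
        grid = np.fft.rfftfreq(128)
        spec = rng.standard_normal(grid.size) + 1j * rng.standard_normal(grid.size)
        got = update_center_frequency(spec, grid)
        p = np.abs(spec) ** 2
        assert got == pytest.approx(float(np.sum(grid * p) / np.sum(p)), abs=1e-12)

    def test_zero_spectrum_degenerate(self):
        with pytest.raises(DegenerateModeError):
            update_center_frequency(np.zeros(8, complex), np.fft.rfftfreq(14))


class TestVmdDecompose:
    def test_single_tone_recovery(self):
        x = make_triharmonic(FS, 1.0, freqs=(50.0, 300.0, 400.0), amps=(1, 0, 0))
        res = vmd_decompose(x, VmdConfig(K=1, alpha=2000.0))
        assert abs(res.center_freqs_hz(FS)[0] - _fft_peak_hz(x, FS)) < 1.0
        assert np.corrcoef(res.modes[0], x)[0, 1] > 0.99

    def test_triharmonic_recovery(self):
        x = make_triharmonic(FS, 1.0)
        res = vmd_decompose(x, VmdConfig(K=3, alpha=2000.0))
        assert np.all(np.abs(res.center_freqs_hz(FS) - TRI_FREQS) < 2.0)

    def test_noise_robustness(self):
        clean = vmd_decompose(
            make_triharmonic(FS, 1.0), VmdConfig(K=3, alpha=2000.0)
        ).center_freqs_hz(FS)
        for seed in (0, 1):
            noisy = vmd_decompose(
                make_triharmonic(FS, 1.0, noise_sigma=0.1, seed=seed),
                VmdConfig(K=3, alpha=2000.0),
            ).center_freqs_hz(FS)
            assert np.all(np.abs(noisy - clean) < 5.0)

    def test_reconstruction_with_dual_ascent(self):
        rng = np.random.default_rng(3)
        # band-limited random input: sum of in-band tones
        t = np.arange(1000) / FS
        x = sum(
            a * np.cos(2 * np.pi * f * t + p)
            for a, f, p in zip(
                rng.uniform(0.5, 1, 4), (25, 80, 160, 310), rng.uniform(0, 6, 4)
            )
        )
        res = vmd_decompose(x, VmdConfig(K=4, alpha=2000.0, tau=0.5))
        assert res.reconstruction_error <= 1e-2
        # stored value equals an independent recomputation
        err = np.linalg.norm(res.modes.sum(axis=0) - x) / np.linalg.norm(x)
        assert res.reconstruction_error == pytest.approx(err, rel=1e-9)

    def test_zero_signal_gives_zero_modes(self):
        res = vmd_decompose(np.zeros(200), VmdConfig(K=3))
        assert np.all(res.modes == 0)
        assert res.reconstruction_error == 0.0

    def test_spectral_compactness(self):
        x = make_triharmonic(FS, 1.0)
        res = vmd_decompose(x, VmdConfig(K=3, alpha=2000.0))
        for mode, f0 in zip(res.modes, res.center_freqs_hz(FS)):
            freqs = np.fft.rfftfreq(mode.size, 1.0 / FS)
            power = np.abs(np.fft.rfft(mode)) ** 2
            inband = power[np.abs(freqs - f0) <= 10.0].sum()
            assert inband / power.sum() >= 0.90

    def test_center_freqs_sorted_and_in_range(self):
        x = make_triharmonic(FS, 1.0, noise_sigma=0.05, seed=2)
        res = vmd_decompose(x, VmdConfig(K=4))
        assert np.all(np.diff(res.center_freqs) >= 0)
        assert np.all((res.center_freqs >= 0) & (res.center_freqs < 0.5))

    def test_deterministic(self):
        x = make_triharmonic(FS, 1.0, noise_sigma=0.1, seed=9)
        cfg = VmdConfig(K=3, init="random", seed=4)
        r1 = vmd_decompose(x, cfg)
        r2 = vmd_decompose(x, cfg)
        assert np.array_equal(r1.modes, r2.modes)
        assert np.array_equal(r1.center_freqs, r2.center_freqs)

    def test_odd_length_handled(self):
        x = make_triharmonic(FS, 1.0)[:999]
        res = vmd_decompose(x, VmdConfig(K=3))
        assert res.modes.shape == (3, 999)
        assert np.all(np.abs(res.center_freqs_hz(FS) - TRI_FREQS) < 2.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            vmd_decompose(np.array([1.0, np.nan, 2.0, 0.0]), VmdConfig(K=1))
        with pytest.raises(ValueError, match="2K"):
            vmd_decompose(np.ones(5), VmdConfig(K=3))

    def test_dc_flag_pins_first_mode(self):
        t = np.arange(1000) / FS
        x = 2.0 + np.cos(2 * np.pi * 100 * t)
        res = vmd_decompose(x, VmdConfig(K=2, dc=True))
        assert res.center_freqs[0] == 0.0
        assert abs(res.center_freqs_hz(FS)[1] - 100.0) < 2.0
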