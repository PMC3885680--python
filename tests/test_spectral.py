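import numpy as np
import pytest

from fingerdecode import spectral
from fingerdecode.types import EpochSet, NormalizedSpectrumSet, SpectrumSet

FS = 250.0


def make_epochs(data, condition="movement", fs=FS):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return EpochSet(data, fs, condition,
                    np.full(n, "thumb", dtype=object), np.zeros(n),
                    [f"C{i}" for i in range(data.shape[1])])


def make_norm(lognorm, freqs):
    n = lognorm.shape[0]
    dummy = np.full(n, "movement", dtype=object)
    return NormalizedSpectrumSet(np.asarray(lognorm, dtype=float),
                                 np.asarray(freqs, dtype=float),
                                 np.ones(lognorm.shape[1:]), dummy,
                                 dummy.copy())


class TestPsdHanning:
    def test_sinusoid_bin_alignment(self):
        t = np.arange(250) / FS
        x = np.sin(2 * np.pi * 10 * t)[None, None, :]
        spec = spectral.psd_hanning(make_epochs(x), 125.0)
        assert spec.freqs[np.argmax(spec.psd[0, 0])] == 10.0

    def test_white_noise_flat(self, rng):
        x = rng.standard_normal((2000, 1, 250))
        spec = spectral.psd_hanning(make_epochs(x), 125.0)
        mean = spec.psd.mean(axis=0)[0]
        assert np.all(np.abs(mean / mean.mean() - 1) < 0.10)

    def test_matches_naive_dft(self, rng):
        # independent oracle: O(n^2) windowed DFT
        x = rng.standard_normal((2, 3, 250))
        spec = spectral.psd_hanning(make_epochs(x), 125.0)
        n = 250
        w = np.hanning(n)
        t = np.arange(n)
        for e in range(2):
            for c in range(3):
                for fi, f in enumerate(spec.freqs):
                    k = int(f)  # bin k corresponds to k Hz at fs=250, T=1 s
                    coef = np.sum(x[e, c] * w
                                  * np.exp(-2j * np.pi * k * t / n))
                    expect = np.abs(coef) ** 2 / (np.sum(w ** 2) * FS / 2)
                    assert spec.psd[e, c, fi] == pytest.approx(
                        expect, rel=1e-9, abs=1e-12)

    def test_grid_excludes_dc_and_nyquist(self):
        x = np.zeros((1, 1, 250)) + 1.0
        spec = spectral.psd_hanning(make_epochs(x), 125.0)
        assert spec.freqs[0] == 1.0
        assert spec.freqs[-1] == 124.0  # Nyquist bin dropped at fs=250

    def test_fmax_above_nyquist_rejected(self):
        x = np.zeros((1, 1, 250))
        with pytest.raises(ValueError):
            spectral.psd_hanning(make_epochs(x), 200.0)


class TestLogNormalize:
    def test_identical_epochs_zero(self):
        psd = np.ones((5, 2, 10))
        spec = SpectrumSet(psd, np.arange(1, 11, dtype=float),
                           np.full(5, "movement", dtype=object),
                           np.full(5, "thumb", dtype=object))
        norm = spectral.log_normalize(spec)
        assert np.allclose(norm.lognorm, 0.0)

    def test_hand_computed_single_cell(self):
        # one epoch with doubled power at one bin among 4 at baseline
        psd = np.ones((4, 1, 3))
        psd[0, 0, 1] = 2.0
        spec = SpectrumSet(psd, np.array([1.0, 2.0, 3.0]),
                           np.full(4, "movement", dtype=object),
                           np.full(4, "thumb", dtype=object))
        norm = spectral.log_normalize(spec)
        mean_factor = (2.0 + 3.0) / 4.0
        assert norm.lognorm[0, 0, 1] == pytest.approx(np.log(2 / mean_factor))
        assert norm.lognorm[1, 0, 1] == pytest.approx(np.log(1 / mean_factor))

    def test_exp_mean_identity(self, rng):
        psd = rng.uniform(0.5, 2.0, size=(20, 3, 8))
        spec = SpectrumSet(psd, np.arange(1, 9, dtype=float),
                           np.full(20, "rest", dtype=object),
                           np.full(20, "ring", dtype=object))
        norm = spectral.log_normalize(spec)
        assert np.allclose(np.exp(norm.lognorm).mean(axis=0), 1.0, atol=1e-9)

    def test_zero_bin_rejected(self):
        psd = np.ones((3, 1, 4))
        psd[1, 0, 2] = 0.0
        spec = SpectrumSet(psd, np.arange(1, 5, dtype=float),
                           np.full(3, "movement", dtype=object),
                           np.full(3, "thumb", dtype=object))
        with pytest.raises(ValueError, match="zero PSD"):
            spectral.log_normalize(spec)


class TestSpectralPCA:
    def test_planted_template_recovery(self, rng):
        freqs = np.arange(1.0, 41.0)
        template = np.exp(-0.5 * ((freqs - 20) / 5) ** 2)
        template /= np.linalg.norm(template)
        scalars = rng.standard_normal(300)
        x = (scalars[:, None] * template[None, :]
             + 0.05 * rng.standard_normal((300, 40)))[:, None, :]
        basis = spectral.spectral_pca(make_norm(x, freqs),
                                      exclude_line=False)
        pc1 = basis.eigvecs[0, :, 0]
        assert abs(np.corrcoef(pc1, template)[0, 1]) >= 0.99

    def test_covariance_matches_brute_force(self, rng):
        # 5 epochs x 10 bins toy, against an explicit outer-product sum
        x = rng.standard_normal((5, 1, 10))
        freqs = np.arange(1.0, 11.0)
        basis = spectral.spectral_pca(make_norm(x, freqs), exclude_line=False)
        xc = x[:, 0, :] - x[:, 0, :].mean(axis=0)
        brute = sum(np.outer(row, row) for row in xc) / 4.0
        recon = (basis.eigvecs[0] * basis.eigvals[0]) @ basis.eigvecs[0].T
        assert np.allclose(recon, brute, atol=1e-9)

    def test_projection_completeness(self, rng):
        x = rng.standard_normal((12, 2, 9))
        freqs = np.arange(1.0, 10.0)
        basis = spectral.spectral_pca(make_norm(x, freqs), exclude_line=False)
        for c in range(2):
            centered = x[:, c, :] - x[:, c, :].mean(axis=0)
            recon = basis.weights[:, c, :] @ basis.eigvecs[c].T
            assert np.allclose(recon, centered, atol=1e-9)

    def test_eigenvalue_sum_equals_trace(self, rng):
        x = rng.standard_normal((30, 3, 15))
        freqs = np.arange(1.0, 16.0)
        basis = spectral.spectral_pca(make_norm(x, freqs), exclude_line=False)
        for c in range(3):
            xc = x[:, c, :] - x[:, c, :].mean(axis=0)
            trace = np.trace(xc.T @ xc / 29.0)
            assert basis.eigvals[c].sum() == pytest.approx(trace, rel=1e-8)

    def test_projection_variance_equals_eigenvalue(self, rng):
        x = rng.standard_normal((40, 2, 12))
        freqs = np.arange(1.0, 13.0)
        basis = spectral.spectral_pca(make_norm(x, freqs), exclude_line=False)
        var = basis.weights.var(axis=0, ddof=1)  # (channels, k)
        assert np.allclose(var, basis.eigvals, rtol=1e-6)

    def test_planted_two_component_subspace(self, rng):
        from scipy.linalg import subspace_angles
        freqs = np.arange(1.0, 61.0)
        flat = np.ones(60) / np.sqrt(60)
        rhythm = np.exp(-0.5 * ((freqs - 10) / 2) ** 2)
        rhythm -= (rhythm @ flat) * flat  # orthogonalize
        rhythm /= np.linalg.norm(rhythm)
        a = rng.standard_normal(300) * 1.0
        b = rng.standard_normal(300) * 0.6
        x = (np.outer(a, flat) + np.outer(b, rhythm)
             + 0.02 * rng.standard_normal((300, 60)))[:, None, :]
        basis = spectral.spectral_pca(make_norm(x, freqs), exclude_line=False)
        span = basis.eigvecs[0, :, :2]
        for template in (flat, rhythm):
            ang = subspace_angles(span, template[:, None]).max()
            assert np.degrees(ang) < 5.0

    def test_null_no_broadband_pc(self, rng):
        x = rng.standard_normal((100, 1, 50))
        freqs = np.arange(1.0, 51.0)
        basis = spectral.spectral_pca(make_norm(x, freqs), exclude_line=False)
        flat = np.ones(50) / np.sqrt(50)
        corr = np.abs(basis.eigvecs[0].T @ flat)
        assert corr.max() < 0.8

    def test_sign_convention_and_order(self, rng):
        x = rng.standard_normal((25, 2, 10))
        basis = spectral.spectral_pca(make_norm(x, np.arange(1.0, 11.0)),
                                      exclude_line=False)
        assert np.all(np.diff(basis.eigvals, axis=1) <= 1e-12)
        assert np.all(basis.eigvecs.sum(axis=1) >= -1e-9)

    def test_line_bins_excluded_by_default(self, rng):
        x = rng.standard_normal((10, 1, 124))
        freqs = np.arange(1.0, 125.0)
        basis = spectral.spectral_pca(make_norm(x, freqs))
        assert not np.any((np.abs(basis.freqs - 60) <= 3)
                          | (np.abs(basis.freqs - 120) <= 3))

    def test_nan_rejected(self):
        x = np.zeros((3, 1, 5))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            spectral.spectral_pca(make_norm(x, np.arange(1.0, 6.0)),
                                  exclude_line=False)


class TestBandPower:
    def flat_spec(self, value=2.0):
        psd = np.full((3, 2, 50), value)
        return SpectrumSet(psd, np.arange(1.0, 51.0),
                           np.full(3, "movement", dtype=object),
                           np.full(3, "index", dtype=object))

    def test_flat_spectrum_log_value(self):
        spec = self.flat_spec(2.0)
        for band in ((8, 12), (13, 30), (40, 50)):
            feats = spectral.band_power_features(spec, band)
            assert np.allclose(feats, np.log(2.0))

    def test_alpha_oscillator_beats_white(self, rng):
        from fingerdecode.synth import narrowband_noise
        osc = np.stack([narrowband_noise(rng, 250, FS, 10.0, 1.0)
                        for _ in range(20)])[:, None, :]  # unit power
        white = rng.standard_normal((20, 1, 250))
        white *= 1.0 / white.std(axis=-1, keepdims=True)
        alpha_e = make_epochs(osc)
        white_e = make_epochs(white)
        fa = spectral.band_power_features(
            spectral.psd_hanning(alpha_e, 125.0), (8, 12)).mean()
        fw = spectral.band_power_features(
            spectral.psd_hanning(white_e, 125.0), (8, 12)).mean()
        assert fa > fw

    def test_gamma_ignores_low_bins(self):
        spec = self.flat_spec()
        before = spectral.band_power_features(spec, (40, 50))
        spec.psd[:, :, 9] *= 100.0  # 10 Hz bin
        after = spectral.band_power_features(spec, (40, 50))
        assert np.array_equal(before, after)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            spectral.band_power_features(self.flat_spec(), (60.5, 60.9))
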