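"""Spectral estimation and per-channel spectral principal components.

The analysis grid is integer frequencies 1..f_max Hz (1 Hz resolution from
the 1 s Hanning window); DC is excluded.  Power at each bin is the squared
magnitude of the windowed Fourier coefficient.

The decoupling step eigendecomposes, per channel, the frequency-by-frequency
covariance of log-normalized single-epoch spectra across epochs; projection
weights of epochs onto the leading components are the downstream features.
"""
from __future__ import annotations

import numpy as np

from .types import (EpochSet, NormalizedSpectrumSet, SpectralBasis,
                    SpectrumSet)

__all__ = ["psd_hanning", "log_normalize", "spectral_pca",
           "band_power_features", "line_bin_mask", "concat_spectra"]


def analysis_grid(fs: float, f_max: float) -> np.ndarray:
    """Integer-Hz grid 1..f_max, excluding DC and the Nyquist bin.

    The Nyquist coefficient of a real FFT is real-valued, so its power has a
    different sampling distribution than interior bins and would otherwise
    dominate a log-power covariance; it is dropped from the analysis grid.
    """
    if f_max > fs / 2:
        raise ValueError("f_max above Nyquist")
    top = int(f_max)
    if top >= fs / 2:
        top = int(fs / 2) - 1
    return np.arange(1, top + 1, dtype=float)


def psd_hanning(epochs: EpochSet, f_max: float) -> SpectrumSet:
    """Hanning-windowed periodogram at integer frequencies 1..f_max Hz."""
    fs = epochs.fs
    n = epochs.epochs.shape[-1]
    if n != int(round(fs * epochs.window_s)) or epochs.window_s != 1.0:
        raise ValueError("epochs must be 1 s long")
    freqs = analysis_grid(fs, f_max)
    window = np.hanning(n)
    coef = np.fft.rfft(epochs.epochs * window, axis=-1)
    psd = (np.abs(coef) ** 2) / (np.sum(window ** 2) * fs / 2.0)
    psd = psd[..., 1:freqs.size + 1]
    cond = np.full(len(epochs), epochs.condition, dtype=object)
    return SpectrumSet(psd, freqs, cond, epochs.fingers.copy())


def concat_spectra(*sets: SpectrumSet) -> SpectrumSet:
    """Stack epoch axes of spectra sharing the same grid."""
    base = sets[0]
    for s in sets[1:]:
        if not np.array_equal(s.freqs, base.freqs):
            raise ValueError("frequency grids differ")
    return SpectrumSet(np.concatenate([s.psd for s in sets]),
                       base.freqs,
                       np.concatenate([s.condition for s in sets]),
                       np.concatenate([s.fingers for s in sets]))


def log_normalize(spectra: SpectrumSet,
                  ensemble_mean: np.ndarray | None = None
                  ) -> NormalizedSpectrumSet:
    """``log(psd / ensemble_mean)`` per channel and frequency.

    The normalizer defaults to the arithmetic mean over the epochs of the
    given (grouped) set; pass a precomputed ``ensemble_mean`` to normalize
    held-out epochs with a training-set normalizer.
    """
    if np.any(spectra.psd == 0):
        raise ValueError("zero PSD bin: degenerate input")
    if ensemble_mean is None:
        ensemble_mean = spectra.psd.mean(axis=0)
    if np.any(ensemble_mean <= 0):
        raise ValueError("non-positive ensemble mean")
    lognorm = np.log(spectra.psd / ensemble_mean)
    return NormalizedSpectrumSet(lognorm, spectra.freqs.copy(),
                                 np.asarray(ensemble_mean, dtype=float),
                                 spectra.condition.copy(),
                                 spectra.fingers.copy())


def line_bin_mask(freqs: np.ndarray, line_freq: float = 60.0,
                  half_width: float = 3.0,
                  harmonics: bool = True) -> np.ndarray:
    """Boolean mask of bins to KEEP (True) after excluding line-noise bins."""
    keep = np.ones(freqs.size, dtype=bool)
    f0 = line_freq
    while f0 <= freqs.max() + half_width:
        keep &= np.abs(freqs - f0) > half_width
        if not harmonics:
            break
        f0 += line_freq
    return keep


def spectral_pca(norm: NormalizedSpectrumSet,
                 exclude_line: bool = True,
                 line_freq: float = 60.0,
                 n_components: int | None = None) -> SpectralBasis:
    """Per-channel PCA of log-normalized spectra across epochs.

    Covariance uses epoch-mean-centered data with an ``M - 1`` denominator.
    Components are sorted by descending eigenvalue and sign-fixed so each
    component's mean over frequencies is non-negative.  Projection weights
    are inner products of centered epochs with each component; restricting
    ``n_components`` truncates the stored eigenvectors/weights (eigenvalues
    are always returned in full so their sum equals the covariance trace).
    """
    if np.any(~np.isfinite(norm.lognorm)):
        raise ValueError("NaN/inf in log-normalized spectra")
    m = len(norm)
    if m < 2:
        raise ValueError("need at least 2 epochs for PCA")
    keep = (line_bin_mask(norm.freqs, line_freq) if exclude_line
            else np.ones(norm.freqs.size, dtype=bool))
    x = norm.lognorm[:, :, keep]  # (epochs, channels, bins)
    freqs = norm.freqs[keep]
    mean = x.mean(axis=0)  # (channels, bins)
    xc = x - mean
    # covariance per channel: (bins, bins)
    cov = np.einsum("ecf,ecg->cfg", xc, xc) / (m - 1)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    vals = np.ascontiguousarray(vals[:, ::-1])
    vecs = np.ascontiguousarray(vecs[:, :, ::-1])
    # sign fix: mean over frequencies >= 0
    sign = np.where(vecs.sum(axis=1, keepdims=True) >= 0, 1.0, -1.0)
    vecs = vecs * sign
    if n_components is not None:
        vecs = vecs[:, :, :n_components]
    weights = np.einsum("ecf,cfk->eck", xc, vecs)
    return SpectralBasis(vals, vecs, mean, weights, freqs,
                         norm.condition.copy(), norm.fingers.copy())


def project(basis: SpectralBasis, norm: NormalizedSpectrumSet,
            exclude_line: bool = True, line_freq: float = 60.0) -> np.ndarray:
    """Project (held-out) log-normalized epochs onto a fitted basis."""
    keep = (line_bin_mask(norm.freqs, line_freq) if exclude_line
            else np.ones(norm.freqs.size, dtype=bool))
    x = norm.lognorm[:, :, keep] - basis.mean
    return np.einsum("ecf,cfk->eck", x, basis.eigvecs)


def band_power_features(spectra: SpectrumSet,
                        band: tuple[float, float]) -> np.ndarray:
    """Mean log-power over the band's bins, per epoch and channel."""
    sel = (spectra.freqs >= band[0]) & (spectra.freqs <= band[1])
    if not np.any(sel):
        raise ValueError(f"band {band} does not intersect frequency grid")
    return np.log(spectra.psd[:, :, sel]).mean(axis=-1)
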