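"""Core containers shared across the pipeline.

All signal amplitudes are in microvolts unless noted otherwise; times are in
seconds; channel-major array layout is ``(channels, samples)`` for continuous
data and ``(epochs, channels, samples)`` for epoched data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FINGERS = ("thumb", "index", "middle", "ring", "little")

#: Trial phase layout in seconds: blank, fixation, cue.
BLANK_S = 2.0
FIXATION_S = 2.0
CUE_S = 2.0
TRIAL_S = BLANK_S + FIXATION_S + CUE_S


@dataclass
class Recording:
    """Continuous multichannel recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names.
    reference : {"original", "car"}
        Referencing state; set to ``"car"`` by
        :func:`fingerdecode.preprocess.common_average_reference`.
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "original"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.reference not in ("original", "car"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialTable:
    """Per-trial event onsets and the cued finger.

    Each trial consists of a blank window, a fixation window (the resting
    condition) and a cue window during which the named finger is moved.
    """

    blank_onset_s: np.ndarray
    fixation_onset_s: np.ndarray
    cue_onset_s: np.ndarray
    cue_duration_s: np.ndarray
    finger: np.ndarray  # dtype str

    def __post_init__(self) -> None:
        self.blank_onset_s = np.asarray(self.blank_onset_s, dtype=float)
        self.fixation_onset_s = np.asarray(self.fixation_onset_s, dtype=float)
        self.cue_onset_s = np.asarray(self.cue_onset_s, dtype=float)
        self.cue_duration_s = np.asarray(self.cue_duration_s, dtype=float)
        self.finger = np.asarray(self.finger, dtype=object)
        n = len(self.cue_onset_s)
        for arr in (self.blank_onset_s, self.fixation_onset_s,
                    self.cue_duration_s, self.finger):
            if len(arr) != n:
                raise ValueError("trial table columns must have equal length")

    def __len__(self) -> int:
        return len(self.cue_onset_s)

    @property
    def cue_end_s(self) -> np.ndarray:
        return self.cue_onset_s + self.cue_duration_s


@dataclass
class EventSet:
    """Detected (or planted) movement peaks.

    ``provenance`` records how the events were obtained: ``"bipolar"`` for the
    potential-difference detector, ``"glove"`` for the position detector and
    ``"ground_truth"`` for events planted by the generator.
    """

    times_s: np.ndarray
    fingers: np.ndarray
    trials: np.ndarray
    amplitudes: np.ndarray
    provenance: str = "bipolar"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.fingers = np.asarray(self.fingers, dtype=object)
        self.trials = np.asarray(self.trials, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        n = len(self.times_s)
        if not (len(self.fingers) == len(self.trials) == len(self.amplitudes) == n):
            raise ValueError("event columns must have equal length")

    def __len__(self) -> int:
        return len(self.times_s)

    def for_finger(self, finger: str) -> "EventSet":
        m = self.fingers == finger
        return EventSet(self.times_s[m], self.fingers[m], self.trials[m],
                        self.amplitudes[m], self.provenance)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.fingers:
            out[f] = out.get(f, 0) + 1
        return out


@dataclass
class EpochSet:
    """Fixed-length windows cut around movement peaks or rest centers."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_times)
    fs: float
    condition: str  # "movement" | "rest"
    fingers: np.ndarray
    centers_s: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    window_s: float = 1.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.fingers = np.asarray(self.fingers, dtype=object)
        self.centers_s = np.asarray(self.centers_s, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (epochs, channels, samples)")
        if self.condition not in ("movement", "rest"):
            raise ValueError(f"unknown condition {self.condition!r}")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    def for_finger(self, finger: str) -> "EpochSet":
        m = self.fingers == finger
        return EpochSet(self.epochs[m], self.fs, self.condition,
                        self.fingers[m], self.centers_s[m],
                        self.channel_labels, self.window_s)


@dataclass
class SpectrumSet:
    """Per-epoch, per-channel power spectral densities on a shared grid."""

    psd: np.ndarray  # (n_epochs, n_channels, n_freqs)
    freqs: np.ndarray  # Hz
    condition: np.ndarray  # per-epoch "movement"/"rest"
    fingers: np.ndarray

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.fingers = np.asarray(self.fingers, dtype=object)
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def __len__(self) -> int:
        return self.psd.shape[0]

    @property
    def n_channels(self) -> int:
        return self.psd.shape[1]


@dataclass
class NormalizedSpectrumSet:
    """Log-normalized spectra: ``log(psd / ensemble_mean)`` elementwise."""

    lognorm: np.ndarray  # (n_epochs, n_channels, n_freqs)
    freqs: np.ndarray
    ensemble_mean: np.ndarray  # (n_channels, n_freqs)
    condition: np.ndarray
    fingers: np.ndarray

    def __len__(self) -> int:
        return self.lognorm.shape[0]


@dataclass
class SpectralBasis:
    """Per-channel eigendecomposition of the frequency covariance.

    ``eigvecs[c, :, k]`` is the k-th principal component of channel ``c`` on
    the grid ``freqs`` (possibly with line-noise bins excluded); eigenvalues
    are sorted descending.  ``weights[e, c, k]`` is the projection of the
    mean-centered log-normalized spectrum of epoch ``e`` onto component ``k``.
    """

    eigvals: np.ndarray  # (n_channels, n_freqs_kept)
    eigvecs: np.ndarray  # (n_channels, n_freqs_kept, n_freqs_kept)
    mean: np.ndarray  # (n_channels, n_freqs_kept) centering offset
    weights: np.ndarray  # (n_epochs, n_channels, n_components)
    freqs: np.ndarray
    condition: np.ndarray
    fingers: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.eigvals.shape[0]
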