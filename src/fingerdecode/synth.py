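"""Synthetic recordings with planted movement-related spectral structure.

The generator emulates the statistical structure the analysis assumes:

* trial layout of blank (2 s), fixation (2 s), cue (2 s) windows;
* ``1/f`` Gaussian background on every channel;
* alpha and beta rhythms (narrowband noise oscillators) that desynchronize
  during cue windows on a contiguous "signal" channel subset;
* a finger-specific multiplicative broadband power increase on the signal
  channels during cues, spatially weighted by a smooth per-finger profile;
* bipolar kinematic traces with ~1 Hz flexion peaks exceeding the detector
  threshold only during cues of the corresponding finger.

Ground-truth events and templates are returned so downstream stages can be
scored against what was planted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (BLANK_S, CUE_S, FINGERS, FIXATION_S, TRIAL_S, EventSet,
                    Recording, TrialTable)

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset",
           "synth_kinematic_trace"]

# Peaks (after jitter) stay >= 0.5 s from both cue edges so that a 1 s
# analysis epoch centered at any peak lies fully inside the cue and the
# detector's latency (0.4 s) and tail-exclusion (0.5 s) rules are met.
_PEAK_MARGIN_S = 0.5
_PEAK_MIN_SEP_S = 0.2  # detector's minimum peak separation


@dataclass
class SynthConfig:
    """Knobs of the synthetic dataset.

    ``broadband_gain`` maps finger name to the multiplicative PSD factor
    (>= 1) applied on signal channels while that finger's cue is on; a scalar
    is broadcast to all fingers.  ``erd_depth`` is the fractional reduction of
    rhythm *power* during cues.  Effect sizes are tuning knobs, not measured
    quantities.
    """

    n_channels: int = 64
    fs: float = 250.0
    trials_per_finger: int = 60
    fingers: tuple[str, ...] = FINGERS
    background_exponent: float = 1.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    erd_depth: float = 0.5
    broadband_gain: object = 2.0  # scalar or {finger: gain}
    signal_channels: tuple[int, ...] = tuple(range(27, 37))
    peak_amplitude_uv: float = 300.0
    peaks_per_cue: int = 2
    seed: int = 0
    # secondary shape parameters
    bg_sigma_uv: float = 10.0
    alpha_amp_uv: float = 14.0
    beta_amp_uv: float = 9.0
    slow_gain_sigma: float = 0.2
    kin_noise_uv: float = 3.0
    spatial_floor: float = 0.7
    spatial_offset: float = 2.0
    peak_jitter_s: float = 0.08
    cue_duration_s: float = CUE_S

    def __post_init__(self) -> None:
        if self.fs not in (250.0, 1000.0, 250, 1000):
            raise ValueError("fs must be 250 or 1000 Hz")
        nyq = self.fs / 2
        for band in (self.alpha_band, self.beta_band):
            if not (0 < band[0] < band[1] < nyq):
                raise ValueError(f"band {band} outside (0, fs/2)")
        if self.alpha_band[1] > self.beta_band[0]:
            raise ValueError("alpha and beta bands must be disjoint")
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must be in [0, 1]")
        gains = self.gain_map()
        if any(g < 1 for g in gains.values()):
            raise ValueError("broadband_gain must be >= 1")
        if any(not 0 <= c < self.n_channels for c in self.signal_channels):
            raise ValueError("signal_channels outside channel range")
        margin = _PEAK_MARGIN_S + self.peak_jitter_s
        layout = (2 * margin + (self.peaks_per_cue - 1)
                  * (_PEAK_MIN_SEP_S + 2 * self.peak_jitter_s))
        if self.cue_duration_s < layout:
            raise ValueError(
                f"cue of {self.cue_duration_s} s too short for "
                f"{self.peaks_per_cue} peaks (needs >= {layout} s)")

    def gain_map(self) -> dict[str, float]:
        if isinstance(self.broadband_gain, dict):
            missing = set(self.fingers) - set(self.broadband_gain)
            if missing:
                raise ValueError(f"broadband_gain missing fingers {missing}")
            return {f: float(self.broadband_gain[f]) for f in self.fingers}
        return {f: float(self.broadband_gain) for f in self.fingers}

    @property
    def n_trials(self) -> int:
        return self.trials_per_finger * len(self.fingers)


@dataclass
class GroundTruth:
    """What was planted: events, spectral templates, spatial weights."""

    events: EventSet
    broadband_template: np.ndarray  # unit norm, flat, on `freqs`
    rhythm_template: np.ndarray  # unit norm, alpha/beta-peaked, on `freqs`
    freqs: np.ndarray
    spatial_weights: dict[str, np.ndarray] = field(default_factory=dict)


def spatial_weight_profile(config: SynthConfig) -> dict[str, np.ndarray]:
    """Smooth unimodal weight over the signal channels, per finger.

    A Gaussian bump with floor ``spatial_floor``; finger-specific centers are
    offset by ``spatial_offset`` channel indices so the topographies overlap
    but differ.  Weights are zero off the signal set.
    """
    s = len(config.signal_channels)
    idx = np.arange(s, dtype=float)
    sigma = max(s / 4.5, 1.0)
    weights: dict[str, np.ndarray] = {}
    mid = (len(config.fingers) - 1) / 2
    for i, f in enumerate(config.fingers):
        center = (s - 1) / 2 + (i - mid) * config.spatial_offset
        bump = np.exp(-0.5 * ((idx - center) / sigma) ** 2)
        w = np.zeros(config.n_channels)
        w[list(config.signal_channels)] = (
            config.spatial_floor + (1 - config.spatial_floor) * bump)
        weights[f] = w
    return weights


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   shape_fn) -> np.ndarray:
    """Unit-variance Gaussian noise with amplitude spectrum ``shape_fn(f)``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = shape_fn(f)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(rng: np.random.Generator, n: int, fs: float,
               exponent: float) -> np.ndarray:
    def shape(f):
        g = np.zeros_like(f)
        nz = f > 0
        g[nz] = f[nz] ** (-exponent / 2.0)
        return g
    return _colored_noise(rng, n, fs, shape)


def narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                     f0: float, sigma_f: float) -> np.ndarray:
    def shape(f):
        return np.exp(-0.5 * ((f - f0) / sigma_f) ** 2)
    return _colored_noise(rng, n, fs, shape)


def synth_kinematic_trace(event_times_s: np.ndarray, fs: float,
                          n_samples: int,
                          peak_amplitude_uv: float = 300.0) -> np.ndarray:
    """Near-zero trace with one dominant ~1 Hz extremum per event.

    Each event contributes a Gaussian-windowed 1 Hz cosine pulse whose energy
    is concentrated in 0.5-2 Hz, so the detector's band-pass preserves the
    peak.  Events closer than 200 ms would overlap into a single lobe and are
    rejected.
    """
    times = np.asarray(event_times_s, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    if times.size and np.any(np.diff(times) < 0.2):
        raise ValueError("events closer than 200 ms violate detector assumptions")
    trace = np.zeros(n_samples)
    sigma_s = 0.26  # keeps >200 uV through the 0.5-2 Hz band-pass at A=300
    half = int(round(0.75 * fs))
    for j, t0 in enumerate(times):
        c = int(round(t0 * fs))
        lo, hi = max(0, c - half), min(n_samples, c + half + 1)
        t = (np.arange(lo, hi) - t0 * fs) / fs
        # alternating polarity (flexion/extension) keeps side lobes of
        # consecutive pulses from summing into a spurious mid-gap extremum
        sign = 1.0 if j % 2 == 0 else -1.0
        trace[lo:hi] += (sign * peak_amplitude_uv
                         * np.exp(-0.5 * (t / sigma_s) ** 2)
                         * np.cos(2 * np.pi * 1.0 * t))
    return trace


def _plant_events(rng: np.random.Generator, table: TrialTable,
                  config: SynthConfig) -> EventSet:
    times, fingers, trials = [], [], []
    k = config.peaks_per_cue
    for i in range(len(table)):
        cue = table.cue_onset_s[i]
        dur = table.cue_duration_s[i]
        lo = cue + _PEAK_MARGIN_S + config.peak_jitter_s
        hi = cue + dur - _PEAK_MARGIN_S - config.peak_jitter_s
        if k == 1:
            base = np.array([(lo + hi) / 2])
        else:
            base = np.linspace(lo, hi, k)
        jit = rng.uniform(-config.peak_jitter_s, config.peak_jitter_s, size=k)
        for t in base + jit:
            times.append(t)
            fingers.append(table.finger[i])
            trials.append(i)
    amps = np.full(len(times), float(config.peak_amplitude_uv))
    return EventSet(np.array(times), np.array(fingers, dtype=object),
                    np.array(trials), amps, provenance="ground_truth")


def make_trial_table(config: SynthConfig,
                     rng: np.random.Generator) -> TrialTable:
    order = np.repeat(np.array(config.fingers, dtype=object),
                      config.trials_per_finger)
    rng.shuffle(order)
    starts = np.arange(config.n_trials) * TRIAL_S
    return TrialTable(blank_onset_s=starts,
                      fixation_onset_s=starts + BLANK_S,
                      cue_onset_s=starts + BLANK_S + FIXATION_S,
                      cue_duration_s=np.full(config.n_trials,
                                             config.cue_duration_s),
                      finger=order)


def generate_dataset(config: SynthConfig):
    """Generate ``(Recording, kinematic traces, TrialTable, GroundTruth)``.

    Deterministic for a fixed config (including seed): identical calls return
    bit-identical arrays.
    """
    rng = np.random.default_rng(config.seed)
    fs = float(config.fs)
    table = make_trial_table(config, rng)
    n = int(round(config.n_trials * TRIAL_S * fs))
    events = _plant_events(rng, table, config)
    weights = spatial_weight_profile(config)
    gains = config.gain_map()

    # per-trial cue sample ranges
    cue_slices = [slice(int(round(table.cue_onset_s[i] * fs)),
                        int(round(table.cue_end_s[i] * fs)))
                  for i in range(len(table))]

    # common slow broadband gain fluctuation (log-amplitude, <0.2 Hz)
    slow = _colored_noise(rng, n, fs,
                          lambda f: np.exp(-0.5 * (f / 0.1) ** 2))
    slow_gain = np.exp(config.slow_gain_sigma * slow)

    a_lo, a_hi = config.alpha_band
    b_lo, b_hi = config.beta_band
    sig_set = set(config.signal_channels)

    samples = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        bg = pink_noise(rng, n, fs, config.background_exponent)
        alpha = narrowband_noise(rng, n, fs, (a_lo + a_hi) / 2,
                                 (a_hi - a_lo) / 4)
        beta = narrowband_noise(rng, n, fs, (b_lo + b_hi) / 2,
                                (b_hi - b_lo) / 4)
        bb_env = np.ones(n)
        erd_env = np.ones(n)
        if c in sig_set:
            for i, sl in enumerate(cue_slices):
                f = table.finger[i]
                w = weights[f][c]
                g = gains[f]
                bb_env[sl] = g ** (w / 2.0)  # amplitude scale -> PSD x g^w
                erd_env[sl] = np.sqrt(1.0 - config.erd_depth * w)
        # broadband gain and the slow common gain multiply the *total*
        # signal so the broadband log-power mode is exactly flat across
        # frequency; ERD scales the rhythm components on top of it
        samples[c] = ((config.bg_sigma_uv * bg
                       + config.alpha_amp_uv * alpha * erd_env
                       + config.beta_amp_uv * beta * erd_env)
                      * bb_env * slow_gain)

    labels = [f"CH{c:03d}" for c in range(config.n_channels)]
    recording = Recording(samples, fs, labels, reference="original")

    kin: dict[str, np.ndarray] = {}
    for f in config.fingers:
        ev = events.for_finger(f)
        trace = synth_kinematic_trace(ev.times_s, fs, n,
                                      config.peak_amplitude_uv)
        trace += config.kin_noise_uv * rng.standard_normal(n)
        kin[f] = trace

    from .spectral import analysis_grid
    freqs = analysis_grid(fs, min(125.0, fs / 2))
    flat = np.ones_like(freqs)
    flat /= np.linalg.norm(flat)
    rhythm = (np.exp(-0.5 * ((freqs - (a_lo + a_hi) / 2)
                             / ((a_hi - a_lo) / 4)) ** 2)
              + np.exp(-0.5 * ((freqs - (b_lo + b_hi) / 2)
                               / ((b_hi - b_lo) / 4)) ** 2))
    rhythm /= np.linalg.norm(rhythm)
    truth = GroundTruth(events=events, broadband_template=flat,
                        rhythm_template=rhythm, freqs=freqs,
                        spatial_weights=weights)
    return recording, kin, table, truth
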