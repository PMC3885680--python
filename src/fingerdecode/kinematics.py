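"""Movement-peak detection from bipolar sensor or data-glove traces.

Detection criteria for bipolar traces (applied per cue window on the
0.5-2 Hz band-passed absolute trace):

1. peak amplitude >= ``amp_threshold`` (default 200 uV);
2. peak at least ``min_latency_ms`` (400 ms) after cue onset;
3. peaks in the last ``tail_exclusion_ms`` (500 ms) of the cue are discarded;
4. peaks at least ``min_separation_ms`` (200 ms) apart; among multiple peaks
   inside a ``merge_window_ms`` (400 ms) window only the strongest survives
   (ties keep the earlier peak).

The glove variant uses a position threshold (default 2, glove units) instead
of band-pass filtering and is not trial-anchored.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import EventSet, TrialTable

__all__ = ["DetectorParams", "bandpass_kinematic", "detect_peaks",
           "detect_peaks_glove"]


@dataclass
class DetectorParams:
    band: tuple[float, float] = (0.5, 2.0)
    amp_threshold: float = 200.0
    min_latency_ms: float = 400.0
    tail_exclusion_ms: float = 500.0
    min_separation_ms: float = 200.0
    merge_window_ms: float = 400.0

    def __post_init__(self) -> None:
        for v in (self.amp_threshold, self.min_latency_ms,
                  self.tail_exclusion_ms, self.min_separation_ms,
                  self.merge_window_ms):
            if v <= 0:
                raise ValueError("detector parameters must be positive")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("invalid band")


def bandpass_kinematic(trace: np.ndarray, fs: float,
                       band: tuple[float, float] = (0.5, 2.0),
                       order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a single kinematic trace."""
    trace = np.asarray(trace, dtype=float)
    if fs <= 2 * band[1]:
        raise ValueError("fs must exceed twice the upper band edge")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    # transient scale of the low corner; require enough samples to pad
    padlen = min(trace.size - 1, int(3 * fs / band[0]))
    if trace.size <= 3 * (2 * sos.shape[0] + 1):
        raise ValueError("trace too short for stable zero-phase filtering")
    return signal.sosfiltfilt(sos, trace, padtype="odd", padlen=padlen)


def _merge_peaks(idx: np.ndarray, amps: np.ndarray,
                 merge_samples: int) -> np.ndarray:
    """Keep the strongest peak among any group closer than the merge window.

    Greedy elimination: while two surviving peaks are within the window, drop
    the weaker (the later one on exact ties).  Deterministic.
    """
    keep = list(range(len(idx)))
    changed = True
    while changed:
        changed = False
        for j in range(len(keep) - 1):
            a, b = keep[j], keep[j + 1]
            if idx[b] - idx[a] < merge_samples:
                # drop the weaker; tie -> keep the earlier
                drop = b if amps[b] <= amps[a] else a
                keep.remove(drop)
                changed = True
                break
    return np.array(keep, dtype=int)


def _scan_window(absx: np.ndarray, fs: float, lo: int, hi: int,
                 params: DetectorParams) -> tuple[np.ndarray, np.ndarray]:
    """Candidate peaks of |x| in [lo, hi) honoring all four criteria."""
    seg = absx[lo:hi]
    min_sep = max(1, int(round(params.min_separation_ms / 1000 * fs)))
    pk, props = signal.find_peaks(seg, height=params.amp_threshold,
                                  distance=min_sep)
    if pk.size == 0:
        return pk, np.empty(0)
    merge = int(round(params.merge_window_ms / 1000 * fs))
    kept = _merge_peaks(pk, props["peak_heights"], merge)
    return pk[kept] + lo, props["peak_heights"][kept]


def detect_peaks(trace: np.ndarray, fs: float, table: TrialTable,
                 params: DetectorParams | None = None,
                 finger: str | None = None,
                 already_filtered: bool = False,
                 exclude_trials: set[int] | None = None) -> EventSet:
    """Detect movement peaks of one bipolar trace within its cue windows.

    ``finger`` restricts detection to trials cueing that finger (the trace
    belongs to one finger's sensor pair); ``exclude_trials`` models trials
    discarded after review.  Peaks are local maxima of the absolute
    band-passed trace.
    """
    params = params or DetectorParams()
    if len(table) == 0:
        raise ValueError("empty trial table")
    order = np.argsort(table.cue_onset_s)
    ends = table.cue_end_s[order]
    if np.any(table.cue_onset_s[order][1:] < ends[:-1]):
        raise ValueError("overlapping trials")
    x = np.asarray(trace, dtype=float)
    if not already_filtered:
        x = bandpass_kinematic(x, fs, params.band)
    absx = np.abs(x)

    times, fingers, trials, amps = [], [], [], []
    for i in range(len(table)):
        if exclude_trials and i in exclude_trials:
            continue
        if finger is not None and table.finger[i] != finger:
            continue
        lo_t = table.cue_onset_s[i] + params.min_latency_ms / 1000
        hi_t = table.cue_end_s[i] - params.tail_exclusion_ms / 1000
        lo = int(np.ceil(lo_t * fs))
        hi = int(np.floor(hi_t * fs)) + 1
        if hi <= lo:
            continue
        pk, heights = _scan_window(absx, fs, lo, min(hi, x.size), params)
        for p, h in zip(pk, heights):
            times.append(p / fs)
            fingers.append(table.finger[i])
            trials.append(i)
            amps.append(h)
    return EventSet(np.array(times), np.array(fingers, dtype=object),
                    np.array(trials, dtype=int), np.array(amps),
                    provenance="bipolar")


def detect_all_fingers(traces: dict[str, np.ndarray], fs: float,
                       table: TrialTable,
                       params: DetectorParams | None = None,
                       exclude_trials: set[int] | None = None) -> EventSet:
    """Run :func:`detect_peaks` per finger trace and merge chronologically."""
    parts = [detect_peaks(traces[f], fs, table, params, finger=f,
                          exclude_trials=exclude_trials)
             for f in traces]
    times = np.concatenate([p.times_s for p in parts])
    fingers = np.concatenate([p.fingers for p in parts])
    trials = np.concatenate([p.trials for p in parts])
    amps = np.concatenate([p.amplitudes for p in parts])
    order = np.argsort(times, kind="stable")
    return EventSet(times[order], fingers[order], trials[order], amps[order],
                    provenance="bipolar")


def detect_peaks_glove(position: np.ndarray, fs: float,
                       params: DetectorParams | None = None,
                       threshold: float = 2.0) -> EventSet:
    """Glove-position variant: threshold crossing peaks >= 200 ms apart.

    A constant trace yields an empty event set.  Plateaus produce a single
    peak (the first sample of maximal height in the plateau).
    """
    params = params or DetectorParams(amp_threshold=threshold)
    x = np.asarray(position, dtype=float)
    min_sep = max(1, int(round(params.min_separation_ms / 1000 * fs)))
    pk, props = signal.find_peaks(x, height=threshold, distance=min_sep,
                                  plateau_size=1)
    if pk.size == 0:
        # find_peaks misses plateaus touching the edges and strictly flat
        # maxima only when the whole trace is constant
        return EventSet(np.empty(0), np.empty(0, dtype=object),
                        np.empty(0, dtype=int), np.empty(0),
                        provenance="glove")
    heights = props["peak_heights"]
    merge = int(round(params.merge_window_ms / 1000 * fs))
    kept = _merge_peaks(pk, heights, merge)
    pk, heights = pk[kept], heights[kept]
    return EventSet(pk / fs, np.full(pk.size, "unknown", dtype=object),
                    np.zeros(pk.size, dtype=int), heights,
                    provenance="glove")
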