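"""Sniff-cycle extraction from intranasal thermistor traces.

Inhalation onsets are troughs of the (cooling) temperature signal and
exhalation onsets are peaks; a polarity flag covers hardware with the
opposite sign convention.  A sniff is one cycle, inhalation onset to the
next inhalation onset; cycles whose duration falls strictly below the 5th
or strictly above the 95th percentile of the session distribution are
excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats


@dataclass
class SniffTrace:
    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[0]) / self.sample_rate


@dataclass
class SniffEvents:
    """Sniff cycles of one recording.

    ``inhalation_onsets`` has n entries; sniff i spans onsets i..i+1, so
    ``durations`` and ``kept_mask`` have n-1 entries.  ``exhalation_onsets``
    are aligned with the inhalation that precedes them (NaN when the peak
    was not found).
    """

    inhalation_onsets: np.ndarray
    exhalation_onsets: np.ndarray
    durations: np.ndarray
    kept_mask: np.ndarray

    def __post_init__(self) -> None:
        self.inhalation_onsets = np.asarray(self.inhalation_onsets, dtype=float)
        self.exhalation_onsets = np.asarray(self.exhalation_onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.inhalation_onsets.size and np.any(np.diff(self.inhalation_onsets) <= 0):
            raise ValueError("inhalation onsets must be strictly increasing")
        if np.any(self.durations[np.isfinite(self.durations)] <= 0):
            raise ValueError("durations must be positive")

    @property
    def n_sniffs(self) -> int:
        return self.durations.shape[0]

    def kept_indices(self) -> np.ndarray:
        return np.nonzero(self.kept_mask)[0]


def smooth_trace(trace: SniffTrace, window: float = 0.025) -> SniffTrace:
    """Boxcar moving average of the stated width (seconds).

    Length-preserving; at the edges the window shrinks to the available
    samples so constants pass through unchanged.
    """
    w = int(round(window * trace.sample_rate))
    w = max(w, 1)
    n = trace.samples.shape[0]
    if w > n:
        raise ValueError("smoothing window longer than the trace")
    kernel = np.ones(w)
    num = np.convolve(trace.samples, kernel, mode="same")
    den = np.convolve(np.ones(n), kernel, mode="same")
    return SniffTrace(samples=num / den, sample_rate=trace.sample_rate, t0=trace.t0)


def _refine_extrema(sig: np.ndarray, idx: np.ndarray, half: int) -> np.ndarray:
    """Least-squares parabola vertex around each candidate extremum,
    snapped back to the nearest sample; suppresses noise-induced +-1-sample
    jitter of the discrete argmin."""
    out = idx.astype(float)
    n = sig.shape[0]
    for k, i in enumerate(idx):
        lo, hi = i - half, i + half + 1
        if lo < 0 or hi > n:
            continue
        t = np.arange(-half, half + 1, dtype=float)
        y = sig[lo:hi]
        a2 = np.sum(t ** 2)
        a4 = np.sum(t ** 4)
        # centered quadratic fit: y ~ c0 + c1 t + c2 t^2
        c1 = np.sum(t * y) / a2
        m = y.shape[0]
        c2 = (m * np.sum(t ** 2 * y) - a2 * y.sum()) / (m * a4 - a2 ** 2)
        if c2 != 0:
            shift = -c1 / (2 * c2)
            if abs(shift) <= half:
                out[k] = i + shift
    return np.round(out).astype(int)


def detect_sniffs(trace: SniffTrace, prominence: float = 0.3,
                  min_separation_s: float = 0.05,
                  inhalation_is_trough: bool = True,
                  refine_window_s: float = 0.004) -> SniffEvents:
    """Detect inhalation/exhalation onsets as alternating extrema.

    Runs peak finding (with a prominence floor and a minimum separation,
    both configurable since hardware differs) on the smoothed trace and on
    its negation, refines each extremum by a local parabolic fit, then
    pairs each inhalation with the first exhalation peak before the next
    inhalation.  A flat trace yields no events.
    """
    sig = trace.samples if inhalation_is_trough else -trace.samples
    dist = max(int(round(min_separation_s * trace.sample_rate)), 1)
    troughs, _ = signal.find_peaks(-sig, prominence=prominence, distance=dist)
    peaks, _ = signal.find_peaks(sig, prominence=prominence, distance=dist)
    half = int(round(refine_window_s * trace.sample_rate))
    if half >= 2:
        troughs = _refine_extrema(-sig, troughs, half)
        peaks = _refine_extrema(sig, peaks, half)
    if troughs.size == 0:
        z = np.zeros(0)
        return SniffEvents(z, z, z, np.zeros(0, dtype=bool))
    inh = trace.t0 + troughs / trace.sample_rate
    peak_t = trace.t0 + peaks / trace.sample_rate
    exh = np.full(inh.shape, np.nan)
    for i, t in enumerate(inh):
        nxt = inh[i + 1] if i + 1 < inh.size else np.inf
        cand = peak_t[(peak_t > t) & (peak_t < nxt)]
        if cand.size:
            exh[i] = cand[0]
    durations = np.diff(inh)
    return SniffEvents(inhalation_onsets=inh, exhalation_onsets=exh,
                       durations=durations,
                       kept_mask=np.ones(durations.shape[0], dtype=bool))


def filter_sniff_durations(events: SniffEvents) -> SniffEvents:
    """Exclude sniffs with duration strictly below the 5th or strictly above
    the 95th percentile of the distribution (linear-interpolation
    quantiles; ties on the boundary are kept)."""
    if events.n_sniffs < 2:
        raise ValueError("need at least 2 sniffs to filter")
    d = events.durations
    lo, hi = np.percentile(d, [5.0, 95.0])
    kept = (d >= lo) & (d <= hi)
    return SniffEvents(events.inhalation_onsets, events.exhalation_onsets,
                       events.durations, kept)


def _enclosing_sniff(t: np.ndarray, events: SniffEvents) -> np.ndarray:
    """Index of the sniff containing each time (kept sniffs only; -1 outside)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    inh = events.inhalation_onsets
    idx = np.searchsorted(inh, t, side="right") - 1
    ok = (idx >= 0) & (idx < events.n_sniffs)
    idx = np.where(ok, idx, 0)
    ok &= events.kept_mask[idx]
    return np.where(ok, idx, -1)


def instantaneous_rate(events: SniffEvents, timebase: np.ndarray) -> np.ndarray:
    """Sniff rate at each query time: 1/duration of the enclosing kept
    sniff, NaN outside the first/last sniff or in excluded sniffs."""
    if int(events.kept_mask.sum()) < 2:
        raise ValueError("need at least 2 kept sniffs")
    idx = _enclosing_sniff(timebase, events)
    rate = np.full(idx.shape, np.nan)
    inside = idx >= 0
    rate[inside] = 1.0 / events.durations[idx[inside]]
    return rate


def sniff_phase(t, events: SniffEvents) -> np.ndarray:
    """Phase in [0, 1) of each time within its kept sniff: elapsed time
    since inhalation onset divided by cycle duration; NaN outside."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    idx = _enclosing_sniff(t_arr, events)
    phase = np.full(t_arr.shape, np.nan)
    inside = idx >= 0
    phase[inside] = ((t_arr[inside] - events.inhalation_onsets[idx[inside]])
                     / events.durations[idx[inside]])
    return phase if np.ndim(t) else float(phase[0])


def compare_duration_distributions(a, b):
    """Two-sample Kolmogorov-Smirnov test on sniff-duration samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
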