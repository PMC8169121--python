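"""Per-frame kinematics from three-point pose and their sniff synchrony.

Three kinematic parameters are derived from the nose/head/body keypoints:
nose speed (frame-to-frame displacement of the snout tip), yaw velocity
(change of the unsigned angle between the snout-head and head-body
segments; centrifugal motion, the nose swinging away from the body axis, is
positive) and Z-velocity (change of the snout-to-head distance, a 2-D proxy
for pitch).  Alignment with sniffing uses 400 ms windows centered on each
inhalation, after advancing the tracking streams by two frames (25 ms) to
compensate the camera-thermistor offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .sniff import SniffEvents, SniffTrace


@dataclass
class KinematicSeries:
    nose_speed: np.ndarray     # cm/frame (multiply by px_per_cm for px/frame)
    yaw_velocity: np.ndarray   # rad/frame, centrifugal positive
    z_velocity: np.ndarray     # cm/frame
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        n = self.frame_times.shape[0]
        for arr in (self.nose_speed, self.yaw_velocity, self.z_velocity):
            if arr.shape[0] != n:
                raise ValueError("kinematic arrays must share length")


@dataclass
class TriggeredMatrix:
    """Event-triggered snippets: one row per usable inhalation, columns are
    lags over a window centered on the event."""

    lags: np.ndarray           # seconds, symmetric about 0
    rows: np.ndarray           # (n_events, n_lags)
    grand_mean: np.ndarray     # column nanmean

    @property
    def n_events(self) -> int:
        return self.rows.shape[0]


def compute_kinematics(nose, head, body, frame_times) -> KinematicSeries:
    """Kinematic parameters from the three keypoints.

    First frames get NaN (no predecessor); frames with any missing keypoint
    propagate NaN into the affected parameters.
    """
    nose = np.asarray(nose, float)
    head = np.asarray(head, float)
    body = np.asarray(body, float)
    frame_times = np.asarray(frame_times, float)
    T = frame_times.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames")
    speed = np.full(T, np.nan)
    speed[1:] = np.linalg.norm(np.diff(nose, axis=0), axis=1)
    seg_nh = nose - head
    seg_hb = head - body
    cosang = np.einsum("ij,ij->i", seg_nh, seg_hb)
    norms = np.linalg.norm(seg_nh, axis=1) * np.linalg.norm(seg_hb, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        angle = np.arccos(np.clip(cosang / norms, -1.0, 1.0))
    yaw = np.full(T, np.nan)
    yaw[1:] = np.diff(angle)       # d|angle|/dt: positive = centrifugal
    dist = np.linalg.norm(seg_nh, axis=1)
    zvel = np.full(T, np.nan)
    zvel[1:] = np.diff(dist)
    return KinematicSeries(nose_speed=speed, yaw_velocity=yaw,
                           z_velocity=zvel, frame_times=frame_times)


def trial_kinematics(trial) -> KinematicSeries:
    return compute_kinematics(trial.nose, trial.head, trial.body, trial.frame_times)


def exclude_glitch_trials(kin_list, px_per_cm: float,
                          threshold_px_per_frame: float = 100.0):
    """Indices of trials free of tracking glitches: a trial containing any
    frame with nose speed above the criterion (100 px/frame) is dropped."""
    keep = []
    for i, kin in enumerate(kin_list):
        px = np.asarray(kin.nose_speed) * px_per_cm
        if not np.any(px[np.isfinite(px)] > threshold_px_per_frame):
            keep.append(i)
    return keep


def align_tracking_to_sniff(values: np.ndarray, shift: int = 2) -> np.ndarray:
    """Advance a tracking-clock stream by ``shift`` frames (25 ms at 80 Hz)
    relative to the sniff clock; vacated leading frames become NaN (or the
    first value for integer label streams)."""
    values = np.asarray(values)
    if shift == 0:
        return values.copy()
    out = np.empty_like(values)
    if shift > 0:
        out[shift:] = values[:-shift]
        fill = np.nan if np.issubdtype(values.dtype, np.floating) else values[0]
        out[:shift] = fill
    else:
        out[:shift] = values[-shift:]
        fill = np.nan if np.issubdtype(values.dtype, np.floating) else values[-1]
        out[shift:] = fill
    return out


def sniff_triggered(values, times, inhalations, window: float = 0.4) -> TriggeredMatrix:
    """Snippets of a uniformly-sampled series in a window centered on each
    inhalation; events whose window leaves the record are dropped."""
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    if times.shape[0] < 2:
        raise ValueError("series too short")
    dt = float(np.median(np.diff(times)))
    half = int(round(window / 2.0 / dt))
    lags = np.arange(-half, half + 1) * dt
    rows = []
    for t_ev in np.atleast_1d(inhalations):
        idx = int(round((t_ev - times[0]) / dt))
        if idx - half < 0 or idx + half >= values.shape[0]:
            continue
        rows.append(values[idx - half: idx + half + 1])
    if rows:
        mat = np.asarray(rows)
        with np.errstate(invalid="ignore"):
            gm = np.nanmean(mat, axis=0)
    else:
        mat = np.zeros((0, lags.shape[0]))
        gm = np.full(lags.shape[0], np.nan)
    return TriggeredMatrix(lags=lags, rows=mat, grand_mean=gm)


def modulation_index(curve) -> float:
    """MI = (max - min) / (max + min) of a non-negative aligned curve;
    NaN when the curve is all-zero or empty."""
    curve = np.asarray(curve, float)
    curve = curve[np.isfinite(curve)]
    if curve.size == 0:
        return float("nan")
    hi, lo = float(curve.max()), float(curve.min())
    if hi + lo == 0.0:
        return float("nan")
    return (hi - lo) / (hi + lo)


def sniff_kinematic_synchrony(kin_values, kin_times, trace: SniffTrace,
                              max_lag_s: float = 0.5,
                              coherence_window_s: float = 1.0):
    """Normalized cross-correlation and Welch coherence between a kinematic
    series and the sniff signal, resampled to the kinematic clock.

    Returns (lags_s, xcorr, freqs_hz, coherence); the cross-correlation is
    Pearson-style (mean-removed, unit variance) so it lies in [-1, 1].
    """
    kin_values = np.asarray(kin_values, float)
    kin_times = np.asarray(kin_times, float)
    y = np.interp(kin_times, trace.times, trace.samples)
    ok = np.isfinite(kin_values)
    x = kin_values.copy()
    x[~ok] = np.nanmean(kin_values)
    dt = float(np.median(np.diff(kin_times)))
    fs = 1.0 / dt
    nper = int(round(coherence_window_s * fs))
    if x.shape[0] < 2 * nper:
        raise ValueError("series shorter than two coherence windows")
    xm = x - x.mean()
    ym = y - y.mean()
    max_lag = int(round(max_lag_s * fs))
    full = sps.correlate(xm, ym, mode="full")
    mid = xm.shape[0] - 1
    sel = slice(mid - max_lag, mid + max_lag + 1)
    denom = xm.shape[0] * x.std() * y.std()
    xcorr = full[sel] / denom if denom > 0 else np.zeros(2 * max_lag + 1)
    lags = np.arange(-max_lag, max_lag + 1) * dt
    freqs, coh = sps.coherence(xm, ym, fs=fs, nperseg=nper)
    return lags, xcorr, freqs, coh


def _null_permutation(n: int, rng: np.random.Generator,
                      exclude_self: bool) -> np.ndarray:
    if not exclude_self:
        return rng.permutation(n)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def trial_shuffle_test(kin_trials, sniff_trials, n: int = 1000, seed: int = 0,
                       window: float = 0.4, exclude_self: bool = False):
    """Permutation test of sniff-kinematic locking across trials.

    The observed statistic is the modulation index of the grand-mean
    sniff-triggered curve (per-trial mean curves averaged across trials).
    The null re-pairs trials' kinematics with other trials' sniff times
    (uniform random permutations of trial indices, the exact randomization
    test; ``exclude_self=True`` restricts the null to derangements).
    Sniff times are used relative to trial start and truncated to the
    paired record.  One-sided p = (1 + #{null >= observed}) / (1 + n).

    ``kin_trials``: list of (times, values); ``sniff_trials``: list of
    inhalation-time arrays on the same clock as the matching kin trial.
    """
    m = len(kin_trials)
    if m < 2:
        raise ValueError("need at least 2 trials")
    if n < 1:
        raise ValueError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    rel = [np.asarray(s, float) - kin_trials[i][0][0] for i, s in enumerate(sniff_trials)]
    # pair curves C[i][j]: kin trial i triggered on sniff train j
    curves = np.full((m, m, 0), np.nan)
    ncols = None
    C = [[None] * m for _ in range(m)]
    for i, (times, values) in enumerate(kin_trials):
        t0 = times[0]
        for j in range(m):
            ev = t0 + rel[j]
            ev = ev[(ev >= times[0]) & (ev <= times[-1])]
            tm = sniff_triggered(values, times, ev, window=window)
            C[i][j] = tm.grand_mean
            ncols = tm.grand_mean.shape[0]

    def stat(perm):
        stack = np.asarray([C[i][perm[i]] for i in range(m)])
        with np.errstate(invalid="ignore"):
            gm = np.nanmean(stack, axis=0)
        return modulation_index(gm)

    observed = stat(np.arange(m))
    null = np.asarray([stat(_null_permutation(m, rng, exclude_self))
                       for _ in range(n)])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n)
    return observed, null, float(p)


def tortuosity(xy) -> float:
    """Path length divided by the straight-line distance between the
    endpoints; NaN when the endpoints coincide."""
    xy = np.asarray(xy, float)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    chord = float(np.linalg.norm(xy[-1] - xy[0]))
    if chord == 0.0:
        return float("nan")
    return float(np.nansum(steps)) / chord
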