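"""Synthetic data generators for every pipeline input.

These generators define the study conditions the test-suite exercises:
ground-truth AR-HMM trajectories, thermistor-style sniff traces with known
inhalation/exhalation times, sniff-phase-locked kinematic series of known
modulation depth, whole behavioral sessions in a 25 x 15 cm arena (origin at
the initiation-port wall, longitudinal axis toward the odor ports, decision
line at 15 cm), and gridded PID plume recordings over a 7 x 5 sampling grid.
Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arhmm import ARHMMParams
from .sniff import SniffEvents, SniffTrace

# arena geometry (cm); origin at the initiation-port wall corner
ARENA_LENGTH = 25.0
ARENA_WIDTH = 15.0
DECISION_LINE = 15.0
INIT_PORT = np.array([0.0, ARENA_WIDTH / 2])
PORT_LEFT = np.array([ARENA_LENGTH, 0.75 * ARENA_WIDTH])
PORT_RIGHT = np.array([ARENA_LENGTH, 0.25 * ARENA_WIDTH])
FRAME_RATE = 80.0


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    params: ARHMMParams | None
    true_labels: list
    true_inhalations: list
    modulation_depth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")


# ---------------------------------------------------------------------------
# AR-HMM ground truth


def gen_arhmm_params(S: int, d: int, separation: float = 3.0, seed: int = 0,
                     persistence: float = 0.9, spectral_radius: float = 0.9,
                     noise_scale: float | None = None) -> ARHMMParams:
    """Random stable AR-HMM parameters with well-separated state dynamics.

    Each state's dynamics contract (spectral radius < 1) toward a
    state-specific fixed point placed ``separation`` units from the origin,
    with a state-specific rotation in the leading two dimensions, so that
    states are distinguishable from short trajectory stretches.  Transition
    rows put ``persistence`` on the diagonal and spread the rest uniformly;
    the initial distribution is uniform.
    """
    if S < 1 or d < 1:
        raise ValueError("S and d must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if not 0.0 < spectral_radius < 1.0:
        raise ValueError("spectral_radius must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sigma = 0.08 * separation if noise_scale is None else float(noise_scale)
    A = np.zeros((S, d, d))
    b = np.zeros((S, d))
    Q = np.zeros((S, d, d))
    for s in range(S):
        theta = ((-1) ** s) * 0.25 + 0.1 * rng.standard_normal()
        As = spectral_radius * np.eye(d)
        if d >= 2:
            c, sn = np.cos(theta), np.sin(theta)
            As[:2, :2] = spectral_radius * np.array([[c, -sn], [sn, c]])
        mu = np.zeros(d)
        if d == 1:
            mu[0] = separation * (2.0 * s / max(S - 1, 1) - 1.0)
        else:
            ang = 2.0 * np.pi * s / S
            mu[0] = separation * np.cos(ang)
            mu[1] = separation * np.sin(ang)
        A[s] = As
        b[s] = (np.eye(d) - As) @ mu
        W = 0.2 * sigma * rng.standard_normal((d, d)) / np.sqrt(d)
        Q[s] = sigma ** 2 * np.eye(d) + W @ W.T
    if S == 1:
        pi = np.ones((1, 1))
    else:
        pi = np.full((S, S), (1.0 - persistence) / (S - 1))
        np.fill_diagonal(pi, persistence)
    params = ARHMMParams(pi=pi, init=np.full(S, 1.0 / S), A=A, b=b, Q=Q)
    params.validate()
    return params


def simulate_trials(params: ARHMMParams, n_trials: int,
                    length_range: tuple[int, int], seed: int = 0):
    """Simulate trials from the generative model.

    Returns (trajectories, labels); labels follow the Markov chain, frames
    the state-conditional AR(1) process.  The first frame is drawn around
    the first state's fixed point.
    """
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 2 or hi < lo:
        raise ValueError("length_range must be (lo, hi) with lo >= 2")
    rng = np.random.default_rng(seed)
    S, d = params.S, params.d
    # state fixed points for initialization (fall back to zero if unstable)
    mus = np.zeros((S, d))
    for s in range(S):
        try:
            mus[s] = np.linalg.solve(np.eye(d) - params.A[s], params.b[s])
        except np.linalg.LinAlgError:
            pass
    chol = np.linalg.cholesky(params.Q + 1e-12 * np.eye(d))
    trajectories, labels = [], []
    for _ in range(n_trials):
        T = int(rng.integers(lo, hi + 1))
        z = np.empty(T, dtype=np.int64)
        x = np.empty((T, d))
        z[0] = rng.choice(S, p=params.init)
        x[0] = mus[z[0]] + chol[z[0]] @ rng.standard_normal(d)
        for t in range(1, T):
            z[t] = rng.choice(S, p=params.pi[z[t - 1]])
            eps = chol[z[t]] @ rng.standard_normal(d)
            x[t] = params.A[z[t]] @ x[t - 1] + params.b[z[t]] + eps
        trajectories.append(x)
        labels.append(z)
    return trajectories, labels


# ---------------------------------------------------------------------------
# sniff traces


def _warped_phase(p: np.ndarray, f: float) -> np.ndarray:
    """Monotone quintic phase warp with phi(0)=0, phi(f)=1/2, phi(1)=1,
    unit slope and zero curvature at every node, so the waveform is locally
    symmetric at its extrema (smoothing cannot bias their locations) while
    inhalation (duration fraction f) and exhalation differ in length."""
    out = np.empty_like(p)
    for p0, p1, y0, y1 in ((0.0, f, 0.0, 0.5), (f, 1.0, 0.5, 1.0)):
        m = (p >= p0) & (p <= p1)
        h = p1 - p0
        t = (p[m] - p0) / h
        w = t ** 3 * (10.0 - 15.0 * t + 6.0 * t ** 2)
        out[m] = y0 + (p[m] - p0) + ((y1 - y0) - h) * w
    return out


def gen_sniff_trace(rate_profile, outlier_fraction: float = 0.0,
                    sample_rate: float = 1000.0, seed: int = 0,
                    duration: float = 10.0, noise_sd: float = 0.01,
                    inhale_frac: float = 0.4, jitter: float = 0.03,
                    t0: float = 0.0):
    """Synthetic thermistor trace with known inhalation/exhalation times.

    ``rate_profile`` is a constant (Hz) or a callable t -> Hz.  Each sniff
    is one cycle of -cos(2 pi phi(p)) with a phase warp that makes the
    trough (inhalation onset) and peak (exhalation onset) locally symmetric;
    sniff durations are log-normally jittered around 1/rate, and a stated
    fraction of sniffs get extreme durations (x0.25 or x3) so percentile
    filtering has known targets.  Returns (SniffTrace, SniffEvents).
    """
    rate = rate_profile if callable(rate_profile) else (lambda t, r=float(rate_profile): r)
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    # start the first cycle a fraction into the record so its trough is an
    # interior sample; a virtual preceding cycle fills the leading samples
    onsets, exhalations = [], []
    t = 0.3 / float(rate(0.0))
    while t < duration:
        r = float(rate(t))
        if r <= 0:
            raise ValueError("rate_profile must be positive")
        if r >= sample_rate / 2:
            raise ValueError("sniff rate exceeds the Nyquist frequency")
        dur = (1.0 / r) * float(np.exp(jitter * rng.standard_normal()))
        if outlier_fraction > 0 and rng.random() < outlier_fraction:
            dur *= 0.25 if rng.random() < 0.5 else 3.0
        # truth lives on the sample grid: snap event times to samples
        t_next = np.round((t + dur) * sample_rate) / sample_rate
        onsets.append(np.round(t * sample_rate) / sample_rate)
        exhalations.append(np.round((t + inhale_frac * dur) * sample_rate) / sample_rate)
        t = t_next
    onsets.append(np.round(t * sample_rate) / sample_rate)  # closes the last sniff
    onsets_arr = np.asarray(onsets)
    exh_arr = np.asarray(exhalations)
    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    sig = np.full(n, -1.0)
    virtual = onsets_arr[0] - 1.0 / float(rate(0.0))
    fill = np.concatenate([[virtual], onsets_arr])
    for i in range(len(fill) - 1):
        a, bnd = fill[i], fill[i + 1]
        m = (times >= a) & (times < bnd)
        if not m.any():
            continue
        p = (times[m] - a) / (bnd - a)
        sig[m] = -np.cos(2 * np.pi * _warped_phase(p, inhale_frac))
    sig += noise_sd * rng.standard_normal(n)
    durs = np.diff(onsets_arr)
    keep_inh = onsets_arr[onsets_arr <= duration - 2.0 / sample_rate]
    events = SniffEvents(
        inhalation_onsets=t0 + keep_inh,
        exhalation_onsets=t0 + exh_arr[: len(keep_inh)],
        durations=durs[: len(keep_inh) - 1],
        kept_mask=np.ones(len(keep_inh) - 1, dtype=bool),
    )
    return SniffTrace(samples=sig, sample_rate=sample_rate, t0=t0), events


def gen_sniff_locked_kinematics(events: SniffEvents, depth: float,
                                baseline: float = 1.0, seed: int = 0,
                                sample_rate: float = FRAME_RATE,
                                noise_sd: float = 0.05):
    """Kinematic series modulated by sniff phase.

    series(t) = baseline * (1 + depth * cos(2 pi phase(t))) + noise, where
    phase is the position of t within its sniff cycle, so the grand-mean
    sniff-triggered curve has modulation index ``depth`` up to noise.
    Returns (times, values).
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    inh = events.inhalation_onsets
    t0, t1 = inh[0], inh[-1]
    times = t0 + np.arange(int(np.floor((t1 - t0) * sample_rate))) / sample_rate
    idx = np.searchsorted(inh, times, side="right") - 1
    idx = np.clip(idx, 0, len(inh) - 2)
    phase = (times - inh[idx]) / (inh[idx + 1] - inh[idx])
    values = baseline * (1.0 + depth * np.cos(2 * np.pi * phase))
    values = values + noise_sd * baseline * rng.standard_normal(times.shape[0])
    return times, values


# ---------------------------------------------------------------------------
# whole sessions


@dataclass
class SessionConfig:
    """Knobs of the synthetic search session.

    Investigation epochs are slow, tortuous and near the initiation port
    with fast sniffing; approach epochs are fast, heading-directed runs at
    the chosen odor port with slower sniffing.  Choices follow a logistic
    read-out of the left-right concentration ratio, so correct and
    incorrect trials are both populated at the default gain.
    """

    n_trials: int = 40
    ratio_conditions: tuple = ((80, 20), (60, 40))
    frame_rate: float = FRAME_RATE
    px_per_cm: float = 20.0
    decision_line: float = DECISION_LINE
    inv_duration_s: tuple = (0.8, 2.2)
    inv_speed: float = 3.0          # cm/s
    app_speed: float = 18.0         # cm/s
    inv_sniff_hz: float = 9.0
    app_sniff_hz: float = 5.0
    choice_gain: float = 6.0
    abort_prob: float = 0.35        # chance an approach bout aborts once
    inv_lateral_sd: float = 3.0     # lateral spread of investigation anchors
    correct_midline_bias: float = 0.0  # shrink anchor spread on correct trials
    iti_s: float = 2.0
    always_correct: bool = False
    modulation_depth: float = 0.0   # sniff-locked speed modulation to plant
    make_traces: bool = True
    pid_sample_rate: float = 1000.0


def _heading_path(rng, start, cfg, side_choice, lat_sd=None):
    """Body-center path: alternate investigation and approach bouts until
    the reward port is reached.  Returns (positions, epoch labels,
    decision crossing index)."""
    dt = 1.0 / cfg.frame_rate
    target = PORT_LEFT if side_choice == "left" else PORT_RIGHT
    pos = [np.array(start, dtype=float)]
    epochs = []
    p = np.array(start, dtype=float)
    v = np.zeros(2)
    h = np.array([1.0, 0.0])
    aborted = False
    # investigation anchor: near the port, lateral offset possibly biased
    bouts = [("inv", None), ("app", None)]
    while bouts:
        kind, anchor = bouts.pop(0)
        if kind == "inv":
            if anchor is None:
                anchor = p + np.array([2.0 + rng.random(), 0.0])
            T = int(rng.uniform(*cfg.inv_duration_s) * cfg.frame_rate)
            step = cfg.inv_speed * dt
            for _ in range(T):
                v = 0.7 * v + 0.04 * (anchor - p) + 0.5 * step * rng.standard_normal(2)
                p = p + v
                p = np.clip(p, [0.3, 0.3], [ARENA_LENGTH - 0.3, ARENA_WIDTH - 0.3])
                pos.append(p.copy())
                epochs.append(0)
        else:
            abort_x = None
            if not aborted and rng.random() < cfg.abort_prob:
                abort_x = rng.uniform(5.0, 11.0)
                aborted = True
            while p[0] < ARENA_LENGTH - 1.0:
                to_t = target - p
                to_t /= np.linalg.norm(to_t) + 1e-12
                h = 0.85 * h + 0.15 * to_t
                h /= np.linalg.norm(h) + 1e-12
                p = p + cfg.app_speed * dt * h + 0.25 * cfg.app_speed * dt * rng.standard_normal(2)
                p = np.clip(p, [0.3, 0.3], [ARENA_LENGTH - 0.3, ARENA_WIDTH - 0.3])
                pos.append(p.copy())
                epochs.append(1)
                if abort_x is not None and p[0] >= abort_x:
                    sd = cfg.inv_lateral_sd if lat_sd is None else lat_sd
                    anchor = np.array([p[0] + 0.5 * rng.standard_normal(),
                                       ARENA_WIDTH / 2 + sd * rng.standard_normal()])
                    bouts = [("inv", anchor), ("app", None)] + bouts
                    abort_x = None
                    break
    pos = np.asarray(pos)
    epochs = np.asarray([0] + epochs)
    cross = np.nonzero(pos[:, 0] >= cfg.decision_line)[0]
    return pos, epochs, int(cross[0]) if cross.size else len(pos) - 1


def simulate_session(cfg: SessionConfig | None = None, seed: int = 0,
                     mouse_id: str = "m00", session_id: str = "s00"):
    """One synthetic mouse-session.

    Returns (SessionBundle, truth) where truth is a GroundTruth holding the
    planted per-frame epoch labels (0 = investigation, 1 = approach) and
    inhalation times per trial.
    """
    from .session import SessionBundle, Trial, TrialMeta

    cfg = cfg or SessionConfig()
    if cfg.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.frame_rate
    trials, epoch_labels, inh_lists = [], [], []
    t_clock = 0.0
    for k in range(cfg.n_trials):
        ratio = cfg.ratio_conditions[int(rng.integers(len(cfg.ratio_conditions)))]
        side = "left" if rng.random() < 0.5 else "right"
        hi, lo = max(ratio), min(ratio)
        # logistic choice on the (signed toward stimulus) sensed contrast
        delta = (hi - lo) / 100.0 + 0.15 * rng.standard_normal()
        p_correct = 1.0 / (1.0 + np.exp(-cfg.choice_gain * delta))
        if cfg.always_correct:
            choice = side
        else:
            choice = side if rng.random() < p_correct else ("right" if side == "left" else "left")
        correct = None if hi == lo == 0 else (choice == side)
        # investigation anchors concentrate at the lateral midline on
        # correct trials when a midline bias is planted
        sd = cfg.inv_lateral_sd * (1.0 - cfg.correct_midline_bias if correct else 1.0)
        start = INIT_PORT + np.array([0.5, float(np.clip(sd * rng.standard_normal(), -6.0, 6.0))])
        pos, epochs, cross = _heading_path(rng, start, cfg, choice, lat_sd=sd)
        T = pos.shape[0]
        times = t_clock + np.arange(T) * dt
        # three-point pose from smoothed heading
        vel = np.gradient(pos, axis=0)
        speed = np.linalg.norm(vel, axis=1)
        hdg = vel / (speed[:, None] + 1e-9)
        for t in range(1, T):  # smooth heading to avoid jitter flips
            hdg[t] = 0.7 * hdg[t - 1] + 0.3 * hdg[t]
            hdg[t] /= np.linalg.norm(hdg[t]) + 1e-12
        nose = pos + 0.02 * rng.standard_normal((T, 2))
        head = pos - 2.0 * hdg + 0.02 * rng.standard_normal((T, 2))
        body = pos - 4.0 * hdg + 0.02 * rng.standard_normal((T, 2))
        for arr in (nose, head, body):
            np.clip(arr[:, 0], 0.0, ARENA_LENGTH, out=arr[:, 0])
            np.clip(arr[:, 1], 0.0, ARENA_WIDTH, out=arr[:, 1])
        # sniffing: epoch-dependent rate profile
        trial_dur = T * dt

        def rate_at(t, _times=times, _ep=epochs, _t0=t_clock):
            i = min(int((t) / dt), len(_ep) - 1)
            return cfg.inv_sniff_hz if _ep[i] == 0 else cfg.app_sniff_hz

        if cfg.make_traces:
            trace, ev = gen_sniff_trace(rate_at, sample_rate=cfg.pid_sample_rate,
                                        seed=int(rng.integers(2 ** 31)),
                                        duration=trial_dur, t0=t_clock)
        else:
            trace = None
            _, ev = gen_sniff_trace(rate_at, sample_rate=400.0,
                                    seed=int(rng.integers(2 ** 31)),
                                    duration=trial_dur, noise_sd=0.0, t0=t_clock)
        meta = TrialMeta(
            start_s=times[0], end_s=times[-1] + dt, side=side,
            ratio=tuple(ratio), choice=choice, correct=correct,
            decision_time_s=times[cross],
            iti_end_s=times[-1] + dt + cfg.iti_s,
        )
        trials.append(Trial(nose=nose, head=head, body=body, frame_times=times,
                            sniff=ev, trace=trace, meta=meta))
        epoch_labels.append(epochs)
        inh_lists.append(ev.inhalation_onsets.copy())
        t_clock = times[-1] + dt + cfg.iti_s
    bundle = SessionBundle(mouse_id=mouse_id, session_id=session_id,
                           trials=trials, px_per_cm=cfg.px_per_cm,
                           frame_rate=cfg.frame_rate)
    truth = GroundTruth(params=None, true_labels=epoch_labels,
                        true_inhalations=inh_lists,
                        modulation_depth=cfg.modulation_depth, seed=seed)
    return bundle, truth


# ---------------------------------------------------------------------------
# plume grids


@dataclass
class PlumeConfig:
    grid_shape: tuple = (7, 5)      # longitudinal x lateral sampling points
    n_trials_per_bin: int = 15
    trial_s: float = 2.0
    pid_sample_rate: float = 1000.0  # the PID sample rate is a free parameter
    noise_sd: float = 0.05
    noise_ar: float = 0.95          # AR(1) coefficient of turbulent noise
    amplitude: float = 1.0
    length_scale: float = 8.0       # cm, exponential decay from the source


def plume_mean_field(side: str, x: np.ndarray, y: np.ndarray,
                     cfg: PlumeConfig | None = None) -> np.ndarray:
    """Noise-free mean concentration on the (x, y) grid for one source side.

    Exponential decay with distance from the active odor port; left and
    right fields are mirror images across the lateral midline.
    """
    cfg = cfg or PlumeConfig()
    port = PORT_LEFT if side == "left" else PORT_RIGHT
    X, Y = np.meshgrid(x, y, indexing="ij")
    dist = np.hypot(X - port[0], Y - port[1])
    return cfg.amplitude * np.exp(-dist / cfg.length_scale)


def gen_plume_session(cfg: PlumeConfig | None = None, seed: int = 0):
    """Gridded PID recordings: for each of the 7 x 5 locations and each
    source side, ``n_trials_per_bin`` two-second traces of mean field value
    plus AR(1) turbulent noise.  Returns a PlumeGrid."""
    from .plume import PlumeGrid

    cfg = cfg or PlumeConfig()
    nx, ny = cfg.grid_shape
    rng = np.random.default_rng(seed)
    x = np.linspace(ARENA_LENGTH / (2 * nx), ARENA_LENGTH - ARENA_LENGTH / (2 * nx), nx)
    y = np.linspace(ARENA_WIDTH / (2 * ny), ARENA_WIDTH - ARENA_WIDTH / (2 * ny), ny)
    n_samp = int(round(cfg.trial_s * cfg.pid_sample_rate))
    fields = {s: plume_mean_field(s, x, y, cfg) for s in ("left", "right")}
    traces, rows, cols, sides = [], [], [], []
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.noise_ar ** 2)
    from scipy.signal import lfilter
    for side in ("left", "right"):
        for i in range(nx):
            for j in range(ny):
                k = cfg.n_trials_per_bin
                e = rng.standard_normal((k, n_samp)) * innov_sd
                x0 = rng.standard_normal((k, 1)) * cfg.noise_sd
                noise, _ = lfilter([1.0], [1.0, -cfg.noise_ar], e, axis=1,
                                   zi=cfg.noise_ar * x0)
                for r in range(k):
                    traces.append(fields[side][i, j] + noise[r])
                    rows.append(i)
                    cols.append(j)
                    sides.append(side)
    return PlumeGrid(x_centers=x, y_centers=y,
                     traces=np.asarray(traces), row=np.asarray(rows),
                     col=np.asarray(cols), side=np.asarray(sides),
                     sample_rate=cfg.pid_sample_rate)
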