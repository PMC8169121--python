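"""Bayesian auto-regressive hidden Markov model (AR-HMM) for trajectory motifs.

The generative model has a discrete Markov layer ``z_t`` over ``S`` states
(movement motifs) and a continuous observed layer ``x_t`` (the d-dimensional
keypoint vector).  Within a state the trajectory follows linear first-order
autoregressive dynamics

    x_t = A_z x_{t-1} + b_z + eps_t,      eps_t ~ N(0, Q_z),

with the first frame of every trial conditioned on, not modelled.  Inference
is fully Bayesian: conjugate Dirichlet priors on the rows of the transition
matrix and matrix-normal-inverse-Wishart (MNIW) priors on the per-state AR
parameters, sampled by Gibbs alternation between exact forward-filter
backward-sample draws of the state sequences and closed-form conjugate draws
of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.stats import invwishart

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ARHMMParams:
    """Full parameter set theta = (pi, init, {A_z}, {b_z}, {Q_z})."""

    pi: np.ndarray     # (S, S) row-stochastic transition matrix
    init: np.ndarray   # (S,) initial state distribution
    A: np.ndarray      # (S, d, d) autoregressive dynamics
    b: np.ndarray      # (S, d) drift terms
    Q: np.ndarray      # (S, d, d) SPD noise covariances

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)

    @property
    def S(self) -> int:
        return self.pi.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]

    def validate(self) -> None:
        S, d = self.S, self.d
        if self.pi.shape != (S, S) or self.init.shape != (S,):
            raise ValueError("transition matrix / init shape mismatch")
        if self.A.shape != (S, d, d) or self.b.shape != (S, d) or self.Q.shape != (S, d, d):
            raise ValueError("AR parameter shape mismatch")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of pi must sum to 1")
        if not np.allclose(self.init.sum(), 1.0, atol=1e-8):
            raise ValueError("init must sum to 1")
        for s in range(S):
            np.linalg.cholesky(self.Q[s])


@dataclass
class PriorHyper:
    """Conjugate prior hyperparameters.

    ``alpha`` is the total Dirichlet concentration of each transition row,
    with a uniform prior mean (each cell gets ``alpha / S``); set
    ``alpha_mode="per_cell"`` to place ``alpha`` in every cell instead.  The
    MNIW prior on ``[A_z b_z]`` has mean ``[mean_A mean_b]``, row covariance
    ``Q_z`` and column covariance ``col_cov``; ``Q_z`` itself is inverse
    Wishart with scale ``iw_scale`` and ``iw_dof`` degrees of freedom.
    Defaults follow the loose-prior convention: alpha=4, iw_scale=I,
    iw_dof=d+2, mean_A=I, mean_b=0, col_cov=I.
    """

    alpha: float = 4.0
    iw_scale: np.ndarray | None = None
    iw_dof: float | None = None
    mean_A: np.ndarray | None = None
    mean_b: np.ndarray | None = None
    col_cov: np.ndarray | None = None
    alpha_mode: str = "uniform_mean"

    def resolve(self, d: int) -> "PriorHyper":
        """Return a copy with all matrix defaults made concrete for dimension d."""
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        out = replace(
            self,
            iw_scale=np.eye(d) if self.iw_scale is None else np.asarray(self.iw_scale, float),
            iw_dof=float(d + 2) if self.iw_dof is None else float(self.iw_dof),
            mean_A=np.eye(d) if self.mean_A is None else np.asarray(self.mean_A, float),
            mean_b=np.zeros(d) if self.mean_b is None else np.asarray(self.mean_b, float),
            col_cov=np.eye(d + 1) if self.col_cov is None else np.asarray(self.col_cov, float),
        )
        if out.iw_dof <= d - 1:
            raise ValueError("iw_dof must exceed d - 1")
        return out

    def row_concentration(self, S: int) -> np.ndarray:
        if self.alpha_mode == "uniform_mean":
            return np.full(S, self.alpha / S)
        if self.alpha_mode == "per_cell":
            return np.full(S, self.alpha)
        raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")


@dataclass
class GibbsConfig:
    n_iter: int = 300
    n_burn: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")


@dataclass
class FitResult:
    """Retained Gibbs draws plus the posterior summaries derived from them."""

    samples: list            # retained ARHMMParams draws
    posterior_marginals: list  # per trial: (T, S) state frequencies over draws
    expected_params: ARHMMParams
    map_sequences: list      # per trial: (T,) argmax of the marginals
    heldout: float | None = None


# ---------------------------------------------------------------------------
# numba kernels: scaled forward recursion and backward sampling


@njit(cache=False)
def _forward_scaled(logb, pi, init):
    T, S = logb.shape
    alpha = np.empty((T, S))
    m = logb[0].max()
    a = init * np.exp(logb[0] - m)
    c = a.sum()
    alpha[0] = a / c
    logz = np.log(c) + m
    for t in range(1, T):
        m = logb[t].max()
        pred = alpha[t - 1] @ pi
        a = pred * np.exp(logb[t] - m)
        c = a.sum()
        alpha[t] = a / c
        logz += np.log(c) + m
    return alpha, logz


@njit(cache=False)
def _sample_cat(w, u):
    acc = 0.0
    for k in range(w.shape[0]):
        acc += w[k]
        if u <= acc:
            return k
    return w.shape[0] - 1


@njit(cache=False)
def _backward_sample(alpha, pi, u):
    T, S = alpha.shape
    z = np.empty(T, dtype=np.int64)
    z[T - 1] = _sample_cat(alpha[T - 1], u[T - 1])
    for t in range(T - 2, -1, -1):
        w = alpha[t] * pi[:, z[t + 1]]
        w = w / w.sum()
        z[t] = _sample_cat(w, u[t])
    return z


# ---------------------------------------------------------------------------
# likelihood pieces


def emission_loglik(params: ARHMMParams, x: np.ndarray) -> np.ndarray:
    """Per-frame, per-state AR emission log densities.

    Row 0 is zero: the first frame of a trial is conditioned on, so state
    z_1 carries no emission term.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != params.d:
        raise ValueError("trial must be (T, d)")
    T = x.shape[0]
    if T < 2:
        raise ValueError("trial length must be >= 2")
    S, d = params.S, params.d
    logb = np.zeros((T, S))
    for s in range(S):
        resid = x[1:] - x[:-1] @ params.A[s].T - params.b[s]
        L = np.linalg.cholesky(params.Q[s])
        sol = solve_triangular(L, resid.T, lower=True)
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        logb[1:, s] = -0.5 * (d * _LOG2PI + logdet + maha)
    return logb


def log_joint_likelihood(params: ARHMMParams, trials, labels) -> float:
    """Joint log-likelihood of trajectories and a given label assignment.

    Sums, over trials and over t >= 2, the transition term
    log pi[z_{t-1}, z_t] and the Gaussian AR emission term; the first frame
    and first state contribute nothing beyond the (uniform) initial
    distribution, which is constant and omitted, matching the joint
    likelihood used for inference.
    """
    if len(trials) != len(labels):
        raise ValueError("trials and labels must align")
    with np.errstate(divide="ignore"):  # zero-prob entries are fine if unvisited
        logpi = np.log(params.pi)
    total = 0.0
    for x, z in zip(trials, labels):
        z = np.asarray(z)
        if z.max() >= params.S or z.min() < 0:
            raise ValueError("label out of range")
        logb = emission_loglik(params, np.asarray(x, float))
        total += logpi[z[:-1], z[1:]].sum()
        total += logb[np.arange(1, len(z)), z[1:]].sum()
    return float(total)


def heldout_loglik(params: ARHMMParams, trials) -> float:
    """Marginal log-likelihood log P(x | theta), states summed out by the
    forward algorithm with a uniform initial distribution."""
    total = 0.0
    for x in trials:
        logb = emission_loglik(params, np.asarray(x, float))
        _, logz = _forward_scaled(logb, params.pi, params.init)
        total += logz
    return float(total)


# ---------------------------------------------------------------------------
# Gibbs sweeps


def sample_states(params: ARHMMParams, trial: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw a state sequence exactly from P(z_1:T | x_1:T, theta)."""
    x = np.asarray(trial, dtype=float)
    logb = emission_loglik(params, x)
    alpha, _ = _forward_scaled(logb, params.pi, params.init)
    u = rng.random(x.shape[0])
    return _backward_sample(alpha, params.pi, u)


def _draw_mniw(Y: np.ndarray, Phi: np.ndarray, prior: PriorHyper,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conjugate MNIW posterior draw for one state's regression (A, b, Q).

    Y is (n, d) of successor frames, Phi is (n, d+1) of [predecessor, 1]
    rows; n may be zero, in which case the draw comes from the prior.
    """
    d = Y.shape[1] if Y.ndim == 2 else prior.mean_b.shape[0]
    M0 = np.concatenate([prior.mean_A, prior.mean_b[:, None]], axis=1)
    V0inv = np.linalg.inv(prior.col_cov)
    Vn_inv = V0inv + Phi.T @ Phi
    Vn = np.linalg.inv(Vn_inv)
    Vn = 0.5 * (Vn + Vn.T)
    Mn = (M0 @ V0inv + Y.T @ Phi) @ Vn
    Sn = prior.iw_scale + Y.T @ Y + M0 @ V0inv @ M0.T - Mn @ Vn_inv @ Mn.T
    Sn = 0.5 * (Sn + Sn.T)
    nun = prior.iw_dof + Y.shape[0]
    Q = np.atleast_2d(invwishart.rvs(df=nun, scale=Sn, random_state=rng))
    try:
        LQ = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError:
        Q = Q + 1e-10 * np.eye(d)
        LQ = np.linalg.cholesky(Q)
    LV = np.linalg.cholesky(Vn)
    Z = rng.standard_normal((d, d + 1))
    W = Mn + LQ @ Z @ LV.T
    return W[:, :d], W[:, d], Q


def sample_params(trials, labels, prior: PriorHyper, rng: np.random.Generator,
                  S: int) -> ARHMMParams:
    """Draw theta from its conjugate conditional posterior given the labels."""
    first = np.asarray(trials[0], dtype=float)
    d = first.shape[1]
    prior = prior.resolve(d)
    # transition counts over consecutive label pairs, pooled across trials
    counts = np.zeros((S, S))
    for z in labels:
        z = np.asarray(z)
        np.add.at(counts, (z[:-1], z[1:]), 1.0)
    conc = prior.row_concentration(S)
    pi = np.stack([rng.dirichlet(conc + counts[a]) for a in range(S)])
    # per-state regression sufficient statistics
    A = np.empty((S, d, d))
    b = np.empty((S, d))
    Q = np.empty((S, d, d))
    Ys: list[list[np.ndarray]] = [[] for _ in range(S)]
    Ps: list[list[np.ndarray]] = [[] for _ in range(S)]
    for x, z in zip(trials, labels):
        x = np.asarray(x, dtype=float)
        z = np.asarray(z)
        prev = x[:-1]
        nxt = x[1:]
        zt = z[1:]  # frame t's state governs the step into frame t
        for s in range(S):
            m = zt == s
            if m.any():
                Ys[s].append(nxt[m])
                Ps[s].append(np.concatenate([prev[m], np.ones((m.sum(), 1))], axis=1))
    for s in range(S):
        if Ys[s]:
            Y = np.concatenate(Ys[s])
            Phi = np.concatenate(Ps[s])
        else:
            Y = np.zeros((0, d))
            Phi = np.zeros((0, d + 1))
        A[s], b[s], Q[s] = _draw_mniw(Y, Phi, prior, rng)
    init = np.full(S, 1.0 / S)
    return ARHMMParams(pi=pi, init=init, A=A, b=b, Q=Q)


def gibbs_fit(trials, S: int, prior: PriorHyper | None = None,
              cfg: GibbsConfig | None = None) -> FitResult:
    """Fit the AR-HMM by Gibbs sampling.

    Label sequences are initialized iid uniform; each iteration draws the
    parameters given the labels, then resamples every trial's label sequence
    by forward-filter backward-sample.  Draws after the burn-in are retained
    (100 under the defaults of 300 iterations with 200 burned); the
    per-frame posterior marginals are the label frequencies across retained
    draws, the expected parameters their average, and the MAP sequence the
    per-frame argmax of the marginals.
    """
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    trials = [np.asarray(x, dtype=float) for x in trials]
    for x in trials:
        if x.shape[0] < 2:
            raise ValueError("every trial must have length >= 2")
    if S < 1:
        raise ValueError("S must be >= 1")
    prior = (prior or PriorHyper()).resolve(trials[0].shape[1])
    cfg = cfg or GibbsConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = [rng.integers(0, S, size=x.shape[0]) for x in trials]
    counts = [np.zeros((x.shape[0], S)) for x in trials]
    retained: list[ARHMMParams] = []
    for it in range(cfg.n_iter):
        params = sample_params(trials, labels, prior, rng, S)
        labels = [sample_states(params, x, rng) for x in trials]
        if it >= cfg.n_burn:
            retained.append(params)
            for c, z in zip(counts, labels):
                c[np.arange(z.shape[0]), z] += 1.0
    marginals = [c / c.sum(axis=1, keepdims=True) for c in counts]
    maps = [np.argmax(m, axis=1) for m in marginals]
    expected = _average_params(retained)
    return FitResult(samples=retained, posterior_marginals=marginals,
                     expected_params=expected, map_sequences=maps)


def _average_params(samples: list) -> ARHMMParams:
    pi = np.mean([p.pi for p in samples], axis=0)
    pi = pi / pi.sum(axis=1, keepdims=True)  # guard rounding
    return ARHMMParams(
        pi=pi,
        init=np.mean([p.init for p in samples], axis=0),
        A=np.mean([p.A for p in samples], axis=0),
        b=np.mean([p.b for p in samples], axis=0),
        Q=np.mean([p.Q for p in samples], axis=0),
    )


# ---------------------------------------------------------------------------
# model assessment utilities


def n_free_parameters(S: int, d: int) -> int:
    """Free parameter count: S(S-1) transition entries plus, per state,
    d^2 (A) + d (b) + d(d+1)/2 (symmetric Q) = 3d(d+1)/2."""
    if S < 1 or d < 1:
        raise ValueError("S and d must be >= 1")
    return S * (S - 1) + 3 * S * d * (d + 1) // 2


def usage_filter(map_sequences, threshold: float = 0.05) -> np.ndarray:
    """Motif ids whose share of assigned frames is at least ``threshold``."""
    all_labels = np.concatenate([np.asarray(z) for z in map_sequences])
    if all_labels.size == 0:
        raise ValueError("empty sequences")
    ids, n = np.unique(all_labels, return_counts=True)
    share = n / all_labels.size
    return ids[share >= threshold]


def match_states(true_labels, est_labels, S: int) -> np.ndarray:
    """Hungarian-optimal permutation ``perm`` such that ``perm[est]`` best
    matches the true labels (maximum frame agreement)."""
    t = np.concatenate([np.asarray(z) for z in true_labels])
    e = np.concatenate([np.asarray(z) for z in est_labels])
    conf = np.zeros((S, S))
    np.add.at(conf, (e, t), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(S, dtype=int)
    perm[rows] = cols
    return perm


def crossval_model_scan(trials, S_list, prior: PriorHyper | None = None,
                        cfg: GibbsConfig | None = None, split_seed: int = 0,
                        test_fraction: float = 0.25):
    """Held-out log-likelihood per candidate state count S.

    Splits at trial granularity, fits one model per S on the training
    trials, and evaluates the fit model's marginal likelihood on the test
    trials.  Returns a list of (S, heldout_loglik) in S_list order.
    """
    if not list(S_list):
        raise ValueError("S_list must be non-empty")
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to split")
    rng = np.random.default_rng(split_seed)
    idx = rng.permutation(len(trials))
    n_test = max(1, int(round(test_fraction * len(trials))))
    test_idx = set(idx[:n_test].tolist())
    train = [x for i, x in enumerate(trials) if i not in test_idx]
    test = [x for i, x in enumerate(trials) if i in test_idx]
    cfg = cfg or GibbsConfig()
    out = []
    for k, S in enumerate(S_list):
        fit = gibbs_fit(train, S, prior=prior,
                        cfg=GibbsConfig(cfg.n_iter, cfg.n_burn, cfg.seed + k))
        out.append((S, heldout_loglik(fit.expected_params, test)))
    return out
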