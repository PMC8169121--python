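"""Decoding trial labels from motif transition statistics.

Each trial's MAP motif sequence is summarized by its empirical transition
probability matrix (counts of consecutive state pairs, row-normalized);
the flattened matrix is the feature vector of a multi-class linear
discriminant analysis (LDA) decoder evaluated with stratified five-fold
cross-validation.  Significance comes from shuffling the training labels
within each fold (100 times), z-scoring the real per-class accuracy
against the shuffle distribution and averaging z across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold


@dataclass
class TransitionFeature:
    trial_id: int
    matrix: np.ndarray         # (S, S) row-normalized
    counts: np.ndarray         # (S, S) raw pair counts
    undefined_rows: np.ndarray  # rows with zero outgoing count (imputed uniform)


def empirical_transition_matrix(sequence, S: int, trial_id: int = 0) -> TransitionFeature:
    """Empirical single-trial transition matrix.

    Counts n_ab of consecutive pairs (z_t = a, z_{t+1} = b), row-normalized;
    rows with no outgoing transitions are imputed uniform and flagged so the
    feature dimension stays fixed.
    """
    z = np.asarray(sequence)
    if z.shape[0] < 2:
        raise ValueError("sequence must have length >= 2")
    if z.min() < 0 or z.max() >= S:
        raise ValueError("state out of range")
    counts = np.zeros((S, S))
    np.add.at(counts, (z[:-1], z[1:]), 1.0)
    row_sum = counts.sum(axis=1)
    undefined = row_sum == 0
    mat = np.empty_like(counts)
    mat[~undefined] = counts[~undefined] / row_sum[~undefined, None]
    mat[undefined] = 1.0 / S
    return TransitionFeature(trial_id=trial_id, matrix=mat, counts=counts,
                             undefined_rows=undefined)


def features_from_sequences(sequences, S: int) -> np.ndarray:
    """(n_trials, S^2) flattened empirical transition matrices."""
    return np.stack([empirical_transition_matrix(z, S, i).matrix.ravel()
                     for i, z in enumerate(sequences)])


def _make_lda(shrinkage):
    if shrinkage is None:
        return LinearDiscriminantAnalysis()
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)


def _per_class_accuracy(y_true, y_pred, classes) -> np.ndarray:
    acc = np.full(len(classes), np.nan)
    for i, c in enumerate(classes):
        m = y_true == c
        if m.any():
            acc[i] = np.mean(y_pred[m] == c)
    return acc


def lda_decode(features, labels, folds: int = 5, seed: int = 0,
               shrinkage="auto"):
    """Cross-validated LDA decoding.

    Stratified k-fold (shuffled, seeded); the LDA uses pooled-covariance
    shrinkage by default since S^2 features can exceed the trial count.
    Returns a dict with the row-normalized confusion matrix (rows sum to
    1), per-class accuracy (the confusion diagonal), overall accuracy, and
    the class order.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    conf = np.zeros((classes.shape[0], classes.shape[0]))
    cls_index = {c: i for i, c in enumerate(classes)}
    correct = 0
    for train, test in skf.split(X, y):
        clf = _make_lda(shrinkage)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        correct += int(np.sum(pred == y[test]))
        for t, p in zip(y[test], pred):
            conf[cls_index[t], cls_index[p]] += 1
    row = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        conf_norm = np.where(row > 0, conf / row, np.nan)
    return {
        "classes": classes,
        "confusion": conf_norm,
        "per_class_accuracy": np.diag(conf_norm),
        "accuracy": correct / y.shape[0],
    }


def shuffle_significance(features, labels, folds: int = 5,
                         n_shuffles: int = 100, seed: int = 0,
                         shrinkage="auto"):
    """Label-shuffle significance of the decoding accuracy.

    Per fold: train on the real labels and score per-class accuracy on the
    test set; then repeatedly shuffle the *training* labels, refit, and
    score on the unshuffled test set to build a null accuracy distribution.
    Per-class z-scores are averaged across folds and converted to one-sided
    p-values via the standard normal tail; a zero-variance null falls back
    to count exceedance.
    """
    if n_shuffles < 1:
        raise ValueError("need at least 1 shuffle")
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    k = classes.shape[0]
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    z_folds = []
    obs_all, null_all = [], []
    for train, test in skf.split(X, y):
        clf = _make_lda(shrinkage)
        clf.fit(X[train], y[train])
        obs = _per_class_accuracy(y[test], clf.predict(X[test]), classes)
        null = np.empty((n_shuffles, k))
        for s in range(n_shuffles):
            y_sh = rng.permutation(y[train])
            clf = _make_lda(shrinkage)
            clf.fit(X[train], y_sh)
            null[s] = _per_class_accuracy(y[test], clf.predict(X[test]), classes)
        mu = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (obs - mu) / sd
        z[sd == 0] = np.nan
        z_folds.append(z)
        obs_all.append(obs)
        null_all.append(null)
    z_folds = np.asarray(z_folds)
    z_mean = np.nanmean(z_folds, axis=0)
    # under the null the fold-averaged z has standard error 1/sqrt(#folds)
    n_eff = np.sum(np.isfinite(z_folds), axis=0)
    p = norm.sf(z_mean * np.sqrt(np.maximum(n_eff, 1)))
    # exceedance fallback where every fold had a degenerate null
    for i in range(k):
        if not np.isfinite(z_mean[i]):
            obs_i = np.nanmean([o[i] for o in obs_all])
            pooled = np.concatenate([nl[:, i] for nl in null_all])
            p[i] = (1.0 + np.sum(pooled >= obs_i)) / (1.0 + pooled.shape[0])
    return {
        "classes": classes,
        "z_per_fold": z_folds,
        "z": z_mean,
        "p": p,
    }
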