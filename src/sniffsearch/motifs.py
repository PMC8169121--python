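"""Higher-order structure of motif sequences.

Motifs are grouped into two behavioral states — investigation and approach —
by clustering the rows of the fit transition matrix (Euclidean metric on
raw transition probabilities).  Motif onsets (frames whose label differs
from the previous frame) are then related to the sniff cycle in time
(PSTH of inhalations around onsets) and in phase (onset position within
the normalized sniff cycle), with modulation indices tested against
trial-shuffled nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .kinematics import modulation_index
from .sniff import SniffEvents, sniff_phase

INVESTIGATION = "investigation"
APPROACH = "approach"


@dataclass
class StateGrouping:
    motif_ids: np.ndarray      # retained motif ids, ascending
    group: np.ndarray          # 0/1 cluster index per motif
    linkage_record: np.ndarray | None = None
    names: dict | None = None  # group index -> semantic name, once assigned

    def __post_init__(self) -> None:
        self.motif_ids = np.asarray(self.motif_ids)
        self.group = np.asarray(self.group)
        if set(np.unique(self.group)) - {0, 1}:
            raise ValueError("exactly two groups expected")

    def group_of(self, motif: int) -> int | None:
        hits = np.nonzero(self.motif_ids == motif)[0]
        return int(self.group[hits[0]]) if hits.size else None


def cluster_transition_matrix(pi: np.ndarray, motif_ids=None,
                              method: str = "ward", seed: int = 0) -> StateGrouping:
    """Split motifs into two groups by clustering transition-matrix rows.

    Ward agglomerative clustering (Euclidean, cut at k=2) by default;
    ``method="kmeans"`` uses k-means with 100 restarts.  Rows are the raw
    outgoing transition probabilities of each retained motif.
    """
    pi = np.asarray(pi, float)
    if pi.ndim != 2 or pi.shape[0] != pi.shape[1]:
        raise ValueError("pi must be square")
    S = pi.shape[0]
    if S < 2:
        raise ValueError("need at least 2 motifs to cluster")
    motif_ids = np.arange(S) if motif_ids is None else np.asarray(motif_ids)
    if method == "ward":
        Z = linkage(pi, method="ward", metric="euclidean")
        lab = fcluster(Z, t=2, criterion="maxclust") - 1
        rec = Z
    elif method == "kmeans":
        km = KMeans(n_clusters=2, n_init=100, random_state=seed)
        lab = km.fit_predict(pi)
        rec = None
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # canonical labeling: group containing the lowest motif id is 0
    if lab[0] == 1:
        lab = 1 - lab
    return StateGrouping(motif_ids=motif_ids, group=lab, linkage_record=rec)


def assign_state_names(grouping: StateGrouping, mean_speed_per_motif) -> StateGrouping:
    """Name the slower cluster 'investigation' and the faster 'approach'
    based on mean nose speed per motif."""
    v = np.asarray(mean_speed_per_motif, float)
    m0 = np.nanmean(v[grouping.group == 0])
    m1 = np.nanmean(v[grouping.group == 1])
    names = {0: INVESTIGATION, 1: APPROACH} if m0 <= m1 else {0: APPROACH, 1: INVESTIGATION}
    grouping.names = names
    return grouping


def motif_onsets(map_sequences, frame_times_list) -> pd.DataFrame:
    """Onset events: the first frame of every trial plus every frame whose
    motif differs from the previous frame's.  Columns: motif, time_s, trial."""
    recs = []
    for trial, (z, t) in enumerate(zip(map_sequences, frame_times_list)):
        z = np.asarray(z)
        t = np.asarray(t, float)
        onset_idx = np.concatenate([[0], 1 + np.nonzero(np.diff(z) != 0)[0]])
        for i in onset_idx:
            recs.append((int(z[i]), float(t[i]), trial))
    return pd.DataFrame(recs, columns=["motif", "time_s", "trial"])


def onset_time_psth(onset_times, inhalation_times, window: float = 0.4,
                    bin_s: float = 0.0125):
    """Rate-normalized PSTH of inhalation times around motif onsets.

    Counts inhalations at lags in [-window/2, window/2] relative to each
    onset and normalizes to a rate in Hz (counts / (n_onsets * bin)).
    Returns (bin_centers_s, rate_hz).
    """
    onset_times = np.asarray(onset_times, float)
    inhalation_times = np.sort(np.asarray(inhalation_times, float))
    half = window / 2.0
    edges = np.arange(-half, half + bin_s / 2, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(centers.shape[0])
    if onset_times.size == 0 or inhalation_times.size == 0:
        return centers, counts
    for t0 in onset_times:
        lo = np.searchsorted(inhalation_times, t0 - half)
        hi = np.searchsorted(inhalation_times, t0 + half)
        lags = inhalation_times[lo:hi] - t0
        counts += np.histogram(lags, bins=edges)[0]
    rate = counts / (onset_times.size * bin_s)
    return centers, rate


def onset_phase_hist(onset_times, events: SniffEvents, n_bins: int = 10):
    """Histogram of the sniff phase of motif onsets over [0, 1).

    Onsets outside any kept sniff are excluded.  Also reports the mean
    end-of-inhalation phase of the kept sniffs (the inhalation/exhalation
    boundary on the normalized cycle).  Returns (bin_centers, counts,
    mean_inhalation_end_phase).
    """
    onset_times = np.asarray(onset_times, float)
    phases = sniff_phase(onset_times, events) if onset_times.size else np.zeros(0)
    phases = phases[np.isfinite(phases)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.histogram(phases, bins=edges)[0].astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kept = events.kept_mask
    # phase of the exhalation onset within each kept sniff
    if events.n_sniffs:
        dur = events.durations[kept]
        exh = events.exhalation_onsets[: events.n_sniffs][kept]
        inh = events.inhalation_onsets[: events.n_sniffs][kept]
        frac = (exh - inh) / dur
        mean_end = float(np.nanmean(frac)) if frac.size else float("nan")
    else:
        mean_end = float("nan")
    return centers, counts, mean_end


def onset_modulation_test(onsets_per_trial, sniffs_per_trial, trial_starts,
                          n: int = 1000, seed: int = 0, window: float = 0.4,
                          bin_s: float = 0.0125, n_phase_bins: int = 10,
                          exclude_self: bool = False):
    """Modulation of motif onsets by the sniff cycle, in time and phase.

    MI_time is the modulation index of the mean onset-triggered inhalation
    PSTH across trials; MI_phase the same for the onset phase histogram.
    Nulls re-pair onset trains with sniff trains across trials (uniform
    random permutations of trial indices, trains taken relative to trial
    start; ``exclude_self=True`` restricts to derangements).  Returns
    (MI_time, MI_phase, p_time, p_phase).
    """
    m = len(onsets_per_trial)
    if m < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    rel_on = [np.asarray(o, float) - trial_starts[i] for i, o in enumerate(onsets_per_trial)]
    rel_ev = []
    for i, ev in enumerate(sniffs_per_trial):
        shifted = SniffEvents(
            inhalation_onsets=ev.inhalation_onsets - trial_starts[i],
            exhalation_onsets=ev.exhalation_onsets - trial_starts[i],
            durations=ev.durations, kept_mask=ev.kept_mask)
        rel_ev.append(shifted)
    # pairwise histograms: onsets of trial i against sniffs of trial j
    Ht = np.empty((m, m), dtype=object)
    Hp = np.empty((m, m), dtype=object)
    for i in range(m):
        for j in range(m):
            _, Ht[i, j] = onset_time_psth(rel_on[i], rel_ev[j].inhalation_onsets,
                                          window=window, bin_s=bin_s)
            _, Hp[i, j], _ = onset_phase_hist(rel_on[i], rel_ev[j], n_bins=n_phase_bins)

    def stats(perm):
        ht = np.mean([Ht[i, perm[i]] for i in range(m)], axis=0)
        hp = np.mean([Hp[i, perm[i]] for i in range(m)], axis=0)
        return modulation_index(ht), modulation_index(hp)

    mi_t, mi_p = stats(np.arange(m))
    from .kinematics import _null_permutation
    null = np.asarray([stats(_null_permutation(m, rng, exclude_self))
                       for _ in range(n)])
    with np.errstate(invalid="ignore"):
        p_t = (1.0 + np.nansum(null[:, 0] >= mi_t)) / (1.0 + n)
        p_p = (1.0 + np.nansum(null[:, 1] >= mi_p)) / (1.0 + n)
    return mi_t, mi_p, float(p_t), float(p_p)


def state_frame_labels(map_sequences, grouping: StateGrouping):
    """Per-frame two-state labels (group index 0/1); frames whose motif is
    not covered by the grouping get -1."""
    lut = np.full(int(max(int(np.max(np.concatenate(map_sequences))) + 1,
                          int(grouping.motif_ids.max()) + 1)), -1, dtype=int)
    lut[grouping.motif_ids] = grouping.group
    return [lut[np.asarray(z)] for z in map_sequences]


def state_summary(map_sequences, speed_per_trial, rate_per_trial,
                  mouse_ids=None) -> pd.DataFrame:
    """Mean nose speed and sniff rate per motif, z-scored within mouse.

    ``rate_per_trial`` entries may be None (missing sniff data for that
    trial); the sniff-rate column is then NaN for frames of those trials.
    """
    mouse_ids = ["m00"] * len(map_sequences) if mouse_ids is None else list(mouse_ids)
    recs = []
    for z, sp, rt, mid in zip(map_sequences, speed_per_trial, rate_per_trial, mouse_ids):
        z = np.asarray(z)
        sp = np.asarray(sp, float)
        rt = np.full(z.shape, np.nan) if rt is None else np.asarray(rt, float)
        for t in range(z.shape[0]):
            recs.append((mid, int(z[t]), sp[t], rt[t]))
    df = pd.DataFrame(recs, columns=["mouse", "motif", "speed", "rate"])
    out = df.groupby(["mouse", "motif"], as_index=False).mean()

    def _z(col):
        v = col.to_numpy(float)
        if not np.isfinite(v).any():
            return np.full_like(v, np.nan)
        sd = np.nanstd(v)
        if not np.isfinite(sd) or sd == 0:
            return np.zeros_like(v)
        return (v - np.nanmean(v)) / sd

    out["speed_z"] = out.groupby("mouse")["speed"].transform(_z)
    out["rate_z"] = out.groupby("mouse")["rate"].transform(_z)
    return out
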