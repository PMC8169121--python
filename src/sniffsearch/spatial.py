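"""Allocentric maps and spatial statistics over the 15 x 25 cm arena.

Maps are 2-D histograms of nose position (0.5 cm bins, 50 x 30, for
occupancy and sniff rate; 1 cm bins, 25 x 15, for the two-state occupancy
maps), anchored at the initiation-port corner: axis 0 is longitudinal
(0 -> 25 cm toward the odor ports), axis 1 lateral (0 -> 15 cm).  The
investigation-approach index (I.A.I.) is (investigation - approach
occupancy) / (their sum) per bin; the transition zone is the 5-10 cm
longitudinal band.  Correct/incorrect comparisons are evaluated against
nulls built by scrambling trial outcome labels within mice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

ARENA_EXTENT = (0.0, 25.0, 0.0, 15.0)  # (x0, x1, y0, y1) cm


@dataclass
class SpatialMap:
    grid: np.ndarray               # (nx, ny): longitudinal x lateral
    bin_size: float                # cm
    extent: tuple = ARENA_EXTENT
    smoothing_sigma: float | None = None   # bins; recorded when applied
    n_clipped: int = 0

    @property
    def x_centers(self) -> np.ndarray:
        x0, x1, _, _ = self.extent
        return x0 + self.bin_size * (0.5 + np.arange(self.grid.shape[0]))

    @property
    def y_centers(self) -> np.ndarray:
        _, _, y0, y1 = self.extent
        return y0 + self.bin_size * (0.5 + np.arange(self.grid.shape[1]))

    def smoothed(self, sigma: float = 1.0) -> "SpatialMap":
        g = ndimage.gaussian_filter(np.nan_to_num(self.grid), sigma=sigma)
        return replace(self, grid=g, smoothing_sigma=sigma)


@dataclass
class IAIProfile:
    axis: str                      # "longitudinal" | "lateral"
    bin_centers: np.ndarray        # cm
    values: np.ndarray
    zone: tuple | None = None      # restriction on the orthogonal axis (cm)


def _grid_shape(bin_size: float, extent=ARENA_EXTENT) -> tuple[int, int]:
    x0, x1, y0, y1 = extent
    nx = int(round((x1 - x0) / bin_size))
    ny = int(round((y1 - y0) / bin_size))
    if abs(nx * bin_size - (x1 - x0)) > 1e-9 or abs(ny * bin_size - (y1 - y0)) > 1e-9:
        raise ValueError("bins must tile the arena exactly")
    return nx, ny


def occupancy_map(xy, bin_size: float = 0.5, extent=ARENA_EXTENT,
                  normalize: bool = False) -> SpatialMap:
    """2-D histogram of nose positions; out-of-arena points are clipped to
    the edge bins and counted in ``n_clipped``."""
    xy = np.asarray(xy, float)
    xy = xy[np.all(np.isfinite(xy), axis=1)]
    x0, x1, y0, y1 = extent
    nx, ny = _grid_shape(bin_size, extent)
    out = ((xy[:, 0] < x0) | (xy[:, 0] > x1) | (xy[:, 1] < y0) | (xy[:, 1] > y1))
    eps = 1e-9
    xs = np.clip(xy[:, 0], x0, x1 - eps)
    ys = np.clip(xy[:, 1], y0, y1 - eps)
    grid, _, _ = np.histogram2d(xs, ys, bins=(nx, ny),
                                range=((x0, x1), (y0, y1)))
    if normalize and xy.shape[0]:
        grid = grid / xy.shape[0]
    return SpatialMap(grid=grid, bin_size=bin_size, extent=extent,
                      n_clipped=int(out.sum()))


def sniff_rate_map(sniff_xy, occupancy: SpatialMap,
                   frame_rate: float | None = None) -> SpatialMap:
    """Sniff count per position bin divided by the occupancy count: sniffs
    per frame (or Hz when ``frame_rate`` is given); NaN where unvisited."""
    counts = occupancy_map(sniff_xy, bin_size=occupancy.bin_size,
                           extent=occupancy.extent)
    if counts.grid.shape != occupancy.grid.shape:
        raise ValueError("grid mismatch")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = counts.grid / occupancy.grid
    rate[occupancy.grid == 0] = np.nan
    if frame_rate is not None:
        rate = rate * frame_rate
    return replace(occupancy, grid=rate, n_clipped=counts.n_clipped)


def state_occupancy_maps(xy, state_labels, bin_size: float = 1.0,
                         extent=ARENA_EXTENT, normalize: bool = False):
    """Occupancy compiled separately for investigation (label 0) and
    approach (label 1) frames; unlabeled frames (-1) are skipped.  With
    ``normalize`` each map becomes its share of the total per-bin
    occupancy (inv / (inv + app))."""
    xy = np.asarray(xy, float)
    lab = np.asarray(state_labels)
    inv = occupancy_map(xy[lab == 0], bin_size=bin_size, extent=extent)
    app = occupancy_map(xy[lab == 1], bin_size=bin_size, extent=extent)
    if normalize:
        tot = inv.grid + app.grid
        with np.errstate(invalid="ignore", divide="ignore"):
            gi, ga = inv.grid / tot, app.grid / tot
        gi[tot == 0] = np.nan
        ga[tot == 0] = np.nan
        inv = replace(inv, grid=gi)
        app = replace(app, grid=ga)
    return inv, app


def iai(inv: SpatialMap, app: SpatialMap) -> SpatialMap:
    """Investigation-approach index per bin: (inv - app) / (inv + app);
    NaN where both are zero."""
    if inv.grid.shape != app.grid.shape:
        raise ValueError("maps must share the grid")
    tot = inv.grid + app.grid
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (inv.grid - app.grid) / tot
    v[tot == 0] = np.nan
    return replace(inv, grid=v)


def axis_profile(map_: SpatialMap, axis: str = "longitudinal",
                 zone: tuple | None = None) -> IAIProfile:
    """Project a map onto one axis by summing over the other, optionally
    restricted to a ``zone`` (cm window) on the orthogonal axis."""
    grid = np.nan_to_num(map_.grid)
    if axis == "longitudinal":
        ortho_centers, centers = map_.y_centers, map_.x_centers
        sum_axis = 1
    elif axis == "lateral":
        ortho_centers, centers = map_.x_centers, map_.y_centers
        sum_axis = 0
    else:
        raise ValueError("axis must be 'longitudinal' or 'lateral'")
    if zone is not None:
        lo, hi = zone
        x0, x1, y0, y1 = map_.extent
        bound = (x0, x1) if axis == "lateral" else (y0, y1)
        if lo < bound[0] - 1e-9 or hi > bound[1] + 1e-9:
            raise ValueError("zone lies outside the arena")
        keep = (ortho_centers >= lo) & (ortho_centers <= hi)
        grid = grid[keep, :] if sum_axis == 0 else grid[:, keep]
    vals = grid.sum(axis=sum_axis)
    return IAIProfile(axis=axis, bin_centers=centers, values=vals, zone=zone)


def iai_axis_profile(inv: SpatialMap, app: SpatialMap,
                     axis: str = "longitudinal",
                     zone: tuple | None = None) -> IAIProfile:
    """I.A.I. computed on axis projections: project both maps first, then
    take (inv - app)/(inv + app) per projected bin."""
    pi = axis_profile(inv, axis, zone)
    pa = axis_profile(app, axis, zone)
    tot = pi.values + pa.values
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (pi.values - pa.values) / tot
    v[tot == 0] = np.nan
    return IAIProfile(axis=axis, bin_centers=pi.bin_centers, values=v, zone=zone)


def reorient_by_choice(trials, arena_width: float = 15.0):
    """Flip the lateral axis of right-choice trials (y -> width - y) so all
    trajectories end on the same side; trials without a recorded choice are
    excluded with a warning."""
    from dataclasses import replace as dc_replace
    out = []
    for tr in trials:
        if tr.meta.choice is None:
            warnings.warn("trial without choice excluded from reorientation")
            continue
        if tr.meta.choice == "right":
            flip = np.array([1.0, -1.0])
            off = np.array([0.0, arena_width])
            tr = dc_replace(tr, nose=tr.nose * flip + off,
                            head=tr.head * flip + off,
                            body=tr.body * flip + off)
        out.append(tr)
    return out


def correct_incorrect_permutation(profiles_by_mouse, n: int = 1000, seed: int = 0):
    """Permutation test of outcome differences in spatial profiles.

    ``profiles_by_mouse``: list over mice of (profiles, correct) where
    profiles is (n_trials, n_bins) and correct a boolean array.  The
    observed statistic is the grand mean over mice of per-mouse
    (mean correct - mean incorrect) profiles; the null scrambles outcome
    labels within each mouse before re-averaging, so it carries both
    within- and across-mouse variability.  Returns (observed, null array
    (n, n_bins), pointwise two-sided p).
    """
    if n < 1:
        raise ValueError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    usable = []
    for profiles, correct in profiles_by_mouse:
        profiles = np.asarray(profiles, float)
        correct = np.asarray(correct, bool)
        if correct.all() or (~correct).all():
            warnings.warn("mouse with a single outcome class excluded")
            continue
        usable.append((profiles, correct))
    if not usable:
        raise ValueError("no mouse has both outcome classes")

    def diff(profiles, mask):
        return profiles[mask].mean(axis=0) - profiles[~mask].mean(axis=0)

    observed = np.mean([diff(p, c) for p, c in usable], axis=0)
    null = np.empty((n, observed.shape[0]))
    for k in range(n):
        per_mouse = []
        for p, c in usable:
            per_mouse.append(diff(p, rng.permutation(c)))
        null[k] = np.mean(per_mouse, axis=0)
    p = (1.0 + (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)) / (1.0 + n)
    return observed, null, p


def familywise_max_statistic_p(observed, null) -> float:
    """Family-wise p via the max-|statistic| distribution of the null."""
    mx = np.abs(null).max(axis=1)
    return float((1.0 + (mx >= np.abs(observed).max()).sum()) / (1.0 + null.shape[0]))


def split_stay_switch(trials, leave_x: float = 5.0, arena_width: float = 15.0):
    """Partition trials by whether the first-turn side equals the chosen side.

    The first-turn side is the lateral half (left = y above the midline)
    occupied at the first frame with longitudinal position beyond
    ``leave_x`` (leaving the initiation-port region); trials never leaving
    the region are excluded.
    """
    stay, switch = [], []
    mid = arena_width / 2.0
    for tr in trials:
        beyond = np.nonzero(tr.nose[:, 0] > leave_x)[0]
        if beyond.size == 0 or tr.meta.choice is None:
            continue
        first_side = "left" if tr.nose[beyond[0], 1] > mid else "right"
        (stay if first_side == tr.meta.choice else switch).append(tr)
    return stay, switch


def session_performance(trials, frame_rate: float = 80.0):
    """Session summary: percent correct, mean trial duration, mean nose-path
    tortuosity, and a binomial test of performance against chance (0.5).

    Trials with undefined outcome (0:0 condition) are excluded from the
    percent-correct numerator and denominator.
    """
    from .kinematics import tortuosity
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    outcomes = [tr.meta.correct for tr in trials if tr.meta.correct is not None]
    n = len(outcomes)
    k = int(sum(outcomes))
    pct = 100.0 * k / n if n else float("nan")
    p_binom = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue) if n else float("nan")
    durs = [tr.duration_s for tr in trials]
    torts = [tortuosity(tr.nose) for tr in trials]
    return {
        "percent_correct": pct,
        "mean_duration_s": float(np.mean(durs)),
        "mean_tortuosity": float(np.nanmean(torts)),
        "binomial_p": p_binom,
        "n_trials": len(trials),
    }


def ranksum_compare(a, b):
    """Wilcoxon rank-sum comparison between two condition samples."""
    res = stats.ranksums(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
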