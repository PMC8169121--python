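"""Odor-plume maps from gridded PID recordings.

Two-second PID traces recorded at a 7 x 5 grid of arena locations (for
left-source and right-source trials) are reduced to 25 ms chunk means —
about one inhalation's worth of odor sampling.  Mean-concentration maps
average chunks per location; discriminability maps run ROC analysis per
location between the left-trial and right-trial distributions, report
|2*AUC - 1| in [0, 1], and can be quantized to eight grayscale levels for
display.  Gradient discriminability assembles pseudosamples (one chunk
mean per location), takes the spatial gradient angle per bin, and runs the
same ROC on the angle distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class PlumeGrid:
    x_centers: np.ndarray          # (nx,) longitudinal cm
    y_centers: np.ndarray          # (ny,) lateral cm
    traces: np.ndarray             # (n_recordings, n_samples)
    row: np.ndarray                # (n,) longitudinal grid index
    col: np.ndarray                # (n,) lateral grid index
    side: np.ndarray               # (n,) "left" | "right"
    sample_rate: float
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.traces.ndim != 2:
            raise ValueError("traces must be (n_recordings, n_samples)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.x_centers.shape[0], self.y_centers.shape[0]


@dataclass
class DiscriminabilityMap:
    values: np.ndarray             # (nx, ny) scaled |auROC| in [0, 1]
    kind: str                      # "absolute" | "gradient"
    x_centers: np.ndarray | None = None
    y_centers: np.ndarray | None = None
    quantization_levels: int | None = None


def chunk_means(trace, sample_rate: float, chunk_s: float = 0.025) -> np.ndarray:
    """Mean of consecutive chunks of the stated length; a trailing
    remainder shorter than one chunk is dropped."""
    trace = np.asarray(trace, float)
    w = int(round(chunk_s * sample_rate))
    if w < 1 or w > trace.shape[0]:
        raise ValueError("chunk longer than the trace")
    k = trace.shape[0] // w
    return trace[: k * w].reshape(k, w).mean(axis=1)


def auroc_scaled(a, b) -> float:
    """Scaled absolute ROC area between two samples: |2*AUC - 1|, 0 for
    identical distributions and 1 for disjoint ones."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    y = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    auc = roc_auc_score(y, np.concatenate([a, b]))
    return float(abs(2.0 * auc - 1.0))


def mean_concentration_map(grid: PlumeGrid, side: str):
    """Trial-and-time mean PID value per sampling location for one source
    side; locations without recordings get NaN.  Returns an (nx, ny) array
    aligned with the grid centers."""
    nx, ny = grid.shape
    out = np.full((nx, ny), np.nan)
    for i in range(nx):
        for j in range(ny):
            m = (grid.row == i) & (grid.col == j) & (grid.side == side)
            if m.any():
                out[i, j] = float(grid.traces[m].mean())
    return out


def _chunk_distributions(grid: PlumeGrid, chunk_s: float):
    """Per-location, per-side list of chunk means (trial order preserved)."""
    nx, ny = grid.shape
    dist = {s: [[None] * ny for _ in range(nx)] for s in ("left", "right")}
    for s in ("left", "right"):
        for i in range(nx):
            for j in range(ny):
                m = (grid.row == i) & (grid.col == j) & (grid.side == s)
                if m.any():
                    dist[s][i][j] = np.concatenate(
                        [chunk_means(tr, grid.sample_rate, chunk_s)
                         for tr in grid.traces[m]])
    return dist


def auroc_map_absolute(grid: PlumeGrid, chunk_s: float = 0.025) -> DiscriminabilityMap:
    """Absolute-concentration discriminability: per location, ROC between
    the left-trial and right-trial chunk-mean distributions."""
    nx, ny = grid.shape
    dist = _chunk_distributions(grid, chunk_s)
    vals = np.full((nx, ny), np.nan)
    for i in range(nx):
        for j in range(ny):
            a, b = dist["left"][i][j], dist["right"][i][j]
            if a is not None and b is not None:
                vals[i, j] = auroc_scaled(a, b)
    return DiscriminabilityMap(values=vals, kind="absolute",
                               x_centers=grid.x_centers, y_centers=grid.y_centers)


def gradient_pseudosamples(grid: PlumeGrid, chunk_s: float = 0.025):
    """Gradient-angle distributions per location and side.

    For each side, pseudosample j pairs the j-th chunk mean across all
    locations into one spatial snapshot (truncated to the shared count);
    the gradient angle per bin comes from central differences on the grid
    (one-sided at edges).  Returns {side: (n_pseudosamples, nx, ny) angle
    array in radians}.
    """
    nx, ny = grid.shape
    dist = _chunk_distributions(grid, chunk_s)
    out = {}
    for s in ("left", "right"):
        cells = dist[s]
        if any(cells[i][j] is None for i in range(nx) for j in range(ny)):
            raise ValueError(f"missing recordings for side {s!r}")
        k = min(cells[i][j].shape[0] for i in range(nx) for j in range(ny))
        fields = np.empty((k, nx, ny))
        for i in range(nx):
            for j in range(ny):
                fields[:, i, j] = cells[i][j][:k]
        gx, gy = np.gradient(fields, grid.x_centers, grid.y_centers,
                             axis=(1, 2))
        out[s] = np.arctan2(gy, gx)
    return out


def auroc_map_gradient(angles_by_side: dict, transform: str = "sine") -> DiscriminabilityMap:
    """Gradient-direction discriminability per bin.

    Angles are circular; by default they are linearized as the sine of
    their deviation from the longitudinal axis (angle 0) before the ROC —
    exactly the component that distinguishes mirrored plumes.  Use
    ``transform="raw"`` for ROC on raw angle values.
    """
    a = angles_by_side["left"]
    b = angles_by_side["right"]
    if transform == "sine":
        a, b = np.sin(a), np.sin(b)
    elif transform != "raw":
        raise ValueError("transform must be 'sine' or 'raw'")
    nx, ny = a.shape[1], a.shape[2]
    vals = np.full((nx, ny), np.nan)
    for i in range(nx):
        for j in range(ny):
            vals[i, j] = auroc_scaled(a[:, i, j], b[:, i, j])
    return DiscriminabilityMap(values=vals, kind="gradient")


def quantize_map(map_: DiscriminabilityMap, levels: int = 8) -> DiscriminabilityMap:
    """Quantize [0, 1] values to ``levels`` equal-width bins (bin centers),
    for low-bit-depth display; idempotent on already-quantized maps."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    v = map_.values
    q = np.minimum(np.floor(v * levels), levels - 1)
    out = (q + 0.5) / levels
    out[~np.isfinite(v)] = np.nan
    return DiscriminabilityMap(values=out, kind=map_.kind,
                               x_centers=map_.x_centers,
                               y_centers=map_.y_centers,
                               quantization_levels=levels)
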