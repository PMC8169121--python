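"""Readers and writers for every on-disk format, plus session assembly.

Tables are CSV/TSV, sidecars and configs JSON/YAML, posterior samples
HDF5.  Tracking CSVs carry the three keypoints per frame
(frame,time_s,nose_x,...,body_y) with optional per-keypoint likelihood
columns; low-confidence points become NaN on read.  Every writer/reader
pair round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .arhmm import ARHMMParams, FitResult
from .session import SessionBundle, Trial, TrialMeta
from .sniff import SniffEvents, SniffTrace
from .spatial import SpatialMap


class ConfigError(Exception):
    """Malformed or incomplete configuration (CLI exit code 2)."""


class DataError(Exception):
    """Malformed or inconsistent data files (CLI exit code 3)."""


TRACKING_COLUMNS = ["frame", "time_s", "nose_x", "nose_y", "head_x", "head_y",
                    "body_x", "body_y"]
LIKELIHOOD_COLUMNS = ["nose_likelihood", "head_likelihood", "body_likelihood"]


def write_tracking_csv(path, frame_times, nose, head, body, likelihood=None) -> None:
    n = len(frame_times)
    df = pd.DataFrame({
        "frame": np.arange(n),
        "time_s": np.asarray(frame_times, float),
        "nose_x": nose[:, 0], "nose_y": nose[:, 1],
        "head_x": head[:, 0], "head_y": head[:, 1],
        "body_x": body[:, 0], "body_y": body[:, 1],
    })
    if likelihood is not None:
        for k, col in enumerate(LIKELIHOOD_COLUMNS):
            df[col] = likelihood[:, k]
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracking_csv(path, likelihood_threshold: float = 0.9):
    """Read a tracking CSV; returns dict of arrays.  Points whose keypoint
    likelihood falls below the threshold become NaN (count reported under
    'n_low_confidence')."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"tracking file {path} is missing column {missing[0]!r}")
    out = {
        "frame_times": df["time_s"].to_numpy(float),
        "nose": df[["nose_x", "nose_y"]].to_numpy(float),
        "head": df[["head_x", "head_y"]].to_numpy(float),
        "body": df[["body_x", "body_y"]].to_numpy(float),
        "n_low_confidence": 0,
    }
    if all(c in df.columns for c in LIKELIHOOD_COLUMNS):
        n_low = 0
        for key, col in zip(("nose", "head", "body"), LIKELIHOOD_COLUMNS):
            low = df[col].to_numpy(float) < likelihood_threshold
            out[key][low] = np.nan
            n_low += int(low.sum())
        out["n_low_confidence"] = n_low
    return out


def write_sniff_csv(path, trace: SniffTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "signal": trace.samples}).to_csv(
        path, index=False, float_format="%.17g")


def read_sniff_csv(path) -> SniffTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise DataError(f"sniff file {path} is missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.shape[0] < 2:
        raise DataError(f"sniff file {path} has fewer than 2 samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return SniffTrace(samples=df["signal"].to_numpy(float),
                      sample_rate=rate, t0=float(t[0]))


def write_events_csv(path, events: SniffEvents) -> None:
    n = events.inhalation_onsets.shape[0]
    dur = np.concatenate([events.durations, [np.nan]]) if n else np.zeros(0)
    kept = np.concatenate([events.kept_mask, [False]]) if n else np.zeros(0, bool)
    pd.DataFrame({
        "inhalation_s": events.inhalation_onsets,
        "exhalation_s": events.exhalation_onsets,
        "duration_s": dur[:n],
        "kept": kept[:n],
    }).to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path) -> SniffEvents:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("inhalation_s", "exhalation_s", "duration_s", "kept"):
        if col not in df.columns:
            raise DataError(f"events file {path} is missing column {col!r}")
    n = len(df)
    return SniffEvents(
        inhalation_onsets=df["inhalation_s"].to_numpy(float),
        exhalation_onsets=df["exhalation_s"].to_numpy(float),
        durations=df["duration_s"].to_numpy(float)[: max(n - 1, 0)],
        kept_mask=df["kept"].to_numpy(bool)[: max(n - 1, 0)],
    )


def write_kinematics_csv(path, kin) -> None:
    pd.DataFrame({
        "frame": np.arange(kin.frame_times.shape[0]),
        "time_s": kin.frame_times,
        "nose_speed": kin.nose_speed,
        "yaw_vel": kin.yaw_velocity,
        "z_vel": kin.z_velocity,
    }).to_csv(path, index=False, float_format="%.17g")


def write_meta_csv(path, bundle: SessionBundle) -> None:
    rows = []
    for tr in bundle.trials:
        m = tr.meta
        rows.append({
            "mouse_id": bundle.mouse_id, "session_id": bundle.session_id,
            "start_s": m.start_s, "end_s": m.end_s, "side": m.side,
            "ratio_hi": m.ratio[0], "ratio_lo": m.ratio[1],
            "choice": m.choice if m.choice is not None else "",
            "correct": "" if m.correct is None else int(m.correct),
            "decision_time_s": m.decision_time_s,
            "iti_end_s": m.iti_end_s,
            "px_per_cm": bundle.px_per_cm, "frame_rate": bundle.frame_rate,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_meta_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("start_s", "end_s", "side", "choice", "correct"):
        if col not in df.columns:
            raise DataError(f"meta file {path} is missing column {col!r}")
    return df


def write_map_tsv(path, map_: SpatialMap) -> None:
    """Map grid as TSV plus a JSON sidecar recording the geometry."""
    path = Path(path)
    np.savetxt(path, map_.grid, delimiter="\t", fmt="%.17g")
    sidecar = {
        "bin_size_cm": map_.bin_size,
        "extent_cm": list(map_.extent),
        "smoothing_sigma_bins": map_.smoothing_sigma,
        "n_clipped": map_.n_clipped,
        "shape": list(map_.grid.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def read_map_tsv(path) -> SpatialMap:
    path = Path(path)
    grid = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SpatialMap(grid=grid, bin_size=meta["bin_size_cm"],
                      extent=tuple(meta["extent_cm"]),
                      smoothing_sigma=meta["smoothing_sigma_bins"],
                      n_clipped=meta["n_clipped"])


def save_model(json_path, h5_path, fit: FitResult, prior=None, cfg=None) -> None:
    """Fit model: expected parameters + hyperparameters as JSON; retained
    samples and posterior marginals as HDF5 (timestamps disabled so
    identical fits produce identical files)."""
    p = fit.expected_params
    doc = {
        "S": p.S, "d": p.d,
        "pi": p.pi.tolist(), "init": p.init.tolist(),
        "A": p.A.tolist(), "b": p.b.tolist(), "Q": p.Q.tolist(),
    }
    if prior is not None:
        doc["prior"] = {"alpha": prior.alpha, "alpha_mode": prior.alpha_mode}
    if cfg is not None:
        doc["gibbs"] = {"n_iter": cfg.n_iter, "n_burn": cfg.n_burn, "seed": cfg.seed}
    Path(json_path).write_text(json.dumps(doc, sort_keys=True))
    with h5py.File(h5_path, "w", track_order=False) as f:
        for name, stack in (("pi", [s.pi for s in fit.samples]),
                            ("A", [s.A for s in fit.samples]),
                            ("b", [s.b for s in fit.samples]),
                            ("Q", [s.Q for s in fit.samples])):
            f.create_dataset(f"samples/{name}", data=np.asarray(stack),
                             track_times=False)
        for i, marg in enumerate(fit.posterior_marginals):
            f.create_dataset(f"marginals/trial{i:04d}", data=marg,
                             track_times=False)
        for i, z in enumerate(fit.map_sequences):
            f.create_dataset(f"map/trial{i:04d}", data=z, track_times=False)


def load_model_params(json_path) -> ARHMMParams:
    doc = json.loads(Path(json_path).read_text())
    return ARHMMParams(pi=np.array(doc["pi"]), init=np.array(doc["init"]),
                       A=np.array(doc["A"]), b=np.array(doc["b"]),
                       Q=np.array(doc["Q"]))


def assemble_session(tracking: dict, meta: pd.DataFrame,
                     traces=None, events=None,
                     shift_frames: int = 2) -> SessionBundle:
    """Slice continuous tracking into trials by the metadata table.

    The 25 ms (two-frame) tracking-to-sniff alignment is applied once here:
    keypoint streams are advanced ``shift_frames`` frames relative to the
    sniff clock.  Trials outside the tracking range are excluded; trials
    overlapping in time raise a DataError.
    """
    from .kinematics import align_tracking_to_sniff

    t = tracking["frame_times"]
    nose = align_tracking_to_sniff(tracking["nose"], shift_frames)
    head = align_tracking_to_sniff(tracking["head"], shift_frames)
    body = align_tracking_to_sniff(tracking["body"], shift_frames)
    meta = meta.sort_values("start_s").reset_index(drop=True)
    ends = meta["end_s"].to_numpy(float)
    starts = meta["start_s"].to_numpy(float)
    if np.any(starts[1:] < ends[:-1]):
        raise DataError("overlapping trials in metadata")
    trials = []
    for k, row in meta.iterrows():
        m = (t >= row["start_s"]) & (t < row["end_s"])
        if not m.any():
            continue
        tm = TrialMeta(
            start_s=float(row["start_s"]), end_s=float(row["end_s"]),
            side=str(row["side"]),
            ratio=(row.get("ratio_hi", 0), row.get("ratio_lo", 0)),
            choice=None if pd.isna(row["choice"]) or row["choice"] == "" else str(row["choice"]),
            correct=None if pd.isna(row["correct"]) or row["correct"] == "" else bool(int(row["correct"])),
            decision_time_s=float(row["decision_time_s"]) if "decision_time_s" in row and pd.notna(row["decision_time_s"]) else None,
            iti_end_s=float(row["iti_end_s"]) if "iti_end_s" in row and pd.notna(row["iti_end_s"]) else None,
        )
        trials.append(Trial(
            nose=nose[m], head=head[m], body=body[m], frame_times=t[m],
            sniff=None if events is None else events[k],
            trace=None if traces is None else traces[k], meta=tm))
    return SessionBundle(
        mouse_id=str(meta["mouse_id"].iloc[0]) if "mouse_id" in meta else "m00",
        session_id=str(meta["session_id"].iloc[0]) if "session_id" in meta else "s00",
        trials=trials,
        px_per_cm=float(meta["px_per_cm"].iloc[0]) if "px_per_cm" in meta else 1.0,
        frame_rate=float(meta["frame_rate"].iloc[0]) if "frame_rate" in meta else 80.0,
    )
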