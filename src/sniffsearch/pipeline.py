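"""End-to-end pipeline: chain the analysis stages on one configuration.

Stages (each seeded from the master seed): simulate a synthetic session
and plume grid; detect and filter sniffs; compute kinematics; fit the
AR-HMM; group motifs into investigation/approach states; build spatial
maps; decode trial labels from transition features; map plume
discriminability.  Every stage writes its artifacts under the output
directory and the run ends with a provenance manifest (config hash, seeds,
versions).  Re-running the same config and seed reproduces every file
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arhmm import GibbsConfig, PriorHyper, gibbs_fit, usage_filter
from .decoding import features_from_sequences, lda_decode, shuffle_significance
from .io import ConfigError, save_model, write_events_csv, write_kinematics_csv, \
    write_map_tsv, write_meta_csv, write_sniff_csv, write_tracking_csv
from .kinematics import trial_kinematics
from .motifs import assign_state_names, cluster_transition_matrix, state_frame_labels
from .plume import auroc_map_absolute, auroc_map_gradient, gradient_pseudosamples, \
    mean_concentration_map
from .sniff import detect_sniffs, filter_sniff_durations, instantaneous_rate, smooth_trace
from .spatial import SpatialMap, iai, occupancy_map, session_performance, \
    sniff_rate_map, state_occupancy_maps
from .synthetic import PlumeConfig, SessionConfig, gen_plume_session, simulate_session

KNOWN_STAGES = ("simulate", "sniff", "kinematics", "fit", "states",
                "spatial", "decode", "plume")


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in cfg:
        raise ConfigError("config must state an explicit seed")
    stages = cfg.get("stages", {})
    for key in stages:
        if key not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {key!r}")


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


_STAGE_DEPS = {
    "simulate": (),
    "sniff": (),
    "kinematics": (),
    "fit": (),
    "states": ("fit", "kinematics"),
    "spatial": ("sniff", "states"),
    "decode": ("fit",),
    "plume": (),
}


def _active_stages(requested) -> set:
    """Requested stages plus their upstream dependencies (and simulate)."""
    active = set(requested) | {"simulate"}
    changed = True
    while changed:
        changed = False
        for s in list(active):
            for dep in _STAGE_DEPS.get(s, ()):
                if dep not in active:
                    active.add(dep)
                    changed = True
    return active


def run_pipeline(cfg: dict, out_dir) -> Path:
    """Run the configured stages (plus their dependencies); returns the
    artifact directory."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg.get("stages", {})
    active = _active_stages(stages.keys() or KNOWN_STAGES)

    # --- simulate ---------------------------------------------------------
    sim = stages.get("simulate", {}) or {}
    scfg = SessionConfig(**{k: v for k, v in sim.items() if k != "plume"})
    bundle, truth = simulate_session(scfg, seed=_stage_seed(seed, "simulate"))
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    write_meta_csv(d / "meta.csv", bundle)
    for i, tr in enumerate(bundle.trials):
        write_tracking_csv(d / f"tracking_trial{i:03d}.csv", tr.frame_times,
                           tr.nose, tr.head, tr.body)
        if tr.trace is not None:
            write_sniff_csv(d / f"sniff_trial{i:03d}.csv", tr.trace)
    if "plume" in active:
        pcfg = PlumeConfig(**(sim.get("plume") or {}))
        grid = gen_plume_session(pcfg, seed=_stage_seed(seed, "plume-sim"))

    # --- sniff ------------------------------------------------------------
    events = []
    if "sniff" in active:
        d = out / "sniff"
        d.mkdir(exist_ok=True)
        for i, tr in enumerate(bundle.trials):
            if tr.trace is not None:
                ev = filter_sniff_durations(detect_sniffs(smooth_trace(tr.trace)))
            else:
                ev = tr.sniff
            events.append(ev)
            write_events_csv(d / f"events_trial{i:03d}.csv", ev)

    # --- kinematics -------------------------------------------------------
    if "kinematics" in active:
        d = out / "kinematics"
        d.mkdir(exist_ok=True)
        kin = [trial_kinematics(tr) for tr in bundle.trials]
        for i, k in enumerate(kin):
            write_kinematics_csv(d / f"kin_trial{i:03d}.csv", k)

    # --- fit --------------------------------------------------------------
    fcfg = stages.get("fit", {}) or {}
    S = int(fcfg.get("S", 3))
    if "fit" in active:
        gc = GibbsConfig(n_iter=int(fcfg.get("n_iter", 60)),
                         n_burn=int(fcfg.get("n_burn", 40)),
                         seed=_stage_seed(seed, "fit"))
        trajs = [np.concatenate([tr.nose, tr.head, tr.body], axis=1)
                 for tr in bundle.trials]
        fit = gibbs_fit(trajs, S, prior=PriorHyper(), cfg=gc)
        d = out / "fit"
        d.mkdir(exist_ok=True)
        save_model(d / "model.json", d / "fit.h5", fit, prior=PriorHyper(), cfg=gc)

    # --- states -----------------------------------------------------------
    if "states" in active:
        d = out / "states"
        d.mkdir(exist_ok=True)
        retained = usage_filter(fit.map_sequences, threshold=0.05)
        pi_r = fit.expected_params.pi[np.ix_(retained, retained)]
        pi_r = pi_r / pi_r.sum(axis=1, keepdims=True)
        grouping = cluster_transition_matrix(pi_r, motif_ids=retained)
        mean_speed = []
        for mid in retained:
            vals = [np.nanmean(k.nose_speed[np.asarray(z) == mid])
                    for k, z in zip(kin, fit.map_sequences)
                    if np.any(np.asarray(z) == mid)]
            mean_speed.append(np.nanmean(vals) if vals else np.nan)
        grouping = assign_state_names(grouping, mean_speed)
        labels2 = state_frame_labels(fit.map_sequences, grouping)
        pd.DataFrame({"motif": grouping.motif_ids,
                      "group": grouping.group,
                      "name": [grouping.names[g] for g in grouping.group]}
                     ).to_csv(d / "grouping.csv", index=False)

    # --- spatial ----------------------------------------------------------
    sp = stages.get("spatial", {}) or {}
    if "spatial" in active:
        d = out / "spatial"
        d.mkdir(exist_ok=True)
        all_nose = np.concatenate([tr.nose for tr in bundle.trials])
        occ = occupancy_map(all_nose, bin_size=float(sp.get("bin_cm", 0.5)))
        write_map_tsv(d / "occupancy.tsv", occ)
        sniff_xy = []
        for tr, ev in zip(bundle.trials, events):
            kept = ev.inhalation_onsets[: ev.n_sniffs][ev.kept_mask]
            idx = np.clip(np.searchsorted(tr.frame_times, kept), 0,
                          tr.n_frames - 1)
            sniff_xy.append(tr.nose[idx])
        rate_map = sniff_rate_map(np.concatenate(sniff_xy), occ,
                                  frame_rate=bundle.frame_rate)
        write_map_tsv(d / "sniff_rate.tsv", rate_map)
        lab_all = np.concatenate(labels2)
        inv, app = state_occupancy_maps(all_nose, lab_all, bin_size=1.0)
        write_map_tsv(d / "occupancy_investigation.tsv", inv)
        write_map_tsv(d / "occupancy_approach.tsv", app)
        write_map_tsv(d / "iai.tsv", iai(inv, app))
        perf = session_performance(bundle.trials, frame_rate=bundle.frame_rate)
        (d / "performance.json").write_text(json.dumps(perf, sort_keys=True))

    # --- decode -----------------------------------------------------------
    dc = stages.get("decode", {}) or {}
    if "decode" in active:
        d = out / "decode"
        d.mkdir(exist_ok=True)
        X = features_from_sequences(fit.map_sequences, S)
        y = np.array([tr.meta.choice for tr in bundle.trials])
        decode_out = {}
        if np.unique(y).shape[0] >= 2 and min(np.bincount(pd.factorize(y)[0])) >= 2:
            folds = int(dc.get("folds", min(5, int(min(np.bincount(pd.factorize(y)[0]))))))
            res = lda_decode(X, y, folds=folds, seed=_stage_seed(seed, "decode"))
            sig = shuffle_significance(X, y, folds=folds,
                                       n_shuffles=int(dc.get("n_shuffles", 100)),
                                       seed=_stage_seed(seed, "decode-shuffle"))
            decode_out = {
                "classes": [str(c) for c in res["classes"]],
                "accuracy": res["accuracy"],
                "per_class_accuracy": [float(v) for v in res["per_class_accuracy"]],
                "z": [float(v) for v in sig["z"]],
                "p": [float(v) for v in sig["p"]],
            }
            np.savetxt(d / "confusion.tsv", res["confusion"], delimiter="\t", fmt="%.17g")
        (d / "decoding.json").write_text(json.dumps(decode_out, sort_keys=True))

    # --- plume ------------------------------------------------------------
    if "plume" in active:
        d = out / "plume"
        d.mkdir(exist_ok=True)
        for side in ("left", "right"):
            np.savetxt(d / f"mean_{side}.tsv", mean_concentration_map(grid, side),
                       delimiter="\t", fmt="%.17g")
        amap = auroc_map_absolute(grid)
        np.savetxt(d / "auroc_absolute.tsv", amap.values, delimiter="\t", fmt="%.17g")
        gmap = auroc_map_gradient(gradient_pseudosamples(grid))
        np.savetxt(d / "auroc_gradient.tsv", gmap.values, delimiter="\t", fmt="%.17g")

    # --- manifest ---------------------------------------------------------
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "stage_seeds": {s: _stage_seed(seed, s) for s in KNOWN_STAGES},
        "versions": {"sniffsearch": __version__, "numpy": np.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                  indent=1, default=str))
    return out


def demo_config(n_trials: int = 12) -> dict:
    """A small configuration exercising every stage in well under the
    15-minute single-CPU budget."""
    return {
        "seed": 7,
        "stages": {
            "simulate": {
                "n_trials": n_trials,
                "make_traces": True,
                "pid_sample_rate": 600.0,
                "plume": {"n_trials_per_bin": 4, "pid_sample_rate": 400.0},
            },
            "sniff": {},
            "kinematics": {},
            "fit": {"S": 3, "n_iter": 40, "n_burn": 25},
            "states": {},
            "spatial": {"bin_cm": 0.5},
            "decode": {"n_shuffles": 25},
            "plume": {},
        },
    }
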