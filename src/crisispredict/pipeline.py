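"""End-to-end orchestration: simulate → label → featurize → fit → evaluate.

A single root seed fans out deterministically to per-stage seeds (simulate,
split, model, evaluate) via :func:`stage_seeds`, so each stage is
independently reproducible and two runs with the same configuration and seed
produce byte-identical feature tables and metrics JSON.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import TASK_MODALITY, TASKS, events_to_frame, label_record
from .evaluate import auroc, balanced_sample, compare_auroc, decision_curve
from .features import build_feature_table, feature_columns
from .models import FAMILIES, fit_model
from .records import write_cohort
from .simulate import SimConfig, simulate_cohort
from .survival import make_blocks, make_test_rows, split_cohort, training_rows

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "sim": {},  # SimConfig fields; n_patients and record_hours are required
    "split": {"train_fraction": 0.7},
    "features": {"tiers": [1, 2, 3], "window_minutes": 30.0},
    "models": {"families": list(FAMILIES), "cv_folds": 5, "grids": {}},
    "evaluate": {"n_boot": 1000, "ci_method": "patient-bootstrap",
                 "balanced_dca": True},
}

_REQUIRED = [("sim", "n_patients"), ("sim", "record_hours")]


def validate_config(config: dict) -> dict:
    """Merge a user config over defaults; reject unknown or missing keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for section, values in config.items():
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        if section == "sim":
            cfg["sim"] = dict(values)
        else:
            bad = set(values) - set(cfg[section])
            if bad:
                raise ValueError(f"unknown config key(s) in {section!r}: {sorted(bad)}")
            cfg[section].update(values)
    for section, key in _REQUIRED:
        if key not in cfg[section]:
            raise ValueError(f"config missing required key {section}.{key}")
    SimConfig.from_dict({**cfg["sim"], "seed": 0})  # field-level validation
    for fam in cfg["models"]["families"]:
        if fam not in FAMILIES:
            raise ValueError(f"unknown model family {fam!r}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds derived from one root seed (< 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("simulate", "split", "model", "evaluate")
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def label_cohort(records) -> tuple[dict, dict]:
    """Detect events and build filtered timelines for every record."""
    timelines, events = {}, {}
    for rec in records:
        tl, evs = label_record(rec)
        timelines[rec.patient_id] = tl
        events[rec.patient_id] = evs
    return timelines, events


def task_feature_table(
    records,
    timelines: dict,
    events: dict,
    task: str,
    tier: int,
    pids,
    blocked: bool,
    window_minutes: float = 30.0,
) -> pd.DataFrame:
    """Concatenated feature table for a set of patients.

    ``blocked=True`` yields one row per emitting 30-min block (training form);
    ``blocked=False`` yields dense per-sample evaluation rows (test form).
    """
    rec_by_id = {r.patient_id: r for r in records}
    modality = TASK_MODALITY[task]
    parts = []
    for pid in pids:
        onsets = [e.onset for e in events[pid][modality]]
        if blocked:
            rows = training_rows(make_blocks(timelines[pid], rec_by_id[pid], task,
                                             onsets, block_minutes=window_minutes))
        else:
            rows = make_test_rows(timelines[pid], rec_by_id[pid], task, onsets,
                                  window_minutes=window_minutes,
                                  horizon_minutes=window_minutes)
        if len(rows):
            parts.append(build_feature_table(rec_by_id[pid], timelines[pid], task,
                                             tier, rows["time"].to_numpy(),
                                             rows["label"].to_numpy(),
                                             window_minutes=window_minutes))
    if not parts:
        return pd.DataFrame(columns=["patient_id", "time", "label", *feature_columns(tier)])
    return pd.concat(parts, ignore_index=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    out = frame.copy()
    for col in out.columns:
        if np.issubdtype(out[col].dtype, np.datetime64):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Run every stage for both tasks, all configured tiers and families.

    Writes the cohort, ground truth, event/state tables, per-task feature
    tables, ``metrics.json`` and ``dca_*.csv`` under ``out_dir`` and returns
    the run manifest (also written as ``manifest.json``).
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)

    sim_cfg = SimConfig.from_dict({**cfg["sim"], "seed": seeds["simulate"]})
    records, truth = simulate_cohort(sim_cfg)
    write_cohort(records, out / "cohort.csv")
    truth.to_json(out / "ground_truth.json")

    timelines, events = label_cohort(records)
    event_frames, state_frames = [], []
    for rec in records:
        for mod_events in events[rec.patient_id].values():
            event_frames.append(events_to_frame(rec.patient_id, mod_events))
        state_frames.append(timelines[rec.patient_id].to_frame())
    nonempty = [f for f in event_frames if len(f)] or event_frames[:1]
    _write_frame(pd.concat(nonempty, ignore_index=True), out / "events.csv")
    _write_frame(pd.concat(state_frames, ignore_index=True), out / "states.csv")

    ids = [r.patient_id for r in records]
    ever = [any(events[p][m] for m in events[p]) for p in ids]
    train_ids, test_ids = split_cohort(ids, ever, cfg["split"]["train_fraction"],
                                      seed=seeds["split"])
    with open(out / "split.json", "w") as fh:
        json.dump({"seed": seeds["split"], "train": train_ids, "test": test_ids},
                  fh, indent=1, sort_keys=True)

    tiers = sorted(cfg["features"]["tiers"])
    window = cfg["features"]["window_minutes"]
    metrics: dict = {"seed": seed, "stage_seeds": seeds, "tasks": {}}

    for task in TASKS:
        train_all = task_feature_table(records, timelines, events, task, max(tiers),
                                       train_ids, blocked=True, window_minutes=window)
        test_all = task_feature_table(records, timelines, events, task, max(tiers),
                                      test_ids, blocked=False, window_minutes=window)
        _write_frame(train_all, out / f"train_{task}.csv")
        _write_frame(test_all, out / f"test_{task}.csv")

        task_metrics: dict = {}
        for tier in tiers:
            cols = feature_columns(tier)
            tr = train_all.dropna(subset=cols)
            te = test_all.dropna(subset=cols)
            tier_metrics: dict = {
                "n_train": int(len(tr)),
                "n_test": int(len(te)),
                "train_prevalence": float(tr["label"].mean()) if len(tr) else None,
                "test_prevalence": float(te["label"].mean()) if len(te) else None,
            }
            if (len(tr) == 0 or len(te) == 0
                    or tr["label"].nunique() < 2 or te["label"].nunique() < 2):
                tier_metrics["note"] = (
                    "skipped: train or test rows missing an outcome class"
                )
                logger.warning("%s tier %d: %s", task, tier, tier_metrics["note"])
                task_metrics[f"tier{tier}"] = tier_metrics
                continue
            risks_by_family = {}
            for family in cfg["models"]["families"]:
                grid = cfg["models"]["grids"].get(family)
                model = fit_model(family, tr[cols], tr["label"].to_numpy(),
                                  groups=tr["patient_id"].to_numpy(),
                                  seed=seeds["model"], cv_folds=cfg["models"]["cv_folds"],
                                  param_grid=grid)
                risks = model.predict_risk(te[cols])
                risks_by_family[family] = risks
                roc = auroc(te["label"].to_numpy(), risks,
                            groups=te["patient_id"].to_numpy(),
                            method=cfg["evaluate"]["ci_method"],
                            n_boot=cfg["evaluate"]["n_boot"], seed=seeds["evaluate"])
                y_dca = te["label"].to_numpy()
                if cfg["evaluate"]["balanced_dca"]:
                    bal = balanced_sample(y_dca, seed=seeds["evaluate"])
                    curve = decision_curve(y_dca[bal], risks[bal])
                else:
                    curve = decision_curve(y_dca, risks)
                curve.to_frame().to_csv(out / f"dca_{task}_tier{tier}_{family}.csv",
                                        index=False)
                tier_metrics[family] = {
                    "auroc": roc.auroc,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                    "ci_method": roc.method,
                    "cv_auroc": model.cv_auroc_,
                    "best_params": model.best_params_,
                    "dca_prevalence": curve.prevalence,
                }
            if "lr" in risks_by_family and "rf" in risks_by_family:
                tier_metrics["delong_rf_vs_lr_p"] = compare_auroc(
                    te["label"].to_numpy(), risks_by_family["rf"], risks_by_family["lr"]
                )
            task_metrics[f"tier{tier}"] = tier_metrics
        metrics["tasks"][task] = task_metrics

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "config": cfg,
        "n_patients": len(records),
        "n_ground_truth_crises": truth.n_crises(),
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
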