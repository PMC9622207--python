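"""Discrete-time survival structure: 30-min blocks, labels, and the 70/30 split.

Training data are blocked into 30-min intervals tiled from each record's first
timestamp. The last observation of a block (the last sample with task data) is
its representative; the block contributes a training row iff that observation
is retained by the succession filter, and the row's binary label says whether
a crisis of the task's type begins within the next block. The last block, and
any block whose following block has neither monitoring data nor an onset, is
right-censored and contributes no row.

Test records are not blocked: every retained sample with a full 30-min
history and an observable 30-min outcome window contributes one evaluation
row, labeled by whether an onset occurs within the following 30 min.

The train/test split is at the patient level (preventing within-patient
leakage), stratified on the patient's ever-event indicator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .events import TASK_MODALITY, TASKS, StateTimeline
from .records import PhysioRecord

logger = logging.getLogger(__name__)


def _onset_minutes(onset_times, t0) -> np.ndarray:
    onsets = np.asarray(onset_times, dtype="datetime64[s]")
    return (onsets - t0) / np.timedelta64(60, "s")


def make_blocks(
    timeline: StateTimeline,
    record: PhysioRecord,
    task: str,
    onset_times,
    block_minutes: float = 30.0,
) -> pd.DataFrame:
    """Tile one patient's record into blocks and label the training rows.

    Returns one row per block with columns ``block_index``, ``start_minute``,
    ``representative_time`` (NaT when the block holds no task observation),
    ``retained``, ``label`` and ``emits``. Training rows are the blocks with
    ``emits`` True: representative retained, next block observable. ``label``
    is 1 iff a task onset (from the events module) falls within the next
    block's interval.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    n = len(timeline)
    if n == 0:
        return pd.DataFrame(
            columns=["patient_id", "block_index", "start_minute",
                     "representative_time", "retained", "label", "emits"]
        )
    minutes = record.minutes
    signal = record.signal(TASK_MODALITY[task])
    has_obs = ~np.isnan(signal)
    retained = timeline.retained[task]
    onset_min = _onset_minutes(onset_times, record.times[0])

    block_of = np.floor(minutes / block_minutes).astype(int)
    n_blocks = int(block_of[-1]) + 1
    rows = []
    for k in range(n_blocks):
        in_block = block_of == k
        obs_idx = np.flatnonzero(in_block & has_obs)
        rep = int(obs_idx[-1]) if obs_idx.size else -1
        nxt_lo, nxt_hi = (k + 1) * block_minutes, (k + 2) * block_minutes
        onset_next = bool(((onset_min >= nxt_lo) & (onset_min < nxt_hi)).any())
        next_has_data = bool((block_of == k + 1).any())
        observable = (k + 1 < n_blocks and next_has_data) or onset_next
        emits = rep >= 0 and bool(retained[rep]) and observable
        rows.append(
            {
                "patient_id": timeline.patient_id,
                "block_index": k,
                "start_minute": k * block_minutes,
                "representative_time": record.times[rep] if rep >= 0 else np.datetime64("NaT"),
                "retained": bool(retained[rep]) if rep >= 0 else False,
                "label": int(onset_next),
                "emits": emits,
            }
        )
    return pd.DataFrame(rows)


def training_rows(blocks: pd.DataFrame) -> pd.DataFrame:
    """The emitted (at-risk, observable) training rows of a block table."""
    out = blocks.loc[blocks["emits"], ["patient_id", "representative_time", "label"]]
    return out.rename(columns={"representative_time": "time"}).reset_index(drop=True)


def make_test_rows(
    timeline: StateTimeline,
    record: PhysioRecord,
    task: str,
    onset_times,
    window_minutes: float = 30.0,
    horizon_minutes: float = 30.0,
) -> pd.DataFrame:
    """Dense (unblocked) evaluation rows for one test-set patient.

    One row per retained sample with task data, a full ``window_minutes`` of
    history, and an observable outcome window; label is 1 iff an onset falls
    within the following ``horizon_minutes``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    n = len(timeline)
    if n == 0:
        return pd.DataFrame(columns=["patient_id", "time", "label"])
    minutes = record.minutes
    signal = record.signal(TASK_MODALITY[task])
    retained = timeline.retained[task]
    onset_min = _onset_minutes(onset_times, record.times[0])
    dt = record.dt_minutes
    coverage_end = minutes[-1] + dt  # each sample represents its following dt

    eligible = (
        ~np.isnan(signal)
        & retained
        & (minutes >= window_minutes)
        & (minutes + horizon_minutes <= coverage_end)
    )
    idx = np.flatnonzero(eligible)
    t = minutes[idx]
    label = (
        (onset_min[None, :] > t[:, None]) & (onset_min[None, :] <= t[:, None] + horizon_minutes)
    ).any(axis=1) if onset_min.size else np.zeros(len(idx), dtype=bool)
    return pd.DataFrame(
        {
            "patient_id": timeline.patient_id,
            "time": record.times[idx],
            "label": label.astype(int),
        }
    )


def split_cohort(
    patient_ids,
    ever_event,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Patient-level train/test split stratified on the ever-event indicator.

    Deterministic given ``seed``; each patient falls wholly in one side; the
    realized training fraction is within one patient of the target. A stratum
    with fewer than 2 patients is merged into a simple random split (logged).
    """
    ids = np.asarray(patient_ids)
    ev = np.asarray(ever_event, dtype=bool)
    if len(ids) < 2:
        raise ValueError("split_cohort needs >= 2 patients")
    if len(ids) != len(ev):
        raise ValueError("patient_ids and ever_event length mismatch")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata = [ids[ev], ids[~ev]]
    if min(len(s) for s in strata) < 2:
        logger.warning("a stratum has <2 patients; merging strata into a simple random split")
        strata = [ids]
    train: list[str] = []
    for s in strata:
        perm = rng.permutation(s)
        k = int(round(train_fraction * len(s)))
        train.extend(str(p) for p in perm[:k])
    # keep both sides non-empty
    all_ids = [str(p) for p in ids]
    if not train:
        train = [all_ids[0]]
    if len(train) == len(all_ids):
        train = train[:-1]
    train_set = set(train)
    test = [p for p in all_ids if p not in train_set]
    train = [p for p in all_ids if p in train_set]  # original cohort order
    return train, test
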