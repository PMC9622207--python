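"""Crisis-event detection and per-sample state labeling.

A crisis is a sustained threshold violation: ICP >= 20 mmHg for strictly more
than 5 min, or PbtO2 <= 20 mmHg for strictly more than 5 min (boundary values
violate; a run of exactly 5 min is not an event). Each sample represents its
following dt interval, so a run of n consecutive samples lasts n*dt minutes.
Missing samples and timestamp gaps break a run — a gap is never assumed to be
supra-threshold.

Per-sample states follow the four-way event typing used at the bedside:

* ``A`` — no crisis,
* ``B`` — ICP crisis only,
* ``C`` — PbtO2 crisis only,
* ``D`` — simultaneous ICP and PbtO2 crisis.

For each prediction task the succession filter marks which samples are at risk
of a *new* crisis of that task's type: for the ICP task the at-risk states are
A and C (a sample already in B or D cannot begin a new ICP crisis); for the
PbtO2 task they are A and B. Episode numbers count, per task, the 1-based
at-risk interval between crises; an episode increments only after an event of
the task's outcome type ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    ICP,
    ICP_THRESHOLD,
    MIN_CRISIS_MINUTES,
    MODALITIES,
    PBTO2,
    PBTO2_THRESHOLD,
    PhysioRecord,
)

logger = logging.getLogger(__name__)

ICP_TASK = "icp"
PBTO2_TASK = "pbto2"
TASKS = (ICP_TASK, PBTO2_TASK)

STATE_A, STATE_B, STATE_C, STATE_D = 0, 1, 2, 3
STATE_NAMES = np.array(["A", "B", "C", "D"])

#: modality whose events define the outcome of each task
TASK_MODALITY = {ICP_TASK: ICP, PBTO2_TASK: PBTO2}


@dataclass(frozen=True)
class CrisisEvent:
    """A maximal sustained threshold violation in one modality."""

    modality: str
    onset: np.datetime64
    offset: np.datetime64  # timestamp of the last violating sample
    peak_value: float

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class StateTimeline:
    """Per-sample A/B/C/D states plus per-task episode numbers and at-risk flags."""

    patient_id: str
    times: np.ndarray
    state: np.ndarray  # int codes STATE_A..STATE_D
    episode: dict  # task -> int array (1-based)
    retained: dict = field(default_factory=dict)  # task -> bool array

    def __len__(self) -> int:
        return len(self.times)

    @property
    def state_names(self) -> np.ndarray:
        return STATE_NAMES[self.state]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"patient_id": self.patient_id, "timestamp": self.times})
        frame["state"] = self.state_names
        for task in TASKS:
            frame[f"episode_{task}"] = self.episode[task]
            if task in self.retained:
                frame[f"retained_{task}"] = self.retained[task].astype(int)
        return frame


def _threshold_mask(values: np.ndarray, modality: str, threshold: float) -> np.ndarray:
    if modality == ICP:
        return values >= threshold
    if modality == PBTO2:
        return values <= threshold
    raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


def detect_events(
    record: PhysioRecord,
    modality: str,
    threshold: float | None = None,
    min_duration: float = MIN_CRISIS_MINUTES,
) -> list[CrisisEvent]:
    """Find maximal sustained threshold violations in one modality.

    A maximal run of consecutive samples violating the threshold (``>=`` for
    ICP, ``<=`` for PbtO2) becomes an event iff its duration ``n_samples * dt``
    strictly exceeds ``min_duration`` minutes. Runs are broken by missing
    samples and by timestamp gaps larger than 1.5x the nominal interval.
    Events are disjoint and time-ordered by construction.
    """
    if threshold is None:
        threshold = ICP_THRESHOLD if modality == ICP else PBTO2_THRESHOLD
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if not min_duration > 0:
        raise ValueError("min_duration must be positive")
    values = record.signal(modality)
    if len(values) == 0:
        return []
    usable = ~np.isnan(values)
    if not usable.any():
        logger.warning("patient %s: %s signal all-missing", record.patient_id, modality)
        return []
    dt = record.dt_minutes
    violate = _threshold_mask(values, modality, threshold) & usable

    # break runs at timestamp gaps (absent rows)
    if len(values) > 1:
        gap_after = np.diff(record.times) / np.timedelta64(60, "s") > 1.5 * dt
    else:
        gap_after = np.zeros(0, dtype=bool)

    events: list[CrisisEvent] = []
    start = None
    for i in range(len(values)):
        if violate[i] and start is None:
            start = i
        if start is not None:
            run_ends = (
                i == len(values) - 1
                or not violate[i + 1]
                or gap_after[i]
            )
            if run_ends:
                n_run = i - start + 1
                if n_run * dt > min_duration:
                    events.append(
                        CrisisEvent(
                            modality=modality,
                            onset=record.times[start],
                            offset=record.times[i],
                            peak_value=float(
                                np.max(values[start : i + 1])
                                if modality == ICP
                                else np.min(values[start : i + 1])
                            ),
                        )
                    )
                start = None
    return events


def _interval_mask(times: np.ndarray, events: list[CrisisEvent]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for ev in events:
        mask |= (times >= ev.onset) & (times <= ev.offset)
    return mask


def _episode_numbers(in_event: np.ndarray) -> np.ndarray:
    """1-based at-risk episode index; increments after each event interval ends."""
    n = len(in_event)
    ended_before = np.zeros(n, dtype=bool)
    if n > 1:
        ended_before[1:] = in_event[:-1] & ~in_event[1:]
    return 1 + np.cumsum(ended_before)


def build_state_timeline(
    record: PhysioRecord,
    icp_events: list[CrisisEvent],
    pbto2_events: list[CrisisEvent],
) -> StateTimeline:
    """Assign per-sample A/B/C/D states and per-task episode numbers.

    Event lists must come from :func:`detect_events` on the same record
    (disjoint within each modality); overlap within a modality is rejected.
    """
    for evs in (icp_events, pbto2_events):
        for a, b in zip(evs, evs[1:]):
            if b.onset <= a.offset:
                raise ValueError("overlapping events within one modality")
    times = record.times
    in_icp = _interval_mask(times, icp_events)
    in_pb = _interval_mask(times, pbto2_events)
    state = np.full(len(times), STATE_A, dtype=np.int8)
    state[in_icp & ~in_pb] = STATE_B
    state[~in_icp & in_pb] = STATE_C
    state[in_icp & in_pb] = STATE_D
    episode = {
        ICP_TASK: _episode_numbers(in_icp),
        PBTO2_TASK: _episode_numbers(in_pb),
    }
    return StateTimeline(
        patient_id=record.patient_id, times=times, state=state, episode=episode
    )


def succession_filter(
    timeline: StateTimeline, task: str, censor_after_first_event: bool = False
) -> StateTimeline:
    """Mark at-risk samples for one prediction task (idempotent).

    ICP task: retained iff state is A or C; samples already in an ICP crisis
    (B/D) cannot be at risk of a new one and are discarded as predictor rows.
    PbtO2 task: retained iff state is A or B. With
    ``censor_after_first_event=True`` every sample from the first task-type
    crisis onward is discarded (the stricter reading in which the record
    remainder is censored after the first transition).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    in_crisis_states = (STATE_B, STATE_D) if task == ICP_TASK else (STATE_C, STATE_D)
    in_crisis = np.isin(timeline.state, in_crisis_states)
    retained = ~in_crisis
    if censor_after_first_event and in_crisis.any():
        retained[np.argmax(in_crisis):] = False
    timeline.retained[task] = retained
    return timeline


def events_to_frame(patient_id: str, events: list[CrisisEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "modality": [e.modality for e in events],
            "onset": [e.onset for e in events],
            "offset": [e.offset for e in events],
            "peak_value": [e.peak_value for e in events],
        }
    )


def label_record(
    record: PhysioRecord, censor_after_first_event: bool = False
) -> tuple[StateTimeline, dict]:
    """Detect both modalities' events and build a fully filtered timeline."""
    evs = {m: detect_events(record, m) for m in MODALITIES}
    timeline = build_state_timeline(record, evs[ICP], evs[PBTO2])
    for task in TASKS:
        succession_filter(timeline, task, censor_after_first_event)
    return timeline, evs
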