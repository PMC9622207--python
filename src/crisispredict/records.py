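"""Per-patient neuromonitoring records and the cohort CSV format.

A :class:`PhysioRecord` holds one patient's regularly sampled intracranial
pressure (ICP, mmHg) and brain tissue oxygen tension (PbtO2, mmHg) series.
Monitoring gaps are represented as absent rows (missing timestamps); a single
missing modality at an otherwise monitored time is an empty field / NaN.

The on-disk cohort format is a UTF-8 CSV with header exactly
``patient_id,timestamp,icp_mmHg,pbto2_mmHg`` and ISO-8601 timestamps; an empty
field encodes a missing value. Reading a written cohort restores bitwise-equal
numeric arrays (no imputation, no resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COHORT_COLUMNS = ["patient_id", "timestamp", "icp_mmHg", "pbto2_mmHg"]

ICP = "ICP"
PBTO2 = "PBTO2"
MODALITIES = (ICP, PBTO2)

#: Crisis thresholds (mmHg). ICP violates at >= threshold, PbtO2 at <= threshold.
ICP_THRESHOLD = 20.0
PBTO2_THRESHOLD = 20.0
#: Minimum sustained violation, strict ("> 5 min"), in minutes.
MIN_CRISIS_MINUTES = 5.0


@dataclass
class PhysioRecord:
    """One patient's ICP/PbtO2 time series at a nominal sampling interval.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    times : ndarray of datetime64[s]
        Strictly increasing sample timestamps. Gaps (absent rows) are allowed.
    icp, pbto2 : ndarray of float
        Signals in mmHg, aligned with ``times``; NaN marks a missing value.
    """

    patient_id: str
    times: np.ndarray
    icp: np.ndarray
    pbto2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.icp = np.asarray(self.icp, dtype=float)
        self.pbto2 = np.asarray(self.pbto2, dtype=float)
        n = len(self.times)
        if len(self.icp) != n or len(self.pbto2) != n:
            raise ValueError(
                f"patient {self.patient_id}: signal lengths "
                f"({len(self.icp)}, {len(self.pbto2)}) != {n} timestamps"
            )
        if n > 1 and not (np.diff(self.times.astype("int64")) > 0).all():
            raise ValueError(f"patient {self.patient_id}: timestamps not strictly increasing")
        for name, sig in (("icp", self.icp), ("pbto2", self.pbto2)):
            bad = np.isinf(sig)
            if bad.any():
                raise ValueError(f"patient {self.patient_id}: non-finite {name} value")

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhysioRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.icp, other.icp, equal_nan=True)
            and np.array_equal(self.pbto2, other.pbto2, equal_nan=True)
        )

    @property
    def minutes(self) -> np.ndarray:
        """Sample times in minutes since the first sample (float array)."""
        return (self.times - self.times[0]) / np.timedelta64(60, "s")

    @property
    def dt_minutes(self) -> float:
        """Nominal sampling interval, the median inter-sample spacing."""
        if len(self.times) < 2:
            return float("nan")
        return float(np.median(np.diff(self.times) / np.timedelta64(60, "s")))

    def signal(self, modality: str) -> np.ndarray:
        if modality == ICP:
            return self.icp
        if modality == PBTO2:
            return self.pbto2
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "timestamp": self.times,
                "icp_mmHg": self.icp,
                "pbto2_mmHg": self.pbto2,
            }
        )


def write_cohort(records: list[PhysioRecord], path) -> None:
    """Serialize a cohort to the canonical CSV format (one row per sample)."""
    if not records:
        raise ValueError("cohort is empty; nothing to write")
    frame = pd.concat([r.to_frame() for r in records], ignore_index=True)
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort(path) -> list[PhysioRecord]:
    """Load a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    ValueError
        If required columns are missing or a timestamp fails to parse; the
        message names the first offending row.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV {path}: missing column(s) {missing}")
    ts = pd.to_datetime(frame["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(
            f"cohort CSV {path}: unparseable timestamp "
            f"{frame['timestamp'].iloc[row]!r} at data row {row + 1}"
        )
    frame["timestamp"] = ts
    records = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        records.append(
            PhysioRecord(
                patient_id=str(pid),
                times=grp["timestamp"].to_numpy().astype("datetime64[s]"),
                icp=grp["icp_mmHg"].to_numpy(dtype=float),
                pbto2=grp["pbto2_mmHg"].to_numpy(dtype=float),
            )
        )
    return records
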