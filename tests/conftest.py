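import numpy as np
import pytest

from crisispredict import SimConfig, simulate_cohort
from crisispredict.records import PhysioRecord

START = np.datetime64("2021-01-01T00:00:00", "s")


@pytest.fixture
def make_record():
    """Factory for simple 1-min-resolution records (NaN = missing sample)."""

    def _make(icp, pbto2=None, patient_id="X", dt_seconds=60, times=None):
        icp = np.asarray(icp, dtype=float)
        n = len(icp)
        if pbto2 is None:
            pbto2 = np.full(n, 28.0)
        if times is None:
            times = START + (np.arange(n) * dt_seconds).astype("timedelta64[s]")
        return PhysioRecord(patient_id, times, icp, np.asarray(pbto2, dtype=float))

    return _make


@pytest.fixture(scope="session")
def cohort50():
    """50-patient canonical synthetic cohort (fixed seed), with ground truth."""
    return simulate_cohort(SimConfig(n_patients=50, record_hours=72.0, seed=1))


@pytest.fixture(scope="session")
def canonical_cohort():
    """The full ~100-patient, 3-day canonical cohort used for model checks."""
    return simulate_cohort(SimConfig(seed=0))
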