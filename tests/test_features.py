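import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisispredict import (
    approximate_entropy,
    build_feature_table,
    feature_columns,
    psd_features,
    window_trends,
)
from crisispredict.events import ICP_TASK, label_record
from oracles import apen as apen_oracle
from oracles import psd_slope_and_spread, trend_stats


def test_constant_window_trends():
    tr = window_trends([15.0] * 30)
    assert tr["mean"] == tr["median"] == tr["min"] == tr["max"] == 15.0
    assert tr["sd"] == 0.0
    assert tr["diff_first_last"] == 0.0
    assert tr["diff_recent"] == 0.0
    assert tr["auc"] == 15.0 * 29


def test_two_point_window_trends():
    tr = window_trends([10.0, 20.0])
    assert tr["mean"] == 15.0
    assert tr["diff_first_last"] == 10.0
    assert tr["auc"] == 15.0


def test_window_trends_requires_two_samples():
    with pytest.raises(ValueError, match=">= 2"):
        window_trends([5.0])


def test_trends_match_oracle_on_random_windows():
    rng = np.random.default_rng(10)
    for _ in range(200):
        n = rng.integers(2, 40)
        v = rng.normal(20, 5, n)
        t = np.cumsum(rng.uniform(0.5, 2.0, n))
        got = window_trends(v, t)
        want = trend_stats(v, t)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, rel=1e-12, abs=1e-12)


def test_pure_sinusoid_has_zero_spectral_spread():
    """A sinusoid at an exact periodogram bin concentrates all spectral mass
    in one bin, so the spectral-spread variance vanishes."""
    t = np.arange(30)
    _, var = psd_features(np.sin(2 * np.pi * 5 * t / 30), dt_minutes=1.0)
    assert var == pytest.approx(0.0, abs=1e-20)


def test_white_noise_spectrum_is_flat_on_average():
    """The flat-spectrum property: averaging many white-noise periodograms
    (in the power domain) gives a log-log slope ~0 within Monte-Carlo error.

    The per-window log-periodogram slope itself has a small negative
    finite-sample bias (chi-square log asymmetry and the half-width Nyquist
    bin), so the per-window mean is instead checked against an independent
    simulation oracle built on the direct-summation DFT.
    """
    from scipy.signal import periodogram

    rng = np.random.default_rng(11)
    windows = rng.standard_normal((400, 30))
    f, p = periodogram(windows - windows.mean(axis=1, keepdims=True),
                       fs=1.0, window="boxcar", detrend=False, axis=1)
    # interior bins only: the one-sided Nyquist bin carries half the density
    mean_power = p[:, 1:-1].mean(axis=0)
    slope_of_mean = np.polyfit(np.log10(f[1:-1]), np.log10(mean_power), 1)[0]
    assert abs(slope_of_mean) < 0.1

    slopes = [psd_features(w, 1.0)[0] for w in windows]
    oracle_rng = np.random.default_rng(99)
    oracle_slopes = [
        psd_slope_and_spread(oracle_rng.standard_normal(30), 1.0)[0]
        for _ in range(400)
    ]
    se = np.sqrt(np.var(slopes, ddof=1) / 400 + np.var(oracle_slopes, ddof=1) / 400)
    assert np.mean(slopes) == pytest.approx(np.mean(oracle_slopes), abs=4 * se)


def test_psd_matches_direct_summation_dft_oracle():
    rng = np.random.default_rng(12)
    v = rng.normal(25, 4, 32)
    slope, var = psd_features(v, dt_minutes=1.0)
    o_slope, o_var = psd_slope_and_spread(v, 1.0)
    assert slope == pytest.approx(o_slope, rel=1e-9)
    assert var == pytest.approx(o_var, rel=1e-9)


def test_psd_variance_power_mode():
    rng = np.random.default_rng(13)
    v = rng.normal(0, 1, 30)
    _, var = psd_features(v, 1.0, variance_mode="power")
    from oracles import dft_psd

    _, power = dft_psd(v, 1.0)
    assert var == pytest.approx(np.var(power), rel=1e-9)


def test_apen_constant_window_is_zero():
    assert approximate_entropy([7.0] * 30) == 0.0


def test_apen_alternating_series_is_nearly_zero_and_matches_oracle():
    """A strictly periodic series is almost perfectly regular; the tiny
    positive residual comes from end-of-series template counts."""
    v = np.array([1.0, 2.0] * 15)
    got = approximate_entropy(v, m=2, r=0.1)
    assert got == pytest.approx(apen_oracle(v, 2, 0.1), abs=1e-12)
    assert 0 <= got < 0.01


def test_apen_matches_double_loop_oracle_to_high_precision():
    rng = np.random.default_rng(14)
    v = rng.normal(20, 3, 30)
    r = 0.2 * np.std(v, ddof=1)
    assert approximate_entropy(v, 2, r) == pytest.approx(
        apen_oracle(v, 2, r), abs=1e-12
    )


def test_apen_input_validation():
    with pytest.raises(ValueError, match="length"):
        approximate_entropy([1.0, 2.0, 3.0], m=2)
    with pytest.raises(ValueError, match="positive"):
        approximate_entropy(np.arange(10.0), m=2, r=0.0)


@settings(max_examples=100, derandomize=True)
@given(shift=st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_signal_shift_invariance(shift):
    """ApEn (relative r) and spectral features are invariant to adding a
    constant to the signal; trends shift accordingly."""
    rng = np.random.default_rng(15)
    v = rng.normal(20, 3, 30)
    assert approximate_entropy(v + shift) == pytest.approx(
        approximate_entropy(v), abs=1e-9
    )
    s0, var0 = psd_features(v, 1.0)
    s1, var1 = psd_features(v + shift, 1.0)
    assert s1 == pytest.approx(s0, rel=1e-6, abs=1e-9)
    assert var1 == pytest.approx(var0, rel=1e-6, abs=1e-12)
    tr0, tr1 = window_trends(v), window_trends(v + shift)
    assert tr1["mean"] == pytest.approx(tr0["mean"] + shift, abs=1e-9)
    assert tr1["sd"] == pytest.approx(tr0["sd"], abs=1e-9)


def test_time_translation_invariance(make_record, cohort50):
    """Shifting all timestamps by a constant leaves feature values unchanged."""
    records, _ = cohort50
    rec = records[0]
    tl, evs = label_record(rec)
    from crisispredict.records import PhysioRecord

    shifted = PhysioRecord(rec.patient_id, rec.times + np.timedelta64(3600, "s"),
                           rec.icp, rec.pbto2)
    tl2, _ = label_record(shifted)
    obs = rec.times[100:110]
    tab1 = build_feature_table(rec, tl, ICP_TASK, 3, obs, np.zeros(10))
    tab2 = build_feature_table(shifted, tl2, ICP_TASK, 3,
                               obs + np.timedelta64(3600, "s"), np.zeros(10))
    for col in feature_columns(3):
        assert np.allclose(tab1[col], tab2[col], equal_nan=True)


def test_tier_column_counts(make_record):
    """Tier 1 has the two base predictors; tier 3 has all thirteen."""
    assert feature_columns(1) == ["last_value", "episode_number"]
    assert len(feature_columns(2)) == 10
    assert len(feature_columns(3)) == 13


def test_short_record_yields_empty_tier2_table(make_record):
    rec = make_record(np.full(20, 12.0))
    tl, _ = label_record(rec)
    tab = build_feature_table(rec, tl, ICP_TASK, 2, rec.times[-1:], [0])
    assert len(tab) == 0


def test_gap_in_window_blanks_frequency_features_only(make_record):
    icp = np.full(80, 15.0) + np.sin(np.arange(80))
    icp[40] = np.nan
    rec = make_record(icp)
    tl, _ = label_record(rec)
    obs = rec.times[[60, 75]]  # windows (30,60] and (45,75]: first has the gap
    tab = build_feature_table(rec, tl, ICP_TASK, 3, obs, [0, 0])
    assert len(tab) == 2
    assert np.isnan(tab.loc[0, "apen"]) and np.isnan(tab.loc[0, "psd_slope"])
    assert not np.isnan(tab.loc[0, "mean"])  # trends fall back to usable samples
    assert not np.isnan(tab.loc[1, "apen"])


def test_batch_features_match_scalar_paths(cohort50):
    """The vectorized table builder agrees with the one-window functions."""
    records, _ = cohort50
    rec = records[1]
    tl, _ = label_record(rec)
    idx = np.arange(40, 400, 37)
    obs = rec.times[idx]
    tab = build_feature_table(rec, tl, ICP_TASK, 3, obs, np.zeros(len(idx)))
    mins = rec.minutes
    for row_i, j in enumerate(idx):
        sel = (mins > mins[j] - 30) & (mins <= mins[j])
        v = rec.icp[sel]
        tr = window_trends(v, mins[sel])
        for key, val in tr.items():
            assert tab.loc[row_i, key] == pytest.approx(val, rel=1e-12)
        slope, var = psd_features(v, 1.0)
        assert tab.loc[row_i, "psd_slope"] == pytest.approx(slope, rel=1e-9)
        assert tab.loc[row_i, "psd_variance"] == pytest.approx(var, rel=1e-9)
        assert tab.loc[row_i, "apen"] == pytest.approx(
            approximate_entropy(v), abs=1e-12
        )
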