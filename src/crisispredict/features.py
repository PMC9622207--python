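"""Windowed predictor features over the preceding 30 min of a task's signal.

Three nested tiers are used throughout:

* tier 1 — the last recorded measurement and the episode number;
* tier 2 — tier 1 plus longitudinal trends over the preceding 30-min window:
  mean, median, sample standard deviation, minimum, maximum, difference
  between first and last recording, difference between the two most recent
  recordings, and trapezoidal area under the curve (mmHg*min);
* tier 3 — tier 2 plus frequency-domain measures: the log-log slope of the
  power spectrum, the variance of the unit-normalized power-spectrum
  distribution (spectral spread about the centroid), and approximate entropy.

The window is the half-open 30 min ending at (and including) the observation
sample. Trend features tolerate partial windows (>= 2 usable samples; the AUC
uses actual timestamps); frequency features require a gap-free, evenly
sampled window and are set to missing otherwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .events import TASK_MODALITY, TASKS, StateTimeline
from .records import PhysioRecord

logger = logging.getLogger(__name__)

TREND_FEATURES = [
    "mean", "median", "sd", "min", "max", "diff_first_last", "diff_recent", "auc",
]
FREQ_FEATURES = ["psd_slope", "psd_variance", "apen"]


def feature_columns(tier: int) -> list[str]:
    """Predictor column names for a feature tier (1, 2 or 3)."""
    if tier not in (1, 2, 3):
        raise ValueError(f"tier must be 1, 2 or 3, got {tier}")
    cols = ["last_value", "episode_number"]
    if tier >= 2:
        cols += TREND_FEATURES
    if tier >= 3:
        cols += FREQ_FEATURES
    return cols


def window_trends(values: np.ndarray, minutes: np.ndarray | None = None) -> dict:
    """The eight longitudinal trend statistics of one window.

    ``values`` are the usable (non-missing) samples in time order; ``minutes``
    their timestamps in minutes (defaults to unit spacing). Requires >= 2
    samples. ``sd`` is the sample standard deviation (n-1); ``auc`` is the
    trapezoidal area on actual timestamps.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"window_trends needs >= 2 usable samples, got {v.size}")
    t = np.arange(v.size, dtype=float) if minutes is None else np.asarray(minutes, float)
    return {
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "sd": float(np.std(v, ddof=1)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "diff_first_last": float(v[-1] - v[0]),
        "diff_recent": float(v[-1] - v[-2]),
        "auc": float(np.trapezoid(v, t)),
    }


def psd_features(values: np.ndarray, dt_minutes: float,
                 variance_mode: str = "spread") -> tuple[float, float]:
    """Spectral slope and spectral variance of a gap-free window.

    The plain (boxcar, mean-removed) periodogram of the window is computed at
    frequencies in cycles/min. ``psd_slope`` is the OLS slope of log10(power)
    against log10(frequency) over the non-zero frequencies with positive
    power; ``psd_variance`` is, by default, the variance of frequency under
    the power spectrum normalized to a unit distribution (spectral spread).
    ``variance_mode="power"`` instead returns the variance of the power values
    themselves. Returns NaN where the quantity is undefined (e.g. a constant
    window).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError(f"psd_features needs >= 8 samples, got {v.size}")
    if variance_mode not in ("spread", "power"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    freqs, power = periodogram(v - v.mean(), fs=1.0 / dt_minutes,
                               window="boxcar", detrend=False)
    freqs, power = freqs[1:], power[1:]  # drop DC

    pos = power > 0
    if pos.sum() >= 2:
        x, y = np.log10(freqs[pos]), np.log10(power[pos])
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = float("nan")

    total = power.sum()
    if variance_mode == "power":
        variance = float(np.var(power))
    elif total > 0:
        p = power / total
        centroid = float(np.sum(freqs * p))
        variance = float(np.sum((freqs - centroid) ** 2 * p))
    else:
        variance = float("nan")
    return slope, variance


def _phi(dist: np.ndarray, m: int, r: float) -> float:
    """Mean log fraction of m-templates within Chebyshev distance r."""
    n = dist.shape[0]
    nm = n - m + 1
    dmax = dist[:nm, :nm]
    for o in range(1, m):
        dmax = np.maximum(dmax, dist[o : o + nm, o : o + nm])
    c = (dmax <= r).mean(axis=1)
    return float(np.log(c).mean())


def approximate_entropy(values: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r) of a short series.

    ApEn = Phi_m(r) - Phi_{m+1}(r) with Phi_m(r) the average log fraction of
    length-m templates within Chebyshev distance r (self-matches included).
    With the default relative tolerance r = 0.2 * sd(values) (sample sd), a
    constant window has ApEn 0 by definition.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n <= m + 1:
        raise ValueError(f"approximate_entropy needs length > m+1 = {m + 1}, got {n}")
    if r is None:
        sd = float(np.std(v, ddof=1))
        if sd == 0.0:
            return 0.0
        r = 0.2 * sd
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    dist = np.abs(v[:, None] - v[None, :])
    return _phi(dist, m, r) - _phi(dist, m + 1, r)


# ---------------------------------------------------------------------------
# batch (vectorized) versions used by the table builder


def _batch_trends(w_mat: np.ndarray, dt: float) -> dict:
    return {
        "mean": w_mat.mean(axis=1),
        "median": np.median(w_mat, axis=1),
        "sd": w_mat.std(axis=1, ddof=1),
        "min": w_mat.min(axis=1),
        "max": w_mat.max(axis=1),
        "diff_first_last": w_mat[:, -1] - w_mat[:, 0],
        "diff_recent": w_mat[:, -1] - w_mat[:, -2],
        "auc": dt * (w_mat.sum(axis=1) - 0.5 * (w_mat[:, 0] + w_mat[:, -1])),
    }


def _batch_psd(w_mat: np.ndarray, dt: float, variance_mode: str = "spread") -> dict:
    freqs, power = periodogram(w_mat - w_mat.mean(axis=1, keepdims=True),
                               fs=1.0 / dt, window="boxcar", detrend=False, axis=1)
    freqs, power = freqs[1:], power[:, 1:]
    pos = power > 0
    n_pos = pos.sum(axis=1)
    logf = np.log10(freqs)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(pos, np.log10(np.where(pos, power, 1.0)), 0.0)
        sx = (logf * pos).sum(axis=1)
        sy = logp.sum(axis=1)
        sxx = (logf**2 * pos).sum(axis=1)
        sxy = (logf * logp).sum(axis=1)
        slope = (n_pos * sxy - sx * sy) / (n_pos * sxx - sx**2)
    slope = np.where(n_pos >= 2, slope, np.nan)

    total = power.sum(axis=1)
    if variance_mode == "power":
        variance = np.var(power, axis=1)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = power / total[:, None]
            centroid = (freqs[None, :] * p).sum(axis=1)
            variance = ((freqs[None, :] - centroid[:, None]) ** 2 * p).sum(axis=1)
        variance = np.where(total > 0, variance, np.nan)
    return {"psd_slope": slope, "psd_variance": variance}


def _batch_apen(w_mat: np.ndarray, m: int = 2, r_factor: float = 0.2,
                chunk: int = 2000) -> np.ndarray:
    out = np.empty(w_mat.shape[0])
    n = w_mat.shape[1]
    for lo in range(0, w_mat.shape[0], chunk):
        w = w_mat[lo : lo + chunk]
        sd = w.std(axis=1, ddof=1)
        r = r_factor * sd
        dist = np.abs(w[:, :, None] - w[:, None, :])
        phis = []
        for mm in (m, m + 1):
            nm = n - mm + 1
            dmax = dist[:, :nm, :nm]
            for o in range(1, mm):
                dmax = np.maximum(dmax, dist[:, o : o + nm, o : o + nm])
            c = (dmax <= r[:, None, None]).mean(axis=2)
            phis.append(np.log(c).mean(axis=1))
        val = phis[0] - phis[1]
        out[lo : lo + chunk] = np.where(sd > 0, val, 0.0)
    return out


def build_feature_table(
    record: PhysioRecord,
    timeline: StateTimeline,
    task: str,
    tier: int,
    obs_times: np.ndarray,
    labels: np.ndarray,
    window_minutes: float = 30.0,
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
    psd_variance_mode: str = "spread",
) -> pd.DataFrame:
    """Assemble one patient's feature rows at the given observation times.

    ``obs_times``/``labels`` are the representative observations and their
    next-horizon outcome labels from the survival module. The featurized
    signal is the task's own modality (ICP for the ICP task, PbtO2 for the
    PbtO2 task). Rows whose window has fewer than 2 usable samples are
    dropped (logged); frequency features are missing unless the window is
    complete and gap-free.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    cols = feature_columns(tier)
    obs_times = np.asarray(obs_times, dtype="datetime64[s]")
    if len(obs_times) == 0:
        return pd.DataFrame(columns=["patient_id", "time", "label", *cols])

    signal = record.signal(TASK_MODALITY[task])
    dt = record.dt_minutes
    w = int(round(window_minutes / dt))
    times_i = record.times.astype("int64")  # seconds
    idx = np.searchsorted(record.times, obs_times)
    if not np.array_equal(record.times[np.clip(idx, 0, len(record.times) - 1)], obs_times):
        raise ValueError("observation times not found in record")

    rows = pd.DataFrame({
        "patient_id": record.patient_id,
        "time": obs_times,
        "label": np.asarray(labels, dtype=int),
        "last_value": signal[idx],
        "episode_number": timeline.episode[task][idx],
    })

    if tier == 1:
        return rows[["patient_id", "time", "label", *cols]]

    # a tier-2+ row needs its full 30-min history span inside the record;
    # rows too close to the record start are dropped (no complete window)
    rec_minutes = record.minutes
    history_ok = rec_minutes[idx] - rec_minutes[0] >= window_minutes - dt
    if not history_ok.all():
        n_short = int((~history_ok).sum())
        logger.info("patient %s (%s, tier %d): dropped %d row(s) without a full "
                    "%g-min history", record.patient_id, task, tier, n_short,
                    window_minutes)
        rows = rows[history_ok].reset_index(drop=True)
        idx = idx[history_ok]
        if len(rows) == 0:
            for name in TREND_FEATURES + (FREQ_FEATURES if tier >= 3 else []):
                rows[name] = np.nan
            return rows[["patient_id", "time", "label", *cols]]

    # complete window: w consecutive samples at nominal dt ending at the
    # observation, none missing
    span_s = (w - 1) * dt * 60.0
    first = idx - w + 1
    complete = first >= 0
    ok = complete.copy()
    ok[complete] &= (
        times_i[idx[complete]] - times_i[np.maximum(first[complete], 0)] == span_s
    )
    for name in TREND_FEATURES + (FREQ_FEATURES if tier >= 3 else []):
        rows[name] = np.nan

    if ok.any():
        wins = signal[first[ok, None] + np.arange(w)[None, :]]
        gapfree = ~np.isnan(wins).any(axis=1)
        sel = np.flatnonzero(ok)[gapfree]
        wins = wins[gapfree]
        for name, vals in _batch_trends(wins, dt).items():
            rows.loc[rows.index[sel], name] = vals
        if tier >= 3 and len(wins):
            for name, vals in _batch_psd(wins, dt, psd_variance_mode).items():
                rows.loc[rows.index[sel], name] = vals
            rows.loc[rows.index[sel], "apen"] = _batch_apen(
                wins, m=apen_m, r_factor=apen_r_factor
            )
        partial = np.flatnonzero(ok)[~gapfree]
    else:
        partial = np.array([], dtype=int)

    # partial windows (in-window missing values): trends on the usable
    # samples, frequency features stay missing
    incomplete = np.flatnonzero(~ok)
    dropped = 0
    drop_idx: list[int] = []
    for ridx in np.concatenate([incomplete, partial]):
        j = idx[ridx]
        t_min = rec_minutes[j]
        in_win = (rec_minutes > t_min - window_minutes) & (rec_minutes <= t_min)
        vals = signal[in_win]
        mins = rec_minutes[in_win]
        usable = ~np.isnan(vals)
        if usable.sum() < 2:
            dropped += 1
            drop_idx.append(ridx)
            continue
        for name, val in window_trends(vals[usable], mins[usable]).items():
            rows.loc[rows.index[ridx], name] = val
    if dropped:
        logger.info("patient %s (%s, tier %d): dropped %d row(s) with <2 usable window samples",
                    record.patient_id, task, tier, dropped)
        rows = rows.drop(rows.index[drop_idx])
    return rows[["patient_id", "time", "label", *cols]].reset_index(drop=True)
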