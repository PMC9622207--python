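"""Synthetic multi-day ICP/PbtO2 neuromonitoring cohorts with known crisis hazard.

Each patient's baseline physiology is a discretized mean-reverting
(Ornstein-Uhlenbeck) process around a patient-specific baseline drawn from the
cohort distribution. At every 30-min block boundary a crisis onset fires per
modality with probability

    logistic(b0 + b_level * (level - threshold) + b_slope * slope)

where ``level`` is the signal at the last sample before the boundary, ``slope``
is the (last - first) / duration trend over the preceding 30-min window, and
signs are oriented so that higher ICP / lower PbtO2 increases hazard. A fired
onset superimposes a crisis excursion: a linear ramp to
``threshold +/- crisis_margin``, a plateau of lognormal duration (floored so
the sustained violation exceeds 5 min), and a linear ramp back to the baseline
path. While an excursion is active the modality's hazard is suppressed
(no overlapping onsets).

Ground truth records every crisis as realized in the emitted signal: the
maximal threshold-violating run containing the injected plateau, so a run
detector recovers onsets exactly. The generator is bitwise deterministic given
the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .records import (
    ICP,
    ICP_THRESHOLD,
    MIN_CRISIS_MINUTES,
    PBTO2,
    PBTO2_THRESHOLD,
    PhysioRecord,
)

RECORD_START = np.datetime64("2021-01-01T00:00:00", "s")


@dataclass
class SimConfig:
    """Generative parameters for a synthetic neuromonitoring cohort.

    Defaults are the canonical study conditions: ~100 patients monitored for
    three days at 1-min resolution, ICP baseline 14 +/- 3 mmHg and PbtO2
    baseline 28 +/- 4 mmHg, with a per-block logistic onset hazard that makes
    impending crises predictable from recent level and trend.
    """

    n_patients: int = 100
    record_hours: float = 72.0
    dt_minutes: float = 1.0
    icp_baseline_mean: float = 14.0
    icp_baseline_sd: float = 3.0
    pbto2_baseline_mean: float = 28.0
    pbto2_baseline_sd: float = 4.0
    ou_reversion: float = 0.1          # per-minute mean-reversion rate
    ou_noise_sd: float = 1.0           # mmHg per sqrt(minute)
    hazard_intercept: float = -3.0
    hazard_level_coef: float = 0.25    # per mmHg beyond threshold
    hazard_slope_coef: float = 3.0     # per mmHg/min of 30-min trend
    excursion_ramp_minutes: float = 5.0
    excursion_plateau_lognormal_mu: float = math.log(15.0)
    excursion_plateau_lognormal_sigma: float = 0.5
    crisis_margin: float = 4.0         # mmHg beyond threshold at plateau
    block_minutes: float = 30.0        # hazard evaluation interval
    coupling_coef: float = 0.0         # ICP excursion depresses PbtO2 (off)
    gap_rate_per_day: float = 0.0      # monitoring gaps (off)
    gap_mean_minutes: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)):
                if math.isnan(v):
                    raise ValueError(f"SimConfig.{f.name} is NaN")
                if math.isinf(v) and not (f.name == "hazard_intercept" and v < 0):
                    # -inf intercept is the legitimate zero-hazard limit
                    raise ValueError(f"SimConfig.{f.name} is non-finite")
        if self.dt_minutes <= 0:
            raise ValueError("dt_minutes must be > 0")
        if self.record_hours <= 0:
            raise ValueError("record_hours must be > 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("icp_baseline_sd", "pbto2_baseline_sd", "ou_noise_sd",
                     "excursion_plateau_lognormal_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.record_hours * 60.0 / self.dt_minutes))

    @property
    def block_samples(self) -> int:
        return int(round(self.block_minutes / self.dt_minutes))

    @property
    def min_crisis_samples(self) -> int:
        """Smallest run length whose duration strictly exceeds the 5-min rule."""
        return int(math.floor(MIN_CRISIS_MINUTES / self.dt_minutes)) + 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig key(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Injected crises as realized in the emitted signals, plus the hazard used.

    ``crises`` maps patient_id -> modality -> list of (onset, offset)
    datetime64 pairs (offset = last violating sample); onsets are strictly
    increasing per patient and modality.
    """

    crises: dict
    hazard: dict

    def n_crises(self, modality: str | None = None) -> int:
        total = 0
        for per_mod in self.crises.values():
            for mod, ivs in per_mod.items():
                if modality is None or mod == modality:
                    total += len(ivs)
        return total

    def onset_times(self, patient_id: str, modality: str) -> list:
        return [on for on, _ in self.crises.get(patient_id, {}).get(modality, [])]

    def to_json(self, path) -> None:
        payload = {
            "hazard": self.hazard,
            "crises": {
                pid: {
                    mod: [[str(on), str(off)] for on, off in ivs]
                    for mod, ivs in per_mod.items()
                }
                for pid, per_mod in self.crises.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        crises = {
            pid: {
                mod: [
                    (np.datetime64(on, "s"), np.datetime64(off, "s"))
                    for on, off in ivs
                ]
                for mod, ivs in per_mod.items()
            }
            for pid, per_mod in payload["crises"].items()
        }
        return cls(crises=crises, hazard=payload["hazard"])


def _ou_path(mu: float, eps: np.ndarray, rev: float, noise_sd: float,
             dt: float, z0: float) -> np.ndarray:
    """Discretized OU path started from its stationary distribution."""
    phi = 1.0 - rev * dt
    step_sd = noise_sd * math.sqrt(dt)
    if abs(phi) < 1.0 and step_sd > 0:
        stat_sd = step_sd / math.sqrt(1.0 - phi * phi)
    else:
        stat_sd = 0.0
    x0 = mu + stat_sd * z0
    dev, _ = lfilter([1.0], [1.0, -phi], step_sd * eps, zi=[phi * (x0 - mu)])
    out = np.empty(len(eps) + 1)
    out[0] = x0
    out[1:] = mu + dev
    return out


def _realized_runs(violate: np.ndarray, plateau_starts: list[int]) -> list[tuple[int, int]]:
    """Expand each injected plateau to its maximal violating run; dedupe merges."""
    runs: list[tuple[int, int]] = []
    for p0 in plateau_starts:
        lo = p0
        while lo > 0 and violate[lo - 1]:
            lo -= 1
        hi = p0
        while hi + 1 < len(violate) and violate[hi + 1]:
            hi += 1
        if not runs or runs[-1] != (lo, hi):
            runs.append((lo, hi))
    return runs


def _simulate_patient(pid: str, cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_steps
    dt = cfg.dt_minutes
    bs = cfg.block_samples
    ramp_s = max(1, int(round(cfg.excursion_ramp_minutes / dt)))
    min_plateau_s = cfg.min_crisis_samples

    mu_icp = cfg.icp_baseline_mean + cfg.icp_baseline_sd * rng.standard_normal()
    mu_pb = cfg.pbto2_baseline_mean + cfg.pbto2_baseline_sd * rng.standard_normal()
    z0 = rng.standard_normal(2)
    eps = rng.standard_normal((2, max(n - 1, 0)))
    ou = {
        ICP: _ou_path(mu_icp, eps[0], cfg.ou_reversion, cfg.ou_noise_sd, dt, z0[0]),
        PBTO2: _ou_path(mu_pb, eps[1], cfg.ou_reversion, cfg.ou_noise_sd, dt, z0[1]),
    }
    sig = {m: ou[m].copy() for m in (ICP, PBTO2)}
    active_until = {ICP: -1, PBTO2: -1}
    plateau_starts = {ICP: [], PBTO2: []}

    for i in range(bs, n, bs):
        for mod in (ICP, PBTO2):
            if i <= active_until[mod]:
                continue
            level = sig[mod][i - 1]
            lb = min(bs, i)
            slope = (sig[mod][i - 1] - sig[mod][i - lb]) / ((lb - 1) * dt) if lb > 1 else 0.0
            if mod == ICP:
                z = (cfg.hazard_intercept
                     + cfg.hazard_level_coef * (level - ICP_THRESHOLD)
                     + cfg.hazard_slope_coef * slope)
                peak = ICP_THRESHOLD + cfg.crisis_margin
            else:
                z = (cfg.hazard_intercept
                     + cfg.hazard_level_coef * (PBTO2_THRESHOLD - level)
                     - cfg.hazard_slope_coef * slope)
                peak = PBTO2_THRESHOLD - cfg.crisis_margin
            if rng.random() >= expit(z):
                continue
            plateau_min = rng.lognormal(cfg.excursion_plateau_lognormal_mu,
                                        cfg.excursion_plateau_lognormal_sigma)
            plateau_s = max(int(math.ceil(plateau_min / dt)), min_plateau_s)
            span = ramp_s + plateau_s + ramp_s
            if i + span > n:
                continue  # no room for a full sustained excursion before record end
            profile = np.concatenate([
                np.linspace(sig[mod][i - 1], peak, ramp_s + 1)[1:],
                np.full(plateau_s, peak),
                np.linspace(peak, ou[mod][min(i + span, n - 1)], ramp_s + 1)[1:],
            ])
            sl = slice(i, i + span)
            if mod == ICP:
                sig[ICP][sl] = np.maximum(sig[ICP][sl], profile)
                if cfg.coupling_coef != 0.0:
                    sig[PBTO2][sl] = sig[PBTO2][sl] - cfg.coupling_coef * (
                        sig[ICP][sl] - ou[ICP][sl]
                    )
            else:
                sig[PBTO2][sl] = np.minimum(sig[PBTO2][sl], profile)
            plateau_starts[mod].append(i + ramp_s)
            active_until[mod] = i + span - 1

    times = RECORD_START + (np.arange(n) * int(round(dt * 60))).astype("timedelta64[s]")
    crises = {}
    for mod, thresh, cmp_ge in ((ICP, ICP_THRESHOLD, True), (PBTO2, PBTO2_THRESHOLD, False)):
        violate = sig[mod] >= thresh if cmp_ge else sig[mod] <= thresh
        runs = _realized_runs(violate, plateau_starts[mod])
        crises[mod] = [(times[lo], times[hi]) for lo, hi in runs]

    keep = np.ones(n, dtype=bool)
    if cfg.gap_rate_per_day > 0:
        n_gaps = rng.poisson(cfg.gap_rate_per_day * cfg.record_hours / 24.0)
        for _ in range(n_gaps):
            g0 = int(rng.integers(0, n))
            g_len = max(1, int(round(rng.exponential(cfg.gap_mean_minutes) / dt)))
            keep[g0 : g0 + g_len] = False

    record = PhysioRecord(
        patient_id=pid,
        times=times[keep],
        icp=sig[ICP][keep],
        pbto2=sig[PBTO2][keep],
    )
    return record, crises


def simulate_cohort(config: SimConfig) -> tuple[list[PhysioRecord], GroundTruth]:
    """Generate a cohort and its crisis ground truth, deterministically.

    Per-patient random streams are spawned from the configured seed, so the
    whole cohort is bitwise reproducible and patients are independent.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    width = max(3, len(str(config.n_patients)))
    records: list[PhysioRecord] = []
    crises: dict = {}
    for k, ss in enumerate(seeds):
        pid = f"P{k:0{width}d}"
        rec, cr = _simulate_patient(pid, config, np.random.default_rng(ss))
        records.append(rec)
        crises[pid] = cr
    hazard = {
        "intercept": config.hazard_intercept,
        "level_coef": config.hazard_level_coef,
        "slope_coef": config.hazard_slope_coef,
        "block_minutes": config.block_minutes,
    }
    return records, GroundTruth(crises=crises, hazard=hazard)
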