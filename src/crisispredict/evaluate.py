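"""Discrimination and clinical-utility evaluation.

AUROC is pairwise concordance with ties counted 1/2. Confidence intervals use
a patient-level bootstrap by default (resampling patients with replacement
respects the within-patient correlation of dense, unblocked test rows); the
DeLong asymptotic interval is available as an option, and paired model
comparison uses the DeLong test for correlated ROC curves.

Decision-curve analysis reports net benefit

    NB(t) = TP(t)/N - FP(t)/N * t / (1 - t)

of alerting at risk >= t, against the alert-all policy
(NB = pi - (1 - pi) * t/(1 - t), with pi the outcome prevalence) and the
no-alert policy (NB = 0). Following the study design it is computed on a
sample with equal outcome proportions (see :func:`balanced_sample`); note
that balancing sets pi = 0.5 and therefore changes the reference curves —
an unbalanced-sample DCA simply skips the resampling step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score


@dataclass
class RocResult:
    """AUROC with a confidence interval."""

    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes must be present")


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both outcome classes present")
    return n_pos, n_neg


def auroc_point(labels, risks) -> float:
    """Pairwise-concordance AUROC (ties counted 1/2)."""
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(risks, dtype=float)))


def delong_components(labels, risks) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus DeLong structural components (V10 per positive, V01 per negative)."""
    labels = np.asarray(labels, dtype=int)
    risks = np.asarray(risks, dtype=float)
    m, n = _check_two_classes(labels)
    pos, neg = risks[labels == 1], risks[labels == 0]
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # one entry per positive
    v01 = 1.0 - (tz[m:] - ty) / m    # one entry per negative
    return float(auc), v10, v01


def delong_variance(labels, risks) -> float:
    auc, v10, v01 = delong_components(labels, risks)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 observations per class")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def auroc(
    labels,
    risks,
    groups=None,
    method: str = "patient-bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RocResult:
    """AUROC with a confidence interval.

    ``method="patient-bootstrap"`` resamples whole patients (``groups``; rows
    when no groups are given) with replacement ``n_boot`` times and takes
    percentile limits, skipping degenerate single-class resamples.
    ``method="delong"`` uses the asymptotic DeLong variance.
    """
    labels = np.asarray(labels, dtype=int)
    risks = np.asarray(risks, dtype=float)
    n_pos, n_neg = _check_two_classes(labels)
    point = float(roc_auc_score(labels, risks))

    if method == "delong":
        se = np.sqrt(delong_variance(labels, risks))
        z = norm.ppf(1 - alpha / 2)
        return RocResult(point, max(0.0, point - z * se), min(1.0, point + z * se),
                         n_pos, n_neg, "delong")
    if method != "patient-bootstrap":
        raise ValueError(f"unknown CI method {method!r}")

    if groups is None:
        groups = np.arange(len(labels))
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    by_group = {g: np.flatnonzero(groups == g) for g in uniq}
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([by_group[g] for g in chosen])
        yb = labels[idx]
        if yb.min() == yb.max():
            continue
        stats.append(roc_auc_score(yb, risks[idx]))
    if not stats:
        raise ValueError("all bootstrap resamples were single-class; cannot form CI")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return RocResult(point, float(lo), float(hi), n_pos, n_neg, "patient-bootstrap")


def compare_auroc(labels, risks_a, risks_b) -> float:
    """Two-sided p of the paired DeLong test for correlated ROC curves."""
    risks_a = np.asarray(risks_a, dtype=float)
    risks_b = np.asarray(risks_b, dtype=float)
    if len(risks_a) != len(risks_b):
        raise ValueError("paired comparison needs the same rows for both models")
    if np.array_equal(risks_a, risks_b):
        return 1.0
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=2)
    if counts.min() < 2:
        raise ValueError("DeLong comparison needs >= 2 observations per class")
    auc_a, v10_a, v01_a = delong_components(labels, risks_a)
    auc_b, v10_b, v01_b = delong_components(labels, risks_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0 if auc_a == auc_b else 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def balanced_sample(labels, seed: int = 0) -> np.ndarray:
    """Indices of a sample with equal outcome proportions.

    All minority-class rows are kept; the majority class is down-sampled
    without replacement to the same size (seeded). Indices are returned in
    ascending order, so an already balanced input comes back unchanged.
    """
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    keep_major = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, keep_major]))


@dataclass
class DecisionCurve:
    """Net benefit of a model and the two reference alerting policies."""

    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_alert_all: np.ndarray
    net_benefit_no_alert: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.net_benefit_model,
                "nb_alert_all": self.net_benefit_alert_all,
                "nb_no_alert": self.net_benefit_no_alert,
            }
        )


DEFAULT_DCA_THRESHOLDS = np.round(np.arange(0.01, 1.00, 0.01), 2)


def decision_curve(labels, risks, thresholds=None) -> DecisionCurve:
    """Net benefit across alert thresholds (alert at risk >= t)."""
    labels = np.asarray(labels, dtype=int)
    risks = np.asarray(risks, dtype=float)
    t = DEFAULT_DCA_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(labels)
    pi = labels.mean()
    alert = risks[None, :] >= t[:, None]
    tp = (alert & (labels == 1)[None, :]).sum(axis=1)
    fp = (alert & (labels == 0)[None, :]).sum(axis=1)
    nb_model = tp / n - fp / n * t / (1 - t)
    nb_all = pi - (1 - pi) * t / (1 - t)
    return DecisionCurve(
        thresholds=t,
        net_benefit_model=nb_model,
        net_benefit_alert_all=nb_all,
        net_benefit_no_alert=np.zeros_like(t),
        prevalence=float(pi),
    )
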