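"""Performance statistics from labels and decision values.

Covers the 2x2 confusion matrix and its derived statistics (sensitivity,
specificity, balanced accuracy, PPV, positive likelihood ratio,
F-measure), the balanced posterior accuracy credible interval of
Brodersen-style independent beta posteriors, and ROC / precision-recall
curves with a rank-based AUC.

Two conventions are fixed here and documented prominently:

* the *reported* balanced accuracy is the sample value
  (sensitivity + specificity) / 2, while the *credible interval* comes
  from the beta posterior of the same counts — the posterior mean is
  lower than the sample value for small cohorts;
* for comparisons with printed study tables, percentages are rounded to
  the nearest integer (half away from zero) and ratios to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionSummary",
    "PosteriorInterval",
    "confusion_from_decisions",
    "balanced_posterior_interval",
    "roc_points_and_auc",
    "precision_recall_points",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero, the convention of printed clinical tables."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass
class ConfusionSummary:
    """Counts of a 2x2 confusion matrix with derived statistics."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def ppv(self) -> float:
        # undefined when no subject is called positive
        return np.nan if self.TP + self.FP == 0 else self.TP / (self.TP + self.FP)

    @property
    def positive_likelihood_ratio(self) -> float:
        fpr = 1.0 - self.specificity
        return np.inf if fpr == 0 else self.sensitivity / fpr

    @property
    def f_measure(self) -> float:
        p, r = self.ppv, self.sensitivity
        if np.isnan(p) or p + r == 0:
            return np.nan if np.isnan(p) else 0.0
        return 2.0 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "ppv": self.ppv,
            "positive_likelihood_ratio": self.positive_likelihood_ratio,
            "f_measure": self.f_measure,
        }


def confusion_from_decisions(
    actual: np.ndarray,
    decision: np.ndarray,
    threshold: float = 0.0,
) -> ConfusionSummary:
    """Confusion counts from signed decision values.

    Predicted label is +1 for a decision value strictly above the
    threshold, else -1 (a value exactly at the threshold is the
    conservative, non-favorable call).
    """
    actual = np.asarray(actual)
    decision = np.asarray(decision, dtype=float)
    if actual.shape != decision.shape or actual.size == 0:
        raise ValueError("actual and decision must be equal-length non-empty vectors")
    if len(np.unique(actual)) < 2:
        raise ValueError("both classes must be present")
    pred = np.where(decision > threshold, 1, -1)
    return ConfusionSummary(
        TP=int(np.sum((actual == 1) & (pred == 1))),
        FP=int(np.sum((actual == -1) & (pred == 1))),
        TN=int(np.sum((actual == -1) & (pred == -1))),
        FN=int(np.sum((actual == 1) & (pred == -1))),
    )


@dataclass
class PosteriorInterval:
    """Central credible interval for the posterior balanced accuracy."""

    lower: float
    upper: float
    level: float
    posterior_mean: float
    draws: int


def balanced_posterior_interval(
    summary: ConfusionSummary,
    level: float = 0.95,
    draws: int = 10 ** 6,
    seed=0,
) -> PosteriorInterval:
    """Credible interval of the balanced accuracy under beta posteriors.

    With uniform priors, sensitivity ~ Beta(TP+1, FN+1) and specificity
    ~ Beta(TN+1, FP+1) independently; the balanced accuracy is their
    mean. The central interval at ``level`` is estimated from ``draws``
    Monte-Carlo samples, reproducibly for a given seed.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if min(summary.TP, summary.FP, summary.TN, summary.FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    rng = np.random.default_rng(seed)
    sens = rng.beta(summary.TP + 1, summary.FN + 1, size=draws)
    spec = rng.beta(summary.TN + 1, summary.FP + 1, size=draws)
    b = 0.5 * (sens + spec)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(b, [alpha, 1.0 - alpha])
    return PosteriorInterval(
        lower=float(lo), upper=float(hi), level=level,
        posterior_mean=float(b.mean()), draws=draws,
    )


def roc_points_and_auc(actual: np.ndarray, decision: np.ndarray):
    """Empirical ROC curve and its rank-based AUC.

    The AUC is the fraction of (positive, negative) pairs whose positive
    member has the larger decision value, ties counted one half — which
    equals the trapezoidal area under the empirical ROC.
    """
    actual = np.asarray(actual)
    decision = np.asarray(decision, dtype=float)
    if len(np.unique(actual)) < 2:
        raise ValueError("both classes must be present")
    pos = decision[actual == 1]
    neg = decision[actual == -1]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (len(pos) * len(neg))

    thresholds = np.concatenate([[np.inf], np.unique(decision)[::-1]])
    points = []
    for t in thresholds:
        tpr = np.mean(pos >= t) if len(pos) else 0.0
        fpr = np.mean(neg >= t) if len(neg) else 0.0
        points.append((float(fpr), float(tpr)))
    return points, float(auc)


def precision_recall_points(actual: np.ndarray, decision: np.ndarray):
    """Precision/recall pairs at every distinct threshold, descending."""
    actual = np.asarray(actual)
    decision = np.asarray(decision, dtype=float)
    if len(np.unique(actual)) < 2:
        raise ValueError("both classes must be present")
    n_pos = int(np.sum(actual == 1))
    points = []
    for t in np.unique(decision)[::-1]:
        called = decision >= t
        tp = int(np.sum(called & (actual == 1)))
        precision = tp / int(called.sum())
        recall = tp / n_pos
        points.append((float(recall), float(precision)))
    return points
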