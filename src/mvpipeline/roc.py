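"""ROC analysis of the complexity score as a predictor of surgical approach.

The positive class is *replacement*: the score measures lesion complexity,
so higher scores should make valve replacement more likely.  Because the
score is integer-valued, candidate cutoffs are placed at midpoints between
consecutive distinct scores — the convention that yields half-integer
cutoffs such as 8.5 — and a patient is called positive when their score is
at or above the cutoff.  The optimal cutoff maximizes the Youden index
J = sensitivity + specificity - 1, with ties resolved toward the lower
threshold (favoring sensitivity).

The AUC is the trapezoidal area under the ROC polygon, which for this
construction equals the Mann-Whitney concordance probability
P(score_pos > score_neg) + 0.5 * P(tie).  The 95% CI is a stratified
percentile bootstrap (cases and controls resampled separately).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = ["ROCResult", "roc_curve", "auc", "auc_ci", "youden_cutoff", "analyze"]


@dataclass(frozen=True)
class ROCResult:
    """ROC curve of a score against a binary label.

    ``thresholds`` descend from above the maximum score to below the
    minimum; ``sensitivity[i]`` / ``one_minus_specificity[i]`` are the
    operating point when calling positive at ``score >= thresholds[i]``,
    so both coordinates are non-decreasing along the arrays.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    best_cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 1 or labels.ndim != 1 or scores.shape != labels.shape:
        raise ValidationError("scores and labels must be equal-length 1-D sequences")
    if scores.size == 0:
        raise DegenerateInputError("empty input")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValidationError("labels must be binary (0 = repair, 1 = replacement)")
    if labels.min() == labels.max():
        raise DegenerateInputError(
            "both label classes must be present to form an ROC curve"
        )
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    return scores, labels


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve with one point per candidate cutoff.

    Cutoffs are midpoints between consecutive distinct scores, plus one
    above the maximum (operating point (0, 0)) and one below the minimum
    ((1, 1)).
    """
    scores, labels = _validate(scores, labels)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[-1] + 1.0], mids[::-1], [distinct[0] - 1.0]])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    sens = np.empty_like(thresholds)
    fpr = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        called = scores >= t
        sens[i] = np.sum(called & (labels == 1)) / n_pos
        fpr[i] = np.sum(called & (labels == 0)) / n_neg
    return ROCResult(thresholds=thresholds, sensitivity=sens, one_minus_specificity=fpr)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC polygon (trapezoid rule); equals the
    Mann-Whitney concordance probability with ties counted 0.5."""
    curve = roc_curve(scores, labels)
    return float(np.trapezoid(curve.sensitivity, curve.one_minus_specificity))


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC.

    Cases and controls are resampled separately (so every replicate keeps
    both classes), deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValidationError(f"n_boot must be >= 100, got {n_boot}", field="n_boot")
    scores, labels = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    stats = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        n = rng.choice(neg, size=neg.size, replace=True)
        # concordance computed directly: mean over pos/neg pairs
        greater = (p[:, None] > n[None, :]).mean()
        ties = (p[:, None] == n[None, :]).mean()
        stats[i] = greater + 0.5 * ties
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(low), float(high)


def youden_cutoff(roc: ROCResult) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1; ties are
    broken toward the lower threshold (higher sensitivity)."""
    j = roc.sensitivity - roc.one_minus_specificity
    # thresholds descend, so the last argmax is the lowest threshold
    best = np.flatnonzero(j == j.max())[-1]
    return float(roc.thresholds[best])


def analyze(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """Full ROC analysis: curve, AUC, bootstrap CI and Youden cutoff."""
    curve = roc_curve(scores, labels)
    area = float(np.trapezoid(curve.sensitivity, curve.one_minus_specificity))
    ci = auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    cutoff = youden_cutoff(curve)
    at = int(np.flatnonzero(curve.thresholds == cutoff)[0])
    return replace(
        curve,
        auc=area,
        auc_ci=ci,
        best_cutoff=cutoff,
        sens_at_cutoff=float(curve.sensitivity[at]),
        spec_at_cutoff=float(1.0 - curve.one_minus_specificity[at]),
    )
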