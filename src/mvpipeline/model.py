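"""Seeded k-fold cross-validated gradient-boosted classification of
surgical approach (repair vs replacement) from echocardiographic features.

The feature vector carries the effective variables (ruptured chordae,
leaflet morphology, leaflet motion, vegetation and perforation/cleft count
classes, the three calcification sites and commissural fusion) and the
uncertain variables (the 8 prolapse flags).  Demographics and diagnosis
are deliberately excluded: they were found ineffective for approach
prediction.  Classes are encoded repair = 0, replacement = 1.

Defaults mirror the reference protocol: 3 folds drawn from a seeded
permutation (seed 0), 15 base classifiers, learning rate 0.3, maximum
tree depth 2.  Per-fold feature importances use the boosting *gain*
measure, normalized to percentages, and are aggregated across folds by
superposition (elementwise sum, renormalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from xgboost import XGBClassifier

from .cohort import Approach, PatientRecord
from .errors import DegenerateInputError, ValidationError
from .scoring import (
    EchoFeatures,
    LeafletMorphology,
    LeafletMotion,
    PROLAPSE_FIELDS,
)

__all__ = [
    "ModelConfig",
    "CVResult",
    "FEATURE_NAMES",
    "encode",
    "encode_cohort",
    "kfold_split",
    "train_eval",
    "cross_validate",
    "accuracy",
    "aggregate_importance",
]

#: Versioned encoding map: ordinal codes for the ordered categoricals.
MORPHOLOGY_CODES = {
    LeafletMorphology.NORMAL: 0,
    LeafletMorphology.THICKENING: 1,
    LeafletMorphology.REDUNDANT: 2,
}
MOTION_CODES = {
    LeafletMotion.NORMAL: 0,
    LeafletMotion.EXCESSIVE: 1,
    LeafletMotion.RESTRICTION: 2,
}

#: Declared column order of the feature vector (effective variables first,
#: then the 8 prolapse indicators).
FEATURE_NAMES: tuple[str, ...] = (
    "ruptured_chordae",
    "leaflet_morphology",
    "leaflet_motion",
    "vegetation_class",
    "perforation_cleft_class",
    "calc_annulus",
    "calc_leaflet",
    "calc_chordae",
    "commissure_fusion",
) + PROLAPSE_FIELDS

CLASS_NAMES = ("repair", "replacement")


@dataclass(frozen=True)
class ModelConfig:
    """Boosting and cross-validation hyperparameters."""

    n_base_classifiers: int = 15
    learning_rate: float = 0.3
    max_tree_depth: int = 2
    k_folds: int = 3
    seed: int = 0
    importance_type: str = "gain"
    stratified: bool = False

    def __post_init__(self):
        if self.n_base_classifiers < 1:
            raise ValidationError("n_base_classifiers must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValidationError("learning_rate must be in (0, 1]")
        if self.max_tree_depth < 1:
            raise ValidationError("max_tree_depth must be >= 1")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.importance_type not in ("gain", "weight", "cover"):
            raise ValidationError(
                f"importance_type must be gain/weight/cover, got {self.importance_type!r}"
            )


@dataclass(frozen=True)
class CVResult:
    """Outputs of one cross-validated run.

    Confusion matrices are 2x2 with rows = true class, columns = predicted,
    class order (repair, replacement).  ``mean_accuracy`` is the unweighted
    mean of the fold accuracies (the average of the k experiments);
    ``pooled_accuracy`` pools all held-out predictions instead.
    Importances are percentages per feature, one vector per fold, plus
    their superposition renormalized to 100.
    """

    fold_assignment: np.ndarray
    confusion_matrices: list[np.ndarray]
    fold_accuracies: list[float]
    mean_accuracy: float
    pooled_accuracy: float
    fold_importance: list[np.ndarray]
    aggregate_importance: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    class_names: tuple[str, ...] = CLASS_NAMES

    def ranked_importance(self) -> list[tuple[str, float]]:
        return aggregate_importance([self.aggregate_importance], self.feature_names)


def encode(record: "PatientRecord | EchoFeatures") -> np.ndarray:
    """Encode one patient into the declared numeric feature vector.

    Demographics and diagnosis never enter the vector, so records that
    differ only in those fields encode identically.
    """
    f = record.features if isinstance(record, PatientRecord) else record
    if not isinstance(f, EchoFeatures):
        raise ValidationError(f"cannot encode {type(record).__name__}")
    values = [
        int(f.ruptured_chordae),
        MORPHOLOGY_CODES[f.leaflet_morphology],
        MOTION_CODES[f.leaflet_motion],
        int(f.vegetation_class),
        int(f.perforation_cleft_class),
        int(f.calc_annulus),
        int(f.calc_leaflet),
        int(f.calc_chordae),
        int(f.commissure_fusion),
    ] + [int(getattr(f, name)) for name in PROLAPSE_FIELDS]
    return np.asarray(values, dtype=float)


def encode_cohort(cohort: Sequence[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and 0/1 label vector (replacement = 1) for a cohort."""
    X = np.stack([encode(r) for r in cohort])
    y = np.array([int(r.approach is Approach.REPLACEMENT) for r in cohort])
    return X, y


def kfold_split(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Assign ``n`` samples to ``k`` folds from a seeded permutation.

    The permutation is cut into contiguous blocks whose sizes differ by at
    most one (the first ``n mod k`` folds take the extra sample), so
    n = 143, k = 3 gives sizes 48, 48, 47.
    """
    if not isinstance(n, int) or not isinstance(k, int):
        raise ValidationError("n and k must be integers")
    if k < 2 or k > n:
        raise ValidationError(f"need 2 <= k <= n, got k={k}, n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=int)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    start = 0
    for fold, size in enumerate(sizes):
        assignment[perm[start : start + size]] = fold
        start += size
    return assignment


def accuracy(cm: np.ndarray) -> float:
    """(TP + TN) / (TP + FN + FP + TN) from a 2x2 confusion matrix."""
    cm = np.asarray(cm)
    if cm.shape != (2, 2) or np.any(cm < 0):
        raise ValidationError("confusion matrix must be 2x2 with non-negative entries")
    total = cm.sum()
    if total == 0:
        raise ValidationError("confusion matrix is all-zero")
    return float(np.trace(cm) / total)


def aggregate_importance(
    per_fold: Sequence[np.ndarray], feature_names: Sequence[str] = FEATURE_NAMES
) -> list[tuple[str, float]]:
    """Superpose per-fold importance vectors and rank features.

    Elementwise sum renormalized to percentages; stable descending sort
    with ties resolved by the declared feature order.
    """
    if len(per_fold) == 0:
        raise ValidationError("need at least one importance vector")
    vectors = [np.asarray(v, dtype=float) for v in per_fold]
    dim = vectors[0].size
    if any(v.size != dim for v in vectors) or dim != len(feature_names):
        raise ValidationError("importance vectors must all match the feature count")
    if any(np.any(v < 0) for v in vectors):
        raise ValidationError("importances must be non-negative")
    total = np.sum(vectors, axis=0)
    s = total.sum()
    if s > 0:
        total = 100.0 * total / s
    order = sorted(range(dim), key=lambda i: (-total[i], i))
    return [(feature_names[i], float(total[i])) for i in order]


def _fit_importance(model: XGBClassifier, config: ModelConfig) -> np.ndarray:
    booster = model.get_booster()
    raw = booster.get_score(importance_type=config.importance_type)
    vec = np.zeros(len(FEATURE_NAMES))
    for key, value in raw.items():
        idx = int(key[1:]) if key.startswith("f") else FEATURE_NAMES.index(key)
        vec[idx] = value
    s = vec.sum()
    return 100.0 * vec / s if s > 0 else vec


def cross_validate(
    X: np.ndarray, y: np.ndarray, config: ModelConfig = ModelConfig()
) -> CVResult:
    """Run the seeded k-fold protocol on an encoded feature matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if X.shape[0] != n:
        raise ValidationError("X and y lengths differ")
    if config.k_folds > n:
        raise ValidationError(f"k_folds={config.k_folds} exceeds n={n}")
    if config.stratified:
        assignment = _stratified_split(y, config.k_folds, config.seed)
    else:
        assignment = kfold_split(n, config.k_folds, config.seed)

    cms: list[np.ndarray] = []
    accs: list[float] = []
    importances: list[np.ndarray] = []
    pooled_pred = np.empty(n, dtype=int)
    for fold in range(config.k_folds):
        test = assignment == fold
        train = ~test
        y_train = y[train]
        if y_train.min() == y_train.max():
            raise DegenerateInputError(
                f"training split for fold {fold} contains a single class; "
                "re-seed the split or use a larger cohort"
            )
        model = XGBClassifier(
            n_estimators=config.n_base_classifiers,
            learning_rate=config.learning_rate,
            max_depth=config.max_tree_depth,
            random_state=config.seed,
            eval_metric="logloss",
            n_jobs=1,
        )
        model.fit(X[train], y_train)
        pred = model.predict(X[test])
        pooled_pred[test] = pred
        cm = _sk_confusion(y[test], pred, labels=[0, 1])
        cms.append(cm)
        accs.append(accuracy(cm))
        importances.append(_fit_importance(model, config))

    agg = np.sum(importances, axis=0)
    s = agg.sum()
    if s > 0:
        agg = 100.0 * agg / s
    return CVResult(
        fold_assignment=assignment,
        confusion_matrices=cms,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        pooled_accuracy=float(np.mean(pooled_pred == y)),
        fold_importance=importances,
        aggregate_importance=agg,
    )


def _stratified_split(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Class-stratified variant of the seeded fold assignment."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        for fold in range(k):
            assignment[idx[fold::k]] = fold
    return assignment


def train_eval(
    cohort: Sequence[PatientRecord], config: ModelConfig = ModelConfig()
) -> CVResult:
    """Encode a cohort and run the cross-validated boosted classifier."""
    if len(cohort) == 0:
        raise DegenerateInputError("empty cohort")
    X, y = encode_cohort(cohort)
    return cross_validate(X, y, config)


def cutoff_baseline_accuracy(
    scores: np.ndarray, y: np.ndarray, assignment: np.ndarray
) -> list[float]:
    """Single-cutoff baseline under the same folds: for each fold the Youden
    cutoff is fit on the training portion of the complexity scores and
    applied to the held-out fold (score >= cutoff -> replacement).

    Returns the per-fold accuracies, comparable to a :class:`CVResult`'s.
    """
    from .roc import roc_curve, youden_cutoff

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    accs = []
    for fold in range(int(assignment.max()) + 1):
        test = assignment == fold
        train = ~test
        cutoff = youden_cutoff(roc_curve(scores[train], y[train]))
        pred = (scores[test] >= cutoff).astype(int)
        accs.append(float(np.mean(pred == y[test])))
    return accs
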