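"""ROC construction, AUC/concordance equivalence, bootstrap CI, Youden."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from mvpipeline.errors import DegenerateInputError, ValidationError
from mvpipeline.roc import analyze, auc, auc_ci, roc_curve, youden_cutoff


def concordance_oracle(scores, labels) -> Fraction:
    """Mann-Whitney concordance by exhaustive pair counting in exact
    rational arithmetic (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    acc = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                acc += 1
            elif p == n:
                acc += Fraction(1, 2)
    return acc / (len(pos) * len(neg))


def binary_labels_with_both_classes(n_max=50):
    return st.integers(2, n_max).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 12), min_size=n, max_size=n),
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            ),
        )
    )


def test_perfect_separation_curve_and_auc():
    scores, labels = [1, 2, 3, 4], [0, 0, 1, 1]
    curve = roc_curve(scores, labels)
    assert 2.5 in curve.thresholds
    at = np.flatnonzero(curve.thresholds == 2.5)[0]
    assert curve.sensitivity[at] == 1.0
    assert curve.one_minus_specificity[at] == 0.0
    assert auc(scores, labels) == 1.0


def test_midpoint_convention_yields_half_integer_cutoffs():
    """Integer scores separated between 8 and 9 must offer 8.5 as a
    candidate threshold."""
    scores = [2, 4, 6, 8, 9, 10, 11]
    labels = [0, 0, 0, 0, 1, 1, 1]
    curve = roc_curve(scores, labels)
    assert 8.5 in curve.thresholds
    assert youden_cutoff(curve) == 8.5


def test_curve_monotone_and_endpoints():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 15, size=60)
    labels = rng.integers(0, 2, size=60)
    labels[0], labels[1] = 0, 1
    curve = roc_curve(scores, labels)
    assert curve.sensitivity[0] == 0.0 and curve.one_minus_specificity[0] == 0.0
    assert curve.sensitivity[-1] == 1.0 and curve.one_minus_specificity[-1] == 1.0
    assert np.all(np.diff(curve.sensitivity) >= 0)
    assert np.all(np.diff(curve.one_minus_specificity) >= 0)


def test_curve_coordinates_match_exhaustive_counting():
    rng = np.random.default_rng(11)
    scores = rng.integers(0, 8, size=30).astype(float)
    labels = rng.integers(0, 2, size=30)
    labels[:2] = [0, 1]
    curve = roc_curve(scores, labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    for t, sens, fpr in zip(
        curve.thresholds, curve.sensitivity, curve.one_minus_specificity
    ):
        tp = sum(1 for s, l in zip(scores, labels) if l == 1 and s >= t)
        fp = sum(1 for s, l in zip(scores, labels) if l == 0 and s >= t)
        assert sens == tp / n_pos
        assert fpr == fp / n_neg


@pytest.mark.parametrize(
    "scores,labels,expected",
    [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),
        ([1, 2, 2, 3], [0, 1, 0, 1], 0.875),
    ],
)
def test_auc_known_values(scores, labels, expected):
    assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=150)
@given(binary_labels_with_both_classes())
def test_auc_equals_concordance_oracle(data):
    scores, labels = data
    expected = concordance_oracle(scores, labels)
    assert auc(scores, labels) == pytest.approx(float(expected), abs=1e-12)


@settings(derandomize=True, max_examples=60)
@given(binary_labels_with_both_classes(n_max=30))
def test_auc_matches_sklearn(data):
    scores, labels = data
    assert auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


@settings(derandomize=True, max_examples=60)
@given(binary_labels_with_both_classes(n_max=30))
def test_relabeling_flips_auc(data):
    scores, labels = data
    flipped = [1 - l for l in labels]
    assert auc(scores, labels) == pytest.approx(1.0 - auc(scores, flipped), abs=1e-12)


def test_shift_invariance():
    rng = np.random.default_rng(4)
    scores = rng.integers(0, 12, size=40).astype(float)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    base = analyze(scores, labels, n_boot=200, seed=0)
    shifted = analyze(scores + 100.0, labels, n_boot=200, seed=0)
    assert shifted.auc == pytest.approx(base.auc, abs=1e-12)
    assert shifted.best_cutoff == pytest.approx(base.best_cutoff + 100.0)
    assert shifted.sens_at_cutoff == base.sens_at_cutoff
    assert shifted.spec_at_cutoff == base.spec_at_cutoff


def test_single_class_labels_rejected():
    with pytest.raises(DegenerateInputError):
        roc_curve([1, 2, 3], [1, 1, 1])


def test_auc_ci_deterministic_and_collapses_when_perfect():
    scores, labels = [1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1]
    ci1 = auc_ci(scores, labels, n_boot=300, seed=7)
    ci2 = auc_ci(scores, labels, n_boot=300, seed=7)
    assert ci1 == ci2 == (1.0, 1.0)
    with pytest.raises(ValidationError):
        auc_ci(scores, labels, n_boot=50)


def test_auc_ci_brackets_point_estimate(medium_cohort):
    scores = [r.complexity.total for r in medium_cohort]
    labels = [int(r.approach.value == "replacement") for r in medium_cohort]
    result = analyze(scores, labels, n_boot=500, seed=0)
    low, high = result.auc_ci
    assert low <= result.auc <= high
    assert high - low < 0.15  # n = 600 gives a tight interval


def test_youden_matches_brute_force_search():
    rng = np.random.default_rng(21)
    for _ in range(20):
        n = rng.integers(10, 40)
        scores = rng.integers(0, 10, size=n).astype(float)
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels)
        js = curve.sensitivity - curve.one_minus_specificity
        best_j = js.max()
        candidates = curve.thresholds[js == best_j]
        assert youden_cutoff(curve) == candidates.min()  # tie -> lower cutoff


def test_youden_representational_check_table5_regime():
    """An operating point with sens 0.73 / 1-spec 0.33 (J = 0.40) at 8.5 is
    selected over lower-J thresholds."""
    # 100 replacements, 100 repairs; 73 replacements and 33 repairs >= 9
    scores = [9] * 73 + [5] * 27 + [9] * 33 + [5] * 67
    labels = [1] * 100 + [0] * 100
    result = analyze(scores, labels, n_boot=200, seed=0)
    assert result.best_cutoff == 7.0  # midpoint of the two distinct scores
    assert result.sens_at_cutoff == pytest.approx(0.73)
    assert result.spec_at_cutoff == pytest.approx(0.67)
    j = result.sens_at_cutoff + result.spec_at_cutoff - 1.0
    assert j == pytest.approx(0.40)


def test_ci_covers_generating_concordance_across_replicate_cohorts():
    """Percentile-bootstrap CI covers the large-sample concordance of the
    generating model in most replicate cohorts."""
    from mvpipeline.cohort import default_config, generate_cohort

    big = generate_cohort(default_config(n_patients=20_000, seed=123))
    s = np.array([r.complexity.total for r in big], dtype=float)
    y = np.array([int(r.approach.value == "replacement") for r in big])
    target = auc(s, y)  # analytic concordance proxy at large n

    covered = 0
    n_rep = 12
    for rep in range(n_rep):
        cohort = generate_cohort(default_config(n_patients=300, seed=500 + rep))
        scores = [r.complexity.total for r in cohort]
        labels = [int(r.approach.value == "replacement") for r in cohort]
        low, high = auc_ci(scores, labels, n_boot=400, seed=rep)
        covered += low <= target <= high
    assert covered >= 0.9 * n_rep - 1  # allow one miss below the 90% line
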