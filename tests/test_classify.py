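import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coevdimer.classify import (
    ClassificationError,
    SplitPlan,
    compare_norm_distributions,
    confusion_metrics,
    rbf_kernel,
    train_eval_protocol,
)
from coevdimer.features import NormFeatureTable


def make_table(x: np.ndarray, labels: list[str]) -> NormFeatureTable:
    cols = pd.MultiIndex.from_tuples([("MI", t) for t in range(x.shape[1])])
    idx = [f"d{k:03d}" for k in range(len(x))]
    return NormFeatureTable(
        features=pd.DataFrame(np.abs(x), index=idx, columns=cols),
        labels=pd.Series(labels, index=idx),
    )


# --- kernel ----------------------------------------------------------------


def test_rbf_kernel_identity_and_decay():
    assert rbf_kernel([1.0, 2.0], [1.0, 2.0], sigma=3.0) == 1.0
    assert rbf_kernel([0.0], [2.0], sigma=1.0) == pytest.approx(math.exp(-2.0))
    vals = [rbf_kernel([0.0], [d], sigma=1.0) for d in (0.5, 1.0, 2.0, 4.0)]
    assert vals == sorted(vals, reverse=True)  # strictly decreasing in distance


def test_rbf_kernel_rejects_bad_sigma():
    with pytest.raises(ClassificationError):
        rbf_kernel([0.0], [1.0], sigma=0.0)


# --- confusion metrics -----------------------------------------------------


def test_confusion_metrics_worked_example():
    r = confusion_metrics(tp=8, fp=2, tn=9, fn=1)
    assert r.accuracy == pytest.approx(0.85)
    assert r.sensitivity == pytest.approx(8 / 9)
    assert r.specificity == pytest.approx(9 / 11)
    assert r.precision == pytest.approx(0.8)
    assert r.npv == pytest.approx(0.9)
    assert r.bm == pytest.approx(8 / 9 + 9 / 11 - 1)


def test_confusion_metrics_perfect_classifier():
    r = confusion_metrics(tp=10, tn=15, fp=0, fn=0)
    assert (r.accuracy, r.sensitivity, r.specificity, r.precision, r.npv) == (
        1.0, 1.0, 1.0, 1.0, 1.0,
    )
    assert (r.fpr, r.fnr) == (0.0, 0.0)
    assert r.bm == 1.0
    assert r.undefined == ()


def test_bm_from_best_sensitivity_specificity():
    """Sensitivity 1 with specificity 0.962 gives informedness 0.962."""
    assert 1.0 + 0.962 - 1.0 == pytest.approx(0.962)
    r = confusion_metrics(tp=25, fn=0, tn=25, fp=1)
    assert r.bm == pytest.approx(r.sensitivity + r.specificity - 1.0)


def test_zero_denominator_is_flagged_not_zeroed():
    r = confusion_metrics(tp=0, fp=0, tn=5, fn=3)
    assert math.isnan(r.precision)
    assert "precision" in r.undefined
    r2 = confusion_metrics(tp=0, fp=2, tn=5, fn=0)
    assert "sensitivity" in r2.undefined and "bm" in r2.undefined


def test_all_zero_counts_rejected():
    with pytest.raises(ClassificationError):
        confusion_metrics(0, 0, 0, 0)


@settings(max_examples=200, deadline=None)
@given(
    tp=st.integers(0, 100), tn=st.integers(0, 100),
    fp=st.integers(0, 100), fn=st.integers(0, 100),
)
def test_metric_identities(tp, tn, fp, fn):
    """accuracy*total = tp+tn; fpr = 1-specificity; fnr = 1-sensitivity;
    bm = sensitivity+specificity-1 — exactly, for any counts."""
    total = tp + tn + fp + fn
    if total == 0:
        return
    r = confusion_metrics(tp, tn, fp, fn)
    assert r.accuracy * total == pytest.approx(tp + tn, abs=1e-9)
    if not math.isnan(r.specificity):
        assert r.fpr + r.specificity == pytest.approx(1.0, abs=1e-12)
    if not math.isnan(r.sensitivity):
        assert r.fnr + r.sensitivity == pytest.approx(1.0, abs=1e-12)
    if not math.isnan(r.bm):
        assert r.bm == pytest.approx(r.sensitivity + r.specificity - 1.0, abs=1e-12)


# --- protocol --------------------------------------------------------------

FAST_PLAN = dict(cv_folds=5, tuning_rotations=2)


def test_separable_classes_classified_perfectly(rng):
    """Positives shifted five standard deviations from negatives."""
    neg = rng.normal(10.0, 1.0, size=(40, 3))
    pos = rng.normal(15.0, 1.0, size=(40, 3))
    table = make_table(np.vstack([neg, pos]), ["negative"] * 40 + ["positive"] * 40)
    r = train_eval_protocol(table, SplitPlan(random_seed=0, **FAST_PLAN))
    assert r.accuracy == 1.0


def test_protocol_deterministic_under_seed(rng):
    x = rng.normal(5.0, 1.0, size=(60, 4))
    labels = ["positive" if k % 2 else "negative" for k in range(60)]
    table = make_table(x, labels)
    r1 = train_eval_protocol(table, SplitPlan(random_seed=7, **FAST_PLAN))
    r2 = train_eval_protocol(table, SplitPlan(random_seed=7, **FAST_PLAN))
    assert r1.to_json() == r2.to_json()


def test_permuted_labels_give_chance_accuracy(rng):
    """With labels shuffled independently of the features, held-out
    accuracy over many seeds stays inside the binomial interval of 0.5."""
    correct = total = 0
    for seed in range(20):
        local = np.random.default_rng(seed)
        x = local.normal(5.0, 1.0, size=(60, 3))
        labels = ["positive"] * 30 + ["negative"] * 30
        local.shuffle(labels)
        table = make_table(x, labels)
        r = train_eval_protocol(table, SplitPlan(random_seed=seed, **FAST_PLAN))
        correct += r.tp + r.tn
        total += r.tp + r.tn + r.fp + r.fn
    acc = correct / total
    half_width = 1.96 * math.sqrt(0.25 / total)
    assert abs(acc - 0.5) <= half_width


def test_training_is_test_blind(rng):
    """Perturbing test-set feature rows after the split cannot change
    the trained model: labels (hence the stratified split) are held
    fixed, only rows landing in the 30% test partition differ."""
    from sklearn.model_selection import train_test_split

    x = np.abs(rng.normal(5.0, 1.0, size=(60, 3)))
    y = np.array([1 if k % 2 else 0 for k in range(60)])
    idx = np.arange(60)
    _, test_idx = train_test_split(idx, test_size=0.30, random_state=3, stratify=y)
    x2 = x.copy()
    x2[test_idx] = np.abs(rng.normal(50.0, 5.0, size=(len(test_idx), 3)))
    labels = list(np.where(y == 1, "positive", "negative"))
    plan = SplitPlan(random_seed=3, **FAST_PLAN)
    r1, m1 = train_eval_protocol(make_table(x, labels), plan, return_model=True)
    r2, m2 = train_eval_protocol(make_table(x2, labels), plan, return_model=True)
    assert r1.best_params == r2.best_params
    np.testing.assert_allclose(
        m1.named_steps["svm"].dual_coef_, m2.named_steps["svm"].dual_coef_
    )
    np.testing.assert_allclose(m1.named_steps["svm"].intercept_,
                               m2.named_steps["svm"].intercept_)


def test_single_class_rejected(rng):
    x = np.abs(rng.normal(size=(20, 2)))
    table = make_table(x, ["positive"] * 20)
    with pytest.raises(ClassificationError):
        train_eval_protocol(table, SplitPlan(**FAST_PLAN))


def test_too_few_samples_for_folds(rng):
    x = np.abs(rng.normal(size=(8, 2)))
    table = make_table(x, ["positive"] * 4 + ["negative"] * 4)
    with pytest.raises(ClassificationError, match="fewer"):
        train_eval_protocol(table, SplitPlan(random_seed=0))


# --- Mann-Whitney ----------------------------------------------------------


def test_mannwhitney_complete_separation():
    pos = list(np.arange(10) + 100.0)
    neg = list(np.arange(10) + 1.0)
    res = compare_norm_distributions(pos, neg)
    assert res.u_statistic == 100.0  # all pairwise comparisons won
    assert res.p_value < 1e-3
    assert res.significant


def test_mannwhitney_identical_lists_not_significant():
    vals = [1.0, 2.0, 3.0, 4.0]
    res = compare_norm_distributions(vals, vals)
    assert not res.significant


def test_mannwhitney_empty_input_rejected():
    with pytest.raises(ClassificationError):
        compare_norm_distributions([], [1.0])
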