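"""Metric arithmetic, ROC/AUC, cross-validation and the ablation harness."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from gazenest import evaluation
from gazenest.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    f1_from_precision_recall,
    format_report_table,
    metrics,
    relative_improvement,
    roc_auc,
)


# -- confusion --------------------------------------------------------------


def test_confusion_all_correct_and_all_positive():
    y = [1] * 5 + [0] * 5
    assert confusion(y, y) == ConfusionCounts(tp=5, fp=0, fn=0, tn=5)
    assert confusion(y, [1] * 10) == ConfusionCounts(tp=5, fp=5, fn=0, tn=0)


def test_confusion_matches_four_branch_loop_oracle(rng):
    y = rng.integers(0, 2, 200)
    p = rng.integers(0, 2, 200)
    c = confusion(y, p)
    tp = fp = fn = tn = 0
    for yi, pi in zip(y, p):
        if yi == 1 and pi == 1:
            tp += 1
        elif yi == 0 and pi == 1:
            fp += 1
        elif yi == 1 and pi == 0:
            fn += 1
        else:
            tn += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
    assert c.total == 200


def test_confusion_rejects_length_mismatch_and_nonbinary():
    with pytest.raises(ValueError):
        confusion([1, 0], [1])
    with pytest.raises(ValueError):
        confusion([1, 2], [1, 0])


# -- metrics ----------------------------------------------------------------


def test_perfect_counts_give_unit_metrics():
    m = metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
    assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1"))
    assert m["undefined"] == set()


def test_f1_is_harmonic_mean_of_rounded_pair():
    assert round(f1_from_precision_recall(0.87, 0.89), 2) == 0.88


def test_metrics_match_formula_oracle(rng):
    for _ in range(50):
        tp, fp, fn, tn = rng.integers(1, 50, size=4)
        m = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
        assert abs(m["accuracy"] - (tp + tn) / (tp + fp + fn + tn)) < 1e-12
        assert abs(m["precision"] - tp / (tp + fp)) < 1e-12
        assert abs(m["recall"] - tp / (tp + fn)) < 1e-12
        p, r = m["precision"], m["recall"]
        assert abs(m["f1"] - 2 * p * r / (p + r)) < 1e-12


def test_undefined_metrics_flagged_not_zeroed():
    m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
    assert "precision" in m["undefined"] and np.isnan(m["precision"])
    assert "f1" in m["undefined"]
    assert m["recall"] == 0.0  # defined: tp + fn > 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_metrics_invariant_under_subject_permutation(seed):
    r = np.random.default_rng(seed)
    y = r.integers(0, 2, 40)
    p = r.integers(0, 2, 40)
    perm = r.permutation(40)
    assert confusion(y, p) == confusion(y[perm], p[perm])


# -- ROC / AUC --------------------------------------------------------------


def test_perfectly_separated_scores_have_unit_auc():
    curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert curve.auc == 1.0
    assert curve.fpr[0] == 0 and curve.tpr[0] == 0
    assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1


def test_constant_scores_give_diagonal_auc():
    assert roc_auc([0.5] * 10, [1, 0] * 5).auc == 0.5


def test_auc_equals_normalized_mann_whitney(rng):
    for _ in range(100):
        n1, n0 = int(rng.integers(3, 20)), int(rng.integers(3, 20))
        scores = np.round(rng.normal(size=n1 + n0), 1)  # rounding forces ties
        y = np.array([1] * n1 + [0] * n0)
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert abs(roc_auc(scores, y).auc - u / (n1 * n0)) < 1e-12


def test_roc_curve_monotone_nondecreasing(rng):
    scores = rng.normal(size=30)
    y = rng.integers(0, 2, 30)
    y[:2] = [0, 1]
    curve = roc_auc(scores, y)
    assert np.all(np.diff(curve.fpr) >= 0)
    assert np.all(np.diff(curve.tpr) >= 0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_auc_negation_symmetry(seed):
    r = np.random.default_rng(seed)
    scores = r.normal(size=20)
    y = np.array([1] * 10 + [0] * 10)
    assert abs(roc_auc(scores, y).auc - (1 - roc_auc(-scores, y).auc)) < 1e-12


def test_one_class_roc_is_degenerate():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# -- relative improvement ----------------------------------------------------


def test_relative_improvement_worked_examples():
    assert relative_improvement(0.80, 0.87) == 8.75
    assert relative_improvement(0.78, 0.85) == 8.97
    assert relative_improvement(0.42, 0.42) == 0.00
    with pytest.raises(ValueError):
        relative_improvement(0.0, 0.5)


# -- cross-validation --------------------------------------------------------


class _CentroidModel:
    """Cheap deterministic stand-in: scores by distance to class centroids."""

    def fit(self, views):
        X = np.stack([v.maps.mean(axis=(0, 1)) for v in views]).reshape(len(views), -1)
        y = np.array([v.label for v in views])
        self.c0 = X[y == 0].mean(axis=0)
        self.c1 = X[y == 1].mean(axis=0)
        return self

    def predict_proba(self, views):
        X = np.stack([v.maps.mean(axis=(0, 1)) for v in views]).reshape(len(views), -1)
        d0 = np.linalg.norm(X - self.c0, axis=1)
        d1 = np.linalg.norm(X - self.c1, axis=1)
        return 1.0 / (1.0 + np.exp(d1 - d0))

    def predict(self, views):
        return (self.predict_proba(views) >= 0.5).astype(int)


def _centroid_factory(train_views, fold_seed):
    return _CentroidModel().fit(train_views)


def test_stratified_folds_balanced_and_reproducible(delta1_views):
    rep1 = cross_validate(delta1_views, _centroid_factory, k=4, seed=3)
    rep2 = cross_validate(delta1_views, _centroid_factory, k=4, seed=3)
    assert [f["n_test"] for f in rep1.fold_metrics] == [f["n_test"] for f in rep2.fold_metrics]
    for a, b in zip(rep1.fold_metrics, rep2.fold_metrics):
        assert a["accuracy"] == b["accuracy"] and a["auc"] == b["auc"]
    sizes = [f["n_test"] for f in rep1.fold_metrics]
    assert max(sizes) - min(sizes) <= 2  # 60 subjects over 4 folds: 15 each
    assert sum(sizes) == len(delta1_views)


def test_centroid_model_separates_delta1_cohort(delta1_views):
    rep = cross_validate(delta1_views, _centroid_factory, k=4, seed=3)
    assert rep.mean("accuracy") >= 0.9  # designed group contrast


def test_label_permutation_destroys_signal(delta1_views, rng):
    """With labels shuffled, the same pipeline scores at chance."""
    perm = rng.permutation(len(delta1_views))
    labels = [delta1_views[i].label for i in perm]
    shuffled = [
        type(v)(subject_id=v.subject_id, label=lab, maps=v.maps)
        for v, lab in zip(delta1_views, labels)
    ]
    rep = cross_validate(shuffled, _centroid_factory, k=4, seed=3)
    assert 0.35 <= rep.mean("accuracy") <= 0.65


def test_too_few_subjects_per_class_rejected(tiny_views):
    with pytest.raises(ValueError):
        cross_validate(tiny_views, _centroid_factory, k=5, seed=0)


# -- ablation harness --------------------------------------------------------


def test_ablation_suite_rows_hashes_and_consistency(tiny_views):
    from dataclasses import replace

    from gazenest.nested_ae import TrainConfig

    base = TrainConfig(epochs=2)
    reports = evaluation.ablation_suite(tiny_views, seed=1, base_config=base)
    assert len(reports) == 8
    hashes = [r.config_hash for r in reports]
    assert len(set(hashes)) == 8
    # the full-model row equals an independent run with the same switches
    full = next(r for r in reports if r.model == "full_model")
    cfg = replace(base, use_inner_decoder=True, use_outer_decoder=True, use_fusion_layer=True)
    indep = cross_validate(
        tiny_views, evaluation.make_nested_ae_factory(cfg), k=4, seed=1, model_name="full_model"
    )
    for a, b in zip(full.fold_metrics, indep.fold_metrics):
        assert a["accuracy"] == b["accuracy"]
        assert a["auc"] == b["auc"]


def test_report_table_renders_all_rows(tiny_views):
    rep = cross_validate(tiny_views, _centroid_factory, k=4, seed=0, model_name="centroid")
    table = format_report_table([rep])
    assert "centroid" in table
    assert "Mean accuracy" in table
    # rendered values equal the summary's rounded strings
    s = rep.summary()
    assert s["accuracy"] in table
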