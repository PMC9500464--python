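"""Metrics, ROC/AUC, stratified four-fold cross-validation and ablations.

PwAD is the positive class. Metrics are the standard confusion-matrix
quantities: accuracy (TP+TN)/N, precision TP/(TP+FP), recall TP/(TP+FN)
and F1 = 2PR/(P+R). Reports aggregate per-fold values as mean +/- sample
standard deviation (ddof=1) rounded half-even to two decimals -- the layout
of the comparison tables this mirrors. Metrics with zero denominators are
reported as NaN with an explicit flag, never silently zeroed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .heatmap import SubjectViews
from .nested_ae import NestedAutoencoderClassifier, TrainConfig

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "MetricsReport",
    "confusion",
    "metrics",
    "f1_from_precision_recall",
    "roc_auc",
    "cross_validate",
    "relative_improvement",
    "ablation_suite",
    "ABLATION_CONFIGS",
    "make_nested_ae_factory",
    "format_report_table",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class RocCurve:
    """Threshold-sweep ROC: (FPR, TPR) points plus trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Exhaustive confusion counts with PwAD (label 1) positive."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict:
    """Accuracy/precision/recall/F1 from counts; undefined ratios flagged.

    Returns the four metrics plus an ``undefined`` set naming any metric
    whose denominator was zero (its value is NaN).
    """
    undefined: set[str] = set()
    acc = (counts.tp + counts.tn) / counts.total if counts.total else np.nan
    if counts.total == 0:
        undefined.add("accuracy")
    if counts.tp + counts.fp:
        prec = counts.tp / (counts.tp + counts.fp)
    else:
        prec = np.nan
        undefined.add("precision")
    if counts.tp + counts.fn:
        rec = counts.tp / (counts.tp + counts.fn)
    else:
        rec = np.nan
        undefined.add("recall")
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        f1 = np.nan
        undefined.add("f1")
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return {
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "undefined": undefined,
    }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); the F1 a printed (P, R) pair implies."""
    if precision + recall == 0:
        raise ValueError("F1 undefined for precision + recall == 0")
    return 2.0 * precision * recall / (precision + recall)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC by descending threshold sweep over unique scores; trapezoid AUC.

    Tied scores enter together, which makes the AUC equal the normalized
    Mann-Whitney U statistic (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one subject in each class")
    uniq = np.unique(s)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in uniq:
        sel = s >= t
        tpr.append(((y == 1) & sel).sum() / n_pos)
        fpr.append(((y == 0) & sel).sum() / n_neg)
    fpr_a, tpr_a = np.array(fpr), np.array(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    thresholds = np.concatenate(([np.inf], uniq))
    return RocCurve(fpr=fpr_a, tpr=tpr_a, thresholds=thresholds, auc=auc)


def relative_improvement(baseline: float, improved: float) -> float:
    """Percent change 100*(improved - baseline)/baseline, 2 decimals."""
    if baseline == 0:
        raise ValueError("relative improvement undefined for baseline == 0")
    return round(100.0 * (improved - baseline) / baseline, 2)


# -- cross-validation -------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold metrics with table-style mean +/- std aggregation."""

    model: str
    config_hash: str
    fold_metrics: list[dict] = field(default_factory=list)

    def values(self, name: str) -> np.ndarray:
        return np.array([fm[name] for fm in self.fold_metrics], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.values(name)))

    def std(self, name: str) -> float:
        v = self.values(name)
        return float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0

    def summary(self) -> dict:
        """Rounded (half-even, 2 dp) mean +/- std per metric."""
        out = {"model": self.model, "config_hash": self.config_hash}
        for name in METRIC_NAMES:
            out[name] = f"{round(self.mean(name), 2):.2f} ± {round(self.std(name), 2):.2f}"
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "config_hash": self.config_hash,
            "fold_metrics": [
                {k: (sorted(v) if isinstance(v, set) else v) for k, v in fm.items()}
                for fm in self.fold_metrics
            ],
            "mean": {n: self.mean(n) for n in METRIC_NAMES},
            "std": {n: self.std(n) for n in METRIC_NAMES},
        }


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 100003 + fold * 7919 + 1) % (2**31)


def cross_validate(
    views: list[SubjectViews],
    model_factory: Callable[[list[SubjectViews], int], object],
    k: int = 4,
    seed: int = 0,
    model_name: str = "model",
    config_hash: str = "",
) -> MetricsReport:
    """Subject-level stratified k-fold CV, training from scratch per fold.

    ``model_factory(train_views, fold_seed)`` must return a fitted object
    with ``predict_proba(views) -> scores``; scores are thresholded at 0.5
    for probabilistic models (see factory) via ``predict`` when available,
    else at 0.5.
    """
    y = np.array([v.label for v in views])
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    report = MetricsReport(model=model_name, config_hash=config_hash)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_views = [views[i] for i in tr]
        test_views = [views[i] for i in te]
        model = model_factory(train_views, _fold_seed(seed, fold))
        scores = np.asarray(model.predict_proba(test_views), dtype=float)
        if hasattr(model, "predict"):
            preds = np.asarray(model.predict(test_views)).astype(int)
        else:
            preds = (scores >= 0.5).astype(int)
        fold_y = y[te]
        m = metrics(confusion(fold_y, preds))
        m["auc"] = roc_auc(scores, fold_y).auc
        m["n_test"] = len(te)
        report.fold_metrics.append(m)
    return report


def make_nested_ae_factory(config: TrainConfig) -> Callable:
    """Factory adapting the nested-autoencoder model to ``cross_validate``."""

    def factory(train_views: list[SubjectViews], fold_seed: int):
        cfg = replace(config, seed=fold_seed, n_views=train_views[0].maps.shape[0])
        model = NestedAutoencoderClassifier(cfg)
        model.fit(train_views)
        return model

    return factory


# -- ablation harness -------------------------------------------------------

# Switch sets mirroring the two ablation tables: progressive module build-up
# (encoders only -> +inner decoder -> +outer decoder -> full), then the
# component-replacement grid (difference maps / inner AE x shallow CNN /
# outer AE). The last grid cell repeats the full configuration under its
# grid name.
ABLATION_CONFIGS: list[tuple[str, dict]] = [
    ("encoders_only", dict(use_inner_decoder=False, use_outer_decoder=False, use_fusion_layer=False)),
    ("encoders+inner_decoder", dict(use_inner_decoder=True, use_outer_decoder=False, use_fusion_layer=False)),
    ("encoders+outer_decoder", dict(use_inner_decoder=False, use_outer_decoder=True, use_fusion_layer=False)),
    ("full_model", dict(use_inner_decoder=True, use_outer_decoder=True, use_fusion_layer=True)),
    ("diffmap+cnn", dict(inner_mode="difference_map", outer_mode="shallow_cnn")),
    ("diffmap+outer_ae", dict(inner_mode="difference_map", outer_mode="autoencoder")),
    ("inner_ae+cnn", dict(inner_mode="autoencoder", outer_mode="shallow_cnn")),
    ("inner_ae+outer_ae", dict(inner_mode="autoencoder", outer_mode="autoencoder")),
]


def config_hash(name: str, config: TrainConfig) -> str:
    from dataclasses import asdict

    payload = json.dumps({"name": name, **asdict(config)}, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def ablation_suite(
    views: list[SubjectViews],
    seed: int = 0,
    base_config: TrainConfig | None = None,
    k: int = 4,
) -> list[MetricsReport]:
    """Run the eight ablation configurations under identical folds."""
    base = base_config or TrainConfig()
    reports = []
    for name, overrides in ABLATION_CONFIGS:
        cfg = replace(base, **overrides)
        reports.append(
            cross_validate(
                views,
                make_nested_ae_factory(cfg),
                k=k,
                seed=seed,
                model_name=name,
                config_hash=config_hash(name, cfg),
            )
        )
    return reports


def format_report_table(reports: list[MetricsReport]) -> str:
    """Plain-text table with the comparison-table column layout."""
    header = ["Model", "Mean precision", "Mean recall", "Mean F1-score", "Mean accuracy", "Mean AUC"]
    rows = [header]
    for rep in reports:
        s = rep.summary()
        rows.append([rep.model, s["precision"], s["recall"], s["f1"], s["accuracy"], s["auc"]])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = []
    for i, row in enumerate(rows):
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip())
        if i == 0:
            lines.append("  ".join("-" * w for w in widths))
    return "\n".join(lines)
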