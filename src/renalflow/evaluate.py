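"""Cross-validation orchestration, classification metrics, fold aggregation,
prediction-consistency auditing, and final test-set evaluation.

The positive class is ARAS throughout; specificity is computed on the
control (normal) class. Undefined ratios (zero denominators) are reported
as ``None``, never silently as 0.

Fold statistics are aggregated as mean, sample SD (denominator k-1),
variance = SD², and a normal-approximation 95% confidence interval
mean ± 1.96·SD/√k.

The consistency audit scores every fold model on the held-out test set —
the only signal set common to all five models, since each training signal
is validated exactly once during CV — and flags each signal as unanimous
when all fold models agree on its class.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import cnn as cnn_mod
from .cnn import CNNConfig, TrainConfig, TrainedModel
from .dataset import Datasheet, SplitAssignment
from .errors import ConfigurationError, DataError

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1", "roc_auc")
Z_95 = 1.96


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with ARAS as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Threshold metrics; ``None`` marks an undefined (0/0) ratio."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ROCCurve:
    """ROC points over grouped score thresholds, plus trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        f, t = np.asarray(self.fpr, float), np.asarray(self.tpr, float)
        if np.any(np.diff(f) < 0) or np.any(np.diff(t) < 0):
            raise DataError("ROC coordinates must be nondecreasing")
        object.__setattr__(self, "fpr", f)
        object.__setattr__(self, "tpr", t)


@dataclass(frozen=True)
class MetricSummary:
    """Across-fold aggregation of one metric."""

    metric: str
    mean: float
    sd: float
    variance: float
    ci_low: float
    ci_high: float


@dataclass
class FoldResult:
    """One fold's validation metrics and predictions."""

    fold_index: int
    metrics: dict  # metric name -> value (None if undefined)
    val_ids: list[str]
    val_predictions: np.ndarray
    val_scores: np.ndarray
    test_predictions: np.ndarray
    test_scores: np.ndarray


@dataclass
class ConsistencyReport:
    """Cross-fold prediction agreement on a common signal set."""

    signal_ids: list[str]
    predictions: np.ndarray  # (k_folds, n_signals) predicted labels
    agreement: np.ndarray  # (n_signals,) bool, True iff unanimous
    unanimous_fraction: float


def confusion(labels, predictions) -> ConfusionMatrix:
    """Exact confusion counts for binary labels/predictions."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise DataError(f"labels {y.shape} and predictions {p.shape} length mismatch")
    if y.size == 0:
        raise DataError("empty inputs")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Accuracy, precision, recall, specificity, F1 from confusion counts."""
    if cm.total == 0:
        raise DataError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(cm.tp, cm.tp + cm.fp)
    recall = ratio(cm.tp, cm.tp + cm.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        precision=precision,
        recall=recall,
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        f1=f1,
    )


def roc_auc(labels, scores) -> ROCCurve:
    """ROC curve by threshold sweep with tied scores grouped; trapezoidal AUC.

    With this tie convention the AUC equals the Mann–Whitney U statistic
    (half credit for ties) divided by n₁·n₀.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise DataError("labels and scores length mismatch")
    if np.unique(y).size < 2:
        raise DataError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def summarize_folds(values, metric: str = "", z: float = Z_95) -> MetricSummary:
    """Aggregate k fold values: mean, sample SD, variance, mean ± z·SD/√k."""
    v = np.asarray([x for x in values], dtype=float)
    if v.size < 2:
        raise ConfigurationError("need at least 2 fold values to summarize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = z * sd / np.sqrt(v.size)
    return MetricSummary(
        metric=metric,
        mean=mean,
        sd=sd,
        variance=sd**2,
        ci_low=mean - half,
        ci_high=mean + half,
    )


def summarize_from_moments(mean: float, sd: float, k: int, metric: str = "") -> MetricSummary:
    """Aggregate from printed (mean, SD) pairs — same formulas as
    :func:`summarize_folds` without access to the raw fold values."""
    half = Z_95 * sd / np.sqrt(k)
    return MetricSummary(
        metric=metric, mean=mean, sd=sd, variance=sd**2, ci_low=mean - half, ci_high=mean + half
    )


def consistency_report(models: list[TrainedModel], signals: np.ndarray, signal_ids) -> ConsistencyReport:
    """Score each model on a common signal set and flag unanimous signals."""
    preds = np.stack([m.predict(signals) for m in models])
    agreement = np.all(preds == preds[0], axis=0)
    return ConsistencyReport(
        signal_ids=list(signal_ids),
        predictions=preds,
        agreement=agreement,
        unanimous_fraction=float(agreement.mean()),
    )


def _fold_seeds(master_seed: int, k: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    return [int(s) for s in rng.integers(0, 2**31, size=k)]


def _evaluate_predictions(y, preds, scores) -> dict:
    m = metrics(confusion(y, preds)).as_dict()
    m["roc_auc"] = roc_auc(y, scores).auc
    return m


@dataclass
class CVResult:
    fold_results: list[FoldResult]
    summaries: dict  # metric -> MetricSummary
    consistency: ConsistencyReport
    test_checksum: str


def run_cross_validation(
    ds: Datasheet,
    split: SplitAssignment,
    folds: list[list[str]],
    cnn_cfg: CNNConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> CVResult:
    """k-fold cross-validation on the training portion of the split.

    For each fold a fresh model is trained on the other folds' signals and
    evaluated on the fold's validation signals; every training signal is
    therefore validated exactly once. All fold models additionally score
    the held-out test set to populate the consistency report — the test
    set itself never influences training. Per-fold seeds derive
    deterministically from the master training seed.
    """
    cnn_cfg = cnn_cfg or CNNConfig()
    train_cfg = train_cfg or TrainConfig()
    train_patients = set(split.train_patients)
    covered = [p for fold in folds for p in fold]
    if sorted(covered) != sorted(train_patients):
        raise DataError("folds do not partition the training patients")

    test_ds = ds.subset_by_signal_ids(split.test_ids)
    test_checksum = test_ds.checksum()
    x_test, y_test = test_ds.velocities(), test_ds.labels01()

    seeds = _fold_seeds(train_cfg.seed, len(folds))
    fold_results: list[FoldResult] = []
    models: list[TrainedModel] = []
    for i, fold_patients in enumerate(folds):
        val_pats = set(fold_patients)
        fit_pats = [p for fold in folds for p in fold if p not in val_pats]
        fit_ds = ds.subset_by_patients(fit_pats)
        val_ds = ds.subset_by_patients(val_pats)
        tcfg_i = TrainConfig(
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            epochs=train_cfg.epochs,
            seed=seeds[i],
        )
        tm = cnn_mod.fit(fit_ds.velocities(), fit_ds.labels01(), cnn_cfg, tcfg_i)
        models.append(tm)
        val_scores = tm.score_positive(val_ds.velocities())
        val_preds = tm.predict(val_ds.velocities())
        test_scores = tm.score_positive(x_test)
        test_preds = tm.predict(x_test)
        fold_results.append(
            FoldResult(
                fold_index=i,
                metrics=_evaluate_predictions(val_ds.labels01(), val_preds, val_scores),
                val_ids=val_ds.signal_ids(),
                val_predictions=val_preds,
                val_scores=val_scores,
                test_predictions=test_preds,
                test_scores=test_scores,
            )
        )

    summaries = {}
    for name in METRIC_NAMES:
        vals = [fr.metrics[name] for fr in fold_results]
        if any(v is None for v in vals):
            continue  # undefined in some fold; cannot aggregate
        summaries[name] = summarize_folds(vals, metric=name)

    consistency = consistency_report(models, x_test, test_ds.signal_ids())
    if ds.subset_by_signal_ids(split.test_ids).checksum() != test_checksum:
        raise DataError("test rows changed during cross-validation")
    return CVResult(
        fold_results=fold_results,
        summaries=summaries,
        consistency=consistency,
        test_checksum=test_checksum,
    )


@dataclass
class FinalReport:
    metrics: dict
    confusion: ConfusionMatrix
    roc: ROCCurve
    test_ids: list[str]
    predictions: np.ndarray
    scores: np.ndarray
    model: TrainedModel
    test_checksum: str

    def as_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "confusion": asdict(self.confusion),
            "roc": {
                "fpr": self.roc.fpr.tolist(),
                "tpr": self.roc.tpr.tolist(),
                "auc": self.roc.auc,
            },
            "test_ids": self.test_ids,
            "predictions": self.predictions.tolist(),
            "test_checksum": self.test_checksum,
            "seed": self.model.train_config.seed,
        }


def final_evaluation(
    ds: Datasheet,
    split: SplitAssignment,
    cnn_cfg: CNNConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> FinalReport:
    """Train one model on the full training portion; score the untouched
    test set exactly once."""
    cnn_cfg = cnn_cfg or CNNConfig()
    train_cfg = train_cfg or TrainConfig()
    train_ds = ds.subset_by_signal_ids(split.train_ids)
    test_ds = ds.subset_by_signal_ids(split.test_ids)
    checksum = test_ds.checksum()
    tm = cnn_mod.fit(train_ds.velocities(), train_ds.labels01(), cnn_cfg, train_cfg)
    x_test, y_test = test_ds.velocities(), test_ds.labels01()
    preds = tm.predict(x_test)
    scores = tm.score_positive(x_test)
    cm = confusion(y_test, preds)
    roc = roc_auc(y_test, scores)
    final_metrics = metrics(cm).as_dict()
    final_metrics["roc_auc"] = roc.auc
    return FinalReport(
        metrics=final_metrics,
        confusion=cm,
        roc=roc,
        test_ids=test_ds.signal_ids(),
        predictions=preds,
        scores=scores,
        model=tm,
        test_checksum=checksum,
    )


# ---------------------------------------------------------------------------
# report serialization and plots
# ---------------------------------------------------------------------------


def config_hash(*configs) -> str:
    """Stable short hash of one or more dataclass configs."""
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def summaries_to_markdown(summaries: dict) -> str:
    lines = [
        "| Metric | Mean | SD | Variance | 95% CI |",
        "| --- | --- | --- | --- | --- |",
    ]
    for name, s in summaries.items():
        lines.append(
            f"| {name} | {s.mean:.4f} | {s.sd:.4f} | {s.variance:.4f} | "
            f"{s.ci_low:.4f}–{s.ci_high:.4f} |"
        )
    return "\n".join(lines)


def plot_roc(roc: ROCCurve, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title("ROC — test set")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.array([[cm.tn, cm.fp], [cm.fn, cm.tp]])
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["normal", "ARAS"])
    ax.set_yticks([0, 1], ["normal", "ARAS"])
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    ax.set_title("Confusion matrix — test set")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
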