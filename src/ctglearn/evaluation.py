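"""Classifier evaluation: repeated stratified k-fold cross-validation,
confusion metrics, F-measure, rank-based AUC and ROC export.

The cross-validation error is the fold-size-weighted mean of the fold
mean squared errors on 0/1 labels — for hard predictions this equals the
misclassification rate, so an all-majority classifier on a 46/552 cohort
scores the 8.33% case base rate and 50% on a balanced 300/300 design.
AUC is the Mann-Whitney rank statistic
A = (S0 - n1(n1+1)/2) / (n1 n2) with midranks for ties, which equals the
area under the ROC curve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import LabelledDataset
from .models import make_model
from .records import ValidationError

__all__ = [
    "CvConfig",
    "EvaluationReport",
    "cross_validate",
    "confusion_metrics",
    "auc_rank",
    "roc_points",
    "roc_export",
]


@dataclass(frozen=True)
class CvConfig:
    k_folds: int = 5
    repetitions: int = 1           # 1 or 30 in the classical design
    stratified: bool = True
    seed: int = 0
    pooled: bool = False           # pool held-out predictions instead of fold-averaging

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")


@dataclass
class EvaluationReport:
    model: str
    n: int
    folds: int
    repetitions: int
    seed: int
    sensitivity: float | None
    specificity: float | None
    f_measure: float
    auc: float
    cv_error: float
    per_fold: list = field(default_factory=list)
    roc_points: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("per_fold")
        d.pop("roc_points")
        return d


def confusion_metrics(labels, predictions):
    """(sensitivity, specificity, f_measure) for binary labels (1 = case).

    Sensitivity is None (missing, not 0) when there are no positive
    labels, specificity likewise without negatives; the F-measure is 0
    when precision + recall is undefined or zero.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.size == 0:
        raise ValidationError("empty label vector")
    tp = int(np.sum((y == 1) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = sens if sens is not None else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return sens, spec, f


def auc_rank(scores_case, scores_control) -> float:
    """Rank-sum AUC with midranks for ties."""
    a = np.asarray(scores_case, dtype=float)
    b = np.asarray(scores_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both score groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    s0 = float(np.sum(ranks[: a.size]))
    n1, n2 = a.size, b.size
    return (s0 - 0.5 * n1 * (n1 + 1)) / (n1 * n2)


def roc_points(labels, scores):
    """ROC staircase from thresholds at every distinct score, as
    (threshold, fpr, tpr) triples from (inf, 0, 0) upward; fpr and tpr
    are monotone non-decreasing."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], int)
    cut_idx = np.concatenate([distinct, [s_sorted.size - 1]])
    tps = np.cumsum(y_sorted == 1)[cut_idx]
    fps = np.cumsum(y_sorted == 0)[cut_idx]
    n_pos = max(int(np.sum(y == 1)), 1)
    n_neg = max(int(np.sum(y == 0)), 1)
    pts = [(float("inf"), 0.0, 0.0)]
    for i, tp, fp in zip(cut_idx, tps, fps):
        pts.append((float(s_sorted[i]), float(fp / n_neg), float(tp / n_pos)))
    return pts


def roc_export(labels, scores, path) -> list:
    """Write the ROC staircase as CSV ``threshold,fpr,tpr``; returns the points."""
    pts = roc_points(labels, scores)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "fpr", "tpr"])
        for thr, fpr, tpr in pts:
            writer.writerow([repr(thr) if np.isfinite(thr) else "inf", repr(fpr), repr(tpr)])
    return pts


def _fold_splitter(cfg: CvConfig, rep_seed: int):
    cls = StratifiedKFold if cfg.stratified else KFold
    return cls(n_splits=cfg.k_folds, shuffle=True, random_state=rep_seed)


def cross_validate(
    data: LabelledDataset,
    model_spec,
    cfg: CvConfig | None = None,
    resampler=None,
) -> EvaluationReport:
    """Repeated k-fold cross-validation of one model.

    ``model_spec`` is a model kind name ('flda' | 'rf' | 'dl'), a
    ``(kind, params_dict)`` pair, or a callable ``factory(seed) -> model``
    for custom models obeying the fit/predict contract (e.g. a constant
    baseline classifier). ``resampler``, if given, is applied to
    each training fold only (e.g. a SMOTE closure) — the statistically
    sound alternative to resampling before CV. Metrics are averaged over
    folds then repetitions (or pooled over held-out predictions when
    ``cfg.pooled``). Deterministic given ``cfg.seed``.
    """
    cfg = cfg or CvConfig()
    cfg.validate()
    if callable(model_spec) and not isinstance(model_spec, str):
        factory = model_spec
        kind = getattr(model_spec, "__name__", "custom")
    else:
        kind, params = (model_spec, {}) if isinstance(model_spec, str) else model_spec
        factory = lambda seed: make_model(kind, seed=seed, **params)  # noqa: E731
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required for cross-validation")

    rep_reports = []
    all_scores, all_labels = [], []
    per_fold = []
    for rep in range(cfg.repetitions):
        rep_seed = cfg.seed + rep
        fold_stats = []
        for fold_no, (train_idx, test_idx) in enumerate(
            _fold_splitter(cfg, rep_seed).split(data.features, y)
        ):
            train = data.take(train_idx)
            if len(np.unique(train.labels)) < 2:
                raise ValidationError(
                    "a training fold lost a class; enable stratified folds"
                )
            if resampler is not None:
                train = resampler(train, rep_seed * 1000 + fold_no)
            model = factory(rep_seed * 1000 + fold_no)
            model.fit(train)
            pred = model.predict(data.features[test_idx])
            y_test = y[test_idx]
            mse = float(np.mean((y_test - pred.label) ** 2))
            sens, spec, f = confusion_metrics(y_test, pred.label)
            auc = (
                auc_rank(pred.score[y_test == 1], pred.score[y_test == 0])
                if 0 < y_test.sum() < y_test.size
                else None
            )
            fold_stats.append(
                dict(rep=rep, fold=fold_no, n=int(y_test.size), mse=mse,
                     sensitivity=sens, specificity=spec, f_measure=f, auc=auc)
            )
            all_scores.append(pred.score)
            all_labels.append(y_test)
        per_fold.extend(fold_stats)
        n = int(y.size)
        cv_error = sum(fs["mse"] * fs["n"] / n for fs in fold_stats)
        rep_reports.append(
            dict(
                cv_error=cv_error,
                sensitivity=_mean_or_none([fs["sensitivity"] for fs in fold_stats]),
                specificity=_mean_or_none([fs["specificity"] for fs in fold_stats]),
                f_measure=float(np.mean([fs["f_measure"] for fs in fold_stats])),
                auc=_mean_or_none([fs["auc"] for fs in fold_stats]),
            )
        )

    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    if cfg.pooled:
        sens, spec, f = confusion_metrics(labels, (scores > 0.5).astype(int))
        auc = auc_rank(scores[labels == 1], scores[labels == 0])
        cv_error = float(np.mean([r["cv_error"] for r in rep_reports]))
    else:
        sens = _mean_or_none([r["sensitivity"] for r in rep_reports])
        spec = _mean_or_none([r["specificity"] for r in rep_reports])
        f = float(np.mean([r["f_measure"] for r in rep_reports]))
        auc = _mean_or_none([r["auc"] for r in rep_reports])
        cv_error = float(np.mean([r["cv_error"] for r in rep_reports]))
    return EvaluationReport(
        model=kind,
        n=int(y.size),
        folds=cfg.k_folds,
        repetitions=cfg.repetitions,
        seed=cfg.seed,
        sensitivity=sens,
        specificity=spec,
        f_measure=f,
        auc=auc if auc is not None else float("nan"),
        cv_error=cv_error,
        per_fold=per_fold,
        roc_points=roc_points(labels, scores),
    )


def _mean_or_none(values):
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None
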