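"""Binary-classifier evaluation: confusion metrics, AUC, cross-validation.

The five confusion-matrix metrics follow the usual definitions with
"positive" = interacting:

    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Recall      = TP / (TP + FN)          (aliased: sensitivity)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators: MCC returns 0 when any factor under the
radical is 0 (standard convention); recall/specificity/precision
return 0 with a warning.  AUC is the Mann-Whitney rank statistic
(ties count 1/2).  Raw confusion counts are always carried in the
report so any alternative convention can be recomputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from ppiwave.exceptions import InvalidInputError, UndefinedAUCError
from ppiwave.model import ModelConfig, YTypeModel, build_model
from ppiwave.pairs import PairFeature, augment_forward_backward, pair_matrix


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The five confusion metrics plus AUC and the raw counts.

    ``recall`` equals sensitivity (one field, aliased property).
    """

    accuracy: float
    recall: float
    specificity: float
    precision: float
    mcc: float
    counts: ConfusionCounts
    auc: float | None = None
    per_fold: tuple = field(default=())

    @property
    def sensitivity(self) -> float:
        return self.recall

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "specificity": self.specificity,
            "precision": self.precision,
            "mcc": self.mcc,
            "TP": self.counts.TP, "TN": self.counts.TN,
            "FP": self.counts.FP, "FN": self.counts.FN,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(predictions, labels) -> ConfusionCounts:
    """Tally a confusion matrix; 1 = interacting (positive), 0 = not."""
    p = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape or p.ndim != 1:
        raise InvalidInputError(
            f"predictions {p.shape} and labels {y.shape} must be equal-length 1-D"
        )
    if p.size == 0:
        raise InvalidInputError("empty prediction list")
    return ConfusionCounts(
        TP=int(np.sum((p == 1) & (y == 1))),
        TN=int(np.sum((p == 0) & (y == 0))),
        FP=int(np.sum((p == 1) & (y == 0))),
        FN=int(np.sum((p == 0) & (y == 1))),
    )


def _ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} denominator is 0; returning 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five confusion metrics of one evaluated split (AUC separate)."""
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    rad = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if rad == 0 else (tp * tn - fp * fn) / math.sqrt(rad)
    return MetricsReport(
        accuracy=_ratio(tp + tn, c.total, "accuracy"),
        recall=_ratio(tp, tp + fn, "recall"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        precision=_ratio(tp, tp + fp, "precision"),
        mcc=mcc,
        counts=c,
    )


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Tied scores contribute 1/2.  Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidInputError("scores and labels must be equal-length 1-D")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: only one class present")
    ranks = rankdata(s)  # average ranks handle ties
    r_pos = ranks[y == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def kfold_split(n: int, k: int = 5, *, seed: int = 0, labels=None,
                stratify: bool = True) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive (train, test) index partitions.

    Stratified by label by default (pass ``labels``); deterministic per
    seed; fold sizes differ by at most 1.
    """
    if n < k:
        raise InvalidInputError(f"cannot split {n} records into {k} folds")
    idx = np.arange(n)
    if stratify and labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        y = np.asarray(labels).astype(int)
        return [(tr, te) for tr, te in splitter.split(idx, y)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(idx)]


def evaluate_pairs(model: YTypeModel, pairs: list[PairFeature]) -> MetricsReport:
    """Score a split and derive the full metrics report (with AUC)."""
    X, Y = pair_matrix(pairs)
    scores = model.predict_proba(X)
    preds = (scores > 0.5).astype(int)
    truth = Y[:, 0].astype(int)  # one-hot column 0 = interacting
    report = metrics(confusion(preds, truth))
    try:
        a = auc(scores, truth)
    except UndefinedAUCError:
        a = None
    return MetricsReport(**{**report.__dict__, "auc": a})


def run_cv(
    pairs: list[PairFeature],
    config: ModelConfig,
    *,
    k: int = 5,
    seed: int = 0,
    epochs: int | None = None,
    holdout: list[PairFeature] | None = None,
):
    """Stratified k-fold cross-validation of the Y-type classifier.

    Per fold: the training portion is forward/backward augmented (the
    test portion never is), a fresh model is trained, and the fold's
    test portion is scored.  The best model is the one with the highest
    fold accuracy (ties: lowest fold index); it is optionally evaluated
    once on a hold-out split.

    Returns ``(fold_reports, best_model, holdout_report)``.
    """
    labels = [1 if p.interacting else 0 for p in pairs]
    folds = kfold_split(len(pairs), k, seed=seed, labels=labels)
    reports: list[MetricsReport] = []
    models: list[YTypeModel] = []
    for fold_i, (tr, te) in enumerate(folds):
        train_split = [pairs[i] for i in tr]
        test_split = [
            PairFeature(values=pairs[i].values, label=pairs[i].label,
                        id_a=pairs[i].id_a, id_b=pairs[i].id_b,
                        is_training=False)
            for i in te
        ]
        augmented = augment_forward_backward(train_split)
        model = build_model(config, seed=seed + fold_i)
        model.train(augmented, epochs=epochs)
        reports.append(evaluate_pairs(model, test_split))
        models.append(model)
    best_i = int(np.argmax([r.accuracy for r in reports]))  # ties: lowest index
    best = models[best_i]
    holdout_report = None
    if holdout is not None:
        holdout_report = evaluate_pairs(best, holdout)
    return reports, best, holdout_report
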