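"""Evaluation: confusion-matrix metrics, ROC/AUC, stratified k-fold
cross-validation, and nested CV for hyperparameter choice.

Abnormal is the positive class (label 1).  The metrics are

    accuracy    = (TP + TN) / n
    sensitivity = TP / (TP + FN)      (recall, TPR)
    specificity = TN / (TN + FP)      (TNR)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

Zero-denominator ratios are reported as 0 and flagged in ``undefined``
rather than raising, so pooled CV never crashes on a degenerate fold.
AUC is the Mann-Whitney probability P(score_pos > score_neg) + 1/2
P(tie), computed with midranks; it equals the area under the empirical
ROC curve and is invariant under strictly increasing score transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifiers import make_classifier
from .dataset import LabeledDataset
from .errors import ParameterError, StratificationError, UndefinedMetricError


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float | None
    confusion: ConfusionCounts
    undefined: set[str] = field(default_factory=set)
    per_fold: list[dict] = field(default_factory=list)


def metrics(c: ConfusionCounts) -> dict:
    """All confusion-derived metrics; undefined ratios -> 0 with a flag."""
    if c.n == 0:
        raise ParameterError("cannot evaluate an empty confusion matrix")
    undefined: set[str] = set()

    def _ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    f1 = _ratio(2 * prec * sens, prec + sens, "f1")
    return {
        "accuracy": (c.tp + c.tn) / c.n,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "undefined": undefined,
    }


def roc_auc(scores, y) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _resolve_model(model) -> Callable[[], object]:
    if isinstance(model, str):
        return lambda: make_classifier(model)
    if callable(model) and not hasattr(model, "fit"):
        return model
    if hasattr(model, "clone"):
        return model.clone
    raise ParameterError("model must be a kind name, a factory, or a clonable classifier")


def _stratified_folds(y, folds: int, rng_seed: int):
    y = np.asarray(y, int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    return list(skf.split(np.zeros_like(y), y))


def _report(pooled: ConfusionCounts, scores, y_true, per_fold) -> EvalReport:
    m = metrics(pooled)
    auc = None
    try:
        auc = roc_auc(scores, y_true)
    except UndefinedMetricError:
        m["undefined"].add("auc")
    return EvalReport(
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        precision=m["precision"],
        f1=m["f1"],
        auc=auc,
        confusion=pooled,
        undefined=m["undefined"],
        per_fold=per_fold,
    )


def cross_validate(
    data: LabeledDataset, model, folds: int = 5, rng_seed: int = 0
) -> EvalReport:
    """Stratified k-fold CV; pooled confusion counts, per-fold metrics, and
    AUC from the concatenated out-of-fold scores."""
    factory = _resolve_model(model)
    pooled = ConfusionCounts()
    per_fold = []
    oof_scores = np.empty(data.n)
    for train, test in _stratified_folds(data.y, folds, rng_seed):
        clf = factory().fit(data.X[train], data.y[train])
        pred = clf.predict(data.X[test])
        oof_scores[test] = clf.predict_proba(data.X[test])[:, 1]
        c = ConfusionCounts.from_predictions(data.y[test], pred)
        pooled = pooled + c
        fold_m = metrics(c)
        fold_m["n"] = c.n
        per_fold.append(fold_m)
    return _report(pooled, oof_scores, data.y, per_fold)


def nested_select(
    data: LabeledDataset,
    candidates: Sequence,
    make_model: Callable[[object], object],
    outer: int = 5,
    inner: int = 5,
    rng_seed: int = 0,
) -> tuple[list, EvalReport]:
    """Nested CV hyperparameter choice.

    Per outer training split, the candidate maximizing inner-CV accuracy is
    chosen (ties to the earlier candidate) and evaluated on the outer test
    split.  Returns (per-outer-fold chosen candidates, outer EvalReport).
    """
    if len(candidates) < 1:
        raise ParameterError("need at least one candidate")
    choices = []
    pooled = ConfusionCounts()
    per_fold = []
    oof_scores = np.empty(data.n)
    for k, (train, test) in enumerate(_stratified_folds(data.y, outer, rng_seed)):
        inner_data = LabeledDataset(
            X=data.X[train], y=data.y[train], feature_names=list(data.feature_names)
        )
        if len(candidates) == 1:
            best = candidates[0]
        else:
            best, best_acc = None, -1.0
            for cand in candidates:
                rep = cross_validate(
                    inner_data, lambda c=cand: make_model(c), folds=inner, rng_seed=rng_seed + k
                )
                if rep.accuracy > best_acc:
                    best, best_acc = cand, rep.accuracy
        choices.append(best)
        clf = make_model(best).fit(data.X[train], data.y[train])
        pred = clf.predict(data.X[test])
        oof_scores[test] = clf.predict_proba(data.X[test])[:, 1]
        c = ConfusionCounts.from_predictions(data.y[test], pred)
        pooled = pooled + c
        fold_m = metrics(c)
        fold_m["n"] = c.n
        fold_m["chosen"] = best
        per_fold.append(fold_m)
    return choices, _report(pooled, oof_scores, data.y, per_fold)
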