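"""Multiple-classifier systems: bagging (parallel), AdaBoost (cascaded),
and averaging fusion over heterogeneous members.

Bagging fits each member on an n-sample bootstrap resample and averages
the members' probabilities.  AdaBoost follows the M1 scheme with
weight-proportional resampling: each round fits the base learner on a
resample drawn according to the current instance weights, computes the
weighted training error e_t, stops on e_t >= 0.5 or e_t = 0, weights the
member by a_t = 0.5 ln((1 - e_t) / e_t), multiplies misclassified
instance weights by exp(a_t) and renormalizes.  The decision is the sign
of the weighted vote; the class-1 probability is the logistic of the
alpha-normalized margin, which provides the continuous score ROC/AUC
needs.  The averaging fusion simply takes the unweighted mean of the
fitted members' probability rows (prediction ties go to class 0).
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError, SchemaError

logger = logging.getLogger(__name__)

_ALPHA_CAP_EPS_SCALE = 0.5  # e~ = _ALPHA_CAP_EPS_SCALE / n caps alpha when e_t = 0


def _resolve_factory(base) -> Callable[[], object]:
    if callable(base) and not hasattr(base, "fit"):
        return base
    if hasattr(base, "clone"):
        return base.clone
    raise ParameterError("base must be a factory callable or a clonable classifier")


class BaggingEnsemble:
    def __init__(self, base, size: int = 10, seed: int = 0, resample: bool = True):
        if size < 1:
            raise ParameterError("size must be >= 1")
        self.factory = _resolve_factory(base)
        self.size = size
        self.seed = seed
        self.resample = resample
        self.members_ = None

    def fit(self, X, y) -> "BaggingEnsemble":
        X, y = np.asarray(X, float), np.asarray(y, int)
        rng = np.random.default_rng(self.seed)
        self.members_ = []
        for _ in range(self.size):
            idx = rng.choice(y.size, size=y.size, replace=True) if self.resample else np.arange(y.size)
            self.members_.append(self.factory().fit(X[idx], y[idx]))
        return self

    def predict_proba(self, Q) -> np.ndarray:
        if self.members_ is None:
            raise ParameterError("ensemble must be fitted first")
        return np.mean([m.predict_proba(Q) for m in self.members_], axis=0)

    def predict(self, Q) -> np.ndarray:
        return np.argmax(self.predict_proba(Q), axis=1)


class AdaBoostEnsemble:
    def __init__(self, base, size: int = 10, seed: int = 0):
        if size < 1:
            raise ParameterError("size must be >= 1")
        self.factory = _resolve_factory(base)
        self.size = size
        self.seed = seed
        self.members_ = None
        self.alphas_ = None
        self.weight_history_ = None

    def fit(self, X, y) -> "AdaBoostEnsemble":
        X, y = np.asarray(X, float), np.asarray(y, int)
        n = y.size
        if n < 2 or len(np.unique(y)) != 2:
            raise ParameterError("AdaBoost needs >= 2 samples of both binary classes")
        rng = np.random.default_rng(self.seed)
        w = np.full(n, 1.0 / n)
        members, alphas, history = [], [], []
        eps_floor = _ALPHA_CAP_EPS_SCALE / n
        for t in range(self.size):
            idx = rng.choice(n, size=n, replace=True, p=w)
            member = self.factory().fit(X[idx], y[idx])
            miss = member.predict(X) != y
            eps = float(w[miss].sum())
            if eps >= 0.5:
                if t == 0:
                    logger.warning(
                        "round-1 weighted error %.3f >= 0.5; keeping the single "
                        "round-1 member", eps
                    )
                    members.append(member)
                    alphas.append(1.0)
                    history.append(w.copy())
                break
            alpha = 0.5 * np.log((1 - max(eps, eps_floor)) / max(eps, eps_floor))
            members.append(member)
            alphas.append(alpha)
            if eps == 0.0:
                history.append(w.copy())
                break
            w = w * np.where(miss, np.exp(alpha), 1.0)
            w = w / w.sum()
            history.append(w.copy())
        self.members_ = members
        self.alphas_ = np.asarray(alphas)
        self.weight_history_ = history
        return self

    def decision_margin(self, Q) -> np.ndarray:
        """Alpha-normalized vote margin in [-1, 1] (positive favours class 1)."""
        if not self.members_:
            raise ParameterError("ensemble must be fitted first")
        votes = np.array([2 * m.predict(Q) - 1 for m in self.members_], dtype=float)
        return (self.alphas_[:, None] * votes).sum(axis=0) / self.alphas_.sum()

    def predict_proba(self, Q) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_margin(Q)))
        return np.column_stack([1 - p1, p1])

    def predict(self, Q) -> np.ndarray:
        return (self.decision_margin(Q) > 0).astype(int)


class AveragingEnsemble:
    """Averaging fusion of already-fitted heterogeneous members."""

    def __init__(self, members: Sequence):
        if len(members) < 2:
            raise ParameterError("averaging fusion needs >= 2 fitted members")
        self.members_ = list(members)

    def predict_proba(self, Q) -> np.ndarray:
        probas = [np.asarray(m.predict_proba(Q)) for m in self.members_]
        shapes = {p.shape for p in probas}
        if len(shapes) != 1:
            raise SchemaError(f"members disagree on the class set: shapes {shapes}")
        return np.mean(probas, axis=0)

    def predict(self, Q) -> np.ndarray:
        # argmax with ties to class 0
        return np.argmax(self.predict_proba(Q), axis=1)


def bagging_fit(data, base, size: int = 10, seed: int = 0, resample: bool = True):
    return BaggingEnsemble(base, size=size, seed=seed, resample=resample).fit(data.X, data.y)


def adaboost_fit(data, base, size: int = 10, seed: int = 0):
    return AdaBoostEnsemble(base, size=size, seed=seed).fit(data.X, data.y)


def averaging_mcs(members: Sequence) -> AveragingEnsemble:
    return AveragingEnsemble(members)
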