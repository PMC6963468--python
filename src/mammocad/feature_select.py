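"""Wrapper feature selection: best-first (bidirectional, backtracking)
and random search over feature subsets.

The objective of a subset is the stratified cross-validated accuracy of a
chosen classifier trained on the column-restricted data; the fold
assignment is frozen per search and every subset's objective is memoized,
so re-evaluating a subset is free and deterministic.

Best-first keeps an open list of evaluated subsets ordered by objective
and repeatedly expands the most promising one into its single-feature
additions (and, bidirectionally, deletions); because earlier subsets stay
on the open list, the search backtracks to them when a branch turns out
worse.  It stops after ``stale_limit`` consecutive expansions without
improving the incumbent; with an unlimited stale budget on d <= 8 it
enumerates all 2^d - 1 nonempty subsets and is exhaustive.  Random search
starts from a uniformly random nonempty subset and spends a fixed budget
of evaluations on random single-feature mutations of the incumbent mixed
with uniformly drawn subsets, deduplicated, keeping the best.

Ties between equal-objective subsets always resolve to the smaller
subset, then to the lexicographically earlier one in canonical feature
order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .classifiers import make_classifier
from .dataset import LabeledDataset
from .errors import ParameterError
from .evaluate import _stratified_folds


@dataclass
class FSResult:
    selected: tuple[str, ...]
    objective: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    @property
    def n_evaluated(self) -> int:
        return len(self.trace)


class SubsetObjective:
    """Memoized CV-accuracy objective over feature subsets."""

    def __init__(
        self,
        data: LabeledDataset,
        classifier: str | Callable[[], object] = "knn",
        cv_folds: int = 5,
        rng_seed: int = 0,
    ):
        self.data = data
        if isinstance(classifier, str):
            kind = classifier
            classifier = lambda: make_classifier(kind)
        self.factory = classifier
        self.folds = _stratified_folds(data.y, cv_folds, rng_seed)
        self._cache: dict[frozenset, float] = {}

    def canonical(self, subset) -> tuple[str, ...]:
        """Subset as a tuple in canonical (dataset) feature order."""
        chosen = set(subset)
        unknown = chosen - set(self.data.feature_names)
        if unknown:
            raise ParameterError(f"unknown features {sorted(unknown)}")
        return tuple(n for n in self.data.feature_names if n in chosen)

    def __call__(self, subset) -> float:
        names = self.canonical(subset)
        if not names:
            raise ParameterError("subset must be nonempty")
        key = frozenset(names)
        if key not in self._cache:
            idx = [self.data.feature_names.index(n) for n in names]
            X, y = self.data.X[:, idx], self.data.y
            correct = 0
            for train, test in self.folds:
                clf = self.factory().fit(X[train], y[train])
                correct += int((clf.predict(X[test]) == y[test]).sum())
            self._cache[key] = correct / y.size
        return self._cache[key]


def _better(a: tuple[float, tuple[str, ...]], b: tuple[float, tuple[str, ...]] | None) -> bool:
    """Is candidate (objective, subset) a better than incumbent b?"""
    if b is None:
        return True
    if a[0] != b[0]:
        return a[0] > b[0]
    if len(a[1]) != len(b[1]):
        return len(a[1]) < len(b[1])
    return a[1] < b[1]


def best_first_search(
    data: LabeledDataset,
    classifier: str | Callable[[], object] = "knn",
    direction: str = "bidirectional",
    stale_limit: float = 5,
    cv_folds: int = 5,
    rng_seed: int = 0,
    objective: SubsetObjective | None = None,
) -> FSResult:
    """Best-first subset search with backtracking."""
    if direction not in ("forward", "bidirectional"):
        raise ParameterError("direction must be 'forward' or 'bidirectional'")
    obj = objective or SubsetObjective(data, classifier, cv_folds, rng_seed)
    names = list(data.feature_names)
    order = {n: i for i, n in enumerate(names)}

    trace: list[tuple[tuple[str, ...], float]] = []
    seen: set[frozenset] = set()
    best: tuple[float, tuple[str, ...]] | None = None

    # heap entries: (-objective, subset size, canonical tuple) — ties prefer
    # smaller then lexicographically earlier subsets
    heap: list[tuple[float, int, tuple[str, ...]]] = []
    heapq.heappush(heap, (-math.inf, 0, ()))  # empty start set, never a result
    seen.add(frozenset())

    stale = 0
    while heap and stale < stale_limit:
        _, _, current = heapq.heappop(heap)
        improved = False
        neighbours = [tuple(sorted(set(current) | {n}, key=order.get)) for n in names if n not in current]
        if direction == "bidirectional" and len(current) > 1:
            neighbours += [tuple(n for n in current if n != drop) for drop in current]
        for cand in neighbours:
            key = frozenset(cand)
            if key in seen:
                continue
            seen.add(key)
            score = obj(cand)
            trace.append((cand, score))
            if _better((score, cand), best):
                best = (score, cand)
                improved = True
            heapq.heappush(heap, (-score, len(cand), cand))
        stale = 0 if improved else stale + 1

    assert best is not None
    return FSResult(selected=best[1], objective=best[0], trace=trace)


def random_search(
    data: LabeledDataset,
    classifier: str | Callable[[], object] = "knn",
    budget: int = 100,
    rng_seed: int = 0,
    cv_folds: int = 5,
    objective: SubsetObjective | None = None,
) -> FSResult:
    """Random subset search: random nonempty start, then ``budget``
    deduplicated random proposals (single-feature mutations of the
    incumbent mixed with uniform subsets), keeping the best."""
    if budget < 1:
        raise ParameterError("budget must be >= 1")
    obj = objective or SubsetObjective(data, classifier, cv_folds, rng_seed)
    names = list(data.feature_names)
    d = len(names)
    rng = np.random.default_rng(rng_seed)

    def mask_to_subset(mask: int) -> tuple[str, ...]:
        return tuple(n for i, n in enumerate(names) if mask >> i & 1)

    def subset_to_mask(subset) -> int:
        chosen = set(subset)
        return sum(1 << i for i, n in enumerate(names) if n in chosen)

    all_masks = (1 << d) - 1
    seen_masks: set[int] = set()
    trace: list[tuple[tuple[str, ...], float]] = []

    def evaluate(mask: int):
        nonlocal best
        seen_masks.add(mask)
        cand = mask_to_subset(mask)
        score = obj(cand)
        trace.append((cand, score))
        if _better((score, cand), best):
            best = (score, cand)

    best: tuple[float, tuple[str, ...]] | None = None
    evaluate(int(rng.integers(1, all_masks + 1)))  # random nonempty start

    for _ in range(budget):
        if len(seen_masks) >= all_masks:
            break
        proposal = None
        for _attempt in range(20):
            if rng.random() < 0.5:
                flip = 1 << int(rng.integers(0, d))
                cand_mask = subset_to_mask(best[1]) ^ flip
            else:
                cand_mask = int(rng.integers(1, all_masks + 1))
            if cand_mask != 0 and cand_mask not in seen_masks:
                proposal = cand_mask
                break
        if proposal is None:  # exhaust deterministically once duplicates dominate
            unseen = sorted(set(range(1, all_masks + 1)) - seen_masks)
            proposal = unseen[int(rng.integers(0, len(unseen)))]
        evaluate(proposal)

    assert best is not None
    return FSResult(selected=best[1], objective=best[0], trace=trace)


def exhaustive_search(
    data: LabeledDataset,
    classifier: str | Callable[[], object] = "knn",
    cv_folds: int = 5,
    rng_seed: int = 0,
    objective: SubsetObjective | None = None,
) -> FSResult:
    """Enumerate every nonempty subset (feasible at d <= ~16); the standing
    oracle for validating the heuristic searches on the 8-feature space."""
    obj = objective or SubsetObjective(data, classifier, cv_folds, rng_seed)
    names = list(data.feature_names)
    d = len(names)
    best = None
    trace = []
    for mask in range(1, 1 << d):
        cand = tuple(n for i, n in enumerate(names) if mask >> i & 1)
        score = obj(cand)
        trace.append((cand, score))
        if _better((score, cand), best):
            best = (score, cand)
    return FSResult(selected=best[1], objective=best[0], trace=trace)
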