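"""Weighted-sum ensembling of the three base classifiers (EDLM).

The ensemble score of sample i is the convex combination

    g_i = sum_n w_n * f_{n,i}

of the base-model scores f_{n,i} (probability of the mutated class), with
non-negative weights normalized to sum to 1.  Weights default to being
proportional to each base model's accuracy on a reference set; uniform,
explicit, and a coarse grid search over the weight simplex are available as
alternatives.  Scores at exactly the decision threshold classify as mutated,
which makes sensitivity/specificity accounting deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .errors import ParameterError, TrainingError

DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class EnsembleWeights:
    """Normalized non-negative weights, one per base model."""

    w: tuple[float, ...]

    def __post_init__(self):
        if not self.w:
            raise ParameterError("weights must be non-empty")
        arr = np.asarray(self.w, dtype=float)
        if (arr < 0).any():
            raise ParameterError(f"weights must be non-negative, got {self.w}")
        total = arr.sum()
        if total <= 0:
            raise ParameterError("at least one weight must be positive")
        object.__setattr__(self, "w", tuple(arr / total))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


@dataclass(frozen=True)
class EnsemblePrediction:
    """Per-sample ensemble scores and thresholded binary labels."""

    scores: np.ndarray
    labels: np.ndarray
    threshold: float = DECISION_THRESHOLD


def derive_weights(accuracies: Sequence[float]) -> EnsembleWeights:
    """Accuracy-proportional weights; uniform when every accuracy is zero."""
    if len(accuracies) == 0:
        raise ParameterError("need at least one accuracy")
    arr = np.asarray(accuracies, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ParameterError(f"accuracies must lie in [0, 1], got {list(arr)}")
    if arr.sum() == 0:
        arr = np.ones_like(arr)
    return EnsembleWeights(tuple(arr / arr.sum()))


def ensemble_scores(
    per_model: Sequence[np.ndarray],
    weights: EnsembleWeights,
    threshold: float = DECISION_THRESHOLD,
) -> EnsemblePrediction:
    """Weighted sum of base-model score vectors, thresholded (ties -> mutated)."""
    if len(per_model) != len(weights.w):
        raise ParameterError(
            f"{len(per_model)} score vectors but {len(weights.w)} weights"
        )
    arrays = [np.asarray(s, dtype=float) for s in per_model]
    if len({a.shape for a in arrays}) != 1:
        raise ParameterError(
            f"score vectors differ in shape: {[a.shape for a in arrays]}"
        )
    mat = np.vstack(arrays)
    scores = weights.as_array() @ mat
    return EnsemblePrediction(scores, (scores >= threshold).astype(np.int64), threshold)


def grid_search_weights(
    per_model: Sequence[np.ndarray],
    truth01: np.ndarray,
    step: float = 0.1,
    threshold: float = DECISION_THRESHOLD,
) -> EnsembleWeights:
    """Exhaustive search over the weight simplex (given step) maximizing accuracy.

    Ties prefer the earliest candidate in lexicographic order, which keeps
    the result deterministic.
    """
    n = len(per_model)
    ticks = int(round(1.0 / step))
    best, best_acc = None, -1.0
    for combo in product(range(ticks + 1), repeat=n - 1):
        if sum(combo) > ticks:
            continue
        w = [c / ticks for c in combo] + [(ticks - sum(combo)) / ticks]
        if sum(w) <= 0:
            continue
        pred = ensemble_scores(per_model, EnsembleWeights(tuple(w)), threshold)
        acc = float((pred.labels == truth01).mean())
        if acc > best_acc:
            best, best_acc = w, acc
    return EnsembleWeights(tuple(best))


class WeightedEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper: fit base models, combine their scores.

    Parameters
    ----------
    estimators : list of (name, estimator)
        The base classifiers (cloned-by-reference; pass ``prefit=True`` to
        reuse already-fitted models and skip fitting).
    weighting : {"accuracy", "uniform", "grid", "explicit"}
        How weights are derived.  "accuracy" uses each base model's accuracy
        on the weight-reference set; "grid" searches the simplex (step 0.1)
        for the accuracy-maximizing combination on that set.
    weights : sequence of float, optional
        Required for ``weighting="explicit"``.
    validation_fraction : float, default 0.0
        If > 0, a stratified fraction of the training data is held out from
        base-model fitting and used as the weight-reference set; otherwise
        the training data itself is the reference (no extra fits).
    """

    def __init__(
        self,
        estimators,
        weighting: str = "accuracy",
        weights: Sequence[float] | None = None,
        validation_fraction: float = 0.0,
        threshold: float = DECISION_THRESHOLD,
        prefit: bool = False,
        random_state: int = 0,
    ):
        self.estimators = estimators
        self.weighting = weighting
        self.weights = weights
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.prefit = prefit
        self.random_state = random_state

    def fit(self, X, y):
        if self.weighting not in ("accuracy", "uniform", "grid", "explicit"):
            raise ParameterError(f"unknown weighting {self.weighting!r}")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise TrainingError("ensemble requires exactly two classes")
        names = [name for name, _ in self.estimators]
        ests = [est for _, est in self.estimators]

        if self.validation_fraction > 0 and not self.prefit:
            idx = np.arange(len(y))
            fit_idx, ref_idx = train_test_split(
                idx,
                test_size=self.validation_fraction,
                stratify=y,
                random_state=self.random_state,
            )
            X_fit = X[fit_idx] if isinstance(X, np.ndarray) else [X[i] for i in fit_idx]
            X_ref = X[ref_idx] if isinstance(X, np.ndarray) else [X[i] for i in ref_idx]
            y_fit, y_ref = y[fit_idx], y[ref_idx]
        else:
            X_fit = X_ref = X
            y_fit = y_ref = y

        if not self.prefit:
            for est in ests:
                est.fit(X_fit, y_fit)
        self.estimators_ = ests
        self.names_ = names

        truth01 = (y_ref == self.classes_[1]).astype(np.int64)
        ref_scores = [est.predict_scores(X_ref) for est in ests]
        if self.weighting == "uniform":
            self.weights_ = EnsembleWeights(tuple([1.0] * len(ests)))
        elif self.weighting == "explicit":
            if self.weights is None:
                raise ParameterError("weighting='explicit' requires weights")
            self.weights_ = EnsembleWeights(tuple(self.weights))
        elif self.weighting == "grid":
            self.weights_ = grid_search_weights(
                ref_scores, truth01, threshold=self.threshold
            )
        else:  # accuracy-proportional
            accs = [
                float(((s >= self.threshold).astype(np.int64) == truth01).mean())
                for s in ref_scores
            ]
            self.weights_ = derive_weights(accs)
        return self

    def predict_scores(self, X) -> np.ndarray:
        per_model = [est.predict_scores(X) for est in self.estimators_]
        return ensemble_scores(per_model, self.weights_, self.threshold).scores

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.predict_scores(X)
        return self.classes_[(s >= self.threshold).astype(int)]
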