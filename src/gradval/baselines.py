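"""Baseline valuation methods: random, leave-one-out, TMC Data Shapley.

All three share the gradient method's "higher value = more useful"
orientation so a single evaluation path serves every method.  Leave-one-out
and Data Shapley require retraining a learner many times; the
:class:`RetrainableLearner` contract below abstracts the fit/score pair so
any scikit-learn estimator (or the closed-form mean predictor used in
exact-value tests) can stand behind them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, mean_squared_error, r2_score, roc_auc_score

from .dvgs import DataValues

__all__ = [
    "RetrainableLearner",
    "SklearnLearner",
    "MeanRegressor",
    "AutoencoderLearner",
    "ShapleyConfig",
    "random_values",
    "loo_values",
    "tmc_shapley",
]


class RetrainableLearner(Protocol):
    """Fit/score contract used by the retraining-based baselines."""

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0): ...

    def score(self, fitted, X: np.ndarray, y: np.ndarray, metric: str) -> float: ...

    def empty_score(self, X: np.ndarray, y: np.ndarray, metric: str) -> float: ...


def _metric(metric: str, y_true, y_score, y_pred) -> float:
    if metric == "auroc":
        if np.min(y_true) == np.max(y_true):
            raise ValueError("AUROC undefined for single-class evaluation set")
        return float(roc_auc_score(y_true, y_score))
    if metric == "accuracy":
        return float(accuracy_score(y_true, y_pred))
    if metric == "neg_mse":
        return -float(mean_squared_error(y_true, y_pred))
    if metric == "r2":
        return float(r2_score(y_true, y_pred))
    raise ValueError(f"unknown metric {metric!r}")


class _ConstantClassifier:
    def __init__(self, label: int):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)

    def predict_proba_positive(self, X):
        return np.full(len(X), 0.5)  # uninformative score


class SklearnLearner:
    """Classifier learner backed by a seeded scikit-learn estimator.

    A training subset containing a single class (which occurs routinely in
    short Shapley permutations) yields a constant predictor with an
    uninformative score instead of an error.
    """

    def __init__(self, factory: Callable[[int], object] | None = None):
        self.factory = factory or (lambda seed: LogisticRegression(max_iter=1000, random_state=seed))

    def fit(self, X, y, seed: int = 0):
        y = np.asarray(y)
        if len(X) == 0:
            return _ConstantClassifier(0)
        if np.min(y) == np.max(y):
            return _ConstantClassifier(int(y[0]))
        est = self.factory(seed)
        est.fit(X, y)
        return est

    def _scores(self, fitted, X):
        if isinstance(fitted, _ConstantClassifier):
            return fitted.predict_proba_positive(X), fitted.predict(X)
        proba = fitted.predict_proba(X)
        score = proba[:, 1] if proba.shape[1] == 2 else proba.max(axis=1)
        return score, fitted.predict(X)

    def score(self, fitted, X, y, metric: str = "auroc") -> float:
        y_score, y_pred = self._scores(fitted, X)
        return _metric(metric, np.asarray(y), y_score, y_pred)

    def empty_score(self, X, y, metric: str = "auroc") -> float:
        """Score of the uninformed (no-training-data) predictor."""
        return self.score(_ConstantClassifier(0), X, y, metric)


class MeanRegressor:
    """Closed-form learner predicting the global training mean.

    Its leave-one-out and Shapley values have simple exact forms, which
    makes it the oracle learner in correctness tests.
    """

    def fit(self, X, y, seed: int = 0):
        y = np.asarray(y, dtype=float)
        return float(y.mean()) if len(y) else 0.0

    def score(self, fitted, X, y, metric: str = "neg_mse") -> float:
        pred = np.full(len(np.asarray(y)), fitted)
        return _metric(metric, np.asarray(y, dtype=float), pred, pred)

    def empty_score(self, X, y, metric: str = "neg_mse") -> float:
        return self.score(0.0, X, y, metric)


class AutoencoderLearner:
    """Reconstruction learner: a seeded autoencoder trained by mini-batch SGD.

    Used for filter-and-retrain curves on expression-style data, scored by
    reconstruction R^2 on a held-out matrix.
    """

    def __init__(self, latent_dim: int = 32, learning_rate: float = 0.5,
                 epochs: int = 100, batch_size: int = 32):
        self.latent_dim = latent_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size

    def fit(self, X, y=None, seed: int = 0):
        from .dvgs import _apply_update, _batch_gradient_layers
        from .models import LossSpec, make_autoencoder

        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            raise ValueError("cannot fit an autoencoder on an empty set")
        model = make_autoencoder(X.shape[1], self.latent_dim, seed=seed)
        loss = LossSpec("mse_reconstruction")
        rng = np.random.default_rng(seed)
        bs = min(self.batch_size, len(X))
        for _ in range(self.epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X) - bs + 1, bs):
                xb = X[order[start : start + bs]]
                _apply_update(model, _batch_gradient_layers(model, xb, xb, loss),
                              self.learning_rate)
        return model

    def score(self, fitted, X, y=None, metric: str = "r2") -> float:
        X = np.asarray(X, dtype=float)
        recon = fitted.forward(X)
        if metric == "r2":
            return float(r2_score(X, recon))
        if metric == "neg_mse":
            return -float(np.mean((X - recon) ** 2))
        raise ValueError(f"unknown reconstruction metric {metric!r}")

    def empty_score(self, X, y=None, metric: str = "r2") -> float:
        X = np.asarray(X, dtype=float)
        zeros = np.zeros_like(X)
        if metric == "r2":
            return float(r2_score(X, zeros))
        return -float(np.mean(X**2))


@dataclass
class ShapleyConfig:
    """Monte-Carlo settings for truncated-permutation Data Shapley."""

    max_permutations: int = 200
    truncation_tolerance: float | None = None  # default: 1% of |full score|
    convergence_tolerance: float = 0.001
    convergence_window: int = 10
    seed: int = 0
    exhaustive: bool = False  # enumerate all n! permutations (tiny n only)

    def __post_init__(self) -> None:
        if self.max_permutations < 1:
            raise ValueError("max_permutations must be >= 1")
        if self.truncation_tolerance is not None and self.truncation_tolerance < 0:
            raise ValueError("tolerances must be non-negative")
        if self.convergence_tolerance < 0:
            raise ValueError("tolerances must be non-negative")


def random_values(n: int, seed: int = 0) -> DataValues:
    """Uniform(0, 1) values — the null model every method is compared to."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return DataValues(values=rng.uniform(0.0, 1.0, size=n), method="random")


def loo_values(
    learner: RetrainableLearner, source, target, metric: str = "auroc", seed: int = 0
) -> DataValues:
    """Leave-one-out values: performance drop when a sample is removed.

    ``value_k = score(fit(S), target) - score(fit(S \\ {k}), target)``;
    positive values mean the sample helps target performance.  Samples whose
    removal makes training degenerate get NaN and the run continues.
    """
    Xs, ys = source
    Xt, yt = target
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys)
    if len(Xs) < 2:
        raise ValueError("leave-one-out needs at least two source samples")
    full = learner.score(learner.fit(Xs, ys, seed=seed), Xt, yt, metric)
    values = np.empty(len(Xs))
    keep = np.ones(len(Xs), dtype=bool)
    for k in range(len(Xs)):
        keep[k] = False
        try:
            reduced = learner.score(learner.fit(Xs[keep], ys[keep], seed=seed), Xt, yt, metric)
            values[k] = full - reduced
        except ValueError:
            values[k] = np.nan
        keep[k] = True
    return DataValues(values=values, method="loo")


def tmc_shapley(
    learner: RetrainableLearner,
    source,
    target,
    metric: str = "auroc",
    config: ShapleyConfig | None = None,
) -> DataValues:
    """Truncated Monte-Carlo estimate of Data Shapley values.

    Random permutations of the source set are scanned; each sample's
    marginal contribution is the score change when it joins the growing
    prefix.  A permutation is truncated once the running score is within
    ``truncation_tolerance`` of the full-data score (remaining marginals
    are zero).  Estimation stops at ``max_permutations`` or earlier when
    the running means move less than ``convergence_tolerance`` over the
    last ``convergence_window`` permutations.

    With ``config.exhaustive`` every one of the n! permutations is visited
    exactly once; combined with ``truncation_tolerance=0`` this computes
    the exact Shapley value (feasible only for very small source sets).
    """
    config = config or ShapleyConfig()
    Xs, ys = source
    Xt, yt = target
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys)
    n = len(Xs)
    if n < 2:
        raise ValueError("Shapley valuation needs at least two source samples")
    rng = np.random.default_rng(config.seed)
    v_full = learner.score(learner.fit(Xs, ys, seed=config.seed), Xt, yt, metric)
    v_empty = learner.empty_score(Xt, yt, metric)
    trunc = (
        config.truncation_tolerance
        if config.truncation_tolerance is not None
        else 0.01 * abs(v_full)
    )

    if config.exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        perms = itertools.permutations(range(n))
    else:
        perms = (rng.permutation(n) for _ in range(config.max_permutations))

    marg_sum = np.zeros(n)
    history: list[np.ndarray] = []
    converged = False
    t = 0
    for t, perm in enumerate(perms, start=1):
        perm = np.asarray(perm)
        prev = v_empty
        truncated = False
        for pos, k in enumerate(perm):
            if truncated or abs(v_full - prev) < trunc:
                truncated = True
                continue  # remaining marginals are zero
            subset = perm[: pos + 1]
            new = learner.score(
                learner.fit(Xs[subset], ys[subset], seed=config.seed), Xt, yt, metric
            )
            marg_sum[k] += new - prev
            prev = new
        history.append(marg_sum / t)
        w = config.convergence_window
        if t > w:
            if np.max(np.abs(history[-1] - history[-1 - w])) < config.convergence_tolerance:
                converged = True
                break
    values = marg_sum / t
    return DataValues(values=values, method="shapley", converged=converged, n_recorded=t)
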