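"""Differentiable models for gradient-based data valuation.

The valuation algorithm only needs small feedforward networks with exact
per-sample gradients, so the two architectures used throughout — a 2-layer
MLP classifier and a 2-layer-encoder/2-layer-decoder autoencoder — are
implemented directly on numpy with hand-written backpropagation.  This keeps
every gradient exact and reproducible, and lets the valuation loop compute
per-sample gradient statistics without materialising an
``n_samples x n_parameters`` matrix (see :mod:`gradval.dvgs`).

Parameter ordering is fixed: layers in forward order, weight matrix before
bias, both flattened C-order.  Two models built from the same descriptor and
seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LossSpec",
    "FeedForwardNet",
    "make_mlp",
    "make_autoencoder",
    "per_sample_loss",
    "batch_loss",
]

_ACTIVATIONS = ("relu", "linear")


@dataclass
class LossSpec:
    """Loss criterion used for training and valuation.

    Parameters
    ----------
    name:
        ``"cross_entropy"`` (softmax cross-entropy, classification) or
        ``"mse_reconstruction"`` (mean squared error over features).
    class_weights:
        Optional non-negative per-class weights.  Batch losses are the
        weighted mean of per-sample losses, each sample weighted by its
        class weight (weights normalised by their sum over the batch), so
        e.g. inverse-frequency weights make every class contribute equally
        to a batch gradient.
    """

    name: str = "cross_entropy"
    class_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in ("cross_entropy", "mse_reconstruction"):
            raise ValueError(f"unknown loss {self.name!r}")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if not np.all(np.isfinite(w)) or np.any(w < 0) or not np.any(w > 0):
                raise ValueError("class_weights must be finite, non-negative, not all zero")
            self.class_weights = w


def _init_layer(rng: np.random.Generator, d_in: int, d_out: int) -> tuple[np.ndarray, np.ndarray]:
    w = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
    b = np.zeros(d_out)
    return w, b


@dataclass
class FeedForwardNet:
    """Fully-connected network with ReLU/linear activations.

    ``task_kind`` is ``"classification"`` (softmax head) or
    ``"reconstruction"`` (linear output matching the input dimension).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: list[str]
    task_kind: str
    seed: int | None = None
    descriptor: dict = field(default_factory=dict)

    # ---- parameter vector ------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def get_parameters(self) -> np.ndarray:
        """All trainable parameters flattened in the fixed ordering."""
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    def set_parameters(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_parameters,):
            raise ValueError(f"expected parameter vector of length {self.n_parameters}")
        pos = 0
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = theta[pos : pos + w.size].reshape(w.shape).copy()
            pos += w.size
            self.biases[i] = theta[pos : pos + b.size].copy()
            pos += b.size

    def copy(self) -> "FeedForwardNet":
        return FeedForwardNet(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            activations=list(self.activations),
            task_kind=self.task_kind,
            seed=self.seed,
            descriptor=dict(self.descriptor),
        )

    # ---- forward ---------------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """Forward pass.  With ``cache=True`` also return per-layer inputs
        and pre-activations, needed for backpropagation."""
        A = np.atleast_2d(np.asarray(X, dtype=float))
        caches = []
        for w, b, act in zip(self.weights, self.biases, self.activations):
            Z = A @ w + b
            if cache:
                caches.append((A, Z))
            A = np.maximum(Z, 0.0) if act == "relu" else Z
        return (A, caches) if cache else A

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Model output: class probabilities or reconstructions."""
        out = self.forward(X)
        if self.task_kind == "classification":
            return _softmax(out)
        return out

    # ---- backward --------------------------------------------------------
    def backward(self, caches, delta: np.ndarray) -> np.ndarray:
        """Flat gradient of a scalar loss given the output-layer delta
        ``dLoss/dZ_out`` (one row per sample; contributions are summed)."""
        grads_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore[list-item]
        for i in range(len(self.weights) - 1, -1, -1):
            A_prev, _ = caches[i]
            grads_w[i] = A_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if self.activations[i - 1] == "relu":
                    delta = delta * (caches[i - 1][1] > 0)
        parts = []
        for gw, gb in zip(grads_w, grads_b):
            parts.append(gw.ravel())
            parts.append(gb.ravel())
        return np.concatenate(parts)

    def backward_layers(self, caches, delta: np.ndarray):
        """Like :meth:`backward` but keep the per-layer (dW, db) structure."""
        grads = []
        deltas = [None] * len(self.weights)
        for i in range(len(self.weights) - 1, -1, -1):
            deltas[i] = delta
            if i > 0:
                delta = delta @ self.weights[i].T
                if self.activations[i - 1] == "relu":
                    delta = delta * (caches[i - 1][1] > 0)
        for i in range(len(self.weights)):
            A_prev, _ = caches[i]
            grads.append((A_prev.T @ deltas[i], deltas[i].sum(axis=0)))
        return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---- constructors --------------------------------------------------------

def make_mlp(
    input_dim: int,
    hidden_dim: int = 100,
    n_classes: int = 2,
    seed: int = 0,
) -> FeedForwardNet:
    """2-layer MLP classifier: ``input -> hidden (ReLU) -> n_classes``.

    Softmax + cross-entropy is used uniformly, also for binary tasks
    (two output units), so multi-class problems need no special casing.
    """
    for name, v in (("input_dim", input_dim), ("hidden_dim", hidden_dim), ("n_classes", n_classes)):
        if int(v) < 1:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    rng = np.random.default_rng(seed)
    w1, b1 = _init_layer(rng, input_dim, hidden_dim)
    w2, b2 = _init_layer(rng, hidden_dim, n_classes)
    return FeedForwardNet(
        weights=[w1, w2],
        biases=[b1, b2],
        activations=["relu", "linear"],
        task_kind="classification",
        seed=seed,
        descriptor={
            "kind": "mlp",
            "input_dim": input_dim,
            "hidden_dim": hidden_dim,
            "n_classes": n_classes,
            "activation": "relu",
            "seed": seed,
        },
    )


def make_autoencoder(
    input_dim: int,
    latent_dim: int = 32,
    seed: int = 0,
    hidden_dim: int | None = None,
) -> FeedForwardNet:
    """Autoencoder with 2-layer encoder and 2-layer decoder.

    The single hidden width defaults to the geometric mean of ``input_dim``
    and ``latent_dim`` (a deterministic, scale-free interpolation), giving
    ``input -> hidden (ReLU) -> latent -> hidden (ReLU) -> input``.
    """
    if input_dim < 1 or latent_dim < 1:
        raise ValueError("dimensions must be positive")
    if latent_dim >= input_dim:
        raise ValueError(f"latent_dim ({latent_dim}) must be smaller than input_dim ({input_dim})")
    if hidden_dim is None:
        hidden_dim = int(round(np.sqrt(input_dim * latent_dim)))
    rng = np.random.default_rng(seed)
    dims = [input_dim, hidden_dim, latent_dim, hidden_dim, input_dim]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        w, b = _init_layer(rng, d_in, d_out)
        weights.append(w)
        biases.append(b)
    return FeedForwardNet(
        weights=weights,
        biases=biases,
        activations=["relu", "linear", "relu", "linear"],
        task_kind="reconstruction",
        seed=seed,
        descriptor={
            "kind": "autoencoder",
            "input_dim": input_dim,
            "hidden_dim": hidden_dim,
            "latent_dim": latent_dim,
            "activation": "relu",
            "seed": seed,
        },
    )


# ---- losses --------------------------------------------------------------

def _check_classification_targets(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("class labels must be a 1-d integer vector")
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    return y.astype(int)


def per_sample_loss(
    model: FeedForwardNet, X: np.ndarray, y: np.ndarray, loss: LossSpec
) -> np.ndarray:
    """Vector of per-sample losses (unweighted; class weights enter only
    when samples are combined into a batch loss)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = model.forward(X)
    if loss.name == "cross_entropy":
        if model.task_kind != "classification":
            raise ValueError("cross_entropy requires a classification model")
        y = _check_classification_targets(np.atleast_1d(y), out.shape[1])
        logp = out - out.max(axis=1, keepdims=True)
        logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
        return -logp[np.arange(len(y)), y]
    # mean squared error per sample, averaged over features
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    if Y.shape != out.shape:
        raise ValueError(f"target shape {Y.shape} does not match output shape {out.shape}")
    return np.mean((out - Y) ** 2, axis=1)


def _sample_weights(y, loss: LossSpec, n: int) -> np.ndarray | None:
    if loss.class_weights is None:
        return None
    y = np.atleast_1d(np.asarray(y)).astype(int)
    return loss.class_weights[y]


def batch_loss(model: FeedForwardNet, X: np.ndarray, y: np.ndarray, loss: LossSpec) -> float:
    """Scalar batch loss: (class-weighted) mean of per-sample losses."""
    ls = per_sample_loss(model, X, y, loss)
    w = _sample_weights(y, loss, len(ls)) if loss.name == "cross_entropy" else None
    if w is None:
        return float(ls.mean())
    return float(np.sum(w * ls) / np.sum(w))


def output_delta(
    model: FeedForwardNet,
    out: np.ndarray,
    y: np.ndarray,
    loss: LossSpec,
    reduce: str = "mean",
) -> np.ndarray:
    """d(loss)/d(output pre-activation), one row per sample.

    ``reduce="mean"`` gives deltas of the (weighted-)mean batch loss;
    ``reduce="none"`` gives deltas of each individual per-sample loss.
    """
    n = out.shape[0]
    if loss.name == "cross_entropy":
        y = _check_classification_targets(np.atleast_1d(y), out.shape[1])
        p = _softmax(out)
        delta = p.copy()
        delta[np.arange(n), y] -= 1.0
        if reduce == "mean":
            w = _sample_weights(y, loss, n)
            if w is None:
                delta /= n
            else:
                delta *= (w / w.sum())[:, None]
        return delta
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    delta = 2.0 * (out - Y) / out.shape[1]
    if reduce == "mean":
        delta = delta / n
    return delta
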