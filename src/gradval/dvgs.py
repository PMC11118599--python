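"""Data valuation with gradient similarity (DVGS).

Each source sample is valued by how well its individual loss gradient aligns
with the gradient of a *target* dataset along an SGD trajectory driven by the
target alone.  Concretely: run plain SGD on target mini-batches; every
``similarity_period`` iterations, before the parameter update, record the
cosine similarity between every source sample's gradient and the current
target-batch gradient; a sample's value is the mean of its recorded
similarities over iterations (and, optionally, over several independently
initialised runs).  Samples whose gradients consistently point with the
target's descent direction are useful to the target task; mislabeled or
noisy samples tend to point against it and receive low (often negative)
values.

The recording step never perturbs the optimisation: the parameter trajectory
is identical whether similarities are recorded at every iteration, every
T-th iteration, or not at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .models import FeedForwardNet, LossSpec, batch_loss, output_delta

__all__ = [
    "ValuationConfig",
    "DataValues",
    "cosine_similarity",
    "per_sample_gradient",
    "per_sample_gradients",
    "target_batch_gradient",
    "run_dvgs",
    "aggregate_runs",
    "balanced_class_weights",
]


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class ValuationConfig:
    """Hyper-parameters of a gradient-similarity valuation run.

    Attributes
    ----------
    learning_rate:
        SGD step size for the target-driven updates.
    n_iterations:
        Number of SGD iterations per run.
    target_batch_size:
        Mini-batch size drawn from the target set each iteration.
    similarity_period:
        Record source-gradient similarities every this many iterations
        (1 = every iteration).  Larger periods cut runtime roughly
        proportionally with little effect on the resulting ranking.
    n_runs:
        Independent repetitions with fresh initialisation and batch order;
        values are averaged across runs.
    base_seed:
        Run ``r`` uses seed ``base_seed + r`` for both weight
        initialisation and batch shuffling.
    loss:
        Loss criterion (cross-entropy or reconstruction MSE).
    similarity:
        ``"cosine"`` (default, values in [-1, 1]); ``"dot"`` and
        ``"neg_euclidean"`` are provided as pluggable alternatives but are
        not part of the validated method.
    class_balance:
        Weight target-batch per-sample losses inversely to the class
        frequencies of the *full* target set, so each class contributes
        equally to the update direction regardless of batch composition.
    pretrain_epochs:
        Full passes of target-only SGD performed before any similarity is
        recorded.
    record_per_iteration:
        Keep the full (n_source x n_recorded x n_runs) similarity array.
    """

    learning_rate: float = 0.05
    n_iterations: int = 500
    target_batch_size: int = 50
    similarity_period: int = 1
    n_runs: int = 1
    base_seed: int = 0
    loss: LossSpec = field(default_factory=LossSpec)
    similarity: str = "cosine"
    class_balance: bool = False
    pretrain_epochs: int = 0
    record_per_iteration: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_iterations < 1 or self.target_batch_size < 1 or self.n_runs < 1:
            raise ValueError("n_iterations, target_batch_size and n_runs must be >= 1")
        if not 1 <= self.similarity_period <= self.n_iterations:
            raise ValueError("similarity_period must lie in [1, n_iterations]")
        if self.pretrain_epochs < 0:
            raise ValueError("pretrain_epochs must be non-negative")
        if self.similarity not in ("cosine", "dot", "neg_euclidean"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


@dataclass
class DataValues:
    """Per-source-sample values plus provenance.

    ``values[k]`` is the mean recorded similarity of source sample ``k``
    over all recorded iterations and runs.  With cosine similarity every
    recorded entry, and hence every value, lies in [-1, 1].
    """

    values: np.ndarray
    n_runs: int = 1
    n_recorded: int = 0
    per_iteration: np.ndarray | None = None  # (n_source, n_recorded, n_runs)
    method: str = "dvgs"
    config: ValuationConfig | None = None
    converged: bool | None = None

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# similarity and gradient primitives
# ---------------------------------------------------------------------------

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two gradient vectors, in [-1, 1].

    By convention the similarity is 0 when either vector has zero norm
    (a vanished gradient carries no directional information).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"gradient length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("gradient vectors must be finite")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def _similarity_from_stats(dots: np.ndarray, sqnorms: np.ndarray, ref_sqnorm: float,
                           kind: str) -> np.ndarray:
    """Map per-sample (g_k . g_t, ||g_k||^2) statistics to similarities."""
    if kind == "cosine":
        denom = np.sqrt(sqnorms) * np.sqrt(ref_sqnorm)
        out = np.zeros_like(dots)
        ok = denom > 0
        out[ok] = np.clip(dots[ok] / denom[ok], -1.0, 1.0)
        return out
    if kind == "dot":
        return dots
    # neg_euclidean: -||g_k - g_t||
    return -np.sqrt(np.maximum(sqnorms - 2.0 * dots + ref_sqnorm, 0.0))


def per_sample_gradient(
    model: FeedForwardNet, x: np.ndarray, y, loss: LossSpec
) -> np.ndarray:
    """Exact flattened gradient of one sample's loss w.r.t. all parameters."""
    y_arr = np.atleast_1d(y) if loss.name == "cross_entropy" else np.atleast_2d(y)
    g = per_sample_gradients(model, np.atleast_2d(np.asarray(x, dtype=float)), y_arr, loss)
    return g[0]


def per_sample_gradients(
    model: FeedForwardNet, X: np.ndarray, y, loss: LossSpec
) -> np.ndarray:
    """Per-sample gradient matrix (n_samples x n_parameters).

    This is the explicit path: it materialises every gradient vector and is
    used for small problems and as the reference in oracle-equivalence
    tests.  The valuation loop itself uses :func:`_per_sample_stats`, which
    computes the similarity statistics layer-wise without forming this
    matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out, caches = model.forward(X, cache=True)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite model output")
    deltas = output_delta(model, out, y, loss, reduce="none")
    n = X.shape[0]
    grads = np.empty((n, model.n_parameters))
    # backprop each sample's delta independently (loop kept deliberately
    # simple; vectorised similarity statistics live in _per_sample_stats)
    for i in range(n):
        sample_caches = [(A[i : i + 1], Z[i : i + 1]) for A, Z in caches]
        grads[i] = model.backward(sample_caches, deltas[i : i + 1])
    return grads


def _per_sample_stats(
    model: FeedForwardNet, X: np.ndarray, y, loss: LossSpec,
    ref_layers: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample ``(g_k . g_ref, ||g_k||^2)`` without materialising g_k.

    A sample's gradient for weight layer ``l`` is the outer product
    ``a_l d_l^T`` of its layer input and backpropagated delta, so
    ``<outer(a,d), G> = a^T G d`` and ``||outer(a,d)||_F^2 =
    ||a||^2 ||d||^2``; bias terms contribute ``d . g_b`` and ``||d||^2``.
    Summing over layers gives the exact dot product and squared norm.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out, caches = model.forward(X, cache=True)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite model output")
    delta = output_delta(model, out, y, loss, reduce="none")
    n = X.shape[0]
    dots = np.zeros(n)
    sqnorms = np.zeros(n)
    for i in range(len(model.weights) - 1, -1, -1):
        A_prev, _ = caches[i]
        gW, gb = ref_layers[i]
        dots += np.einsum("ni,ij,nj->n", A_prev, gW, delta, optimize=True)
        dots += delta @ gb
        a2 = np.einsum("ni,ni->n", A_prev, A_prev)
        d2 = np.einsum("ni,ni->n", delta, delta)
        sqnorms += a2 * d2 + d2
        if i > 0:
            delta = delta @ model.weights[i].T
            if model.activations[i - 1] == "relu":
                delta = delta * (caches[i - 1][1] > 0)
    return dots, sqnorms


def balanced_class_weights(y: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Inverse-frequency class weights, normalised to mean 1 over classes."""
    y = np.asarray(y).astype(int)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    counts = np.bincount(y, minlength=n_classes).astype(float)
    if np.any(counts == 0):
        raise ValueError("every class must appear in the target set for balancing")
    w = len(y) / (n_classes * counts)
    return w


def target_batch_gradient(
    model: FeedForwardNet,
    X: np.ndarray,
    y,
    loss: LossSpec,
) -> np.ndarray:
    """Flat gradient of the (weighted-)mean batch loss.

    Class balancing is expressed through ``loss.class_weights``; weights are
    renormalised within the batch so the result stays a weighted mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    out, caches = model.forward(X, cache=True)
    delta = output_delta(model, out, y, loss, reduce="mean")
    return model.backward(caches, delta)


def _batch_gradient_layers(model, X, y, loss):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out, caches = model.forward(X, cache=True)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite model output")
    delta = output_delta(model, out, y, loss, reduce="mean")
    return model.backward_layers(caches, delta)


def _apply_update(model: FeedForwardNet, grad_layers, lr: float) -> None:
    for i, (gw, gb) in enumerate(grad_layers):
        model.weights[i] -= lr * gw
        model.biases[i] -= lr * gb


class _EpochSampler:
    """Without-replacement mini-batch sampler, reshuffled every epoch."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = min(batch_size, n)
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next_batch(self) -> np.ndarray:
        if self._pos + self.batch_size > self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        idx = self._order[self._pos : self._pos + self.batch_size]
        self._pos += self.batch_size
        return idx


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def _as_xy(dataset, task_kind: str):
    if isinstance(dataset, tuple):
        X, y = dataset
    else:  # objects with .X / .y (e.g. synthetic LabeledTable)
        X = dataset.X
        y = getattr(dataset, "y", None)
    X = np.asarray(X, dtype=float)
    if task_kind == "reconstruction" or y is None:
        return X, X
    return X, np.asarray(y)


def run_dvgs(
    model_factory: Callable[[int], FeedForwardNet],
    source,
    target,
    config: ValuationConfig,
    callback: Callable[[int, int, float], None] | None = None,
) -> DataValues:
    """Value every source sample by gradient similarity to the target.

    Parameters
    ----------
    model_factory:
        ``seed -> FeedForwardNet``; called once per run so each run starts
        from a fresh, seeded initialisation.
    source, target:
        ``(X, y)`` tuples (or objects with ``.X``/``.y``).  For
        reconstruction models the targets are the inputs themselves and
        ``y`` is ignored.
    config:
        See :class:`ValuationConfig`.
    callback:
        Optional ``(run, iteration, target_loss)`` progress hook, invoked
        at every recording iteration.

    Returns
    -------
    DataValues
        Mean similarity per source sample over all recorded iterations and
        runs; the per-iteration record is kept when
        ``config.record_per_iteration`` is set.
    """
    probe = model_factory(config.base_seed)
    task = probe.task_kind
    Xs, ys = _as_xy(source, task)
    Xt, yt = _as_xy(target, task)
    if len(Xs) == 0 or len(Xt) == 0:
        raise ValueError("source and target sets must be non-empty")
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target feature dimensionalities differ")

    loss = config.loss
    if config.class_balance and loss.name == "cross_entropy":
        n_classes = probe.weights[-1].shape[1]
        loss = LossSpec(loss.name, balanced_class_weights(yt, n_classes))

    runs = [
        _single_run(model_factory, Xs, ys, Xt, yt, loss, config,
                    seed=config.base_seed + r, run_index=r, callback=callback)
        for r in range(config.n_runs)
    ]
    agg = aggregate_runs(runs)
    agg.config = config
    return agg


def _single_run(model_factory, Xs, ys, Xt, yt, loss, config: ValuationConfig,
                seed: int, run_index: int, callback) -> DataValues:
    model = model_factory(seed)
    rng = np.random.default_rng(seed)
    sampler = _EpochSampler(len(Xt), config.target_batch_size, rng)
    lr = config.learning_rate

    for _ in range(config.pretrain_epochs * max(1, len(Xt) // sampler.batch_size)):
        idx = sampler.next_batch()
        _apply_update(model, _batch_gradient_layers(model, Xt[idx], _take(yt, idx), loss), lr)

    recorded: list[np.ndarray] = []
    for i in range(config.n_iterations):
        idx = sampler.next_batch()
        xb, yb = Xt[idx], _take(yt, idx)
        try:
            grad_layers = _batch_gradient_layers(model, xb, yb, loss)
        except FloatingPointError as err:
            raise RuntimeError(
                f"optimisation diverged at run {run_index}, iteration {i}: {err}"
            ) from err
        if i % config.similarity_period == 0:
            ref_sq = sum(float(np.sum(gw**2) + np.sum(gb**2)) for gw, gb in grad_layers)
            dots, sqnorms = _per_sample_stats(model, Xs, ys, loss, grad_layers)
            recorded.append(_similarity_from_stats(dots, sqnorms, ref_sq, config.similarity))
            if callback is not None:
                callback(run_index, i, batch_loss(model, xb, yb, loss))
        _apply_update(model, grad_layers, lr)

    sims = np.stack(recorded, axis=1)  # (n_source, n_recorded)
    return DataValues(
        values=sims.mean(axis=1),
        n_runs=1,
        n_recorded=sims.shape[1],
        per_iteration=sims[:, :, None] if config.record_per_iteration else None,
        method="dvgs",
    )


def _take(y, idx):
    y = np.asarray(y)
    return y[idx]


def aggregate_runs(per_run: Sequence[DataValues]) -> DataValues:
    """Combine runs into the grand mean over all recorded similarities.

    Each run's value vector is weighted by its recorded-iteration count, so
    the aggregate equals the mean over every individual recorded similarity.
    """
    if not per_run:
        raise ValueError("no runs to aggregate")
    n = len(per_run[0].values)
    if any(len(dv.values) != n for dv in per_run):
        raise ValueError("runs value different numbers of source samples")
    if len(per_run) == 1:
        return per_run[0]
    counts = np.array([max(dv.n_recorded, 1) for dv in per_run], dtype=float)
    stacked = np.stack([dv.values for dv in per_run], axis=1)  # (n, runs)
    values = (stacked * counts).sum(axis=1) / counts.sum()
    per_iter = None
    if all(dv.per_iteration is not None for dv in per_run):
        per_iter = np.concatenate([dv.per_iteration for dv in per_run], axis=2)
    return DataValues(
        values=values,
        n_runs=sum(dv.n_runs for dv in per_run),
        n_recorded=int(counts.sum()),
        per_iteration=per_iter,
        method="dvgs",
    )
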