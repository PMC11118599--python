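"""Evaluation statistics for data-value quality.

* ``corruption_auroc`` — how well low values flag artificially corrupted
  labels (AUROC of ``-value`` against the corruption mask);
* ``noise_spearman`` — rank correlation between per-sample noise rates and
  ``-value``;
* ``filter_and_retrain`` — test performance after removing the lowest- (or
  highest-) valued fraction of the training data and refitting;
* ``apc`` / ``apc_partition`` — average Pearson correlation among the
  replicate profiles of a perturbation, the replicate-concordance quality
  metric used for L1000-style expression data, and the conventional
  high-quality split at APC > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .corruption import CorruptionMask, NoiseRates

__all__ = [
    "FilterCurve",
    "ApcResult",
    "corruption_auroc",
    "noise_spearman",
    "filter_and_retrain",
    "apc",
    "apc_partition",
]


@dataclass
class FilterCurve:
    """Test score as a function of the fraction of training data removed."""

    fractions: np.ndarray
    direction: str  # "remove_lowest" | "remove_highest"
    scores: np.ndarray  # (reps, len(fractions))
    metric_name: str

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.fractions[0] != 0.0 or np.any(np.diff(self.fractions) <= 0):
            raise ValueError("fractions must be strictly increasing and start at 0")
        if self.scores.shape[1] != len(self.fractions):
            raise ValueError("scores must have one column per fraction")

    def mean_scores(self) -> np.ndarray:
        return self.scores.mean(axis=0)


@dataclass
class ApcResult:
    """Per-group average Pearson correlation between replicates.

    Groups with fewer than two replicates get NaN.  Replicate pairs whose
    correlation is undefined (a constant profile) are excluded from the
    mean; ``n_dropped_pairs`` counts them.
    """

    group_ids: list
    apc: np.ndarray
    n_replicates: np.ndarray
    n_dropped_pairs: int = 0


def _values_array(values) -> np.ndarray:
    return np.asarray(getattr(values, "values", values), dtype=float)


def corruption_auroc(mask: CorruptionMask | np.ndarray, values) -> float:
    """AUROC of ``-value`` as a detector of corrupted samples.

    1.0 means every corrupted sample was valued below every clean one;
    random values give ~0.5.  Ties are handled by mid-ranks.
    """
    m = np.asarray(getattr(mask, "mask", mask)).astype(int)
    v = _values_array(values)
    if len(m) != len(v):
        raise ValueError("mask and values have different lengths")
    if m.min() == m.max():
        raise ValueError("corruption mask contains a single class; AUROC undefined")
    return float(roc_auc_score(m, -v))


def noise_spearman(rates: NoiseRates | np.ndarray, values) -> float:
    """Spearman correlation of noise rates with ``-value``.

    Positive means noisier samples received lower values, as a useful
    valuation should produce.
    """
    r = np.asarray(getattr(rates, "rates", rates), dtype=float)
    v = _values_array(values)
    if len(r) != len(v):
        raise ValueError("rates and values have different lengths")
    if len(r) < 3:
        raise ValueError("need at least 3 samples")
    if np.all(r == r[0]) or np.all(v == v[0]):
        raise ValueError("constant input; Spearman correlation undefined")
    rho = stats.spearmanr(r, -v).statistic
    return float(rho)


def filter_and_retrain(
    values,
    source,
    test,
    learner,
    metric: str,
    fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    direction: str = "remove_lowest",
    reps: int = 1,
    seed: int = 0,
) -> FilterCurve:
    """Remove a fraction of the training pool by value rank and refit.

    For each fraction ``q`` the ``floor(q * n)`` samples with the lowest
    (or highest) values are dropped, the learner is refit ``reps`` times
    with distinct seeds on the remainder, and scored on the held-out test
    set.  Ties at the cutoff are broken by a seeded random order so the
    removed count is exact.
    """
    if direction not in ("remove_lowest", "remove_highest"):
        raise ValueError(f"unknown direction {direction!r}")
    v = _values_array(values)
    Xs, ys = source
    Xtest, ytest = test
    Xs = np.asarray(Xs, dtype=float)
    if len(Xtest) == 0:
        raise ValueError("test set must be non-empty")
    n = len(v)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, v))  # ascending by value
    if direction == "remove_highest":
        order = order[::-1]

    fractions = np.asarray(fractions, dtype=float)
    scores = np.empty((reps, len(fractions)))
    for j, q in enumerate(fractions):
        if not 0.0 <= q < 1.0:
            raise ValueError(f"fractions must lie in [0, 1), got {q}")
        keep = np.sort(order[int(np.floor(q * n)) :])
        Xk, yk = Xs[keep], np.asarray(ys)[keep]
        if len(keep) == 0:
            raise ValueError(f"fraction {q} removes the entire training set")
        for rep in range(reps):
            try:
                fitted = learner.fit(Xk, yk, seed=seed + rep)
            except ValueError as err:
                raise ValueError(f"retraining failed at fraction {q}: {err}") from err
            scores[rep, j] = learner.score(fitted, Xtest, ytest, metric)
    return FilterCurve(fractions=fractions, direction=direction,
                       scores=scores, metric_name=metric)


def apc(expression, groups=None) -> ApcResult:
    """Average Pearson correlation between the replicates of each group.

    Accepts either a ``ReplicateExpressionSet`` (uses its replicate-level
    matrix and group map) or an explicit ``(matrix, groups)`` pair with one
    row per replicate.  For each group the statistic is the unweighted mean
    of Pearson correlations over all unordered replicate pairs.
    """
    if groups is None:
        matrix = np.asarray(expression.level4, dtype=float)
        groups = np.asarray(expression.group_of)
    else:
        matrix = np.asarray(expression, dtype=float)
        groups = np.asarray(groups)
    if len(matrix) != len(groups):
        raise ValueError("one group id per replicate row is required")

    ids = list(dict.fromkeys(groups.tolist()))  # first-appearance order
    apcs = np.full(len(ids), np.nan)
    counts = np.zeros(len(ids), dtype=int)
    dropped = 0
    for gi, g in enumerate(ids):
        rows = matrix[groups == g]
        counts[gi] = len(rows)
        if len(rows) < 2:
            continue
        sd = rows.std(axis=1)
        cors = []
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                if sd[a] == 0 or sd[b] == 0:
                    dropped += 1
                    continue
                cors.append(np.corrcoef(rows[a], rows[b])[0, 1])
        if cors:
            apcs[gi] = float(np.mean(cors))
    if np.all(np.isnan(apcs)):
        raise ValueError("no group has two replicates with defined correlations")
    return ApcResult(group_ids=ids, apc=apcs, n_replicates=counts,
                     n_dropped_pairs=dropped)


def apc_partition(result: ApcResult, threshold: float = 0.5) -> tuple[list, list]:
    """Split groups into high-concordance (APC strictly above the
    threshold) and the rest; groups with undefined APC go to the low side."""
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    high = [g for g, a in zip(result.group_ids, result.apc) if a > threshold]
    low = [g for g, a in zip(result.group_ids, result.apc) if not a > threshold]
    return high, low
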