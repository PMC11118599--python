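"""Seeded synthetic datasets with the structure the benchmarks assume.

Two generators cover the experimental settings end to end, so every stage
is testable without downloading anything:

* :func:`make_blobs` — separable class-conditional Gaussian tables, the
  stand-in for tabular classification benchmarks (census-income-like
  datasets, pretrained image embeddings);
* :func:`make_replicate_expression` — replicate-structured expression
  matrices emulating L1000-style data: a true per-perturbation signature,
  several noisy replicate profiles of it ("level 4"), and their per-group
  mean aggregate ("level 5").  The real pipeline aggregates replicates with
  a moderated z-score (MODZ) weighting; the plain mean used here is a
  declared simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledTable", "ReplicateExpressionSet", "make_blobs",
           "make_replicate_expression"]


@dataclass
class LabeledTable:
    """Feature matrix with class labels and provenance of its generation."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    generator_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class ReplicateExpressionSet:
    """Replicate-grouped expression data.

    ``level4`` holds one row per replicate profile, ``group_of`` maps each
    row to its perturbation group, ``level5`` is the per-group replicate
    mean (one aggregated signature per group, in group order), and
    ``true_signal`` / ``replicate_noise_sd`` retain the generating ground
    truth for evaluation.
    """

    level4: np.ndarray
    group_of: np.ndarray
    level5: np.ndarray
    group_ids: np.ndarray
    true_signal: np.ndarray
    replicate_noise_sd: np.ndarray
    generator_params: dict = field(default_factory=dict)

    def group_noise_sd(self) -> np.ndarray:
        """Mean replicate noise s.d. per group, in ``group_ids`` order."""
        return np.array([
            self.replicate_noise_sd[self.group_of == g].mean() for g in self.group_ids
        ])


def make_blobs(
    n: int,
    d: int = 10,
    n_classes: int = 2,
    separation: float = 4.0,
    seed: int = 0,
) -> LabeledTable:
    """Class-conditional Gaussian blobs, standardized.

    Class means lie ``separation`` apart along random orthogonal directions
    (for two classes, symmetrically at +/- separation/2 along one random
    unit vector) with unit within-class covariance.  Features are
    standardized to zero mean and unit variance after sampling, which
    rescales but does not remove the separation.
    """
    if n < n_classes:
        raise ValueError("need at least one sample per class")
    if n_classes < 2 or d < 1:
        raise ValueError("need n_classes >= 2 and d >= 1")
    if n_classes > d + 1:
        raise ValueError("n_classes must be at most d + 1 for equidistant means")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    if n_classes == 2:
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        means = np.stack([-0.5 * separation * u, 0.5 * separation * u])
    else:
        # random orthonormal directions scaled so all pairwise distances
        # equal `separation`, then centred
        q, _ = np.linalg.qr(rng.standard_normal((d, n_classes)))
        means = (separation / np.sqrt(2.0)) * q.T[:n_classes]
        means -= means.mean(axis=0)
    y = rng.permutation(np.arange(n) % n_classes)
    X = means[y] + rng.standard_normal((n, d))
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    return LabeledTable(
        X=X,
        y=y,
        sample_ids=[f"s{i:05d}" for i in range(n)],
        generator_params={"kind": "blobs", "n": n, "d": d, "n_classes": n_classes,
                          "separation": separation, "seed": seed},
    )


def make_replicate_expression(
    n_groups: int,
    reps_per_group: int = 3,
    n_genes: int = 978,
    signal_sd: float = 1.0,
    noise_sd_range: tuple[float, float] = (0.2, 2.0),
    seed: int = 0,
    signal_rank: int | None | str = "auto",
    contamination: tuple[float, tuple[float, float]] | None = None,
) -> ReplicateExpressionSet:
    """Replicate expression profiles with group-level true signatures.

    Each group draws a true signature with N(0, signal_sd) marginal gene
    effects; each of its replicates observes the signature plus
    N(0, sigma_r) noise, with sigma_r drawn from ``noise_sd_range`` per
    replicate.  The level-5 signature is the replicate mean.  Groups whose
    replicates drew large sigma_r have low replicate concordance (APC) and
    noisy aggregates — the structure a noise-sensitive quality metric is
    supposed to detect.

    By default (``signal_rank="auto"``, i.e. min(20, n_genes)) signatures
    live on a low-dimensional latent
    subspace (signature = latent scores times a fixed loading matrix,
    scaled to the requested marginal s.d.), mimicking the strong gene-gene
    co-expression of real transcriptomic signatures; this is what makes a
    low-dimensional autoencoder able to separate signal from replicate
    noise.  ``signal_rank=None`` draws i.i.d. full-rank signatures instead.

    ``contamination=(fraction, (bad_lo, bad_hi))`` models the failed-assay
    tail seen in real high-throughput data: each *group* is, with the given
    probability, a low-quality experiment whose replicates all draw sigma_r
    from the much larger ``(bad_lo, bad_hi)`` range instead.  Group-level
    failures are the ones that survive replicate aggregation and leave
    garbage aggregated signatures.  Without contamination the noise
    population is homogeneous and removing noisy samples buys little; with
    it, the garbage tail genuinely degrades models trained on unfiltered
    data.
    """
    if n_groups < 1 or n_genes < 1:
        raise ValueError("n_groups and n_genes must be positive")
    if reps_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    lo, hi = noise_sd_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid noise_sd_range ({lo}, {hi})")
    if signal_sd < 0:
        raise ValueError("signal_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if signal_rank == "auto":
        signal_rank = min(20, n_genes)
    if signal_rank is None:
        signal = rng.standard_normal((n_groups, n_genes)) * signal_sd
    else:
        if not 1 <= signal_rank <= n_genes:
            raise ValueError("signal_rank must lie in [1, n_genes]")
        scores = rng.standard_normal((n_groups, signal_rank))
        loadings = rng.standard_normal((signal_rank, n_genes)) / np.sqrt(signal_rank)
        signal = (scores @ loadings) * signal_sd
    n_reps = n_groups * reps_per_group
    group_of = np.repeat(np.arange(n_groups), reps_per_group)
    sigma = rng.uniform(lo, hi, size=n_reps) if hi > lo else np.full(n_reps, lo)
    if contamination is not None:
        frac, (bad_lo, bad_hi) = contamination
        if not 0.0 <= frac <= 1.0 or bad_lo < 0 or bad_hi < bad_lo:
            raise ValueError("contamination must be (fraction in [0,1], (lo, hi))")
        bad = (rng.uniform(size=n_groups) < frac)[group_of]
        sigma = np.where(bad, rng.uniform(bad_lo, bad_hi, size=n_reps), sigma)
    level4 = signal[group_of] + rng.standard_normal((n_reps, n_genes)) * sigma[:, None]
    level5 = level4.reshape(n_groups, reps_per_group, n_genes).mean(axis=1)
    return ReplicateExpressionSet(
        level4=level4,
        group_of=group_of,
        level5=level5,
        group_ids=np.arange(n_groups),
        true_signal=signal,
        replicate_noise_sd=sigma,
        generator_params={
            "kind": "replicate_expression", "n_groups": n_groups,
            "reps_per_group": reps_per_group, "n_genes": n_genes,
            "signal_sd": signal_sd, "noise_sd_range": [lo, hi], "seed": seed,
            "signal_rank": signal_rank, "contamination": contamination,
        },
    )
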