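"""Artificial data-quality defects with retained ground truth.

Two corruption modes are provided for benchmarking valuation methods:

* **label flipping** — a fixed proportion of samples is relabeled, each to a
  class drawn uniformly from the *other* classes (a flipped label is
  guaranteed to differ from the original);
* **per-sample Gaussian feature noise** — each sample draws a noise rate
  phi_i ~ Uniform(low, high) and every feature receives independent
  N(0, phi_i) noise, phi_i acting as the standard deviation, so noisier
  samples have higher-variance perturbations.

Both return the ground truth (binary corruption mask, or the noise-rate
vector) so detection performance can be scored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CorruptionMask", "NoiseRates", "flip_labels", "add_feature_noise"]


@dataclass
class CorruptionMask:
    """Binary ground truth: 1 = corrupted, 0 = untouched."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(int)
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask must be binary")

    def __len__(self) -> int:
        return len(self.mask)


@dataclass
class NoiseRates:
    """Per-sample noise standard deviations and the uniform range they
    were drawn from."""

    rates: np.ndarray
    range: tuple[float, float]

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        lo, hi = self.range
        if np.any(self.rates < lo) or np.any(self.rates > hi):
            raise ValueError("rates fall outside the declared range")

    def __len__(self) -> int:
        return len(self.rates)


def flip_labels(
    y: np.ndarray, proportion: float, n_classes: int | None = None, seed: int = 0
) -> tuple[np.ndarray, CorruptionMask]:
    """Relabel ``round(proportion * n)`` randomly chosen samples.

    Each corrupted label is resampled uniformly from the other
    ``n_classes - 1`` classes, so it always differs from the original.
    Untouched labels are returned unchanged.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion}")
    y = np.asarray(y).astype(int)
    n = len(y)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    if n_classes < 2:
        raise ValueError("need at least two classes to flip labels")
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    rng = np.random.default_rng(seed)
    n_corrupt = int(np.floor(proportion * n + 0.5))  # round half-up
    idx = rng.permutation(n)[:n_corrupt]
    y_out = y.copy()
    # draw from the other classes: offset past the original label
    draws = rng.integers(0, n_classes - 1, size=n_corrupt)
    y_out[idx] = np.where(draws < y[idx], draws, draws + 1)
    mask = np.zeros(n, dtype=int)
    mask[idx] = 1
    return y_out, CorruptionMask(mask)


def add_feature_noise(
    X: np.ndarray, rate_range: tuple[float, float] = (0.0, 1.0), seed: int = 0
) -> tuple[np.ndarray, NoiseRates]:
    """Add sample-specific Gaussian noise to every feature.

    phi_i ~ Uniform(low, high) per sample; the corrupted matrix is
    ``X + E`` with ``E[i, j] ~ N(0, phi_i)`` (phi_i is the standard
    deviation), independent across features.  With ``rate_range=(0, 0)``
    the matrix is returned bitwise unchanged.
    """
    lo, hi = rate_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid rate range ({lo}, {hi})")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    phi = rng.uniform(lo, hi, size=X.shape[0]) if hi > lo else np.full(X.shape[0], lo)
    if hi == 0.0:
        return X.copy(), NoiseRates(phi, rate_range)
    noise = rng.standard_normal(X.shape) * phi[:, None]
    return X + noise, NoiseRates(phi, rate_range)
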