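"""Synthetic Gaussian-mixture benchmarks with known cluster structure.

The generator emulates the cluster geometries the method targets:
K spherical unit-variance Gaussian components whose means are separated
by at least ``separation`` standard deviations (well-separated at 8-10,
overlapping at 2-3), equal component sizes up to a remainder, and an
optional fraction of rows replaced by uniform outliers drawn over an
inflated bounding box (labelled -1).  Ground-truth labels are returned
for evaluation only — the clustering pipeline never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcm import DataMatrix, FcmError

__all__ = ["SyntheticSpec", "generate_gaussian_mixture"]

#: attempts at drawing a mean configuration with the required spacing
_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic mixture draw (component sigma is 1)."""

    K: int
    N: int
    P: int
    separation: float = 8.0
    outlier_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise FcmError("need at least 2 components")
        if self.N < 10 * self.K:
            raise FcmError(f"need N >= 10*K objects, got N={self.N}, K={self.K}")
        if self.P < 1:
            raise FcmError("need at least 1 dimension")
        if self.separation <= 0:
            raise FcmError("separation must be positive")
        if not 0 <= self.outlier_fraction <= 0.2:
            raise FcmError("outlier_fraction must lie in [0, 0.2]")


def _place_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    # box side grows with K^(1/P) so the spacing constraint stays feasible
    side = spec.separation * (2.0 + spec.K ** (1.0 / spec.P))
    for _ in range(_PLACEMENT_RETRIES):
        means = rng.uniform(0.0, side, size=(spec.K, spec.P))
        diffs = means[:, None, :] - means[None, :, :]
        dists = np.linalg.norm(diffs, axis=-1)
        dists[np.diag_indices(spec.K)] = np.inf
        if dists.min() >= spec.separation:
            return means
    raise FcmError(
        f"could not place {spec.K} means at pairwise distance "
        f">= {spec.separation} in {_PLACEMENT_RETRIES} attempts"
    )


def generate_gaussian_mixture(
    spec: SyntheticSpec,
) -> tuple[DataMatrix, np.ndarray]:
    """Draw one mixture; returns (data, labels) with outliers labelled -1."""
    rng = np.random.default_rng(spec.seed)
    means = _place_means(spec, rng)

    sizes = np.full(spec.K, spec.N // spec.K)
    sizes[: spec.N % spec.K] += 1
    labels = np.repeat(np.arange(spec.K), sizes)
    X = means[labels] + rng.standard_normal((spec.N, spec.P))

    n_out = round(spec.outlier_fraction * spec.N)
    if n_out > 0:
        out_rows = rng.choice(spec.N, size=n_out, replace=False)
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        span = hi - lo
        X[out_rows] = rng.uniform(lo - 0.5 * span, hi + 0.5 * span,
                                  size=(n_out, spec.P))
        labels = labels.copy()
        labels[out_rows] = -1

    perm = rng.permutation(spec.N)
    return DataMatrix(X[perm]), labels[perm]
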