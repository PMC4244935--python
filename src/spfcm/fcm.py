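"""Fuzzy c-means engine: distances, membership/prototype updates, objective.

The model: each object ``x_i`` in R^P holds graded memberships ``u_ij`` in
[0, 1] across C clusters, with each row of the partition matrix U summing
to one.  Prototypes are membership-weighted means and memberships are
inverse-distance ratios raised to ``2/(m-1)``, where the fuzzifier ``m > 1``
controls partition softness (m -> 1 approaches hard k-means).  Alternating
the two updates monotonically decreases the weighted within-cluster
sum-of-squares objective

    J(U, B) = sum_j sum_i u_ij^m * ||x_i - beta_j||^2

and the iteration stops once the prototypes stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DataMatrix",
    "Prototypes",
    "PartitionMatrix",
    "FcmConfig",
    "compute_distances",
    "update_memberships",
    "update_prototypes",
    "fcm_objective",
    "fcm_iterate",
]


class FcmError(ValueError):
    """Invalid input or configuration for the fuzzy c-means engine."""


class DegenerateClusterError(FcmError):
    """A cluster carries no membership mass, so its prototype is undefined."""


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise FcmError(f"{name} must be a 2-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise FcmError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class DataMatrix:
    """An N x P feature matrix (rows = objects, columns = features)."""

    values: np.ndarray
    row_ids: Sequence[str] | None = None
    feature_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        arr = _as_float_matrix(self.values, "data matrix")
        if arr.shape[0] < 2:
            raise FcmError("need at least 2 objects")
        if arr.shape[1] < 1:
            raise FcmError("need at least 1 feature")
        object.__setattr__(self, "values", arr)
        if self.row_ids is not None and len(self.row_ids) != arr.shape[0]:
            raise FcmError("row_ids length does not match number of rows")
        if self.feature_names is not None and len(self.feature_names) != arr.shape[1]:
            raise FcmError("feature_names length does not match number of columns")

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Prototypes:
    """C cluster centers in R^P, stacked as a C x P matrix."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_matrix(self.centers, "prototypes")
        if arr.shape[0] < 2:
            raise FcmError("need at least 2 prototypes")
        object.__setattr__(self, "centers", arr)

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]


@dataclass(frozen=True)
class PartitionMatrix:
    """Fuzzy memberships U = [u_ij], N x C, each row summing to one."""

    u: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_matrix(self.u, "partition matrix")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise FcmError("memberships must lie in [0, 1]")
        row_sums = arr.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise FcmError("each membership row must sum to 1")
        object.__setattr__(self, "u", np.clip(arr, 0.0, 1.0))

    @property
    def n_objects(self) -> int:
        return self.u.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.u.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Crisp assignment by maximum membership; ties go to the lowest index."""
        return np.argmax(self.u, axis=1)


@dataclass(frozen=True)
class FcmConfig:
    """Fuzzifier, stabilization tolerance and iteration cap for one FCM run.

    ``tol`` bounds the maximum prototype displacement between sweeps
    (max_j ||beta_j(t) - beta_j(t-1)||); the loop stops once the movement
    falls below it.
    """

    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not self.m > 1.0:
            raise FcmError(f"fuzzifier m must exceed 1, got {self.m}")
        if not self.tol > 0:
            raise FcmError("tol must be positive")
        if self.max_iter < 1:
            raise FcmError("max_iter must be at least 1")


def compute_distances(X: DataMatrix, B: Prototypes) -> np.ndarray:
    """Euclidean distances d_ij = ||x_i - beta_j|| as an N x C matrix."""
    if X.n_features != B.n_features:
        raise FcmError(
            f"dimension mismatch: data has {X.n_features} features, "
            f"prototypes have {B.n_features}"
        )
    return cdist(X.values, B.centers)


def update_memberships(D: np.ndarray, m: float) -> PartitionMatrix:
    """Membership update u_ij = [sum_k (d_ij/d_ik)^(2/(m-1))]^-1.

    Objects at zero distance from one or more prototypes receive full
    membership split equally among the zero-distance clusters (the limit
    of the update as d -> 0), which preserves row-stochasticity.
    """
    if m <= 1.0:
        raise FcmError(f"fuzzifier m must exceed 1, got {m}")
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise FcmError("distance matrix must be 2-D")
    if np.any(D < 0):
        raise FcmError("distances must be nonnegative")

    power = 2.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = np.where(D > 0, D, 1.0) ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)

    # exact-zero rows: limit convention
    zero_rows = np.any(D == 0, axis=1)
    if np.any(zero_rows):
        u[zero_rows] = 0.0
        zmask = (D[zero_rows] == 0).astype(float)
        u[zero_rows] = zmask / zmask.sum(axis=1, keepdims=True)

    # tiny-but-nonzero distances can overflow inv; fall back to the same
    # convention on the minimal-distance entries of any non-finite row
    bad = ~np.all(np.isfinite(u), axis=1)
    if np.any(bad):
        dmin = D[bad].min(axis=1, keepdims=True)
        mask = (D[bad] <= dmin).astype(float)
        u[bad] = mask / mask.sum(axis=1, keepdims=True)

    return PartitionMatrix(u)


def update_prototypes(X: DataMatrix, U: PartitionMatrix, m: float) -> Prototypes:
    """Prototype update: beta_j is the u^m-weighted mean of the data rows."""
    if U.n_objects != X.n_objects:
        raise FcmError("partition matrix and data disagree on N")
    w = U.u ** m
    mass = w.sum(axis=0)
    if np.any(mass <= 0):
        dead = int(np.argmin(mass))
        raise DegenerateClusterError(
            f"cluster {dead} has zero membership mass; prototype undefined"
        )
    centers = (w.T @ X.values) / mass[:, None]
    return Prototypes(centers)


def fcm_objective(X: DataMatrix, B: Prototypes, U: PartitionMatrix, m: float) -> float:
    """The FCM objective J = sum_j sum_i u_ij^m d_ij^2 (nonnegative)."""
    if U.n_clusters != B.n_clusters:
        raise FcmError("partition matrix and prototypes disagree on C")
    D = compute_distances(X, B)
    return float(np.sum(U.u**m * D**2))


def fcm_iterate(
    X: DataMatrix, B0: Prototypes, cfg: FcmConfig
) -> tuple[Prototypes, PartitionMatrix, float]:
    """Alternate membership and prototype updates until the prototypes stabilize.

    Stops when the maximum prototype displacement drops below ``cfg.tol`` or
    after ``cfg.max_iter`` sweeps.  The returned partition is recomputed at
    the final prototypes, so (B, U) is a fixed point of the membership
    update, and J is the objective at that pair.
    """
    B = B0
    for it in range(cfg.max_iter):
        U = update_memberships(compute_distances(X, B), cfg.m)
        B_new = update_prototypes(X, U, cfg.m)
        if not np.all(np.isfinite(B_new.centers)):  # pragma: no cover - defensive
            raise FcmError(f"non-finite prototypes at iteration {it}")
        shift = float(
            np.max(np.linalg.norm(B_new.centers - B.centers, axis=1))
        )
        B = B_new
        if shift < cfg.tol:
            break
    U = update_memberships(compute_distances(X, B), cfg.m)
    J = fcm_objective(X, B, U, cfg.m)
    return B, U, J
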