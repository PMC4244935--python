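"""The SP-FCM outer loop: sweep C downward, prune by cardinality, pick by XB.

Starting from a deliberately overestimated cluster count C_max, each round
(1) stabilizes the current prototypes with particle-swarm search plus FCM
polishing, (2) computes a shadowed-set profile per cluster — an optimal
threshold alpha_j and the cardinality M_j of the elevated band — and the
Xie-Beni index of the stabilized partition, then (3) removes up to
floor(rho * C) clusters whose cardinality falls below epsilon.  When no
cluster is below epsilon the single lowest-cardinality cluster is removed
anyway so the sweep always walks the whole range down to C_min.  The
partition with the smallest Xie-Beni index across the sweep is returned.

Survivors of a removal seed the next round's swarm (one particle carries
the surviving prototypes), which keeps the sweep warm-started, fast and
reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fcm import DataMatrix, FcmConfig, FcmError, PartitionMatrix, Prototypes
from .pso import PsoConfig, pso_fcm_stabilize
from .shadowed import (
    ReductionPolicy,
    optimal_threshold,
    select_clusters_to_remove,
)
from .validity import validity_report

__all__ = [
    "SpfcmConfig",
    "TraceRecord",
    "SpfcmResult",
    "initial_prototypes",
    "remove_clusters",
    "run_spfcm",
]


@dataclass(frozen=True)
class SpfcmConfig:
    """Full configuration of one SP-FCM sweep."""

    c_min: int
    c_max: int
    policy: ReductionPolicy
    fcm: FcmConfig = field(default_factory=FcmConfig)
    pso: PsoConfig = field(default_factory=PsoConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.c_min < self.c_max:
            raise FcmError(
                f"need 2 <= c_min < c_max, got [{self.c_min}, {self.c_max}]"
            )


@dataclass(frozen=True)
class TraceRecord:
    """One sweep step: the stabilized partition at cluster count C."""

    C: int
    xb: float
    db: float
    dunn: float
    J: float
    alphas: tuple[float, ...]
    cardinalities: tuple[int, ...]
    removed: tuple[int, ...]
    B: Prototypes
    U: PartitionMatrix


@dataclass(frozen=True)
class SpfcmResult:
    best_C: int
    best_B: Prototypes
    best_U: PartitionMatrix
    best_xb: float
    trace: tuple[TraceRecord, ...]


def initial_prototypes(X: DataMatrix, c_max: int) -> Prototypes:
    """Exemplar initialization beta_j = x_floor((N/c_max) * j), j = 1..c_max.

    Deterministic stride through the data rows (1-based as conventionally
    written, converted to 0-based internally and clamped into range).
    """
    N = X.n_objects
    if c_max > N:
        raise FcmError(f"c_max={c_max} exceeds N={N}")
    rows = [
        min(max(math.floor(N / c_max * j), 1), N) - 1 for j in range(1, c_max + 1)
    ]
    return Prototypes(X.values[rows].copy())


def remove_clusters(
    B: Prototypes, U: PartitionMatrix, idx: list[int]
) -> tuple[Prototypes, PartitionMatrix]:
    """Drop the listed clusters and renormalize each membership row.

    Rows whose surviving membership sums to zero get uniform membership
    over the survivors.
    """
    idx = sorted(set(int(i) for i in idx))
    C = B.n_clusters
    if any(i < 0 or i >= C for i in idx):
        raise FcmError("removal index out of range")
    keep = [j for j in range(C) if j not in idx]
    if len(keep) < 2:
        raise FcmError("removal would leave fewer than 2 clusters")
    u = U.u[:, keep]
    sums = u.sum(axis=1, keepdims=True)
    dead = sums.ravel() <= 0
    if np.any(dead):
        u[dead] = 1.0 / len(keep)
        sums[dead] = 1.0
    u = u / sums
    return Prototypes(B.centers[keep].copy()), PartitionMatrix(u)


def run_spfcm(X: DataMatrix, cfg: SpfcmConfig) -> SpfcmResult:
    """Run the full sweep from c_max down to c_min and select by Xie-Beni."""
    if cfg.c_max > X.n_objects:
        raise FcmError("c_max exceeds the number of objects")
    if np.all(np.ptp(X.values, axis=0) == 0):
        raise FcmError("degenerate data: all rows identical")

    rng = np.random.default_rng(cfg.seed)
    B = initial_prototypes(X, cfg.c_max)
    C = cfg.c_max
    trace: list[TraceRecord] = []

    while True:
        B, U, J = pso_fcm_stabilize(X, C, cfg.pso, cfg.fcm, B_seed=B, rng=rng)
        profiles = [optimal_threshold(U.u[:, j]) for j in range(C)]
        M = [p.cardinality for p in profiles]
        report = validity_report(X, B, U)

        if C > cfg.c_min:
            removals = select_clusters_to_remove(M, cfg.policy)
            max_removable = C - cfg.c_min
            if len(removals) > max_removable:
                removals = sorted(
                    sorted(removals, key=lambda j: (M[j], j))[:max_removable]
                )
            if not removals:
                # forced decrement keeps the sweep walking toward c_min
                removals = [int(np.argmin(M))]
        else:
            removals = []

        trace.append(
            TraceRecord(
                C=C,
                xb=report.xb,
                db=report.db,
                dunn=report.dunn,
                J=J,
                alphas=tuple(p.alpha for p in profiles),
                cardinalities=tuple(M),
                removed=tuple(removals),
                B=B,
                U=U,
            )
        )
        if not removals:
            break
        B, U = remove_clusters(B, U, removals)
        C -= len(removals)

    best = min(trace, key=lambda r: r.xb)
    return SpfcmResult(
        best_C=best.C, best_B=best.B, best_U=best.U, best_xb=best.xb,
        trace=tuple(trace),
    )
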