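"""Shadowed-set thresholding of fuzzy membership columns.

A shadowed set turns one column of a fuzzy partition into a three-way
approximation: memberships at or below a threshold ``alpha`` are reduced
to zero (excluded), memberships at or above ``u_max - alpha`` are elevated
(core), and everything strictly between forms the shadow.  The threshold
is not user-chosen: it minimizes the vagueness-balance objective

    O(alpha) = | sum_{u <= alpha} u
                + sum_{u >= u_max - alpha} (u_max - u)
                - card{ u : alpha < u < u_max - alpha } |

so the membership mass wiped out at the tails is compensated by the
shadow created in between.  ``alpha`` is searched over the feasible range
[u_min, (u_min + u_max)/2].

Every term of O(alpha) is a sum over a set-membership condition, so O is
piecewise constant in alpha with breakpoints at the distinct membership
values and at their mirrors ``u_max - u``; the minimum is attained at one
of those breakpoints or a range endpoint, and the optimizer searches
exactly that finite candidate set, with ties broken toward the smallest
alpha (the least aggressive shadow).

The cardinality of a cluster is the count of objects in its elevated
band, card{ u : u >= u_max - alpha }; clusters whose cardinality falls
below a threshold epsilon are candidates for removal, capped at
floor(rho * C) per reduction step (floored at one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShadowedProfile",
    "ReductionPolicy",
    "feasible_threshold_range",
    "balance_objective",
    "optimal_threshold",
    "cluster_cardinality",
    "select_clusters_to_remove",
]


class ShadowedSetError(ValueError):
    pass


@dataclass(frozen=True)
class ShadowedProfile:
    """Optimal threshold and derived quantities for one membership column."""

    alpha: float
    u_max: float
    u_min: float
    cardinality: int
    objective: float


@dataclass(frozen=True)
class ReductionPolicy:
    """Cluster-removal policy: cardinality threshold and attrition rate.

    ``epsilon`` has no universal default — it should scale with the size of
    the smallest cluster worth keeping (10 suits hundreds of objects, 20-30
    suits thousands).  ``rho`` caps the fraction of clusters removable per
    step.
    """

    epsilon: int
    rho: float

    def __post_init__(self) -> None:
        if self.epsilon < 1:
            raise ShadowedSetError("epsilon must be a positive integer")
        if not 0 < self.rho < 1:
            raise ShadowedSetError("attrition rate rho must lie in (0, 1)")


def _check_column(u_col) -> np.ndarray:
    u = np.asarray(u_col, dtype=float).ravel()
    if u.size == 0:
        raise ShadowedSetError("membership column is empty")
    if np.any(u < 0) or np.any(u > 1):
        raise ShadowedSetError("memberships must lie in [0, 1]")
    return u


def feasible_threshold_range(u_col) -> tuple[float, float]:
    """Feasible alpha interval [u_min, (u_min + u_max)/2] for one column."""
    u = _check_column(u_col)
    u_min = float(u.min())
    u_max = float(u.max())
    return u_min, (u_min + u_max) / 2.0


def balance_objective(
    u_col, alpha: float, u_max: float | None = None, elevation: str = "u_max"
) -> float:
    """Vagueness-balance objective O(alpha) for one membership column.

    ``elevation`` selects the elevated-mass convention: ``"u_max"``
    (default) measures elevation shortfall against the column's own
    maximum membership; ``"one"`` measures it against full membership,
    sum_{u >= 1 - alpha} (1 - u), with the shadow bounded by 1 - alpha.
    Boundary memberships (u == alpha, u == upper cut) belong to the
    reduced/elevated sets, not the shadow.
    """
    u = _check_column(u_col)
    if u_max is None:
        u_max = float(u.max())
    lo, hi = float(u.min()), (float(u.min()) + u_max) / 2.0
    if alpha < lo - 1e-12 or alpha > hi + 1e-12:
        raise ShadowedSetError(
            f"alpha={alpha} outside feasible range [{lo}, {hi}]"
        )
    if elevation == "u_max":
        top = u_max
        elevated_gap = u_max - u
    elif elevation == "one":
        top = 1.0
        elevated_gap = 1.0 - u
    else:
        raise ShadowedSetError(f"unknown elevation convention {elevation!r}")
    cut = top - alpha
    reduced = u[u <= alpha].sum()
    elevated = elevated_gap[u >= cut].sum()
    shadow = int(np.count_nonzero((u > alpha) & (u < cut)))
    return float(abs(reduced + elevated - shadow))


def optimal_threshold(u_col, elevation: str = "u_max") -> ShadowedProfile:
    """Minimize O(alpha) over the candidate set of one membership column.

    Candidates are the distinct membership values and their mirrors
    (``top - u``, where the elevation cut crosses a membership) inside the
    feasible range, plus both endpoints; the smallest alpha wins ties.
    """
    u = _check_column(u_col)
    u_min = float(u.min())
    u_max = float(u.max())
    lo, hi = feasible_threshold_range(u)
    top = u_max if elevation == "u_max" else 1.0
    breaks = np.concatenate([u, top - u])
    inside = breaks[(breaks >= lo) & (breaks <= hi)]
    candidates = np.unique(np.concatenate([[lo, hi], inside]))
    best_alpha = None
    best_obj = math.inf
    for alpha in candidates:  # ascending, so strict '<' keeps the smallest
        obj = balance_objective(u, float(alpha), u_max, elevation=elevation)
        if obj < best_obj - 0.0:
            best_obj = obj
            best_alpha = float(alpha)
    card = cluster_cardinality(u, best_alpha, u_max)
    return ShadowedProfile(
        alpha=best_alpha,
        u_max=u_max,
        u_min=u_min,
        cardinality=card,
        objective=best_obj,
    )


def cluster_cardinality(u_col, alpha: float, u_max: float | None = None) -> int:
    """Count of objects in the elevated band, card{ u : u >= u_max - alpha }."""
    u = _check_column(u_col)
    if u_max is None:
        u_max = float(u.max())
    return int(np.count_nonzero(u >= u_max - alpha))


def select_clusters_to_remove(M, policy: ReductionPolicy) -> list[int]:
    """Indices of clusters nominated for removal under the policy.

    Candidates are clusters with cardinality below ``epsilon``; at most
    max(floor(rho * C), 1) of them — those with the lowest cardinality,
    ties to the lower index — are returned, in ascending index order.
    """
    M = np.asarray(M)
    C = M.size
    if C < 2:
        raise ShadowedSetError("need at least 2 clusters")
    candidates = [j for j in range(C) if M[j] < policy.epsilon]
    cap = max(math.floor(policy.rho * C), 1)
    chosen = sorted(candidates, key=lambda j: (M[j], j))[:cap]
    return sorted(chosen)
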