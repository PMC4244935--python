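"""Cluster-validity indices: Xie-Beni (selection), Davies-Bouldin and Dunn.

Xie-Beni is the compactness/separation ratio

    S_XB = J / (N * d_min^2),   d_min = min_{i<j} ||beta_i - beta_j||,

with J the fuzzy objective evaluated at fuzzifier m = 2.0 regardless of
the fuzzifier used to fit the partition.  Smaller is better: compact
clusters shrink J, well-separated prototypes grow d_min.

Davies-Bouldin (lower better) and Dunn (higher better) form the crisp
evaluation panel; they are computed on hard labels obtained by maximum
membership.  DB uses centroid scatter (mean distance to the cluster
centroid) and centroid separation; Dunn uses single-linkage inter-cluster
distance over the maximum cluster diameter.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .fcm import DataMatrix, FcmError, PartitionMatrix, Prototypes, compute_distances

__all__ = ["ValidityReport", "xie_beni", "davies_bouldin", "dunn", "validity_report"]

from dataclasses import dataclass

#: fuzzifier fixed for the Xie-Beni objective, independent of the run fuzzifier
XB_FUZZIFIER = 2.0


@dataclass(frozen=True)
class ValidityReport:
    xb: float
    db: float
    dunn: float
    C: int
    d_min: float


def xie_beni(X: DataMatrix, B: Prototypes, U: PartitionMatrix) -> float:
    """Xie-Beni index S_XB = J / (N * d_min^2); smaller is better."""
    if B.n_clusters < 2:
        raise FcmError("Xie-Beni needs at least 2 prototypes")
    D = compute_distances(X, B)
    J = float(np.sum(U.u**XB_FUZZIFIER * D**2))
    d_min = float(pdist(B.centers).min())
    if d_min == 0.0:
        warnings.warn("coincident prototypes: Xie-Beni undefined, returning inf",
                      stacklevel=2)
        return np.inf
    return J / (X.n_objects * d_min**2)


def _check_labels(X: DataMatrix, labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if labels.shape != (X.n_objects,):
        raise FcmError("labels must have one entry per object")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise FcmError("need at least 2 nonempty clusters")
    return labels, uniq


def davies_bouldin(X: DataMatrix, labels) -> float:
    """Davies-Bouldin index on hard labels; lower is better.

    Per-cluster scatter is the mean Euclidean distance to the centroid;
    the index averages, over clusters, the worst pairwise ratio
    (s_i + s_j) / ||c_i - c_j||.  Coincident centroids make the ratio
    unbounded and return inf with a warning.
    """
    labels, uniq = _check_labels(X, labels)
    centroids = np.stack([X.values[labels == k].mean(axis=0) for k in uniq])
    scatter = np.array(
        [
            np.linalg.norm(X.values[labels == k] - c, axis=1).mean()
            for k, c in zip(uniq, centroids)
        ]
    )
    sep = cdist(centroids, centroids)
    K = uniq.size
    if np.any(sep[~np.eye(K, dtype=bool)] == 0):
        warnings.warn("coincident centroids: Davies-Bouldin unbounded, returning inf",
                      stacklevel=2)
        return np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / sep
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


def dunn(X: DataMatrix, labels) -> float:
    """Dunn index on hard labels; higher is better.

    min single-linkage inter-cluster distance divided by the maximum
    cluster diameter.  All-singleton labelings have zero diameter and
    return inf with a warning.
    """
    labels, uniq = _check_labels(X, labels)
    groups = [X.values[labels == k] for k in uniq]
    max_diam = 0.0
    for g in groups:
        if g.shape[0] > 1:
            max_diam = max(max_diam, float(pdist(g).max()))
    min_sep = min(
        float(cdist(groups[a], groups[b]).min())
        for a in range(len(groups))
        for b in range(a + 1, len(groups))
    )
    if max_diam == 0.0:
        warnings.warn("all clusters are singletons: Dunn unbounded, returning inf",
                      stacklevel=2)
        return np.inf
    return min_sep / max_diam


def validity_report(X: DataMatrix, B: Prototypes, U: PartitionMatrix) -> ValidityReport:
    """Full index panel for one partition (XB plus the crisp DB/Dunn pair).

    DB and Dunn need at least two nonempty hard clusters; when the hard
    labeling collapses they are reported as NaN rather than failing the
    sweep.
    """
    xb = xie_beni(X, B, U)
    d_min = float(pdist(B.centers).min())
    labels = U.hard_labels()
    try:
        db = davies_bouldin(X, labels)
    except FcmError:
        db = float("nan")
    try:
        dn = dunn(X, labels)
    except FcmError:
        dn = float("nan")
    return ValidityReport(xb=xb, db=db, dunn=dn, C=B.n_clusters, d_min=d_min)
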