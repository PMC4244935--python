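"""Particle-swarm search over prototype sets.

Each particle encodes a full candidate prototype set (a C x P matrix) and
moves under inertia plus attraction toward its personal best and the
swarm's global best:

    V(t+1) = w V(t) + c1 r1 (pbest - P(t)) + c2 r2 (gbest - P(t))
    P(t+1) = P(t) + V(t+1)

with r1, r2 fresh uniform scalars per particle per update.  A particle's
fitness is 1/J, the reciprocal of the fuzzy c-means objective evaluated at
the memberships its position induces, so lower J means higher fitness.
After the swarm loop the global best is polished with plain alternating
FCM so the returned partition is a fixed point of the update equations.

Velocities are clamped to +/- the per-feature data range and positions are
clipped to the data bounding box: a prototype outside the convex hull of
the data can never reduce J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fcm import (
    DataMatrix,
    FcmConfig,
    FcmError,
    PartitionMatrix,
    Prototypes,
    compute_distances,
    fcm_iterate,
    fcm_objective,
    update_memberships,
)

__all__ = [
    "Particle",
    "Swarm",
    "PsoConfig",
    "init_swarm",
    "fitness",
    "update_particle",
    "pso_fcm_stabilize",
]

#: fitness reported when a position attains J = 0 (perfect crisp fit)
MAX_FITNESS = np.inf


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class Swarm:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float


@dataclass(frozen=True)
class PsoConfig:
    """Swarm hyper-parameters.

    Defaults are the regime used throughout the experiments this package
    targets: inertia w = 0.72 with c1 = c2 = 1.49, a swarm of L = 20
    particles and T = 50 iterations (T = 80 suits larger, noisier inputs).
    """

    w: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    L: int = 20
    T: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.w < 0 or self.c1 < 0 or self.c2 < 0:
            raise FcmError("w, c1, c2 must be nonnegative")
        if self.L < 2:
            raise FcmError(f"swarm size L must be at least 2, got {self.L}")
        if self.T < 1:
            raise FcmError("iteration count T must be at least 1")


def fitness(X: DataMatrix, position: np.ndarray, m: float) -> float:
    """Fitness F = 1/J of a candidate prototype set (higher is better)."""
    B = Prototypes(np.asarray(position, dtype=float))
    U = update_memberships(compute_distances(X, B), m)
    J = fcm_objective(X, B, U, m)
    if J == 0.0:
        return MAX_FITNESS
    return 1.0 / J


def init_swarm(
    X: DataMatrix,
    C: int,
    cfg: PsoConfig,
    rng: np.random.Generator,
    B_seed: Prototypes | None = None,
) -> Swarm:
    """Build an initial swarm of candidate prototype sets.

    When ``B_seed`` is given the first particle starts there (warm start);
    every other particle starts at C distinct data exemplars sampled
    uniformly.  Velocities start at zero and each personal best is the
    initial position.
    """
    N = X.n_objects
    if C > N:
        raise FcmError(f"cannot place {C} prototypes with only {N} objects")
    if C < 2:
        raise FcmError("C must be at least 2")
    if cfg.L >= N:
        warnings.warn(
            f"swarm size L={cfg.L} is not smaller than N={N}; "
            "particles will repeat exemplar sets",
            stacklevel=2,
        )

    positions: list[np.ndarray] = []
    if B_seed is not None:
        if B_seed.n_clusters != C:
            raise FcmError("B_seed cluster count does not match C")
        positions.append(B_seed.centers.copy())
    while len(positions) < cfg.L:
        idx = rng.choice(N, size=C, replace=False)
        positions.append(X.values[idx].copy())

    particles = []
    for pos in positions:
        particles.append(
            Particle(
                position=pos,
                velocity=np.zeros_like(pos),
                pbest_position=pos.copy(),
                pbest_fitness=-np.inf,
            )
        )
    swarm = Swarm(particles=particles, gbest_position=positions[0].copy(),
                  gbest_fitness=-np.inf)
    return swarm


def _evaluate_and_track(swarm: Swarm, X: DataMatrix, m: float) -> None:
    for p in swarm.particles:
        f = fitness(X, p.position, m)
        if f > p.pbest_fitness:
            p.pbest_fitness = f
            p.pbest_position = p.position.copy()
        if f > swarm.gbest_fitness:
            swarm.gbest_fitness = f
            swarm.gbest_position = p.position.copy()


def update_particle(
    p: Particle,
    gbest: np.ndarray,
    cfg: PsoConfig,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> Particle:
    """One velocity/position step for a single particle (in place).

    ``bounds`` is the (lo, hi) data bounding box per feature; when given,
    velocity components are clamped to +/-(hi - lo) and the new position
    is clipped into the box.
    """
    r1 = rng.random()
    r2 = rng.random()
    v = (
        cfg.w * p.velocity
        + cfg.c1 * r1 * (p.pbest_position - p.position)
        + cfg.c2 * r2 * (gbest - p.position)
    )
    if bounds is not None:
        lo, hi = bounds
        vmax = hi - lo
        v = np.clip(v, -vmax, vmax)
    pos = p.position + v
    if bounds is not None:
        pos = np.clip(pos, lo, hi)
    p.velocity = v
    p.position = pos
    return p


def pso_fcm_stabilize(
    X: DataMatrix,
    C: int,
    cfg: PsoConfig,
    fcm_cfg: FcmConfig,
    B_seed: Prototypes | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Prototypes, PartitionMatrix, float]:
    """Swarm search for C prototypes followed by FCM polishing.

    Runs T swarm iterations (evaluate, track personal/global bests, move),
    then refines the global best with alternating FCM until the prototypes
    stabilize.  Returns the polished prototypes, partition, and objective.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    swarm = init_swarm(X, C, cfg, rng, B_seed=B_seed)
    lo = X.values.min(axis=0)
    hi = X.values.max(axis=0)
    _evaluate_and_track(swarm, X, fcm_cfg.m)
    for _ in range(cfg.T):
        for p in swarm.particles:
            update_particle(p, swarm.gbest_position, cfg, rng, bounds=(lo, hi))
        _evaluate_and_track(swarm, X, fcm_cfg.m)
    try:
        B, U, J = fcm_iterate(X, Prototypes(swarm.gbest_position), fcm_cfg)
    except FcmError:
        # gbest with coincident prototypes can starve a cluster during
        # polishing; fall back to the unpolished swarm optimum
        B = Prototypes(swarm.gbest_position)
        U = update_memberships(compute_distances(X, B), fcm_cfg.m)
        J = fcm_objective(X, B, U, fcm_cfg.m)
    return B, U, J
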