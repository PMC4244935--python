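"""Particle-swarm optimizer: update rule, best-tracking, determinism."""

import numpy as np
import pytest

from spfcm.fcm import DataMatrix, FcmConfig, FcmError, Prototypes, fcm_iterate
from spfcm.pso import (
    Particle,
    PsoConfig,
    fitness,
    init_swarm,
    pso_fcm_stabilize,
    update_particle,
)
from spfcm.simulate import SyntheticSpec, generate_gaussian_mixture


def make_particle(pos, vel=None, pbest=None, fit=-np.inf):
    pos = np.asarray(pos, dtype=float)
    return Particle(
        position=pos.copy(),
        velocity=np.zeros_like(pos) if vel is None else np.asarray(vel, float),
        pbest_position=pos.copy() if pbest is None else np.asarray(pbest, float),
        pbest_fitness=fit,
    )


# ------------------------------------------------------------------ config


def test_swarm_size_floor():
    with pytest.raises(FcmError, match="swarm size"):
        PsoConfig(L=1)


def test_init_rejects_too_many_clusters(random_data):
    with pytest.raises(FcmError, match="prototypes"):
        init_swarm(random_data, C=random_data.n_objects + 1, cfg=PsoConfig(),
                   rng=np.random.default_rng(0))


def test_init_warns_when_swarm_not_smaller_than_data():
    X = DataMatrix(np.random.default_rng(0).normal(size=(5, 2)))
    with pytest.warns(UserWarning, match="L=20"):
        init_swarm(X, C=2, cfg=PsoConfig(L=20), rng=np.random.default_rng(0))


# -------------------------------------------------------------- init_swarm


def test_init_swarm_deterministic_and_seeded(random_data):
    cfg = PsoConfig(L=5)
    s1 = init_swarm(random_data, 3, cfg, np.random.default_rng(42))
    s2 = init_swarm(random_data, 3, cfg, np.random.default_rng(42))
    for a, b in zip(s1.particles, s2.particles):
        assert np.array_equal(a.position, b.position)
        assert np.all(a.velocity == 0)


def test_init_swarm_carries_seed_prototypes(random_data):
    B_seed = Prototypes(random_data.values[[0, 5, 9]])
    s = init_swarm(random_data, 3, PsoConfig(L=4), np.random.default_rng(1),
                   B_seed=B_seed)
    assert np.array_equal(s.particles[0].position, B_seed.centers)


def test_init_swarm_positions_are_exemplars(random_data):
    s = init_swarm(random_data, 3, PsoConfig(L=4), np.random.default_rng(1))
    rows = {tuple(r) for r in random_data.values}
    for p in s.particles:
        assert all(tuple(r) in rows for r in p.position)


# ----------------------------------------------------------------- fitness


def test_fitness_is_reciprocal_objective(random_data):
    from spfcm.fcm import compute_distances, fcm_objective, update_memberships

    pos = random_data.values[[0, 10]]
    B = Prototypes(pos)
    U = update_memberships(compute_distances(random_data, B), 2.0)
    J = fcm_objective(random_data, B, U, 2.0)
    assert fitness(random_data, pos, 2.0) == pytest.approx(1.0 / J)


def test_fitness_perfect_fit_sentinel():
    X = DataMatrix([[0.0, 0.0], [4.0, 4.0]])
    assert fitness(X, X.values, 2.0) == np.inf


def test_fitness_falls_when_prototype_displaced(two_blobs):
    X, labels = two_blobs
    means = np.stack([X.values[labels == k].mean(axis=0) for k in (0, 1)])
    base = fitness(X, means, 2.0)
    shifted = means.copy()
    shifted[0] += 3.0
    assert fitness(X, shifted, 2.0) < base


# --------------------------------------------------------- particle update


def test_update_all_zero_coefficients_freezes():
    p = make_particle([[1.0, 2.0]], vel=[[0.5, -0.5]])
    cfg = PsoConfig(w=0.0, c1=0.0, c2=0.0)
    update_particle(p, np.array([[9.0, 9.0]]), cfg, np.random.default_rng(0))
    assert np.all(p.velocity == 0)
    assert np.array_equal(p.position, [[1.0, 2.0]])


def test_update_at_both_bests_with_zero_inertia_is_still():
    pos = np.array([[2.0, 3.0]])
    p = make_particle(pos, vel=[[1.0, 1.0]], pbest=pos)
    cfg = PsoConfig(w=0.0, c1=1.49, c2=1.49)
    update_particle(p, pos, cfg, np.random.default_rng(5))
    assert np.all(p.velocity == 0)
    assert np.array_equal(p.position, pos)


def test_update_pure_inertia_advances_by_v0():
    p = make_particle([[0.0]], vel=[[0.25]], pbest=[[0.0]])
    cfg = PsoConfig(w=1.0, c1=0.0, c2=0.0)
    for step in range(1, 4):
        update_particle(p, np.array([[0.0]]), cfg, np.random.default_rng(0))
        assert p.position[0, 0] == pytest.approx(0.25 * step)


def test_velocity_decays_geometrically_without_attraction():
    p = make_particle([[0.0, 0.0]], vel=[[8.0, -8.0]], pbest=[[0.0, 0.0]])
    cfg = PsoConfig(w=0.5, c1=0.0, c2=0.0)
    mags = []
    for _ in range(6):
        update_particle(p, p.pbest_position, cfg, np.random.default_rng(0))
        mags.append(np.abs(p.velocity).max())
    ratios = [b / a for a, b in zip(mags, mags[1:])]
    assert all(r == pytest.approx(0.5) for r in ratios)


def test_update_respects_bounds():
    p = make_particle([[0.9]], vel=[[0.0]], pbest=[[0.9]])
    cfg = PsoConfig(w=0.0, c1=0.0, c2=10.0)
    lo, hi = np.array([0.0]), np.array([1.0])
    update_particle(p, np.array([[100.0]]), cfg, np.random.default_rng(3),
                    bounds=(lo, hi))
    assert 0.0 <= p.position[0, 0] <= 1.0
    assert abs(p.velocity[0, 0]) <= 1.0


# --------------------------------------------------------------- stabilize


def test_stabilize_finds_blob_means(two_blobs):
    X, labels = two_blobs
    means = np.stack([X.values[labels == k].mean(axis=0) for k in (0, 1)])
    B, U, J = pso_fcm_stabilize(X, 2, PsoConfig(T=20), FcmConfig(),
                                rng=np.random.default_rng(0))
    got = B.centers[np.argsort(B.centers[:, 0])]
    want = means[np.argsort(means[:, 0])]
    assert np.allclose(got, want, atol=0.2)
    assert np.allclose(U.u.sum(axis=1), 1.0, atol=1e-9)


def test_stabilize_degenerate_run_contract(random_data):
    B, U, J = pso_fcm_stabilize(random_data, 2, PsoConfig(L=2, T=1),
                                FcmConfig(), rng=np.random.default_rng(0))
    assert U.u.shape == (random_data.n_objects, 2)
    assert np.allclose(U.u.sum(axis=1), 1.0, atol=1e-9)
    assert J >= 0


def test_stabilize_seeded_bit_identical(two_blobs):
    X, _ = two_blobs
    out = []
    for _ in range(2):
        B, U, J = pso_fcm_stabilize(X, 2, PsoConfig(T=10), FcmConfig(),
                                    rng=np.random.default_rng(99))
        out.append((B.centers.copy(), U.u.copy(), J))
    assert np.array_equal(out[0][0], out[1][0])
    assert np.array_equal(out[0][1], out[1][1])
    assert out[0][2] == out[1][2]


def test_gbest_fitness_monotone_over_iterations(two_blobs):
    X, _ = two_blobs
    from spfcm.pso import _evaluate_and_track

    cfg = PsoConfig(L=6, T=15)
    rng = np.random.default_rng(2)
    swarm = init_swarm(X, 2, cfg, rng)
    lo, hi = X.values.min(axis=0), X.values.max(axis=0)
    _evaluate_and_track(swarm, X, 2.0)
    history = [swarm.gbest_fitness]
    pbest_hist = {i: [p.pbest_fitness] for i, p in enumerate(swarm.particles)}
    for _ in range(cfg.T):
        for p in swarm.particles:
            update_particle(p, swarm.gbest_position, cfg, rng, bounds=(lo, hi))
        _evaluate_and_track(swarm, X, 2.0)
        history.append(swarm.gbest_fitness)
        for i, p in enumerate(swarm.particles):
            pbest_hist[i].append(p.pbest_fitness)
    assert all(a <= b for a, b in zip(history, history[1:]))
    for seq in pbest_hist.values():
        assert all(a <= b for a, b in zip(seq, seq[1:]))


def test_pso_no_worse_than_plain_fcm_over_trials():
    """On separable mixtures the swarm-polished J never exceeds plain FCM's."""
    wins = 0
    trials = 20
    for s in range(trials):
        X, _ = generate_gaussian_mixture(
            SyntheticSpec(K=2, N=60, P=2, separation=8.0, seed=500 + s)
        )
        B0 = Prototypes(X.values[[0, 1]])  # adversarial seed: both in one blob
        _, _, J_fcm = fcm_iterate(X, B0, FcmConfig())
        _, _, J_pso = pso_fcm_stabilize(
            X, 2, PsoConfig(L=10, T=15), FcmConfig(), B_seed=B0,
            rng=np.random.default_rng(s),
        )
        if J_pso <= J_fcm + 1e-9:
            wins += 1
    assert wins == trials
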