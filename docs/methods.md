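# Methods

## Model and procedure

`spfcm` clusters a numeric matrix `X ∈ R^{N×P}` with fuzzy *c*-means
(FCM) and estimates the cluster count `C` automatically. Three mechanisms
cooperate:

1. **Alternating FCM.** Memberships
   `u_ij = [Σ_k (d_ij/d_ik)^{2/(m−1)}]^{−1}` and prototypes
   `β_j = Σ_i u_ij^m x_i / Σ_i u_ij^m` are alternated until the maximum
   prototype displacement `max_j ‖β_j(t) − β_j(t−1)‖` falls below `tol`.
   Each full sweep weakly decreases the objective
   `J = Σ_j Σ_i u_ij^m d_ij²`, which the tests assert within 1e-9.
   Objects at distance zero from one or more prototypes receive full
   membership split equally among the zero-distance clusters — the limit
   of the update, preserving row-stochasticity and continuity.

2. **Particle-swarm stabilization.** For a fixed `C`, a swarm of `L`
   candidate prototype sets is evolved for `T` iterations under
   `V ← wV + c1 r1 (pbest − P) + c2 r2 (gbest − P)`, `P ← P + V`, with
   fitness `1/J` (sentinel `inf` at `J = 0`). `r1, r2` are scalar draws
   per particle per update — the literal reading of the update rule.
   Velocities are clamped to ± the per-feature data range and positions
   clipped to the data bounding box, since a prototype outside the hull
   can never reduce `J`; both are standard swarm hygiene and give
   testable bounds. No label alignment is attempted between particles
   (each particle is a complete candidate solution); this is a known
   caveat of swarm clustering and is mitigated by the final FCM polish,
   which makes the returned `(B, U)` a fixed point of the update
   equations. With `c1 = c2 = 0` and `w < 1` velocities decay
   geometrically — a property test.

3. **Shadowed-set reduction and Xie-Beni selection.** Per membership
   column, the threshold `α_j` minimizes the vagueness balance
   `O(α) = |Σ_{u≤α} u + Σ_{u≥u_max−α}(u_max − u) − card{α < u < u_max−α}|`
   over the feasible range `[u_min, (u_min+u_max)/2]`. Every term is a
   sum over a set condition, so `O` is piecewise constant with
   breakpoints at the distinct membership values **and their mirrors**
   `u_max − u`; the optimizer enumerates exactly that finite set (plus
   the endpoints), which a 1000-point grid oracle confirms. Ties go to
   the smallest `α` (narrowest shadow). The elevated-band cardinality
   `M_j = card{u ≥ u_max − α_j}` drives pruning: clusters with
   `M_j < ε` are candidates, at most `max(⌊ρ·C⌋, 1)` of the
   lowest-cardinality candidates are removed per round, and removals are
   additionally capped so at least `c_min` clusters survive. When no
   cluster falls below `ε`, the single lowest-cardinality cluster is
   removed anyway, so the sweep always visits a strictly decreasing
   sequence of `C` values down to `c_min` and terminates in at most
   `c_max − c_min + 1` stabilization rounds. Each visited `C` is scored
   with the Xie-Beni index `S_XB = J/(N·d_min²)` **after** stabilization
   and **before** removal — the index must score a converged partition —
   and the trace entry with the smallest `S_XB` is returned.

Membership columns lost to a removal are repaired by renormalizing each
row over the survivors (uniform membership where nothing survives), and
the surviving prototypes warm-start the next round's swarm through its
first particle. Initial prototypes at `C_max` are the deterministic data
exemplars `β_j = x_⌊(N/C_max)·j⌋` (1-based), which makes whole runs
reproducible from a single seed.

### Elevation convention

The discrete balance uses `u_max` — the column's own maximum — as the
elevation target, so `O(α)` is computed from the shortfalls
`u_max − u`. An alternative convention elevates toward full membership 1
(shortfalls `1 − u`, cut at `1 − α`); it is available as
`elevation="one"` on the shadowed-set functions for comparison, but the
`u_max` form is the default because a fuzzy column whose maximum is well
below 1 (common at large `C`, where clusters compete) would otherwise
elevate nothing.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `m` | fuzzifier (> 1) | 2.0 | the conventional choice; also fixed inside `S_XB` regardless of run `m` |
| `tol` | prototype-stabilization threshold | 1e-5 | max per-prototype displacement, scale-free in `C` |
| `max_iter` | FCM sweep cap | 100 | exceeds observed convergence on all test instances |
| `w, c1, c2` | swarm inertia / attractions | 0.72, 1.49, 1.49 | the standard constriction-like regime |
| `L, T` | swarm size / iterations | 20, 50 | `T = 80` for large, noisy matrices |
| `ε` | cardinality threshold | required | ~10 for hundreds of objects; 20–30 for thousands |
| `ρ` | attrition rate in (0,1) | required | cap `⌊ρC⌋` per round (floored at 1); 0.1 small data, 0.01–0.08 large |
| `c_min, c_max` | sweep range | — | overestimate `c_max`; rule of thumb `C ≤ √N` |
| `standardize` | z-score features | off | exposed on reader and CLI; no scaling is applied silently |

`ε` and `ρ` are required on the CLI precisely because no single value
suits all data sizes: too small an `ε` stalls the reduction, too large
an `ε` (unchecked by `ρ`) collapses it.

## Validity indices

Xie-Beni is the selection criterion. Davies-Bouldin (lower better) and
Dunn (higher better) are reported alongside, computed on hard labels
obtained by maximum membership (ties to the lowest cluster index):
centroid scatter/separation for DB, single-linkage inter-cluster
distance over maximum cluster diameter for Dunn. Degenerate geometry is
reported with `inf` sentinels and a warning (coincident prototypes or
centroids, all-singleton labelings) rather than raised mid-sweep. The DB
implementation is cross-checked against an independent reference
implementation in the test suite.

## Synthetic benchmarks

`generate_gaussian_mixture` draws `K` spherical unit-σ Gaussian
components with means placed uniformly at random subject to a pairwise
separation of at least `separation`·σ (rejection sampling, 200
attempts), component sizes equal up to a remainder, and an optional
fraction of rows replaced by uniform draws over a 2×-inflated bounding
box (labelled −1). Defaults model the study conditions used throughout
the tests: well-separated structure at separation 8–10, `N = 100K`. What
it deliberately does **not** emulate: anisotropic or unequal-variance
components, correlated features, heavy-tailed noise, or class imbalance
— so passing recovery tests demonstrate correct behavior on
well-posed spherical structure, not robustness to those complications.

## Numerical choices

* Distances via `scipy.spatial.distance.cdist`; memberships vectorized
  as `d^{−2/(m−1)}` normalized per row, with exact-zero rows handled by
  the equal-split convention and overflowing rows (subnormal distances)
  by the same convention on their minimal-distance entries.
* A removal that would leave fewer than two clusters is refused.
* Threshold ties broken toward the smallest `α`; removal-candidate ties
  toward the lower cluster index. Trace ties on `S_XB` resolve to the
  earlier (larger-C) entry of `min`.
* All randomness flows from one `numpy.random.Generator` seeded at the
  sweep level; no global RNG is touched, and identical seeds give
  bit-identical sweeps (asserted in tests, including through the CLI).

## Problem sizes in the test suite

The recovery tests use `K ∈ {3,4,5}`, `N = 100K`, `P = 2`, separation
8σ, 20 seeds per `K`, sweeping `[2, 2K+2]` with `ε = 10, ρ = 0.1` —
small enough to run the whole suite on one CPU in a few minutes while
still exercising every stage end to end.

## Known limitations

* The Xie-Beni criterion at `m = 2` has a documented preference for
  coarse partitions on data whose true groups overlap: on the classic
  Iris and Wine matrices the converged two-cluster partition scores a
  lower `S_XB` than the three-cluster one (Iris: ≈ 0.054 vs ≈ 0.137 at
  the FCM fixed points, raw features; standardizing does not change the
  ordering), so the sweep selects `C = 2` there. The structural-recovery
  expectations of 3 for those benchmarks are kept in the acceptance
  tests and fail honestly; on well-separated mixtures the selection is
  reliable (≥ 90% recovery in the tests).
* Swarm search adds robustness to bad initializations, not a global
  optimality guarantee.
* Features are used as given; whether to standardize is the analyst's
  call (`--standardize`).
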