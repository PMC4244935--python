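# spfcm

Fuzzy *c*-means clustering with swarm-optimized prototypes, shadowed-set
cluster pruning, and automatic selection of the number of clusters.

## The problem

Classical fuzzy *c*-means (FCM) asks the analyst to fix the cluster count
*C* in advance and is sensitive to its initial prototypes — two chronic
nuisances when clustering gene-expression profiles or any numeric feature
matrix whose group structure is unknown and whose cluster boundaries
overlap. `spfcm` addresses both at once:

* **FCM core.** For data `X = {x_1..x_N} ⊂ R^P`, prototypes
  `B = {β_1..β_C}` and memberships `U = [u_ij]` (rows summing to 1), it
  alternates the standard update equations minimizing

  `J(U, B) = Σ_j Σ_i u_ij^m ‖x_i − β_j‖²`,  fuzzifier `m > 1` (default 2.0).

* **Particle-swarm search (PSO).** Each particle is a full candidate
  prototype set scored by fitness `F = 1/J`; particles move under inertia
  `w` plus attraction toward personal and global bests (`c1`, `c2`),
  escaping the local minima plain FCM falls into. The global best is then
  polished by FCM so the returned partition is a fixed point of the
  update equations.

* **Shadowed-set pruning.** Each membership column is split three ways by
  a threshold `α_j` chosen to balance the membership mass wiped out at
  the tails against the shadow created in between
  (`α_j = argmin O(α)` over `[u_min, (u_min+u_max)/2]`). The cluster's
  cardinality `M_j = card{u_ij ≥ u_jmax − α_j}` counts its core; clusters
  with `M_j < ε` are candidates for removal, at most `⌊ρ·C⌋` (≥ 1) per
  step.

* **Automatic C.** Starting from an overestimated `C_max`, the sweep
  stabilizes, scores each visited partition with the Xie-Beni index
  `S_XB = J / (N · d_min²)` and walks down to `C_min`; the partition with
  the smallest `S_XB` wins. Davies-Bouldin and Dunn indices are computed
  alongside as an evaluation panel.

## Worked example

```python
from spfcm import SPFCM, SyntheticSpec, generate_gaussian_mixture

X, truth = generate_gaussian_mixture(
    SyntheticSpec(K=4, N=400, P=2, separation=10.0, seed=1))
res = SPFCM(X.values, c_min=2, c_max=10, epsilon=10, rho=0.1).fit(seed=3)
print(res.summary())
```

prints (abridged):

```
SP-FCM clustering results
========================================
objects, features      400, 2
C range swept          [2, 10]
selected C             4
Xie-Beni at selection  0.008551
cluster sizes (hard)   [100, 100, 100, 100]

validity trace (lower XB is better):
  C       xb     db    dunn         J  n_removed
 10   0.3408  1.014 0.009511     261.7          1
  ...
  4 0.008551 0.1409    1.491     751.7          1
  3  0.06062 0.3781   0.7327      9887          1
  2   0.1208 0.7547   0.6728 2.765e+04          0
```

The sweep visited every C from 10 down to 2, and the Xie-Beni index is
two orders of magnitude smaller at C = 4 — the true component count —
than anywhere else; the hard partition recovers the four blobs of 100
points each. `res.save("out/")` writes the membership table (with
core/shadow/excluded status per object), prototypes, the trace above and
a YAML manifest from which the run can be reproduced bit-identically.

The same analysis from the shell:

```sh
spfcm simulate --k 4 --n 400 --p 2 --sep 10 --seed 1 --out sim.csv
spfcm run --input sim.csv --cmin 2 --cmax 10 --epsilon 10 --rho 0.1 \
          --seed 3 --out results/
```

`ε` and `ρ` have no universal default: `ε = 10, ρ = 0.1` suits data sets
of a few hundred objects; `ε = 20-30` with `ρ = 0.01-0.08` suits
thousands of objects and larger sweeps (see `docs/methods.md`).

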