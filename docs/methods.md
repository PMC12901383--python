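# Methods

This note documents the models and procedures implemented in `opso`, the
parameter choices that matter, the synthetic data the tests rely on, and the
limitations a user should know before trusting a result.

## The optimizers

**Classical PSO baseline** (`run_pso`).  Velocity
`v ← w·v + c1·r1∘(pbest−x) + c2·r2∘(gbest−x)`, position `x ← x + v`, with
`c1 = c2 = 2.0` and inertia `w` annealed linearly 0.9 → 0.4 — the textbook
configuration for a decreasing-inertia PSO.  `r1, r2` are element-wise
uniform(0,1) vectors drawn fresh per particle per iteration.  Initial
velocities are zero and initial positions uniform in the box; both choices
avoid extra scale parameters.  Out-of-bounds coordinates are absorbed:
clamped to the violated bound with that velocity component zeroed.

**OPSO** (`run_opso`) replaces the bare cognitive/social delta by an
adaptive blend with an "optical" delta (see README for the full chain).
Parameters and defaults:

| symbol | meaning | default |
|---|---|---|
| `C1, C2` | cognitive/social weights in Δ_C | 2.05 |
| `φ` | stability parameter of the constriction factor | 2.05 |
| `w` | inertia, linear in t | 0.7 → 0.3 |
| `M_β0` | initial optical mixing ratio, decays linearly to 0 | 0.9 |
| `p` | per-particle reseeding probability | 0.03 |
| `α` | saturation strength in `z/(1+α·z²)` | 1.0 |
| `σ` | phase-noise level, linear in t | 0.1 → 0.01 |
| `A₀` | optical delta gain, annealed `A₀(1−t/t_max)` | 0.5 |

The constriction factor `χ = 2/|2 − φ − √(φ²−4φ)|` has a negative
discriminant at φ = 2.05; the square root is evaluated in the complex domain
and the modulus taken, which gives χ = 1 exactly (|2−2.05−i·1.9994| = 2).
The classical real-arithmetic reading (requiring φ ≥ 4; e.g. χ(4.1) =
0.7298) is available via `chi_mode="real"`.

The mixing matrix `W_opt` is the first D rows of a Haar-random 3D×3D
unitary, drawn once per run from the run's seed (one fixed "device" shared
by all particles; periodic refresh is available).  Rows are orthonormal, so
the mixing is non-expansive; together with `|z/(1+α|z|²)| ≤ |z|` this bounds
the optical delta by the annealing gain — the operator can perturb but not
destabilize the swarm.

**Units of the optical delta.**  `Δ_opt = A(t)·Re(z_nl)` operates on the
scale of the unit-normalized state, independent of the box size
(`delta_units="normalized"`, the default, which follows the update rule as
written).  The alternative `delta_units="box"` multiplies by the
per-dimension box width, making the kick proportional to the search range.
We measured the box-scaled variant to be uniformly harmful on wide boxes
(on the ±16384 inverse-Hilbert problem it triples the final error: the early
kicks are ~30 % of the search range and the swarm cannot contract until the
annealing has nearly finished), so it is an option, not the default.

**Randomness protocol.**  One PCG64 generator per run; draw order is fixed
(r1, r2 blocks, then phase noise if the optical path is enabled, then reseed
draws if p > 0).  With `mbeta0 = 0` the optical path consumes no randomness
at all, so an OPSO run is draw-for-draw — and therefore bit-for-bit —
identical to a constricted classical PSO; the test suite verifies this
against an independently coded oracle.  Evaluation budget is
`N·(t_max+1)`: one initial sweep plus one evaluation per particle per
iteration, identical for both optimizers (built-in objectives are evaluated
batched, which changes nothing about the count).

**Reseeding** redraws a particle's position uniformly and zeroes its
velocity while keeping its personal-best memory, and is never applied to
the particle currently holding the global best, so elitism is preserved and
the best-so-far curve is monotone by construction.

## Benchmarks

CEC2019 F1–F3 are data-free and implemented from the reference-code
conventions, reporting **raw objective values** (no bias shift): F1 is
Storn's Chebyshev fitting objective (D = 9, the degree-8 Chebyshev
polynomial scores exactly 0), F2 the 4×4 inverse-Hilbert objective
`Σ|H·X − I|` (convex; 0 at the exact integer inverse, which lies inside the
±16384 box), F3 the 6-atom Lennard-Jones energy offset by the known minimum
−12.712062 (so 0 is the optimal cluster and ≈12.712 means no atom pair
bound).  F4–F10 are shift/rotation compositions of classic bases and need a
plain-text data file (one shift row, then the rotation matrix); classic test
functions (sphere, Rastrigin, Ackley, Griewank, Weierstrass, Schwefel) are
exposed directly.

**What the benchmark runs do and do not reproduce.**  At the published
scale (population 100, 1000 iterations, 10 seeds) our runs reproduce the
qualitative Lennard-Jones picture — both optimizers descend well below the
"no cluster" level 12.702, OPSO typically reaching 2–6 — but they do not
reproduce two published numbers: the claimed inverse-Hilbert plateau of
17.343 with zero spread (our faithful implementation stalls at a few
hundred with seed-to-seed spread of the same order; the problem is convex
with floor 0, and we verified by LP analysis that no natural reading of the
problem has an attainable floor of 17.343), and the claim that the baseline
plateaus at 12.702 on Lennard-Jones (our baseline is stronger than that —
it binds several atom pairs).  We also do not observe the optical blend
outperforming the baseline on multimodal classics (e.g. Rastrigin D = 10,
matched budgets: OPSO median ≈ 6, baseline ≈ 2, while the constriction core
alone with the optical path off reaches ≈ 1).  The annealed-mixing design
spends most of the budget with the cognitive/social attraction scaled by
1 − M_β(t) ≤ 0.1…1, which delays contraction; users wanting the strongest
pure optimizer in this package should run `OPSOParams(mbeta0=0,
reseed_p=0)`.  `scripts/acceptance.py` recomputes and reports these
quantities honestly rather than forcing published values.

## Feature selection

Wrapper selection optimizes a continuous position in [0,1]^n_features;
`mask[d] = 1` iff `x[d] > 0.5`.  Fitness is
`0.99·(mean CV error) + 0.01·(selected/total)` — the error term dominates
and the ratio term breaks ties toward sparser subsets; an empty mask scores
the worst attainable value 1.0 so the optimizer stays total.  Folds
partition subjects (exactly one row per subject is enforced), are
label-stratified, and are frozen per run so the fitness is a deterministic
function of the mask; masks are cached.  The default classifier inside the
wrapper is 5-nearest-neighbours — the standard light-weight choice for
wrapper fitness on 70-subject tables — and any sklearn classifier can be
substituted.  AUC uses the classifier's positive-class probability (for
k-NN, the positive-neighbour fraction).  The initial swarm always contains
one particle at the all-ones position, so the returned fitness can never be
worse than using every feature.  The optimizer budget for mask search
defaults to 20 particles × 40 iterations, which on 34–450-feature tables is
where we observed the fitness curve flatten; it is a parameter, not a
constant.

`SwarmFeatureSelector` wraps all of this as a scikit-learn
`SelectorMixin` estimator (`fit(X, y, groups=subject_ids)` /
`transform` / `get_support`), so it composes with pipelines and model
selection.

## Synthetic data

`generate_etdd_like` emulates per-subject reading-task feature tables:
70 subjects, exactly balanced classes, unit-variance Gaussian features.
Informative features carry a class-mean shift equal to the standardized
effect size (mimicking the longer fixations, shorter saccades and extra
regressions of affected readers); redundant features are informative
columns plus N(0, 0.5²) noise; the rest is pure noise; the ground-truth
mask ships with the dataset.  `generate_task_suite` emits six datasets with
feature counts (450, 34, 34, 450, 34, 34) and effect sizes (1.5, 1.2, 0.9)
per block — a documented difficulty gradient.  Defaults (effect 1.2, six
informative of 34) make the all-features k-NN error clearly nonzero but
reducible, the regime in which feature selection is worth doing.

What the generator does **not** emulate: feature correlation structure of
real oculomotor summaries beyond the planted linear redundancy,
non-Gaussian/heavy-tailed marginals, label noise, and any within-subject
repeated measures.  Passing recovery tests therefore demonstrate the
machinery (optimization, grouping, leakage-free evaluation), not clinical
performance on real eye-tracking data.

## Rank statistics

`friedman_mean_ranks` ranks algorithms within each dataset row ascending in
the raw metric with midrank ties (so ranks sum to k(k+1)/2 exactly): for a
higher-is-better metric the best algorithm holds rank k, for fitness-like
tables rank 1.  The chi-square statistic uses the standard tie correction
`1 − Σ(t³−t)/(n·k·(k²−1))`; an all-tied table degenerates to p = 1 rather
than an error.  The shipped per-dataset result tables reproduce the full
published rank summary — all 40 mean ranks and all five p-values at printed
precision (printed values are truncated to two decimals, e.g. 3.1667 → 3.16)
— which pins the tie convention.  `nemenyi_posthoc` computes
`CD = q_{α,k}·√(k(k+1)/(6n))` from a shipped critical-value table
(k = 2…20, α ∈ {0.05, 0.10}; the values are the infinite-df studentized
range divided by √2, and the tests cross-check them against
`scipy.stats.studentized_range`).

## Numerical and degenerate-input choices

- Objectives must return finite values; a non-finite value raises an error
  naming the point.  The Lennard-Jones guard returns 1e20 for
  near-coincident atoms instead (finite, so the optimizer can move away).
- `t_max = 0` runs the initial sweep only (empty history, best = initial
  best).
- Degenerate CV folds (single-class training split) are skipped with a
  warning; if all folds degenerate, evaluation errors out.
- Metric-table cells must be complete and numeric; ragged or non-numeric
  tables raise format errors (CLI exit code 3).
- All result files are written atomically (write-then-rename), and every
  CLI output directory contains the materialized configuration and a
  provenance log for exact replay.

## Test-suite problem sizes

Convergence checks use sphere D = 10 (50×300 for the baseline, 100×200 for
OPSO); the full-scale benchmark check and the acceptance script use the
published setting 100×1000 with 10 seeds; feature-selection recovery uses
50 features / 5 informative / effect 1.5 over 10 seeds with the default
20×40 wrapper budget.  These sizes keep the whole suite in the
few-minutes range while exercising every code path at realistic scale.
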