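# Methods

## The search problem

Blind docking asks where on an entire receptor surface a flexible ligand
binds, with no prior pocket. The conformation of the ligand is a point
in an `N`-dimensional design space — three translations of the rigid
root, three rigid-body rotations (stored as a rotation vector), and one
torsion angle per rotatable bond, so `N = 6 + rotatable bonds`. A
stochastic global search over this space alternates Monte Carlo
proposals with quasi-Newton (BFGS) local optimization; local
optimization dominates the cost, so the central engineering question is
*which proposals deserve it*.

## The two-stage significance check

A proposal is worth optimizing only if it lies in an energy well no
earlier descent has explored. The first-order test compares gradients:
a candidate is *significant* against a history point when, for **every**
design variable, the two partial derivatives have opposite signs or one
is zero (`g_c[k] * g_h[k] <= 0` for all `k`). A candidate with an
exactly zero gradient passes trivially — it is itself a stationary
point.

The hybrid check runs this test in two stages:

1. **Global (G)** — up to `P1` end points from the shared archive, among
   those within spatial radius `R` of the candidate, ordered nearer to
   farther by full-`N` Euclidean distance. The first pass accepts.
2. **Individual (I)** — if the global stage neither accepted nor had
   enough near points, the nearest `p2 = P − p1` points of the walker's
   own circular buffer are tested, where `p1` is the number of global
   checks *actually performed* (not `P − P1`).

If no history point at all is available the candidate is accepted by
default, otherwise the search could never start. Defaults derive from
`N`: `P = 4N` total checks, circular capacity `Q = 5N`, `P1 = 1N`,
`R = 5 Å` — e.g. a 4-bond ligand has `N = 10`, tests at most 40 points
among its latest 50, at most 10 of them global.

## History storage

Every visited point enters the proposing walker's circular buffer
(capacity `Q`, oldest evicted). Only *end points* — the output of the
final local-optimization iteration, each the lowest point along the
descent of up to 600 predecessors — enter the shared archive. The
archive is an octree over the spatial search box: leaves split into
eight exactly-tiling children when they exceed `S_MAX = 8` points,
unless any child dimension would drop below `W_MIN = 0.1 Å`, in which
case the leaf over-fills (`W_MIN` outranks `S_MAX`; cells this small
occur exactly where minima accumulate and recursing further buys
nothing). Only the three spatial dimensions are indexed; orientation
and torsions ride along as payload. Queries prune whole cells farther
than `R`, then order survivors by full-`N` distance with ties broken by
insertion order. End points that leave the box (the optimizer is
unconstrained) are clamped for indexing while keeping their true
coordinates. The archive is unbounded; the per-walker buffer is
strictly bounded. A `SynchronizedArchive` wrapper provides the
exclusive-writer / consistent-snapshot contract; under the
deterministic scheduler it degenerates to sequential access.

## The walker loop and scheduling

Each of `E` ("exhaustiveness") walkers repeats, for `s = 1..S`: mutate
the current point (one of: Gaussian translation, small random rotation
composed onto the orientation, or one torsion increment; spatial
coordinates clamped to the box, angles normalized); evaluate; run the
hybrid check. Accepted proposals get an "essential" local optimization
(≤ 300 BFGS iterations), a Metropolis test of the optimized score
against the current score (`T = 1.2` score units), and — if passed — a
second local optimization (≤ 300 iterations) whose end point is
archived, collected as a candidate pose, and becomes the walker's
current point. Rejected proposals skip optimization but still stand or
fall by Metropolis on their raw score: the check saves optimizations,
not moves — without this the chain freezes whenever its neighborhood is
explored.

The step budget is `S = multiplier × (70·(movable_atoms +
10·rotatable_bonds) + 500)` with `multiplier ∈ {1, 2, 4}`; the base is a
documented surrogate (the original heuristic is unpublished), and a
dimensionless landscape uses the floor of 500. Walkers run under a
cooperative round-robin in 1000-step slices with per-walker random
streams spawned from one seed, so results are bit-reproducible and
independent of host parallelism. Final minima from all walkers are
clustered into modes (greedy, best-score-first, 2 Å pose distance —
heavy-atom RMSD for docking objectives, Euclidean distance for
landscapes) and ranked by score.

## Objectives

Scoring is pluggable behind a small contract (score + analytic gradient
+ bounds). Two objectives ship:

* **Gaussian landscapes** — sums of negative Gaussian wells with
  recorded ground truth, optionally textured (below).
* **Toy docking** — a smooth pairwise receptor–ligand potential (Morse
  well: depth 1.0 at 3.5 Å, steep repulsion below ~2.5 Å, C1-switched
  to zero at 8 Å) summed over heavy-atom pairs and composed with the
  conformation map. The gradient is exact: a forward-mode Jacobian is
  propagated through the conformation chain, using the SO(3) right
  Jacobian for the rotation-vector block and Rodrigues derivatives for
  torsion axes (the axes themselves move with upstream transforms).

Translations are displacements of the ligand root centroid from its
input position, so the all-zero point is the identity conformation.
Angle normalization maps torsions into `[−π, π)` component-wise; the
rotation-vector block is normalized as a unit (angle magnitude folded,
axis flipped) because wrapping its components independently would
change the encoded rotation. A sign-preserving `(−2π, 2π)` mode exists
for compatibility. Full-`N` distances mix Å and radians unweighted,
with minimal angular differences on angular components.

## The synthetic battery

The search-quality and trend tests run on twenty seeded two-well
landscapes emulating a wide blind-docking surface (3 spatial
dimensions): a 75 Å box; a deep and a shallow main well (depths 10 and
6, width 3 Å) separated by ≥ 30 Å — an order of magnitude beyond the
basin width; 250 shallow decoy minima (depths 0.3–1.5, widths 1–2 Å,
kept ≥ 6 Å from the main centers); and a smooth cosine texture
(amplitude 0.25, wavelengths 1–1.5 Å). The texture models the
sub-Ångström interpolation roughness of grid-based scoring functions:
it disperses optimization stop points across basin bottoms with
decorrelated residual gradients. Without it every descent collapses
onto one machine-precision stationary point, and the nearest-ordered
global checks become systematically same-side/same-sign — a degenerate
regime no real docking landscape exhibits. For the same reason the
engine's stop-point gradient tolerance is deliberately coarse
(`1e-3`), emulating iteration-capped optimization fidelity. Ground
truth on textured surfaces is the deepest of a grid of refined starts
around the deep-well center.

Each battery run uses `E = 8`, the ×4 step multiplier (S = 2000 per
walker), and the default check configuration. The hybrid arm is
compared against an individual-buffer-only ablation at the identical
step budget.

What the battery does **not** show: absolute docking accuracy on real
complexes, wall-clock acceleration (all timing quantities here are
step counts or user-supplied measurements), or receptor-dependent
effects — the toy surfaces have no chemistry.

## Trace analytics

For walkers `i ≠ j`, the proximity indicator asks whether `i`'s head at
step `t` lies within `R` (spatial, 5 Å) of any point `j` recorded
before `t`; multiple near points of the same walker count once. The sum
over other walkers divided by `t` is `SoF_it`; the mean over walkers is
`ASoF_t ∈ [0, n]`. Instantaneous semantics (score at `t` divided by
`t`) are the default because they reproduce the canonical three-walker
progression (0, 0.167, 0.222, 0.333); a cumulative reading (running
event count over `t`) is available as an option. G sensitivity is the
fraction of buffered acceptances won at the global stage; decision cost
is the total pairwise checks spent on passed tests in a window.
`asof_sensitivity_correlation` computes the Pearson correlation between
the frame-wise ASoF and G-sensitivity series of a run — the pipeline
for studying how walker proximity drives global-stage success.
Acceleration ratios divide reference by new times (search and overall),
with the overall ratio normalizable by the step base `B ∈ {1, 2, 4}`.

## Known limitations

* **Desk-scale trend compression.** With 8 walkers × 2000 steps the
  shared archive covers the 75 Å box within the first few hundred
  accepted proposals, so the global stage reaches its steady state
  almost immediately and no "loading phase" of near-zero proximity
  exists. The reference setting for the rising proximity, rising
  sensitivity and falling decision cost is ~64 threads over hundreds of
  thousands of steps on a protein surface — a search-to-coverage ratio
  about two orders of magnitude larger. On the twenty-run battery the
  three trend statistics measure flat or slightly reversed (mean
  frame-wise ASoF 0.0027 in the initial segment vs 0.0021 mid-search;
  checks per accepted proposal 5.10 in the first step-quartile vs 5.39
  in the last; windowed G-sensitivity Spearman rho > 0 in 5/20 runs),
  while the search-quality results are clean (the exact global minimum
  is found and ranked first in 20/20 runs; hybrid and individual-only
  median best scores are equal at this budget). The corresponding
  trend acceptance tests are left failing deliberately: this is a scale
  limitation of the desk-sized battery, not a defect of the check logic,
  which is verified exactly against a sequential oracle.
* The toy pair potential has no electrostatics, solvation or receptor
  flexibility; PDBQT support covers the rigid-receptor/flexible-ligand
  subset only.
* The base step formula is a surrogate, not a claim about the original
  tools' schedule; likewise the Metropolis temperature and mutation
  amplitudes are package defaults, configurable but not calibrated to
  any published schedule.
* Full-`N` distances weight Å against radians 1:1, as stated by the
  plain Euclidean ordering rule; no evidence either way exists for the
  original weighting.
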