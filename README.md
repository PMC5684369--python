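# widedock

Blind protein–ligand docking searches the *whole* receptor surface for
binding poses, with no prior pocket. Stochastic search engines struggle
there: a fixed step budget spread over a huge box samples the energy
landscape too thinly. `widedock` implements a multi-walker Monte Carlo +
BFGS search in which walkers share the hard-won end points of their
local optimizations through a spatial octree archive, and a two-stage
gradient-sign *significance check* decides — global shared history
first, then the walker's own — whether a proposed conformation deserves
the expensive optimization at all. The package also ships the search
instrumentation used to study this mechanism: proximity statistics
(ASoF), global-stage sensitivity, and decision-cost analytics.

## The model

A ligand conformation is a point `x ∈ R^N`, `N = 6 + #rotatable bonds`
(3 translations in Å, 3 rotation-vector components, one angle per
rotatable bond). Each of `E` walkers repeats, for `s = 1..S`:

1. **mutate** the current point and evaluate score `f(x)` and gradient
   `∇f(x)`;
2. **check significance**: `x` is worth optimizing iff some nearby
   history point `h` satisfies `∂f/∂x_k(x) · ∂f/∂x_k(h) ≤ 0` for
   *every* design variable `k` — first against up to `P1 = 1N` shared
   end points within `R = 5 Å` (ordered by full-`N` distance), then
   against the nearest `p2 = P − p1` of the walker's own latest
   `Q = 5N` points, with `P = 4N`;
3. if significant: **essential** BFGS (≤ 300 iterations), a
   **Metropolis** test on the optimized score (`T = 1.2`), and on
   acceptance a second BFGS whose **end point** is archived in the
   shared octree (`S_MAX = 8` points per leaf, minimum cell width
   `W_MIN = 0.1 Å`, `W_MIN` wins) and collected as a candidate pose.

Runs are deterministic for a given seed: walkers hold independent
spawned random streams and are scheduled round-robin in 1000-step
frames. Final minima are clustered into modes at 2 Å and ranked by
score. A prediction within 2 Å heavy-atom RMSD of the reference pose
counts as a success.

The proximity statistic driving the analysis: walker `i` scores the
number of *other* walkers whose recorded history lies within 5 Å of its
head at step `t`, divided by `t` (`SoF`); the walker average is `ASoF`.
For three walkers where A passes one history point of C at `t = 2`,
A–B and B–C at `t = 3`, and A–B, B–{A,C}, C–B at `t = 4`, the ASoF
progression is `0, 0.167, 0.222, 0.333`.

## Worked example

Generate a toy receptor/ligand fixture, dock, and analyze the trace:

```sh
widedock make-fixture --kind rigid --seed 7 --out-dir fx
widedock dock --receptor fx/receptor.pdbqt --ligand fx/ligand.pdbqt \
    --center_x 15 --center_y 15 --center_z 15 \
    --size_x 24 --size_y 24 --size_z 24 \
    --exhaustiveness 4 --seed 11 --out poses.pdbqt --trace trace.tsv
widedock analyze-trace trace.tsv --frame-len 500 --out metrics.csv
```

The dock command prints the ranked binding modes (scores in the toy
pair-potential's units, lower is better):

```
mode  score (9 modes)
   1    -56.5248
   2    -23.2274
   3    -23.0136
   ...
```

Mode 1 is the ligand bound inside the pocket — the fixture's reference
pose (translation-grid refined) scores −56.0897, and the search, which
also optimizes orientation, lands marginally below it. The gap to mode
2 (a surface placement near −23) is the pocket's funnel depth.
`metrics.csv` holds one row per 500-step frame with the frame's mean
ASoF, the fraction of acceptances won at the global stage, and the
total pairwise checks spent on accepted proposals:

```
frame,asof,g_sensitivity,decision_cost
1,0.011859710178457158,0.3712480252764613,6805
2,0.003698693199290272,0.27765726681127983,5493
```

Synthetic landscapes work without any files:

```sh
widedock landscape-bench --dim 3 --wells 2 --seed 1 --exhaustiveness 4
```

```
ground-truth minimum score: -8.6216
best found score:           -8.6216
modes found: 9; proposals: 2000; accepted: 383
```

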