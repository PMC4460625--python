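# Methods

## Model

`ppianet` identifies *network biomarkers* — a small set of protein–protein
interactions (edges) plus single genes (nodes) whose joint expression profile
separates sample classes — from two inputs: a non-negative, linear-scale
gene-expression matrix `X (m samples × n genes)` and a binary PPI edge list.

**Interaction affinities.** The activity of the complex formed by interacting
proteins *u* and *v* is approximated through the law of mass action: with
protein concentrations taken proportional to their mRNA levels and a common
(unit) affinity constant, the complex concentration in sample *i* is the
product

    a_ij = x_iu · x_iv        (edge j = {u, v})

Each mapped PPI edge therefore becomes one feature column of an affinity
matrix `A (m × q)`. Single genes enter the feature space as squared
expression `x_ig²`, i.e. the affinity of a gene paired with itself. Putting
nodes on the same quadratic scale as edge products is what lets the
node-weight multiplier λ default to 1. An alternative *differential* edge
feature `a_ij = |x_iu − x_iv|` is implemented purely for comparison.

**Ellipsoid separation LP.** Every class k is represented by an axis-aligned
ellipsoid centred on its per-feature centers (mean by default, median
available). Non-negative per-feature weights `w ∈ [0,1]^{q+n}` — shared
across classes — define the metric; the weighted squared deviation of sample
j from class k's center is `d_jk(w) = Σ_i w_i (f_ji − f̄_ik)²`. The program

    min  Σ_edges w + λ Σ_nodes w + α Σ_k (z1_k − z2_k) + C Σ_{j,k} ξ_jk
    s.t. d_jk(w) ≤ z1_k + ξ_jk          for j in class k
         d_jk(w) ≥ z2_k − ξ_jk          for j not in class k
         0 ≤ z1_k ≤ z2_k,  0 ≤ w ≤ 1,  ξ ≥ 0

asks class members to fall inside the inner radius `z1_k`, all other samples
to fall outside the outer radius `z2_k`, and trades off three goals: few
features (the w terms), a wide inner/outer radius gap per class (α), and a
small total violation budget (C). Because the squared deviations are
precomputed constants, the problem is a linear program: it is solved to
global optimality (HiGHS via `scipy.optimize.linprog`), and the all-zeros
point is always feasible. Features whose optimal weight exceeds a threshold
(default 1e-4) form the biomarker set.

**Evaluation.** Selected features are scored by leave-one-out or stratified
10-fold cross-validated accuracy of a random forest (500 trees, fixed seed),
and the selected gene panel by its *redundancy score*, the mean absolute
Pearson correlation over all N = g(g−1)/2 gene pairs (lower = less
duplicated information). Welch t-test (two classes) and one-way F-test
(multi-class) per-gene rankings provide the conventional single-gene
baselines.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `entropy_threshold` | 1.5 bits | genes whose expression histogram carries less entropy are dropped before feature construction |
| `n_bins` | 10 | equal-width histogram bins over each gene's own [min, max]; entropy is therefore invariant to affine rescaling |
| `lambda` | 1.0 | node-weight multiplier; 1 because squared node features share the edge products' scale |
| `alpha` | 2.0 | reward per unit of inner/outer radius gap, relative to a unit cost per selected feature |
| `C` | 0.1 | penalty per unit of slack; a soft margin that tolerates diffuse classes |
| `weight_threshold` | 1e-4 | minimum optimal weight for a feature to enter the biomarker set; applied identically to edges and nodes, which share the [0,1] scale |
| `center_statistic` | mean | median available for heavy-tailed data |
| `n_trees` | 500 | random-forest size; accuracy is stable well below this, the default simply removes forest-size noise |

α and C are meaningful only relative to the scale of the squared feature
deviations: the feature-sparsity term competes with α·(gap) only when
deviations are roughly O(1)–O(10), i.e. when expression is on a normalized,
unit-median linear scale. On raw intensity scales (hundreds of units) the
gap term dominates every α in the supported grid and the selection stops
being sparse; users should rescale such data (any affine rescaling leaves
the entropy filter and redundancy score unchanged, and gene-wise rescaling
is absorbed by w only within its [0,1] bound).

The package defaults α = 2, C = 0.1 were fixed once by a pilot grid search
on the synthetic generator's default conditions (below), using the package's
own `grid_search` protocol: cells are scored by cross-validated accuracy of
their selection with ties broken toward smaller sets, smaller α, then
smaller C. For new datasets `grid_search` over
α ∈ {0.01, 0.02, 0.1, 0.5, 1, 5, 10} and C ∈ {0.1, 1, 10, 100, 1000} is the
recommended calibration.

**Unbounded corner.** If α > C·(m − m_k) for some class, growing `z2_k`
while paying slack on every outside sample improves the objective forever —
the LP is unbounded. `solve_lp` detects this and raises `UnboundedLPError`
with the remedy (increase C or decrease α); `grid_search` skips such cells.
With the default α = 2, C = 0.1 this requires at least 20 out-of-class
samples per class; smaller studies should pass a larger C explicitly.

## Synthetic data generator

`generate_dataset` emulates a case/control (or multi-subtype) expression
study with known ground truth:

* background expression is i.i.d. lognormal with log-mean `log(base_mean)`
  (default `base_mean = 1`, a normalized intensity scale) and log-sd
  `noise_sd` (default 0.5) — non-negative, right-skewed, like linear-scale
  intensity data;
* `n_planted_edges` (default 10) disjoint gene pairs are "planted": both
  endpoints' means are multiplied by `effect_size` (default 2.0) in the
  edge's active class, so the edge product shifts by `effect_size²` (4×)
  while each single gene shifts only by `effect_size` — pairs discriminate
  more strongly than their member genes;
* the first class is an unperturbed reference; active classes rotate over
  the remaining classes. Planting activity in *every* class (including the
  reference) makes each planted edge improve the other classes' ellipsoids
  while inflating its own class's inner radius by a comparable amount, and
  in the two-class case this cancellation makes part of the ground truth
  structurally unrecoverable for any weighting — which is a property of the
  symmetric design, not of the selector. The case/control design avoids it
  and matches the biology the method targets (disease-activated
  interactions);
* the remaining edges are decoys drawn uniformly over background genes.

With `effect_size = 1` the construction is an exact null. Default sizes are
200 genes, 300 edges, 2 classes × 30 samples.

What the generator does **not** emulate: probe-level artifacts, batch
effects, correlated background co-expression, heavy-tailed outliers, missing
values, or subtype hierarchies. Passing recovery tests on this generator
shows the selector finds jointly shifted pairs against independent lognormal
noise; it does not certify performance on real microarray data, where
background correlation makes planted-edge-style signals harder to isolate.

## Numerical choices

* LP: HiGHS with primal/dual feasibility tolerances of 1e-10; every returned
  solution is re-checked by direct substitution (absolute 1e-8 plus a
  relative term scaled by the row's coefficient magnitudes, so the check is
  meaningful for both O(1) and large-valued data). Non-optimal solver status
  raises — the zero point is always feasible, so infeasibility is a bug.
* LP vertices need not be unique; the selected set is deterministic for a
  fixed solver and method but other solvers may return different, equally
  optimal sets. The solver is pinned in the package for this reason.
* Entropy of a constant gene is 0 (all mass in one bin); a gene with
  min = max never contributes log(0).
* The t/F statistics use a 1e-12 additive guard in denominators so
  zero-variance features yield statistic ≈ 0 / p ≈ 1 instead of NaN;
  rankings sort by ascending p, then descending |statistic|, then gene id,
  and are fully deterministic.
* Zero-variance genes are excluded from the redundancy score (their
  correlation is undefined) with a warning.
* Tab-separated matrices are written with `%.17g`, so write/read round-trips
  are bitwise exact.

## Design choices

* The loader rejects negative values outright rather than shifting them:
  products of log-ratio data are sign-ambiguous, and silently exponentiating
  would hide a modelling decision the user must make.
* Probe collapse (several array probes per gene) is documented as a
  preprocessing step, not implemented: the right collapse rule is
  platform-specific.
* Edge orientation is canonicalized to `(min(u,v), max(u,v))` so duplicate
  detection and output order are deterministic.
* Features are not standardized before the LP; the model consumes raw
  squared deviations and w absorbs per-feature scale within [0, 1].
* Grid search evaluates every (α, C) cell on the same folds and classifier
  seed, so the argmax reflects the selection rather than fold noise. The
  protocol selects parameters by the same cross-validated accuracy it later
  reports, an optimistic-bias risk inherited from the method's design and
  flagged here.
* `scikit-learn`'s random forest stands in for ensemble classifiers used in
  older toolboxes; only statistical behaviour, not bit-for-bit output, is
  comparable across implementations.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at the
generator's default conditions (200 genes, 300 edges, 10 planted, 2 × 30
samples) over 5-seed grids, a 20-permutation null, and 20 random ≤12-variable
LP instances that are verified against a brute-force vertex-enumeration
solver. The shipped checks use forests of 100–200 trees rather than the
500-tree default: out-of-fold accuracy on these feature counts is already
stable at 100 trees, and the smaller forests keep a full run in the minutes
range on one CPU while leaving the statistical conclusions (recovery, null
behaviour, form comparison) well resolved.

## Known limitations

* A feature weight is a single global metric shared by all class ellipsoids;
  signals that would require class-specific metrics are penalized (see the
  generator discussion above).
* The LP grows as (q + n) columns × m·c rows; tens of thousands of edges
  with hundreds of samples remain tractable, but the dense constraint
  matrix is the memory bottleneck.
* With very small classes the default (α, C) corner is unbounded by
  construction; the error message states the fix.
* The redundancy score treats the selected gene panel as a flat set; it does
  not distinguish edge-internal from edge-external correlation.
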