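# Methods

## The model

`graphrf` implements a graph-embedded random forest for binary classification
of expression profiles when a feature-interaction network (protein–protein or
gene–gene) is available. The working assumptions are the usual ones for
network-guided omics analysis: only a small, *connected* sub-graph of features
drives the outcome, and features are statistically dependent on their network
neighbors. A vanilla random forest ignores the second assumption and tends to
select scattered proxies; the graph forest makes neighborhood structure part of
tree construction so that importance mass accumulates on connected modules.

Training has two stages.

**Stage 1 — head-node allocation.** A forest of `n_trees` depth-one trees
("stumps") is fit; each stump is trained on a bootstrap resample with
`ceil(sqrt(p))` random split candidates scored by Gini impurity decrease. The
number of times feature *i* wins the root split, `c_i`, measures how often the
data itself nominates *i* as a strong marginal predictor. Bootstrap resampling
is expressed as multinomial sample weights, which is equivalent for
impurity-based splitting and avoids copying the matrix per stump. A stump whose
resample admits no valid split is redrawn up to 10 times and then dropped with
a warning; in that case the stage-2 budget shrinks accordingly, keeping the
conservation property `sum(c_i) = number of fitted trees`.

**Stage 2 — neighborhood-restricted sub-forests.** For every head node *i* with
`c_i > 0`, a random forest `F_i` of `c_i` trees is fit whose split candidates
are restricted to `Neighbor(i, k)`, the set of features within `k` hops of *i*
in the network, *including i itself* (the head must be available in its own
pool; at `k = 0` every pool is the singleton head). Trees bootstrap and use
`mtry = ceil(sqrt(|pool|))`. Because stage 1 and stage 2 share the budget, the
final model has exactly `n_trees` trees (500 by default), split across
sub-forests in proportion to the head-node counts.

**Importance aggregation.** A length-p vector `I` starts at zero; for each
sub-forest the mean-decrease-in-impurity (Gini) importance is normalized to sum
to one over its pool and added as `I_j += c_i * imp_j^(i)`. Normalizing per
forest keeps sub-forests with very different pool sizes on a comparable scale;
features outside every pool have importance exactly zero, which is the
structural mechanism that confines selection to graph vicinities of the heads.

**Prediction.** The class-1 score of a sample is the tree-count-weighted mean
of the sub-forests' class-1 probabilities (every tree votes with equal weight
overall); the label is class 1 when the score strictly exceeds 0.5, so exact
ties resolve to class 0.

**Baseline.** The comparison arm is a standard Gini random forest with the same
budget (500 trees), depth cap 10 and `mtry = ceil(sqrt(p))`.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_trees` | 500 | total tree budget, shared by both stages; conservation makes "a graph forest with 500 trees" exact |
| `hop` (k) | 2 | pool radius in hops; 2–3 trades locality against pool coverage, 1 is usually too restrictive |
| `max_depth` | 10 | stage-2 depth cap, matching the baseline for a fair comparison; measured as inconsequential for ranking quality (unlimited depth changes hop-3 AUC by <0.005) |
| stump `mtry` | `ceil(sqrt(p))` | standard classification default |
| sub-forest `mtry` | `ceil(sqrt(pool))` | same rule within the restricted pool |

## The synthetic-data generator

The generator emulates a disease-classification study whose signal lives on a
network module:

1. **Graph.** Preferential attachment with kernel `degree^power`, `power=0.5`,
   one edge per new node by default — a tree with a heavy-tailed degree
   distribution (hub degrees 8–20× the mean at p=4000). The
   `edges_per_new_node` parameter is exposed prominently: with values >1 the
   graph acquires cycles and denser predictor sub-graphs.
2. **Covariance.** `Sigma_ij = 0.8^{D_ij}` with `D` the hop-distance matrix;
   the diagonal is exactly 1 and unreachable pairs get 0. On trees this is a
   Gaussian tree correlation and is positive definite; on cyclic graphs a
   one-shot diagonal jitter (1e-8, logged) backs up the Cholesky factorization.
3. **Expression.** `n` i.i.d. rows of `N(0, Sigma)` via the Cholesky factor.
4. **Cores.** Degrees are sorted descending and smoothed with a three-step
   rolling mean `dbar_t`; the change point is the first `t` with
   `(d_{t-1} - d_t) / dbar_t > 0.1`, and all nodes with degree above the
   change-point degree are core candidates. On a regular graph no drop exists
   and the 99th degree percentile is used instead (logged).
5. **Predictor growth.** From one random core (or two cores at distance >= 4,
   each growing toward half of `p0`, alternating), the set S expands in rounds:
   up to `m` uniform frontier neighbors join, then `m` decays by the
   attenuation factor with floor 1. Defaults `m0=10`, `attenuation=0.8` realize
   "at most m per round, attenuated" while guaranteeing termination; if one
   side of a two-core growth exhausts its frontier the other absorbs the
   remainder, and a generation error naming the shortfall is raised when the
   graph cannot supply `p0` connected predictors at all.
6. **Coefficients and outcome.** `|beta_j| ~ U[0.1, 0.8]`, each negated
   independently with probability 0.5 ("some negative" is unquantified; a
   symmetric Bernoulli is the neutral choice). The linear predictor
   `z = X_S beta + beta0` (`beta0 = 0`) maps to labels through either link:
   logistic `P = 1/(e^z + 1)`, `y = I(P > 0.5)` (boundary to 0); or absolute
   `P = |z - mean(z)| + 0.5`. The absolute form exceeds 0.5 almost surely, so a
   literal 0.5 cutoff degenerates to all-ones; the default thresholds `P` at
   its sample median (balanced classes), with the literal rule available via
   `absolute_threshold="fixed"`.

Study-scale defaults are p=4000 features, n=500 samples, true-predictor counts
in 30–210, 7:3 stratified train/test splits.

**What the generator does not emulate.** Real expression is non-Gaussian
(counts, dropout, batch effects), real networks have cycles, cliques and
assortativity that a preferential-attachment tree lacks, and real effect sizes
are not uniform on a fixed band. Passing tests therefore demonstrate that the
method recovers network-structured signal under the stated generative model,
not that it will match any particular real-data benchmark.

## Evaluation conventions

- **Ranking AUC** is the rank-based (Mann–Whitney) AUC of the importance vector
  against the 0/1 true-predictor indicator; ties count one half. It is checked
  in the tests against an independent Mann–Whitney oracle at 1e-12.
- **PR-AUC** is step-wise average precision (no trapezoidal interpolation,
  which is optimistically biased).
- **Top-k selection** breaks importance ties by ascending feature index, making
  every downstream sub-graph report deterministic.
- **Induced sub-graph reports** (density `|E|/(s(s-1)/2)`, component count,
  largest component, average hop distance) average distances only over pairs
  connected *within* the induced sub-graph; disconnected pairs are excluded
  rather than counted as infinite, which keeps the average finite for
  fragmented selections.
- **Benchmark grid.** One dataset per (p0, n_cores, link, replicate) cell,
  seeded by a counter scheme from a master seed so any cell can be re-run in
  isolation; all methods share the identical train/test split; failed
  replicates are recorded in an `error` column, never dropped. Outputs are
  byte-reproducible CSVs.
- **Stability.** R refits of one fixed dataset vary only the fitting seed; the
  report counts per-feature appearances in the R top-k lists and compares the
  union with S and with its one-hop closure.

## Numerical and design choices

- All randomness flows through numpy `SeedSequence` spawning: a config seed
  derives independent substreams per pipeline stage, and experiment seeds
  derive per-replicate streams, so every artifact is bitwise reproducible.
- Distance matrices store unreachable pairs as `inf` (a real sentinel, never a
  large magic number); `0.8^inf = 0` makes the covariance limit automatic.
- Labels are binarized internally with numpy's sorted class order; the larger
  class value is treated as class 1 for scores.
- Degenerate inputs fail loudly: all-constant matrices, single-class labels,
  empty selections, nonpositive log arguments and mismatched alignments raise
  with the offending location.

## Problem sizes used in the shipped experiments

The packaged acceptance run uses the study-scale settings (p=4000, n=500) with
5 replicates for the selection comparison and 20 refits for the stability
experiment; unit and property tests run the same code paths at desk scale
(p=120–800) chosen so the whole suite completes in a few minutes on one CPU.

## Known limitations

- Binary outcomes only; no regression, survival or multiclass targets.
- Unweighted, undirected networks; edge confidences are ignored.
- Mean-decrease-in-impurity importance inherits its known bias toward
  high-cardinality/-variance features; permutation importance is out of scope.
- With `edges_per_new_node=1` the simulated network is a tree, so simulated
  predictor sub-graphs sit near the tree density bound; denser regimes require
  raising that parameter.
- The stability experiment's union-composition statistics are sensitive to the
  (unstated-in-field) expansion and sign parameters of the generator; see the
  defaults above for the conditions this package fixes.
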