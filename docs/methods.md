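# Methods

This note records the models, parameter choices and numerical conventions
behind `csom`, and what the synthetic benchmarks do and do not establish.

## Toroidal SOM

The map is a width × height lattice with periodic boundary conditions;
cell-to-cell distance is Euclidean with per-axis displacement
`min(|δ|, extent − |δ|)`. Weights are initialized i.i.d. uniform on [0, 1)
from a seeded generator. Training is online: each epoch visits the
examples in a fresh seeded permutation, finds the best-matching unit (BMU)
by Euclidean distance in feature space (ties broken toward the smallest
row-major index, which makes every run reproducible), and updates all
neurons within the adaptation radius `r(e)` of the BMU:

    w ← w + α(e) · exp(−d² / (2 (r(e)/2)²)) · (x − w)

Schedules and defaults:

| parameter | default | meaning |
|---|---|---|
| `rounds` | 50 | training epochs |
| `lr_start` → `lr_end` | 2.0 → 0.01 | geometric (exponential) interpolation |
| `radius_start` → `radius_end` | 20 → 1 grid units | linear interpolation |
| grid | 20×20 (benchmarks), 100×100 (CLI default) | lattice extent |

The learning-rate decay form and neighborhood kernel are our choices
(geometric decay and a Gaussian with σ = r/2 are the standard SOM
conventions); only the endpoints are externally given. A starting rate of
2.0 lies outside the contractive range of the update, so the effective rate
is clamped to 1.0 inside the update while the configured value is kept in
the model container verbatim. During the first epochs the clamp makes each
presentation move the BMU exactly onto the example; the configured decay
still controls when the rate drops below 1 and fine convergence begins.

Features are z-scored per feature before training and the scaler is stored
on the grid, so the model is invariant to per-feature unit changes;
zero-variance features get unit scale. Two radius schedules circulate for
the substrate experiment (initial radius 20, and 10 → 1 over 100
iterations); both are expressible through the config and neither is
hard-coded.

## Probability expansion

Occupied cells take the example-count-weighted mean of their examples'
class distributions and are frozen. The fill then proceeds in waves: at
wave k every still-empty cell with at least one filled Moore neighbor
receives the weighted sum of all its filled neighbors' vectors — weight =
example count for occupied sources, 1 for cells filled at earlier waves —
normalized to sum 1. All cells of a wave are committed simultaneously, so
cells of the same wave never feed each other, and the result is invariant
to cell enumeration order and equivariant under torus translations. The
torus is connected, so termination is guaranteed; the wave index is kept on
the output for inspection.

Design choices that were genuinely open: adjacency is 8-connected (Moore),
matching the diagonal transfer of the original scheme; expansion iterates
to a full fill rather than a single pass (a 100×100 map with a thousand
occupied cells cannot be covered in one step); second-generation sources
carry unit weight because expanded cells no longer represent countable
examples.

## Consensus priors

For each of P independently seeded runs (seeds `base .. base+P−1`), each
training example's neighbors — the co-occupants of its BMU cell plus all
examples in the 8 Moore-adjacent cells, itself excluded — are tallied by
label and normalized; the P tallies are averaged. An example with no
neighbors in some run contributes its own label distribution for that run,
so rows always normalize. Multi-label examples contribute a uniform
distribution over their labels wherever a label is counted (tallies and
expansion alike); the dual-substrate case is rare enough that no more
elaborate rule is justified.

The classifier is assembled by training one fresh SOM (seed `base + P`, not
one of the consensus runs), projecting the training set, and expanding with
each example contributing its prior row. When priors are one-hot this
reduces exactly to expansion on raw labels, which is the property the
implementation tests pin down. Priors also shape the frozen occupied-cell
vectors (they are means of prior rows); this is deliberate — an occupied
boundary cell should admit that its occupants are ambiguous.

P = 10 is the default: on the 300-example benchmark the median
per-example max-abs difference between priors at P = 10 and P = 30 is
below 0.01, far under the 0.1 stability band we consider converged.

## Threshold gating

A query's probabilities are read at its BMU cell; the decision is the
argmax class iff its probability is **strictly** greater than t, else the
sentinel `NON_CONCLUSIVE`. The non-conclusive count is therefore
non-decreasing in t and zero at t = 0. Defaults: t = 0.9 for the
substrate-style workflow (heterogeneous data, reliability preferred),
t = 0.5 for the synthetic benchmark comparisons.

## Imbalance handling and metrics

SMOTE draws a seeded-random minority example x and one of its k = 5
nearest same-class neighbors x′ and emits `x + u (x′ − x)`, u ~ U[0, 1];
classes smaller than k + 1 use all available neighbors. Targets default to
balancing every class up to the largest. Undersampling is seeded sampling
without replacement. Both operate on exact-label strata so multi-label
examples are never split across classes.

Non-conclusive predictions are excluded from the confusion matrix and
reported as `pct_out`; accuracy, per-class recall, precision and macro-F
are computed over the conclusive remainder. The multi-class F is the
unweighted mean of per-class F1 (consistent with the recall treatment).
Zero-denominator conventions: recall/precision of an empty class is 0, and
the geometric mean substitutes ε = 1e−12 for zero recalls while flagging
the affected classes, so a collapsed class is visible rather than silently
zeroing the score.

## Descriptor preparation

Correlation pruning scans columns left to right and drops any column whose
|Pearson r| with an already-kept column exceeds 0.9 — absolute value,
because anti-correlated descriptors are equally redundant; the earlier
column wins, making the operation order-preserving and idempotent.
Constant columns (undefined r) are kept with a warning. Sigmoid scaling is
`1/(1+exp(−(x−μ)/σ))` with the training mean and standard deviation, so the
training mean maps to 0.5. The auto-associative reduction is the linear
autoencoder solved in closed form by SVD: top-`n_out` (default 10) right
singular vectors of the centered table, which is Frobenius-optimal among
rank-`n_out` linear maps — no iterative network training is involved. The
bundled descriptor-set name lists (P-gp, MRP1, BCRP, DD17) support column
selection by name; computing descriptor values from structures is out of
scope.

## Validation protocol

Stratified k-fold (default 10) assigns each label-set stratum round-robin
after a seeded shuffle, starting at a seeded offset; strata smaller than k
are spread with a warning. Resampling is applied inside training folds
only — the leakage-free choice, which may depress scores relative to
protocols that resample before splitting. k-NN baselines (k = 5 by
default) vote over the k nearest training examples — Euclidean in raw
space, torus distance between BMU coordinates in SOM space — with
co-distant points included at the boundary and vote ties broken toward the
smallest class index; k-NN is always conclusive. The paired t-test runs on
per-fold mean-recall series; identical series return t = 0, p = 1, while
constant nonzero differences raise an explicit zero-variance error.

## Synthetic benchmark

The generator draws per-class diagonal-covariance Gaussians at exact
counts, covering imbalance ratios from 1:2 to 1:93 (e.g. counts 930 vs 10).
The standard comparison benchmark is 3 classes at 1:1:10 (25/25/250),
unit variance, minority means 3σ from the majority center — clustered but
with genuinely ambiguous boundaries, the regime the consensus machinery
targets. On ten independent draws with 10-fold CV, 20×20 grids, P = 10 and
t = 0.5, the consensus mapper's mean recall matches or beats SOM + k-NN in
8–9 of 10 draws while leaving ~1–2 % of queries non-conclusive.

What this does and does not show: the generator produces isotropic
Gaussian clusters with exact counts and no label noise, feature
correlation structure, or the multi-modal "everything else" class that a
real non-substrate set exhibits. Passing benchmarks therefore validate the
algorithmic machinery (expansion correctness, prior convergence, gating
behavior, the direction of the consensus-vs-k-NN comparison), not absolute
performance on any real descriptor set. Public benchmark tables (wines,
new-thyroid, cars, yeast) are not bundled; `read_table`/`read_keel` load
them once fetched from their repositories.

## Known limitations

- Rectangular toroidal lattices only; no hexagonal or planar maps, no
  batch-SOM training.
- The expansion transfers whole vectors with no distance decay; outputs
  are relative frequencies, not calibrated probabilities.
- Multi-label handling is the uniform-split convention; with more than a
  handful of multi-label examples a dedicated multi-label scheme would be
  preferable.
- Model containers store all arrays as JSON lists: portable and diffable,
  but large for very big maps (a 100×100 × many-class surface is tens of
  megabytes).
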