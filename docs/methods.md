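# Methods

## Model

The catalog of known lncRNA–disease associations is encoded as a binary
matrix `Y` (n lncRNAs × m diseases). The working assumption is that the
true association structure is approximately low-rank: diseases with shared
biology recruit overlapping sets of lncRNAs, so a few latent factors explain
most of the observed links. Prediction proceeds in three stages.

**Features.** `Y = UΣVᵀ` is truncated at rank `e`; lncRNA `i` is embedded
as row `i` of `U_e`, disease `j` as row `j` of `V_e`, and a pair as their
concatenation (width `d = 2e`). Two scalings are available:

* `sqrt_sigma` (default): each block is scaled by `√Σ`, splitting the
  spectrum symmetrically so that the inner product of the two halves
  approximates `y_ij`;
* `raw`: unscaled singular vectors, for the variant that reads the factor
  rows literally as features.

Per-column signs are fixed (largest-magnitude entry of each left singular
vector positive, ties to the first index) so the factorization is
bit-reproducible. If the matrix rank falls below `e`, the trailing singular
values are zero and the corresponding `sqrt_sigma` features vanish; the
feature width stays fixed rather than erroring.

**Classifiers.** Two heads are trained on the same labeled pairs:

* *Boosted CNN.* Real AdaBoost (SAMME.R) with `Q` rounds over a small 1-D
  CNN base learner. The per-sample weight vector `D` starts uniform at
  `1/p`; after round `q` with predicted class probabilities `p_q(x_i)`,
  `D_i ← D_i · exp(−lr · ((K−1)/K) · ỹᵢᵀ log p_q(x_i))` with `K = 2` and the
  coding `ỹ = +1` on the true class, `−1` otherwise, then `D` is
  renormalized to sum 1 (asserted to 1e−9 every round). Probabilities are
  floored at 1e−12 before logs. Prediction sums the per-round log-odds
  contributions `c_k = log o_k − ½(log o_1 + log o_2)`; the hard label is
  the argmax (exact ties resolve to non-association, the conservative call
  when nominating candidates) and the continuous score is the softmax of the
  two sums. Round `q+1`'s network is initialized from round `q`'s trained
  parameters (transfer learning) rather than from scratch.
* *Gradient-boosted trees.* LightGBM (gradient-based one-side sampling and
  exclusive feature bundling). These internals are the published algorithm;
  they are delegated to the `lightgbm` library in deterministic,
  single-threaded mode rather than re-derived. Sanity checks against a
  hand-enumerated depth-1 decision-stump oracle cover the delegation
  boundary.

**Fusion.** `P(x) = α·C(x) + β·F(x)` with `β ≡ 1 − α` (never independently
configurable). `C` is the boosted-CNN *continuous* score — the hard argmax
label cannot be convexly fused, and candidate ranking needs real-valued
probabilities. Endpoints reproduce the single heads' rankings exactly.

## CNN base learner

No architecture is canonical for 64-dimensional embedding vectors; the
smallest network that exercises convolution, pooling and dense softmax
layers is used: conv(16 filters, width 3, ReLU) → max-pool(2) →
conv(32, width 3, ReLU) → global average pool → dense(32, ReLU) →
dense(2, softmax). Convolutions are zero-padded to "same" length so the
network accepts any input width ≥ 2 (toy problems included). Training is
mini-batch SGD with momentum 0.9, batch size 32, step size 0.05, on
weighted cross-entropy; boosting weights are renormalized within each
mini-batch. The network is implemented directly in NumPy (forward and
backward passes); all randomness — initialization (He-scaled normals) and
epoch shuffling — derives from one generator, so training is bit-reproducible
given the seed.

The boosting `learning_rate` (default 0.1) is the SAMME.R shrinkage; the
optimizer step size is a separate knob (`sgd_lr`). Applying the published
"learning rate" to the shrinkage is a design choice: that is the parameter
the boosting update actually exposes, and the optimizer step has no effect
on the aggregation rule.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `e` | 32 | SVD truncation rank; pair width `d = 2e = 64` |
| `scaling` | `sqrt_sigma` | split `Σ` between the factors |
| `Q` (`cnn.n_estimators`) | 100 | boosting rounds |
| `cnn.epochs` | 10 | SGD epochs per round |
| `cnn.learning_rate` | 0.1 | SAMME.R shrinkage |
| `gbm.n_estimators` | 100 | trees |
| `gbm.learning_rate` | 0.1 | tree shrinkage |
| `alpha` | 0.4 | fusion weight of the boosted-CNN head |
| `neg_ratio` | 1.0 | sampled negatives per positive |
| `threshold` | 0.5 | operating point for the four thresholded metrics |

`a = b = e` (symmetric treatment of the two entity types) fixes `e = d/2`.
Training data default to *balanced* sampling — all positives plus an equal
number of unobserved cells drawn uniformly without replacement — because the
catalogs are positive-unlabeled and near-balanced thresholded metrics
otherwise lose meaning; enumerating all `n×m` cells (`all_pairs`) is
retained as an option.

## Cross-validation

Three fivefold schemes: partition lncRNAs (`lncrna`), diseases (`disease`),
or a balanced pair sample (`pair`) into five folds of sizes differing by at
most one. Entity schemes are cold-start: every pair touching a held-out
entity is unseen during training. Per fold the pipeline refits the SVD on
the training-side matrix with the fold's held-out positives zeroed
(`mask=True`, default) so test associations cannot leak through the
features; the unmasked variant (factorize the full matrix once) is retained
for comparison since leakage-free handling of new entities is otherwise
impossible — a fully held-out lncRNA has a zero row and hence a zero
embedding, and its pairs are scored from the disease half alone. Test
negatives are sampled from the held-out side only, at `neg_ratio`, with a
fold-derived seed. Folds whose test side lacks positives or negatives are
skipped with a warning and excluded from the mean ± sd aggregation
(sample sd, ddof = 1).

Metrics: thresholded precision/recall/accuracy/F1 from the confusion matrix
at `score ≥ 0.5`; AUC as the probability a random positive outscores a
random negative (ties ½); AUPR by step interpolation (not trapezoidal, which
is optimistic on PR curves). These are computed via scikit-learn, whose
definitions match, and are cross-checked against brute-force
pairwise/step-integration oracles in the test suite to 1e−9.

The ablation harness evaluates the fusion grid `α ∈ {0, 0.2, 0.4, 0.6,
0.8, 1}` and three single-model baselines (boosted CNN, plain AdaBoost on
decision stumps, LightGBM) on identical folds, features and seeds; heads are
trained once per fold and all rows derive from the cached scores, so the
`α = 0` row equals the tree head exactly.

Candidate discovery trains on the full catalog and, for one disease, ranks
all lncRNAs with no recorded association by fused score (descending, ties by
lncRNA index), truncated to `k = 15` by default.

## Synthetic data

The generator emulates the regime of the public lncRNA–disease catalogs
(order 10²×10² entities, ~5–10% density): nonnegative rank-`r` factors
(Gamma(2,1) entries) form a score matrix that is z-scored, passed through a
logistic with slope 3, and shifted (by bisection) so the mean Bernoulli
probability equals the target density ρ; cells are drawn independently and
each realized cell is flipped with probability η < 0.5. The base draw and
the flips use separate seed streams, so raising η at a fixed seed perturbs
the same underlying matrix. Defaults: 60×80, r = 4, ρ = 0.1, η = 0.

What the generator does **not** emulate: positive-unlabeled curation (its
zeros are true negatives), the heavy-tailed degree distributions of real
catalogs, correlated annotation errors, and any sequence- or
ontology-derived signal. Passing the recovery tests therefore shows the
pipeline recovers planted low-rank structure from sparse binary data at
realistic size and sparsity — not that it attains any particular accuracy on
curated human data.

## Problem sizes and numerical choices

Tests and the acceptance report run the pipeline at a reduced training
profile — `Q = 10` rounds × 3 epochs instead of the published 100 × 10 —
on the 60×80 fixture; this is stated wherever used so the reduced profile
is not mistaken for the method's defaults. Recovery is measured as mean
pair-holdout AUC over 5 seeds at η = 0 and 3 seeds per noisy level
η ∈ {0.1, 0.2, 0.3}, plus a 3-seed label-shuffled null.

Numerical details worth knowing: probability floor 1e−12 before all logs in
the aggregation rule; boosting-weight sum asserted to 1e−9 each round;
orthonormality of singular-vector blocks holds to 1e−8; LightGBM runs with
`deterministic=True, force_row_wise=True, n_jobs=1` so results are exactly
reproducible; all derived seeds are reduced below 2³¹. Degenerate inputs:
an all-zero matrix cannot be factorized (error); single-class training
labels error; a single-class test fold yields NaN ranking metrics and is
skipped in CV aggregation.

## Limitations

* Negative sampling treats unobserved pairs as negatives; some are
  unrecorded true associations, which biases both training and the measured
  metrics (inherent to positive-unlabeled evaluation).
* Under lncRNA/disease hold-out with masked features, a new entity's
  embedding is zero; predictions for its pairs rely entirely on the partner
  entity, which bounds cold-start performance.
* The CNN runs on CPU in NumPy; the published operating point (Q = 100,
  10 epochs) is minutes-scale per fold on typical catalogs, not seconds.
* Fusion weights are fixed, not learned; scores are not calibrated
  probabilities.
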