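# Methods

## Model and procedure

The package classifies compounds as active or inactive from a fused
fingerprint/descriptor matrix, using a four-stage chain:

1. **Featurization.** Each SMILES string yields three blocks, concatenated in
   a fixed order: ECFP6 (Morgan circular fingerprint, radius 3, hashed to
   2048 presence/absence bits), the 167 MACCS keys, and 208 two-dimensional
   physicochemical descriptors, for a fused width of 2423. The descriptor
   block is interpreted as a *fixed ordered list* of 2D descriptors rather
   than another hashed fingerprint: 2423 − 2048 − 167 = 208 matches the
   canonical 2D-descriptor count, and the exact name list ships as a
   versioned data file (`data/rdkit_descriptors_208.txt`) so the width can
   never drift with toolkit upgrades. Non-finite descriptor values are
   replaced by 0 with a warning (keeps the matrix dense and finite for the
   network); an empty or unparsable SMILES is an error, never an all-zero
   row (silent zeros would corrupt a decoy set). The descriptor span is
   z-scored using training-row statistics only (on by default): unscaled
   descriptors such as molecular weight would otherwise dominate the binary
   bits in every distance- or dot-product-based stage.

2. **Forest graph.** A classification random forest (Gini impurity,
   bootstrap, √d feature subsampling, p = 1000 trees by default) is fitted
   to the training matrix. Each fitted tree is converted to a directed graph
   over feature indices: one edge (parent split feature → child split
   feature) for every parent split node and each of its non-leaf children;
   leaves carry no feature. Per-tree edge sets are unioned (plain set union
   — duplicate edges collapse, no weights), then the union is symmetrized
   (A ← A ∨ Aᵀ) and given a unit diagonal. Symmetrization and the diagonal
   are required by the next stage: the adjacency is used as a Hadamard mask
   on a square weight matrix, where direction is meaningless and every
   feature must at least reach its own hidden unit.

3. **Graph-embedded network and GCW importance.** The network has three
   hidden layers: a width-d layer whose weights are masked by A, then two
   dense layers (64 and 16 units by default — a small funnel adequate for
   d ≈ 500–2423 and a few hundred samples), then a 2-class softmax head.
   Hidden activations are ReLU. Training is mini-batch (batch 32)
   cross-entropy with Adam at learning rate 1e-4 for 50 epochs; plain SGD is
   a config option. The mask is enforced exactly: W_in is initialized
   masked, its gradient is masked, and it is re-masked after every update,
   so W_in ⊙ (1 − A) = 0 holds to the bit at all times. Class imbalance
   (1:3) is left unweighted by default, with a `class_weight="balanced"`
   option. Non-finite loss or weights abort training with a diagnostic
   rather than silently producing garbage scores.

   Feature i's importance is the Graph Connection Weights score: the sum of
   absolute masked first-layer weights into and out of unit i, plus the sum
   of absolute weights from unit i into the second hidden layer. The third
   term is implemented **ungated**: a gate on it indexed by the first sum's
   variable cannot be evaluated as written, and the only evaluable
   reindexing (does feature i have any graph connection?) is trivially true
   once the diagonal is set. A `gcw_gated` flag provides that literal
   variant — it counts the third term only for features with at least one
   non-self neighbour — for comparison.

4. **Selection and SVM.** The top k features by score (descending, ties to
   the smaller index) are kept — k = 900 at the full fused width, k = 100 in
   the d = 500 synthetic profile (~20% of width, chosen once). The SVM
   solves the soft-margin kernel dual with a maximal-violating-pair SMO
   solver: gradient maintained incrementally, stopping when the KKT gap
   m(α) − M(α) ≤ tol (default 1e-4), bias from the mean over free support
   vectors (midpoint of the violating pair when none are free). The box
   constraint C (default 1.0) is a deliberate soft-margin extension of the
   hard-margin dual; hard-margin behaviour is recovered with large C, which
   is what the closed-form and QP-oracle tests use. Kernels: linear
   (default), polynomial (x·z + 1)^d, RBF exp(−‖x−z‖²/2σ²), sigmoid
   tanh(k x·z + θ). sgn(0) = +1 so tie behaviour is deterministic.

## Evaluation protocol

Stratified k-fold cross-validation (default 10 folds) with **pooled (micro)
confusion counts** across folds for the headline rates and pooled decision
values for the AUC; per-fold reports are also returned, and the k-sweep
utility reports both pooled and fold-mean aggregations. With
`selection_scope="per_fold"` (the default) the forest, network and selection
are refitted inside each training fold, so no information leaks from the
held-out fold; `"global"` performs one selection pass on the full table
before CV, mimicking a single-pass protocol, and is optimistic by
construction — the test suite demonstrates the leakage direction on null
data, where the effect is unconfounded by real signal (with genuine signal
both scopes saturate and the comparison is noise).

The 70/30 split is stratified with floor allocation to the test set
(floor(0.3·n_c) per class), which at 94 actives / 282 decoys gives exactly
28 test actives and 84 test decoys. Rates render in six-decimal fixed point;
undefined rates (zero denominator, e.g. precision of an all-negative
predictor) are carried as None and rendered blank, never coerced to 0.

## Synthetic data

`generate_planted` emulates the structure of a fused screening table without
any external download: m = 94 actives and 3m = 282 decoys (sampled without
replacement from a 2× candidate pool), d = 500 columns of which
d − 40 are binary fingerprint-like and 40 real descriptor-like, with 20
planted informative columns (binary: Bernoulli 0.6 for actives vs 0.2 for
decoys; background 0.1; real: unit-variance with a +1.0 mean shift for
actives). d = 500 keeps forest + network fits fast while preserving the
features-≫-samples regime; a `full_width()` profile (d = 2423, 208 real
columns) exists for integration tests. The `.null()` design sets all rates
equal and the shift to 0 for calibration checks.

What the generator does **not** emulate: correlated fingerprint bits from
shared substructures, the heavy-tailed and discrete marginals of real 2D
descriptors, property-matched decoys (the realistic decoy service matches
charge/MW, making decoys *harder*), or activity cliffs. Passing tests on
planted data therefore show the machinery is correct and calibrated (signal
is found, null is flat), not that real-screen performance will match.
A dozen public canonical SMILES (flavonoids/phytosterols as actives, common
small molecules as inactives) ship as checksummed fixtures for featurization
round-trips; they are fixtures, not a screening dataset.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` / sklearn
  `random_state`; the pipeline derives per-stage and per-fold seeds from one
  `SeedSequence`, so a (data, config, seed) triple reproduces byte-identical
  JSON reports.
- GEDFN weight init is He-scaled Gaussian; the masked layer's init is masked
  before the first step.
- SMO's pair step is clipped to the box; the curvature denominator is
  floored at 1e-12 (indefinite sigmoid kernels); non-convergence within the
  iteration cap raises with the residual KKT gap.
- Descriptor standardization uses σ→1 for constant columns.
- `select_top_k` is deterministic and idempotent (stable argsort).
- Single-class inputs, fold-without-a-class, width mismatches, k > d, and
  invalid rates all raise early with specific messages.

## Problem sizes used in the shipped checks

The cross-validated checks run the full chain (1000 trees, 50 epochs) on the
d = 500 generator defaults: planted-feature recovery is the median over 5
seeds, and the effect/null AUC medians use 3 seeds each — sizes chosen to
exercise the complete protocol at desk scale. The oracle comparisons
(importance score, graph union, SVM dual) use many small random instances
(100 / 50 / 20), where brute force is exact.

## Known limitations

- The network is a plain NumPy implementation: single-threaded, CPU-only, no
  early stopping or hyperparameter search; at d = 2423 the masked layer holds
  ~5.9M parameters and trains in minutes, not seconds.
- The SMO solver is dense (full Gram matrix): fine to a few thousand
  samples, not beyond.
- The network's own softmax predictions are exposed for diagnostics only;
  the method's final classifier is the SVM stage. Alternative classifiers
  can be slotted into that stage via `ForgeNetSVM(classifier=...)` (any
  scikit-learn-style classifier over the selected columns), but none are
  re-implemented here.
- Multi-class problems, probability calibration and sparse-input paths are
  out of scope.
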