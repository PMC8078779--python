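# Methods

`omixaug` implements a small-cohort pipeline for predicting pathologic tumour
stage (I–IV) from paired DNA-mutation and mRNA-expression profiles.  The core
idea is to fight the sample-starvation of clinical cohorts by *generating*
training samples: one generative adversarial network (GAN) per stage learns
the distribution of that stage's training expression and emits synthetic
samples in proportion to the original stage counts.

## Pipeline

1. **Gene selection from mutations.**  A 100-tree random forest is fitted to
   the binary mutation matrix against the stage labels and genes are ranked by
   mean-decrease-in-impurity importance.  Significance comes from a
   label-permutation null: the forest is refitted `B` times under shuffled
   stage labels (each replicate with its own seed) and the p-value of gene *g*
   is the add-one tail estimate

       p_g = (1 + #{b : imp_g(permuted_b) >= imp_g(observed)}) / (1 + B).

   Genes with `p < 0.004` (strict) are kept, ordered by decreasing importance.
   The permutation construction is one of several ways such a gate can be
   built (out-of-bag statistics would be another); it is assumption-free and
   its p-values are exactly super-uniform under the null, which the test suite
   checks.  With `B` permutations the smallest achievable p-value is
   `1/(B+1)`, so `B >= 250` is required for the default threshold; the config
   default is `B = 1000` and the tests use the resolution-minimal `B = 250`.

2. **Batch adjustment (optional).**  Parametric empirical-Bayes
   location/scale adjustment of the selected-gene expression matrix: per-gene
   standardisation against a batch-free fit, shrinkage of per-batch per-gene
   location (γ) and scale (δ) estimates toward their across-gene priors, and
   back-transformation.  The implementation reproduces the reference ComBat
   algorithm to machine precision (verified against scanpy's port in the test
   suite).  Batch labels are a user input; with a single batch (or none) the
   step is an identity pass.  Stage can optionally be supplied as a protected
   covariate; it is off by default.  Only the parametric variant exists.

3. **Augmentation.**  Four methods, all operating on the selected-gene
   *training* partition only:
   * **GAN (the method under study).**  One generator/discriminator pair per
     stage, each a single-hidden-layer net of 256 units.  The latent space is
     not a standard normal: latent vectors are drawn per gene from
     `Normal(mu_g, sigma_g)` with the mean/SD of the (standardised) training
     data, so latent dimensionality equals the gene count.  Generating
     `fold x n_s` samples per stage preserves the training stage ratio
     exactly — this per-stage construction is what gives generated samples
     their labels.  Training-set variants GAN1/5/20/100 use folds 1, 5, 20
     and 100.  GAN training sets contain generated samples only.
   * **MS.**  Per stage, `n_s` draws of `Normal(mean_g, sd_g / 2)` per gene.
     (No output size is inherent to the method; `n_s` mirrors GAN1.)
   * **SMOTE.**  Classic minority interpolation `x + u (x_nn - x)`,
     `u ~ U(0,1)`, `x_nn` one of the k = 5 nearest same-stage neighbours
     (Euclidean), oversampling every stage to the majority count; originals
     are kept, so a 110/383/152/12 training set becomes 383 x 4 = 1,532.
   * **DA.**  A denoising autoencoder (one 256-unit hidden layer) learns to
     restore window-corrupted samples: copy *j* of a sample zeroes genes
     `[5j, 5j+5)`.  The output is the originals plus one reconstruction per
     corrupted copy — `n*floor(m/5) + n` samples, labels inherited from the
     source sample.  (Emitting the corrupted copies directly, without
     reconstruction, would be the other reading of this baseline; we
     reconstruct.)

4. **Classification.**  Three classifiers behind one interface:
   * **1D-CNN** — conv(20 filters, k=5) → ReLU → maxpool(2) → conv(40, k=5) →
     ReLU → maxpool(2) → dense(64, ReLU) → softmax(4); Adam, batch 32.  Valid
     padding with ceil-mode pooling (a trailing partial window is kept), so
     the minimum input length is 13 genes.  Genes are convolved in selection
     order; the order is semantically arbitrary for expression vectors and is
     recorded on the model so results are reproducible.
   * **DNN** — hidden layers (64, 32, 4), ReLU, softmax head (sklearn
     MLPClassifier; training stops at the epoch cap or on a training-loss
     plateau — there is no validation-based early stopping).
   * **RF** — 100 trees, out-of-bag scoring on, `random_state = 123456`.

5. **Evaluation harness.**  One cycle = fresh stratified 70/30 split →
   variant training set → train → score accuracy and macro-F1 on the
   untouched 30%.  Cycles repeat with seeds `base_seed + r`; aggregates are
   mean ± sd and are recomputable from the per-repeat rows.  Macro averaging
   is used for F1 (classes absent from both truth and prediction are
   excluded); it is the variant that penalises neglect of minority stages.
   Welch's unequal-variance t-test compares per-repeat metric vectors of two
   variants (the runs are independent, hence unpaired); a Friedman test over
   matched repeats is available as a companion.  Test-set hygiene — no test
   sample in any augmenter's or classifier's training input — is asserted on
   every cycle.

   The split is stratified by stage even though a plain random split would be
   simpler: with severely imbalanced cohorts (e.g. 12 stage-IV samples) an
   unstratified 30% test set can miss a stage entirely, leaving macro-F1
   undefined.  Per stage, `round(f * n_s)` samples go to the training side,
   clamped so both partitions keep every stage.

## GAN training recipe

The adversarial objective is the non-saturating binary cross-entropy.  Design
choices that matter, fixed after measuring distribution fidelity on a
two-gene Gaussian stage (yardsticks: per-gene generated means within 3 SE of
training means; two-sample Kolmogorov–Smirnov tests not rejecting at 1%):

* the generator is **residual**: `G(z) = z + MLP(z)` with the output layer
  initialised near zero.  Because the latent already matches the training
  marginals per gene, the generator starts at (approximately) the target
  distribution and adversarial training only has to learn correlations and
  shape corrections.  A plain one-hidden-layer ReLU generator leaves
  piecewise-linear kinks (skew ≈ 1) that a KS test detects reliably;
* two discriminator Adam steps (lr 2e-4) per generator step (lr 1e-4),
  beta1 = 0.5 for both;
* generation uses a Polyak (EMA, decay 0.999) average of the generator
  weights, which removes the adversarial wobble of the final iterates.

Per-gene standardisation is applied before training and inverted on output.
Batch size 32, clamped to the stage size with a warning for tiny stages.
Epochs default to 1000 (the regime the method targets is 900–1100); the
reduced-scale harness tests use 100.  Everything is plain numpy, bit
reproducible for a fixed seed.

## Synthetic cohorts

The generator emulates what the pipeline needs from a stage-annotated tumour
cohort and nothing more: four stages with configurable counts (presets mirror
a balanced design, a severely imbalanced 12/24/29/12 rectal-like cohort and a
110/383/152/12 breast-like one), `n_genes` genes of which `n_informative`
carry signal, optional additive batch structure, Gaussian noise.  Signals are
ordinal: an informative gene's expression is `Normal(s * delta, sd)` for
stage *s* (delta defaults to 1.0 within-stage SD) and its mutation is
`Bernoulli(min(1, q0 * gradient * s))` with `q0 = 0.05` and `gradient = 4`,
i.e. mutation frequencies 0.2/0.4/0.6/0.8 across stages — a strong driver
gradient chosen so that the permutation gate's planted-signal recovery, a
stated property of the default configuration, holds with margin.  By default
the same genes carry both signals (the premise that mutation-selected genes
have stage-relevant expression); `coupled=False` plants disjoint sets to
probe the pipeline when that premise fails.

What the generator does **not** emulate: RNA-seq count statistics (negative
binomial dispersion, library sizes), gene–gene correlation structure,
subtype heterogeneity within stages, or realistic mutation co-occurrence.
Tests passing on these cohorts therefore demonstrate the pipeline's
mechanics and the augmentation effect under clean ordinal signal — not
performance on real tumours.

## Problem sizes used by the test suite

Chosen so the whole suite runs on a single CPU in well under half an hour:
selection tests use `B = 250` permutations (resolution floor for p < 0.004);
the harness benefit test uses the `bench` preset (240 samples, 100 genes, 20
informative — enough selected genes to clear the CNN's 13-gene minimum),
GAN/CNN epochs 100 and 5 repeats; the GAN fidelity test uses the two-gene
toy stage with 500 epochs and 5 seeds.

## Known limitations

* The subsample experiment does not reproduce one qualitative claim of the
  augmentation literature on these synthetic cohorts: between 100% and 30%
  cohort fractions the *augmented* arm's accuracy falls more than the
  un-augmented arm's (augmentation still helps at every fraction).  The
  planted ordinal signal keeps the un-augmented CNN learnable at 50 training
  samples, so its decline is shallow, while the augmented arm starts near its
  ceiling.  This persists with fully converged GANs and is a property of the
  clean synthetic signal, not of the implementation.
* Parametric empirical-Bayes batch adjustment leaves a measurable residual
  batch gap on genes whose variance is inflated by un-modelled biology when
  batches are small (~15 samples/stage) — the reference implementation
  behaves identically.  Supplying the biological covariate, or larger
  batches, restores near-complete removal.
* Permutation p-values refit the forest per replicate; at the default
  `B = 1000` this is the pipeline's slowest step (~2.5 min per cohort of
  240 x 200 on one CPU).
* The 1D-CNN's convolution order over genes is arbitrary; accuracy can shift
  slightly under gene reordering.
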