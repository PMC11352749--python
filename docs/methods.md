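# Methods

## Problem and pipeline

Resting-state fMRI classification of autism spectrum disorder (ASD) versus
healthy controls (HC) from multi-site cohorts faces two structural
obstacles: per-subject scan lengths T vary within and across acquisition
sites, and the natural feature space is large (thousands of region-pair
correlations) while cohorts are small (hundreds of subjects), so
classifiers overfit. The pipeline implemented here addresses both:

1. **Features.** Each subject's T×R matrix of regional BOLD signals is
   reduced to the R×R matrix of pairwise Pearson correlations
   r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²), and the strictly upper
   triangle is flattened (row-major, i<j, 0-based) into a fixed-length
   vector of D = R(R−1)/2 entries — 6670 for the 116-region AAL
   parcellation. This removes the variable time dimension without
   windowing. Zero-variance series get r = 0 (logged), never NaN; the
   diagonal is forced to 1; correlations are used raw (no Fisher z),
   since the downstream models consume bounded [−1, 1] features.
2. **Splits.** All partitions stratify jointly on the (site, class) pair,
   because per-site class counts are wildly unequal and an unstratified
   split can starve a small site. Holdout uses round-half-up test counts
   per stratum with a ≥1-train-member guard (singleton strata go to train
   with a warning); k-fold uses a per-stratum round-robin after a seeded
   shuffle with a random starting fold, so per-stratum fold counts differ
   by ≤1; leave-site-out trains on one site (NYU by default) and tests
   each remaining site separately (CMU excluded by default — too few
   subjects to score).
3. **Augmentation.** A conditional GAN is trained on the *training*
   feature vectors. Generator: class embedded to a 500-dim condition
   vector, concatenated with 500-dim standard-normal noise, hidden widths
   2000→3000→4000→5000 (spectral normalization + batch normalization +
   leaky-ReLU 0.1 each), tanh output of width D. Discriminator: class
   embedded to 500 dims, concatenated with the feature vector, spectrally
   normalized leaky-ReLU layers 4000→2000→1000→500→1 ending in one
   logit. Training alternates one discriminator and one generator update
   per minibatch under the binary-cross-entropy realization of the
   minimax objective; the generator loss is non-saturating by default,
   with the literal minimax form behind a flag. Fake batches reuse the
   real batch's class labels, preserving class balance.
4. **Fidelity oracle.** Because GAN losses say nothing about distribution
   match, a denoising autoencoder (encoder 4000→3000→2000→1000→500,
   decoder 1000→2000→3000→4000→D, batch-norm + ReLU per layer, tanh
   output, Gaussian input corruption σ = 0.1, MSE against the clean
   input) is trained on a stratified 25% subset of the training split.
   During cGAN training the autoencoder's reconstruction error on a
   generated batch is recorded every epoch. The probe batch is generated
   in training mode (batch statistics), matching how generated batches
   actually flow during training; probing with eval-mode running
   statistics instead would measure the cold-start lag of the
   normalization layers rather than the generator. Fidelity is a score,
   not a pass/fail gate — no numeric threshold is defined.
5. **Classifier.** Each subject's vector is one token of width D.
   Multi-head attention (10 heads): per-head projections of width D/h for
   query/key/value, weights softmax(QKᵀ/√d_k), heads concatenated, output
   projection, residual connection from the input, layer normalization.
   With a single token the softmax is over one key and every attention
   weight is exactly 1; this degeneracy is retained deliberately as the
   faithful consequence of one-vector-per-subject input, and an optional
   `tokens=k` mode reshapes the vector into k tokens for non-degenerate
   attention. The block feeds a reduction stack 3000→2000→1000→1 where
   each width-changing layer carries a learned linear projection on its
   skip connection ("skip connections from the previous layer" is
   dimensionally impossible verbatim; a projection is the minimal
   consistent reading) plus layer normalization, ending in one logit with
   ASD as the positive class. The ablation classifier is a plain MLP
   4000→3000→2000→1000→500→50→1 with batch-norm, ReLU and 10% dropout.
   Training concatenates real and synthetic tables, reshuffling per
   epoch; loss is binary cross-entropy on the logit; prediction is
   deterministic (dropout off, normalization frozen) with threshold 0.5.
6. **Evaluation.** Sensitivity = TP/(TP+FN) on ASD, specificity =
   TN/(TN+FP) on HC; zero-denominator metrics are reported as undefined
   flags, never NaN. ROC sweeps all score thresholds (ties grouped) with
   trapezoidal AUC; AUC is cross-checked in the tests against the
   Mann–Whitney probability estimator. Aggregation across folds or sites
   recomputes metrics from *summed* confusion counts — the pooled value
   is count-weighted and in general differs from the mean of per-group
   percentages; the report records this. Recall is emitted as a separate
   column even though it equals sensitivity for a binary positive class,
   because consumers of such tables conventionally expect both.

## Compute core

No GPU tensor framework is used. The models run on a small reverse-mode
autodiff engine over numpy arrays (`fcgan.autodiff`) with a layer library
(`fcgan.nn`) providing linear maps, embeddings, batch/layer normalization,
inverted dropout, spectral normalization and Adam. Design choices:

- Spectral normalization estimates the leading singular value with one
  power-iteration step per training forward pass and treats the estimate
  as a constant during backprop (stop-gradient). The stabilizing property
  — effective weight spectral norm ≤ 1 — holds regardless, and is
  asserted in the tests to 1+1e-3.
- Batch normalization keeps running statistics (momentum 0.1) for
  evaluation mode; batches of size 1 fall back to running statistics.
- All initialization and shuffling is driven by explicit
  `numpy.random.Generator` streams derived from the spec seed, so
  identical (inputs, seed) reproduce identical parameters bit-for-bit.
- Gradient correctness is verified against central finite differences.

## Scaling profile

The full-scale architecture (widths above, 5000 epochs per stage,
learning rates 1e-5 for AE/cGAN and 1e-4 for the classifier) is expensive
on one CPU, so every spec carries a `scale` knob multiplying all widths
(minimum width 1 after rounding; noise and condition dimensions scale
with the widths). The default desk profile is scale = 0.01 with 300
epochs per stage, which runs the whole pipeline in minutes;
`paper_profile()` switches a run config to the full-scale settings. The
optimizer step scales inversely with width scale (effective lr =
lr/scale, capped at scale 1): at full scale the stated rates apply
unchanged, while at 1% scale with a 300-epoch budget the total parameter
displacement of the unscaled step (~1.5k Adam updates × 1e-5) would leave
the networks effectively at initialization. Inverse scaling is the
standard accompaniment of width/budget scaling and makes the desk profile
a genuine miniature of the full run rather than an untrained one.

## Synthetic cohorts

The generator of test cohorts (`fcgan.simulate`) emulates exactly the
structural features the pipeline must handle: several sites with unequal
ASD/HC counts (a 17-site composition totalling 408 ASD + 476 HC subjects
is bundled for split-protocol testing), per-subject scan length T drawn
uniformly from a per-site range, and a between-class signal planted
purely in correlation structure — zero-mean multivariate normal series
whose correlation matrix is a uniform background (0.1) plus a shift
Δr = 0.4 on ten planted region pairs for the ASD class. Targets that lose
positive semi-definiteness are repaired by eigenvalue clipping and
re-normalization to unit diagonal (rejected if the smallest eigenvalue is
below −0.5). The reference planted cohort is 16 regions, four sites of
80/60/40/20 subjects per class (200 per class total), T ∈ [80, 120]. A
fast path plants the shift directly on feature vectors plus Gaussian
noise (σ = 0.1, clipped to [−1, 1]) for unit tests.

What the generator does *not* model: hemodynamics, temporal
autocorrelation, scanner noise, site covariate shift, or any realistic
effect size. Passing tests therefore demonstrate that the pipeline
recovers a known correlation-structure signal end to end — not clinical
performance on real cohorts, whose headline numbers require the external
multi-site dataset and are out of scope here.

## Numerical and policy choices

- Correlations clipped to [−1, 1] after computation (floating-point
  guard); exact symmetry enforced by averaging with the transpose.
- Noise z ~ N(0, I); class conditioning via learned embeddings
  concatenated with noise (generator) / features (discriminator).
- "2000 synthetic subjects" is interpreted as 1000 per class; the count
  is a parameter everywhere.
- One global run seed derives per-stage seeds as
  SeedSequence([seed, crc32(stage-name)]) mod 2³¹, so stages are
  independently seeded yet fully reproducible; the run manifest records
  config, stage seeds and SHA-256 checksums of every artifact.
- Diagnosis-code mapping defaults to 1 → ASD, 2 → HC and is
  configurable; site labels are opaque strings and never normalized.
- Epochs = 0 is a supported boundary everywhere (untrained bundle, empty
  trace).

## Known limitations

- Single-token attention is degenerate by construction (see above); the
  `tokens=k` mode exists but is not the default.
- The cGAN conditions only on class, not on site or scan length.
- Spectral normalization's stop-gradient simplification slightly changes
  gradients relative to backpropagating through the norm; at the scales
  tested this has no observable effect on the trained models' behavior.
- Pooled AUC across groups requires retained per-group scores; reports
  loaded from bare confusion counts pool threshold metrics only.
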