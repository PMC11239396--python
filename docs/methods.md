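# Methods

## Overview

`neurofuse` is a late-fusion classification pipeline for case–control
neuroimaging-genomics studies. Per subject it consumes a grey-matter
density volume, a symmetric functional network connectivity (FNC) matrix
from a 53-component ICA decomposition, and an additive SNP dosage vector,
and produces (a) interpretable per-modality feature rankings and (b) a
cross-validated diagnosis classifier on the fused selected features.

## Synthetic cohorts

The generator produces the three modalities jointly, conditioned on a
shared label vector, with planted ground truth retained for auditing.

* **Labels and SNPs.** Per-SNP minor-allele frequencies are drawn
  uniformly from `maf_range` (default 0.05–0.5) and genotypes from
  Hardy–Weinberg proportions, `g ~ Binomial(2, MAF)`. Labels come from a
  logistic model whose per-allele log-odds are non-zero only on planted
  SNPs; dosages are allele-centred so the intercept `logit(case_fraction)`
  fixes the expected case rate. With no planted SNPs this reduces to
  labels-first Bernoulli sampling, and FNC/volume signals are then planted
  conditionally on the labels (discriminative planting). This keeps every
  planted effect recoverable by a per-feature group-difference scan, the
  brute-force oracle used to validate relevance rankings.
* **FNC.** Connection values are sampled in Fisher-z space — a
  per-connection cohort baseline `N(0, 0.3)`, subject noise
  `N(0, noise_sd)` (default 0.2), plus the planted case shift — and mapped
  through `tanh`, guaranteeing entries in (−1, 1), exact symmetry and a
  unit diagonal. Sampling in z-space was chosen because cross-correlation
  matrices have no natural additive generative model on the correlation
  scale.
* **Volumes.** A constant 0.5 background density plus voxel-wise Gaussian
  noise, a planted density shift inside case region-boxes, clipped to
  [0, 1]. The phantom is intentionally structureless: it carries a
  recoverable mean-shift signal without pretending to scanner physics,
  tissue geometry or spatial autocorrelation.
* **Domain map.** The 53 components are partitioned into
  SC(5)/AUD(2)/SM(9)/VIS(9)/CC(17)/DM(7)/CB(4), the standard split for the
  53-component template; other component counts stretch this partition
  proportionally. The map is configurable via `domain_map.csv`.

What the generator does **not** emulate: linkage disequilibrium and
population structure, ICA time-course dynamics, spatially smooth
morphometry, or site/batch effects. Passing tests therefore demonstrate
the pipeline's mechanics (recovery, conservation, leakage guards,
protocol bookkeeping), not clinical performance on real cohorts.

## Morphological encoder

A 3D DenseNet-121: 7×7×7 stride-2 stem convolution (64 channels) with
3×3×3 max pooling; four dense blocks of (6, 12, 24, 16) bottleneck layers
(1×1×1 then 3×3×3 convolution, growth rate 32); transitions apply ReLU,
batch normalization, a 1×1×1 compression convolution (factor 0.5) and
2×2×2 average pooling; a final global average pool yields 1024 features —
the only block configuration whose channel arithmetic ends at 1024.
Convolutions are bias-free and batch normalization is identity at
initialisation, so the encoder is a deterministic, label-blind transform;
it is used as a fixed extractor (no fine-tuning stage), with seeded random
initialisation by default and optional checkpoint loading, including
mean-preserving inflation of 2D DenseNet-121 kernels along the third axis.
Forward passes run in float32 via GEMM-based convolution; a full
121×145×121 volume encodes in well under a minute on one CPU.

Because the encoder is unsupervised and fixed, its features are computed
once for the whole cohort; this cannot leak labels across
cross-validation folds.

## Relevance engine

LRP with the basic z-rule: relevance entering neuron `m` is redistributed
to the previous layer in proportion to `z_lm = a_l · w_lm`. Propagation
starts at the target class unit's pre-softmax activation (the case class
for every subject, making rankings label-consistent regardless of the
predicted class) and stops at the input layer. Numerical choices:

* **Stabilizer.** A sign-matched epsilon (default 1e−9) is added to each
  denominator; a zero denominator with a zero stabilizer raises instead of
  silently producing infinities.
* **Biases** absorb no relevance, which makes layer-wise conservation onto
  the input exact rather than approximate; measured conservation error on
  random conv/pool/dense stacks is ~1e−9 relative.
* **Pooling.** Max-pool routes relevance winner-take-all; average-pool is
  the z-rule with uniform weights (proportional split). ReLU and flatten
  pass relevance through unchanged.
* **Degenerate subjects.** A subject whose hidden activations die
  everywhere yields an all-zero relevance vector; such subjects are
  excluded from aggregation with a warning rather than dividing by zero.

Rankings use `abs`-normalized scores (non-negative, summing to 1), since a
fixed threshold on scores that sum to one presupposes non-negativity;
per-subject vectors are mean-aggregated and re-normalized.

## Modality CNNs

Both the FNC and SNP selectors train the same small 1D CNN: two
convolution layers (kernel 5, stride 2, ReLU; 8 and 16 channels), flatten,
a 32-unit dense hidden layer, and a 2-unit output — trained with Adam
(lr 1e−3, weight decay 1e−4, gradient-norm clip 5, 30 epochs, batch 32) on
per-feature standardized inputs. Training is deterministic given a seed.
If a training trajectory kills every hidden ReLU (a constant predictor
with nothing to attribute), training restarts with a derived seed, at most
twice. "Pre-training" here means training on the current training split
before LRP; selection inside cross-validation uses only that fold's
training subjects.

Selection rules: FNC keeps connections with normalized relevance strictly
above 0.002 (at scores summing to 1 this can keep at most 499 features);
SNPs keep the top 100. The number of connections surviving the threshold
is a data-dependent outcome, not a constant. Ties break toward the lower
feature index for determinism.

## Fusion and evaluation

Segments concatenate in the order morphological ⊕ connectivity ⊕ genomic,
with recorded offsets; any non-empty subset supports ablation runs. The
classifier is XGBoost (`binary:logistic`, hist tree method, single
thread), tuned over a small grid (depth {2, 4} × learning rate
{0.1, 0.3}, 100 trees) on an inner stratified 75:25 validation split
carved from each training fold, then refitted on the full training fold.
Evaluation is stratified 5-fold cross-validation (each fold's 20% is the
test set); stratification prevents degenerate folds on small cohorts.
Metrics use the case class as
positive; precision of an all-negative prediction is defined as 0 with a
warning; summary std is the population standard deviation over folds.

## Problem sizes in the test suite

Deterministic study conditions exercised by the acceptance tests, chosen
as the smallest scales at which the properties are meaningful: recovery
uses 400 subjects with 20 planted connections at Fisher-z shifts
(0.1, 0.3, 0.8) over seeds {1, 2, 3}; the per-seed ≥80% recovery bar is
asserted at the large effect, and monotonicity across effect levels on the
3-seed mean (individual seeds fluctuate by a few connections). The fusion
ordering uses 400 subjects with complementary moderate effects (FNC shift
0.35, SNP log-odds 1.2, volume shift 0.12 at 32×40×32) — moderate so that
no single modality saturates, which is what makes fusion informative.
Encoder dimensionality is asserted at both 32×40×32 and the native
121×145×121.

## Known limitations

* The 1D CNN is deliberately small; at desk scale it can memorize shuffled
  labels, so the null-label control is asserted on held-out subjects
  (accuracy near the class prior), not on training accuracy.
* LRP implements the basic z-rule only (plus the epsilon stabilizer); no
  other attribution families or LRP variants (αβ, γ) are provided.
* Synthetic volumes lack spatial structure, so morphological accuracy in
  examples reflects linear signal recovery through random projections, not
  anatomy.
* Connection rankings are reported as tables, not 3D brain connectograms:
  component spatial coordinates are not modelled.
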