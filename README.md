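# neurofuse

Multimodal neuroimaging–genomics classification with layer-wise relevance
propagation (LRP) feature selection.

## The problem

Schizophrenia classification from a single data modality leaves information
on the table: structural MRI captures morphology, resting-state functional
network connectivity (FNC) captures inter-network coupling, and SNP dosages
capture genetic risk, each with its own signal and noise. `neurofuse`
implements a late-fusion pipeline that

1. encodes each subject's grey-matter density volume (121×145×121 voxels)
   with a 3D DenseNet-121, producing a 1024-dimensional morphological
   vector `X_i`;
2. vectorizes the strict lower triangle of the subject's symmetric 53×53
   FNC matrix into 1378 connection features, trains a small 1D CNN
   classifier on them, and ranks every connection by LRP relevance

       R_l = Σ_m ( z_lm / Σ_l' z_l'm ) · R_m ,   z_lm = a_l · w_lm ,

   keeping connections whose normalized relevance (summing to 1) exceeds
   0.002 — the connectivity vector `Z_i`;
3. does the same for the SNP additive-dosage vector, keeping the top 100
   SNPs — the genomic vector `W_i`;
4. fuses `F_i = X_i ⊕ Z_i ⊕ W_i` (vector concatenation) and classifies
   with a gradient-boosted CART ensemble (XGBoost), `ŷ_i = Σ_t f_t(F_i)`;
5. evaluates with stratified 5-fold cross-validation (each fold holds out
   20%), reporting accuracy, precision, recall and F1 as mean ± std.
   Feature selection and hyperparameter tuning run inside each training
   fold only.

Because the clinical cohorts behind this design are access-controlled, the
package ships a first-class synthetic-cohort generator that emulates all
three modalities with planted, recoverable case–control effects, so every
stage — including relevance recovery of planted signals and the
fused-beats-single-modality ordering — is testable end to end.

## Worked example

```bash
python examples/02_relevance_ranking.py
```

builds a 200-subject synthetic cohort with 5 planted FNC connections,
trains the 1D CNN, and ranks all 190 connections (20 components) by LRP:

```
trained CNN: training accuracy 1.00
aggregated relevance sums to 1.000000
top 8 connections by relevance (planted marked *):
  rank  1  conn 120 * (components 16,0 )  score 0.02795
  rank  2  conn   4 * (components  3,1 )  score 0.02062
  rank  3  conn  40 * (components  9,4 )  score 0.02059
  rank  4  conn  77 * (components 12,11)  score 0.01511
  rank  5  conn 160   (components 18,7 )  score 0.01107
  ...
recovered 4/5 planted connections in the top 35
```

Four of the five planted connections occupy the top four ranks: the
relevance scores (which sum to 1 across all 190 connections) concentrate
on the features that carry the case–control signal, with the remaining
planted connection recovered further down. Other examples cover
cohort simulation and serialization (`01`), morphological encoding (`03`),
and fused-versus-single-modality cross-validation (`04`).

A CLI mirrors the library for shell use:

```bash
neurofuse simulate --config cohort.yaml --seed 1 --out cohort/
neurofuse classify --input cohort/ --modalities smri,fnc,snp --out cv.json
```

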