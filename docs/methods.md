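# Methods

## The prediction problem

Patients with mild cognitive impairment (MCI) either progress to
Alzheimer's disease (pMCI) or remain stable (sMCI) over follow-up.  The
package implements a multimodal classifier of that conversion from three
baseline data sources: a skull-stripped T1 structural MRI volume, 14
clinical features (demographics plus cognitive test scores), and a panel
of SNP allele counts.

## The model

The Dual Interaction Stepwise Fusion Classifier (DISFC) is a three-branch
network with two explicit interaction mechanisms:

* **Intra-modal interaction module** (clinical branch): the 14 normalized
  clinical features are augmented with all C(14,2) = 91 pairwise products,
  giving a 105-dimensional input.  Squared terms are excluded by default
  ("interaction terms" read as distinct pairs) and available behind the
  `include_squares` flag.  Products are computed on the normalized inputs,
  before any learned layer.
* **Inter-modal interaction module** (fusion stage): the flattened outer
  product of the 8-d imaging and clinical embeddings (64 values), modeling
  every cross-modality pair.

Each branch compresses its modality to an 8-dimensional embedding with its
own auxiliary sigmoid head:

* spatial: SepConv stem → stride-2 SepConv → a group of four residual
  SepConv blocks with a single group-level shortcut (1×1×1 projection when
  channel counts differ) → stride-2 SepConv → global average pooling →
  dense layer.  Separable convolution (depthwise k³ then pointwise 1×1×1)
  carries k³·c_in + c_in·c_out weights versus k³·c_in·c_out for a dense
  convolution; for c_in=16, c_out=32, k=3 that is 944 versus 13,824.
* clinical: expanded input → FC block → dense layer.
* genetic: selected allele counts (scaled by ½ to [0,1]) → FC block →
  dense layer.  The genetic branch deliberately has no intra-modal
  expansion.

Fusion is stepwise: stage 1 concatenates the imaging embedding, the
clinical embedding and their outer product (8+8+64 = 80 inputs) into an FC
block; stage 2 concatenates the resulting hidden vector with the genetic
embedding (16+8 = 24 inputs) into the final sigmoid.  The raw embeddings
are fed forward alongside the outer product so the interaction is additive
information rather than a replacement.

Every block follows conv/linear → batch normalization → ReLU → dropout,
with L2 regularization on conv/linear weights.  Channel widths default to
stem 8 and stages 16/32 with small hidden layers — sized for CPU-scale
volumes; a full-resolution configuration can be expressed through
`ModelConfig` but is not exercised by the test suite.

Training minimizes

    L = α·L_fusion + β₁·L_mri + β₂·L_clin + β₃·L_snp,

each term a binary cross-entropy (probabilities clipped to
[1e-7, 1−1e-7]), with default weights (1.0, 1.5, 0.5, 0.5).  The optimizer
is Adam with batch size 6 for 50 epochs by default; the learning rate
ramps linearly from peak/15 to the peak 0.001 over 15 epochs and then
decays exponentially (rate 0.95/epoch — the decay rate is a package
default, chosen in the absence of a stated value, and configurable).

The network and its backpropagation are implemented directly over NumPy
in a small reverse-mode autodiff engine (`disfc._autodiff`, `disfc.nn`).
This keeps runs bit-reproducible on CPU for a fixed seed; gradients are
verified against finite differences in the test suite.

## Preprocessing

* Volumes: center crop to a single global target shape, then max–min
  scaling to [0,1].  A constant volume is a hard error rather than NaN.
* Clinical: sex encoded F→0/M→1; missing values imputed with the column
  mean; min–max scaling.  All statistics are fitted on the training split
  only and reused on held-out data, whose out-of-range values are clipped
  to [0,1].  (Split-wise fitting is a deliberate anti-leakage choice.)
* Genotypes: QC retains SNPs with call rate ≥ 0.95, MAF ≥ 0.05 and exact
  Hardy–Weinberg p ≥ 1e-6 (defaults follow common GWAS practice and are
  configurable; the statistics are always recomputed from the counts).
  Missing calls are imputed with the per-SNP modal genotype, ties
  resolving to the lower allele count; the interface accepts externally
  imputed matrices (e.g. from a haplotype-reference tool) as a drop-in.
  Feature selection is two-stage: an optional knowledge-driven SNP ID
  list, then L1-penalized logistic regression with the penalty bisected
  until the active set has exactly k members (default k=49), preferring
  fewer when k falls inside a path discontinuity.

Within cross-validation, clinical scaling, genotype QC/imputation
statistics and the Lasso selection are all refitted per fold on that
fold's training subjects.

## Evaluation statistics

AUC uses the Mann–Whitney formulation with midrank ties (verified against
an O(n²) pair-counting oracle).  Confusion metrics threshold at 0.5.
Intervals: exact Clopper–Pearson for proportions; percentile intervals
from 2000 stratified bootstrap replicates for AUC.  Tests (two-sided
throughout): DeLong for correlated AUCs (verified against brute-force
structural components, type-I error calibrated by simulation), Fisher's
exact test (probability-ordering two-sided rule), Wilcoxon signed-rank
with continuity correction (normal approximation; zero differences
dropped), and the one-sample proportion score test with continuity
correction.  The continuity-corrected Wilcoxon p-values are slightly
conservative and discrete, so their null distribution is validated by
rejection-rate calibration at conventional α levels rather than by a
strict uniformity test.

## Synthetic cohorts

The generator emulates the statistical structure the model's claims rest
on, not brain anatomy:

* **Volumes** are a smooth low-frequency intensity field plus Gaussian
  noise; for progressors the mean intensity inside a fixed ellipsoid
  (centered at fractional position (0.50, 0.45, 0.60), semi-axes 18% of
  each dimension) is reduced by `atrophy_fraction`.  The mask is
  retrievable, giving occlusion-saliency tests a ground truth.
* **Clinical features** plant a pure interaction: the (MMSE, CDRSB) pair
  is drawn with correlation +ρ for progressors and −ρ for stable subjects
  (identical marginals, so no single feature carries signal); ADAS13 and
  LDELTOTAL carry weak 0.2-SD main effects; everything else, including
  sex, is label-independent.  Columns are affinely mapped to realistic
  clinical scales so real exports are drop-in compatible.
* **Genotypes** are Hardy–Weinberg draws with MAF ~ U(0.1, 0.5); causal
  SNPs shift allele frequency by +0.12 for progressors (the conditional
  analogue of an additive log-odds effect, since labels are generated
  first).  Three tagged decoy blocks violate exactly one QC criterion
  each: rare variants (≈3% MAF, heterozygous carriers only), 10% missing
  calls, and total heterozygote deficiency.  Clean and causal SNPs are
  redrawn until their realized statistics pass the default thresholds, so
  decoy recall and clean-SNP retention are exact ground truth rather than
  probabilistic.  The heterozygote-deficiency decoys only reach p < 1e-6
  for cohorts of roughly 100 subjects and up — smaller cohorts lack
  exact-test power, and QC ground-truth tests use adequate sizes.
* Labels are assigned by exact count (round(prevalence·n), default
  prevalence 0.373) and shuffled by the seed stream; a stratified ~14/252
  fraction becomes the independent test split, and diagnosed-AD positives
  (45 per 252 MCI by default) join only the training splits.

All randomness flows from one seed with counter-keyed substreams, so
cohorts are bit-identical across runs and platforms.

What passing tests on these cohorts do **not** show: performance on real
imaging (no anatomy, scanner effects or registration error), on real
genetic architectures (no LD, population structure or covariates), or at
clinical effect sizes.  The planted-signal experiments demonstrate that
the interaction machinery can exploit signal of the stated form; the
directional interaction-advantage check is a desk-scale analogue, not a
reproduction of the original effect size.

## Attribution

`feature_attributions` supports a Monte-Carlo permutation-sampling
Shapley estimator (background replacement, default background subsample
50) and permutation importance (mean AUC drop).  Two scopes: the fusion
stage's input representation, grouped into {imaging, clinical,
imaging-clinical-interaction, genetic}, and the clinical branch's 105
expanded features.  Spatial importance is occlusion sensitivity (patch
replaced by the volume mean), chosen over gradient saliency for
robustness.

A scale caveat, measured during development: under min–max scaling the
binary sex feature has roughly three times the standard deviation of the
continuous features, and |Shapley| magnitudes scale with input variation.
On synthetic cohorts the planted product term therefore dominates
permutation importance computed on held-out subjects (where sex's AUC
drop is ≈ 0) and ranks first among product terms for Shapley, while
sex-involving terms can top the raw Shapley ranking without carrying
generalizable signal.  Attribution on held-out data is the recommended
usage.

## Problem sizes

The shipped defaults and test configurations run the full pipeline at
desk scale: 8³–(32×36×40) voxel volumes, cohorts of 60–400 subjects,
60–300 SNPs, and 15–30 training epochs.  These sizes are the package's
own choices for a CPU-only workflow; every component accepts the original
full-resolution configuration through its config objects.
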