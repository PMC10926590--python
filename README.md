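# disfc

Multimodal prediction of conversion from mild cognitive impairment (MCI)
to Alzheimer's disease, from three baseline data sources: a 3-D
skull-stripped T1 MRI volume, 14 clinical features, and SNP allele
counts.  The package is aimed at methods researchers who want a fully
seeded, CPU-scale implementation of a dual-interaction fusion network —
including its preprocessing, feature selection, training protocol,
evaluation statistics, ablation harness and attribution tools — together
with a synthetic cohort generator that plants the signal structures the
architecture is designed to exploit.

## The model

The Dual Interaction Stepwise Fusion Classifier (DISFC) runs three
parallel feature extractors, each ending in an 8-dimensional embedding
with an auxiliary sigmoid head:

* **spatial** — separable-convolution (depthwise k³ + pointwise 1×1×1)
  stem, a group of four residual blocks under a single shortcut, global
  average pooling;
* **clinical** — the 14 normalized features augmented by the *intra-modal
  interaction module* with all 91 pairwise products x_i·x_j (i<j), then
  fully connected blocks;
* **genetic** — QC-filtered, Lasso-selected allele counts (default 49)
  through fully connected blocks.

Fusion is *stepwise*: first imaging + clinical, concatenated with their
flattened outer product e_mri ⊗ e_clin (the *inter-modal interaction
module*, 8×8 = 64 cross terms), then the genetic embedding.  Training
minimizes

    L = α·L_fusion + β₁·L_mri + β₂·L_clin + β₃·L_snp,

with per-head binary cross-entropy and weights (α, β₁, β₂, β₃) =
(1.0, 1.5, 0.5, 0.5), using Adam with a linear warmup to 0.001 over 15
epochs followed by exponential decay.  The evaluation protocol is
stratified 10-fold cross-validation with diagnosed-AD positives added to
every training split, plus an independent test split; statistics include
exact Clopper–Pearson intervals, stratified-bootstrap AUC intervals, the
DeLong test, Fisher's exact test, the Wilcoxon signed-rank test and the
one-sample proportion test.

The network and its training loop are implemented in a compact
reverse-mode autodiff engine over NumPy, so every run is bit-reproducible
on CPU for a fixed seed.  See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

```python
from disfc import (SynthConfig, generate_cohort, ModelConfig, TrainConfig,
                   cross_validate)

cohort = generate_cohort(SynthConfig(
    n_subjects=240, volume_shape=(8, 8, 8), n_snps=80,
    n_causal_snps=6, n_decoys_per_block=5, interaction_strength=0.8,
    seed=42))
result = cross_validate(
    cohort,
    ModelConfig(volume_shape=(8, 8, 8), n_snp_features=20),
    TrainConfig(epochs=25, warmup_epochs=8, seed=0),
    k=3)
print(f"fold AUCs: {[round(m.auc, 3) for m in result.per_fold]}")
print(f"mean AUC {result.mean['auc']:.3f} (SD {result.sd['auc']:.3f}), "
      f"mean accuracy {100 * result.mean['accuracy']:.2f}%")
```

prints (about two minutes on one CPU):

```
fold AUCs: [0.789, 0.656, 0.709]
mean AUC 0.718 (SD 0.067), mean accuracy 63.43%
```

The cohort here is synthetic and small — 240 subjects, 8³-voxel volumes,
80 SNPs — so the absolute numbers only demonstrate that the pipeline
learns the planted multimodal signal; they are not clinical performance
estimates.  The same objects accept full-size volumes and SNP panels.

The command line mirrors the library.  For example, evaluating a
predictions CSV (`subject_id,score,label`) containing three progressors
of which one was missed and eleven correctly classified stable subjects:

```bash
disfc evaluate --predictions preds.csv
```

```json
{
  "n": 14,
  "confusion": {"TP": 2, "FP": 0, "TN": 11, "FN": 1},
  "accuracy_pct": 92.86,
  "sensitivity_pct": 66.67,
  "specificity_pct": 100.0,
  "f1_pct": 80.0,
  "accuracy_ci95_pct": [66.13, 99.82],
  "auc": 1.0,
  "auc_ci95": [1.0, 1.0]
}
```

i.e. 13/14 correct at the 0.5 threshold (92.86%), with the exact binomial
95% interval 66.13–99.82% (the missed progressor's score of 0.2 still
ranks above every stable subject here, hence the degenerate AUC of 1.0).  Other subcommands: `simulate`, `preprocess`,
`select-snps`, `train`, `cross-validate`, `ablate`, `explain`; each
writes its resolved configuration and a JSON run log next to its outputs.

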