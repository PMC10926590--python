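"""Training protocol: augmentation, optimizer schedule, stratified 10-fold
cross-validation with AD train-only positives, and the ablation harness.

Fold-wise preprocessing is leakage-free: clinical imputation/scaling
statistics, genotype QC/imputation statistics and the Lasso SNP selection
are all fitted on the training split of each fold and reused on its
held-out subjects.  Everything is seeded; two runs with the same seed
produce identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from . import evalstats, preprocess
from .datatypes import GenotypeMatrix, LabeledCohort, VolumeImage
from .errors import ConfigurationError
from .fusioncore import (
    DISFCModel,
    LossWeights,
    ModelConfig,
    bce_loss,
    build_model,
    total_loss,
)
from .nn import Adam

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "stratified_kfold",
    "lr_at_epoch",
    "augment_volume",
    "augment_tabular",
    "train_fold",
    "cross_validate",
    "ablate",
    "ABLATION_VARIANTS",
    "CVResult",
]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 6
    peak_lr: float = 1e-3
    warmup_epochs: int = 15
    decay_rate: float = 0.95
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    max_rotation_deg: float = 10.0
    max_shift_vox: int = 2
    scale_range: tuple[float, float] = (0.95, 1.05)
    mirror: bool = True
    tabular_sd: float = 0.01

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not (0 < self.warmup_epochs < self.epochs):
            raise ConfigurationError("warmup_epochs must lie in (0, epochs)")
        if self.tabular_sd < 0:
            raise ConfigurationError("tabular_sd must be nonnegative")


@dataclass
class FoldAssignment:
    """Validation-fold index per cross-validation subject."""

    k: int
    fold_index: np.ndarray

    def val_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment: each subject validated exactly once and
    every fold's class ratio within one subject of the global ratio."""
    labels = np.asarray(labels).astype(int)
    if k < 2:
        raise ConfigurationError("k must be >= 2 (no held-out fold otherwise)")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ConfigurationError(
            f"smallest class has {counts.min()} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(len(labels), dtype=int)
    for fold, (_, val) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_index[val] = fold
    return FoldAssignment(k=k, fold_index=fold_index)


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Linear warmup from peak/warmup_epochs to the peak, then exponential decay."""
    if not (0 <= epoch < cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if epoch < cfg.warmup_epochs:
        return cfg.peak_lr * (epoch + 1) / cfg.warmup_epochs
    return cfg.peak_lr * cfg.decay_rate ** (epoch - cfg.warmup_epochs)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_volume(vol, rng: np.random.Generator, cfg: TrainConfig):
    """Random mirror / rotation / shift / scale; shape preserved, output
    clipped to [0, 1].  All magnitudes zero -> identity."""
    arr = vol.intensities if isinstance(vol, VolumeImage) else np.asarray(vol)
    out = np.asarray(arr, dtype=float)
    shape = out.shape
    if cfg.mirror and rng.random() < 0.5:
        out = out[::-1, :, :]
    if cfg.max_rotation_deg > 0:
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        axes = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
        out = ndimage.rotate(out, angle, axes=axes, reshape=False,
                             order=1, mode="nearest")
    if cfg.max_shift_vox > 0:
        shift = rng.integers(-cfg.max_shift_vox, cfg.max_shift_vox + 1, size=3)
        if np.any(shift != 0):
            out = ndimage.shift(out, shift, order=0, mode="nearest")
    lo_s, hi_s = cfg.scale_range
    if not (lo_s == hi_s == 1.0) and hi_s > lo_s:
        factor = rng.uniform(lo_s, hi_s)
        if abs(factor - 1.0) > 1e-6:
            zoomed = ndimage.zoom(out, factor, order=1, mode="nearest")
            out = _center_fit(zoomed, shape)
    out = np.clip(out, 0.0, 1.0)
    if isinstance(vol, VolumeImage):
        return VolumeImage(out, vol.spacing_mm, vol.subject_id)
    return out


def _center_fit(arr: np.ndarray, shape) -> np.ndarray:
    """Center-crop or zero-pad `arr` to `shape`."""
    out = np.zeros(shape, dtype=arr.dtype)
    src_sl, dst_sl = [], []
    for s_arr, s_out in zip(arr.shape, shape):
        if s_arr >= s_out:
            a = (s_arr - s_out) // 2
            src_sl.append(slice(a, a + s_out))
            dst_sl.append(slice(0, s_out))
        else:
            a = (s_out - s_arr) // 2
            src_sl.append(slice(0, s_arr))
            dst_sl.append(slice(a, a + s_arr))
    out[tuple(dst_sl)] = arr[tuple(src_sl)]
    return out


def augment_tabular(x, rng: np.random.Generator, sd: float):
    """Add Gaussian(0, sd) perturbations, clipped back to [0, 1]."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    x = np.asarray(x, dtype=float)
    if sd == 0:
        return x.copy()
    return np.clip(x + rng.normal(0.0, sd, size=x.shape), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Single-fold training
# ---------------------------------------------------------------------------

def train_fold(model_cfg: ModelConfig, train_data: dict, cfg: TrainConfig,
               augment: bool = True) -> tuple[DISFCModel, dict]:
    """Train a DISFC model on one training split.

    `train_data` maps 'volumes' -> (n, 1, D, H, W) normalized intensities,
    'clinical' -> (n, 14) in [0, 1], 'snps' -> (n, m) allele counts (scaled
    by 1/2 internally), 'y' -> (n,) binary labels.  Optimizes the weighted
    four-head binary cross-entropy with Adam under the warmup/decay
    schedule; the history records per-epoch head losses and learning rates.
    """
    y = np.asarray(train_data["y"], dtype=float)
    n = len(y)
    model = build_model(model_cfg, seed=cfg.seed)
    opt = Adam(model.parameters(), l2_params=model.l2_parameters(),
               l2_strength=model_cfg.l2_strength)
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 101])

    use_mri = "mri" in model_cfg.modalities
    use_clin = "clin" in model_cfg.modalities
    use_snp = "snp" in model_cfg.modalities
    vols = np.asarray(train_data["volumes"], dtype=float) if use_mri else None
    clin = np.asarray(train_data["clinical"], dtype=float) if use_clin else None
    snps = np.asarray(train_data["snps"], dtype=float) / 2.0 if use_snp else None

    history = {"epoch": [], "lr": [], "loss_total": []}
    head_names = list(model_cfg.modalities) + ["fusion"]
    for h in head_names:
        history[f"loss_{h}"] = []

    model.set_training(True)
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(n)
        sums = {h: 0.0 for h in head_names}
        sums["total"] = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            vb = cb = sb = None
            if use_mri:
                vb = vols[idx]
                if augment:
                    vb = np.stack([
                        augment_volume(vb[i, 0], rng, cfg) for i in range(len(idx))
                    ])[:, None]
            if use_clin:
                cb = augment_tabular(clin[idx], rng, cfg.tabular_sd) if augment \
                    else clin[idx]
            if use_snp:
                sb = augment_tabular(snps[idx], rng, cfg.tabular_sd) if augment \
                    else snps[idx]
            outputs = model.forward(volumes=vb, clinical=cb, snps=sb)
            losses = {}
            for h in head_names:
                loss = bce_loss(y[idx], outputs[h])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"NaN/inf loss in head '{h}' at epoch {epoch}")
                losses[h] = loss
            loss = total_loss(losses, cfg.loss_weights)
            model.zero_grad()
            loss.backward()
            opt.step(lr)
            for h in head_names:
                sums[h] += float(losses[h].data)
            sums["total"] += float(loss.data)
            n_batches += 1
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["loss_total"].append(sums["total"] / n_batches)
        for h in head_names:
            history[f"loss_{h}"].append(sums[h] / n_batches)
    model.set_training(False)
    model.is_trained = True
    return model, history


# ---------------------------------------------------------------------------
# Fold-wise preprocessing (leakage-free)
# ---------------------------------------------------------------------------

def _genotype_modes(counts: np.ndarray) -> np.ndarray:
    modes = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        col = counts[:, j]
        obs = col[~np.isnan(col)]
        tallies = [(obs == g).sum() for g in (0.0, 1.0, 2.0)]
        modes[j] = float(int(np.argmax(tallies)))
    return modes


def prepare_split(cohort: LabeledCohort, train_idx, val_idx,
                  model_cfg: ModelConfig,
                  qc: preprocess.QCThresholds = preprocess.DEFAULT_QC
                  ) -> tuple[dict, dict, ModelConfig]:
    """Fit all preprocessing on the training subjects and apply to both splits.

    Returns (train_data, val_data, fitted_model_cfg); the model config's
    n_snp_features is adjusted when fewer SNPs survive QC + selection.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    y = cohort.labels

    def norm_stack(idx):
        return np.stack([
            preprocess.normalize_volume(cohort.volumes[i]).intensities
            for i in idx
        ]).astype(float)[:, None]

    data = {}
    if "mri" in model_cfg.modalities:
        data["vol_train"] = norm_stack(train_idx)
        data["vol_val"] = norm_stack(val_idx)

    clin_train, scaler = preprocess.preprocess_clinical(
        cohort.clinical.iloc[train_idx])
    clin_val, _ = preprocess.preprocess_clinical(
        cohort.clinical.iloc[val_idx], fit_stats=scaler)

    gm = cohort.genotypes
    gm_train = GenotypeMatrix(
        counts=gm.counts[train_idx], snp_meta=gm.snp_meta,
        subject_ids=[gm.subject_ids[i] for i in train_idx])
    gm_train_qc, _ = preprocess.qc_filter_snps(gm_train, qc)
    kept_ids = set(gm_train_qc.snp_meta["id"])
    keep_cols = np.flatnonzero(gm.snp_meta["id"].isin(kept_ids).to_numpy())
    counts_train = gm.counts[np.ix_(train_idx, keep_cols)]
    counts_val = gm.counts[np.ix_(val_idx, keep_cols)]
    modes = _genotype_modes(counts_train)
    counts_train = np.where(np.isnan(counts_train), modes, counts_train)
    counts_val = np.where(np.isnan(counts_val), modes, counts_val)

    k = min(model_cfg.n_snp_features, counts_train.shape[1])
    sel = preprocess.lasso_select(counts_train, y[train_idx], k=k)
    fitted_cfg = replace(model_cfg, n_snp_features=len(sel))

    train_data = {
        "volumes": data.get("vol_train"), "clinical": clin_train,
        "snps": counts_train[:, sel], "y": y[train_idx],
    }
    val_data = {
        "volumes": data.get("vol_val"), "clinical": clin_val,
        "snps": counts_val[:, sel], "y": y[val_idx],
    }
    return train_data, val_data, fitted_cfg


def evaluate_model(model: DISFCModel, data: dict) -> tuple[np.ndarray, evalstats.MetricSet]:
    """Fusion-head scores and threshold-0.5 metrics on a prepared split."""
    scores = model.predict_proba(
        volumes=data["volumes"], clinical=data["clinical"],
        snps=np.asarray(data["snps"], dtype=float) / 2.0
        if data.get("snps") is not None else None)
    _, metrics = evalstats.confusion_metrics(scores, data["y"])
    return scores, metrics


def train_and_evaluate(cohort: LabeledCohort, train_idx, val_idx,
                       model_cfg: ModelConfig, train_cfg: TrainConfig
                       ) -> tuple[evalstats.MetricSet, np.ndarray, np.ndarray]:
    """Convenience: prepare a split, train, and score the held-out subjects."""
    train_data, val_data, fitted_cfg = prepare_split(
        cohort, train_idx, val_idx, model_cfg)
    model, _ = train_fold(fitted_cfg, train_data, train_cfg)
    scores, metrics = evaluate_model(model, val_data)
    return metrics, scores, np.asarray(val_data["y"])


# ---------------------------------------------------------------------------
# Cross-validation and ablation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    per_fold: list
    folds: FoldAssignment
    scores: np.ndarray      # pooled held-out fusion scores (cv subjects)
    labels: np.ndarray

    def metric_matrix(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.per_fold])

    @property
    def mean(self) -> dict:
        return self.metric_matrix().mean(numeric_only=True).to_dict()

    @property
    def sd(self) -> dict:
        return self.metric_matrix().std(numeric_only=True, ddof=1).to_dict()


def cross_validate(cohort: LabeledCohort, model_cfg: ModelConfig,
                   train_cfg: TrainConfig, k: int = 10,
                   folds: FoldAssignment | None = None) -> CVResult:
    """Stratified k-fold CV over the cohort's cv-role subjects.

    AD train-only subjects join every training split and no validation
    split.  The summary is the unweighted mean and SD of fold metrics.
    """
    cv_idx = np.flatnonzero(cohort.mask("cv"))
    extra_idx = np.flatnonzero(cohort.mask("train_only_AD"))
    y_cv = cohort.labels[cv_idx]
    if folds is None:
        folds = stratified_kfold(y_cv, k=k, seed=train_cfg.seed)
    per_fold = []
    scores_pool = np.full(len(cv_idx), np.nan)
    for fold in range(folds.k):
        tr = cv_idx[folds.train_indices(fold)]
        va = cv_idx[folds.val_indices(fold)]
        tr = np.concatenate([tr, extra_idx])
        metrics, scores, _ = train_and_evaluate(
            cohort, tr, va, model_cfg, train_cfg)
        per_fold.append(metrics)
        scores_pool[folds.val_indices(fold)] = scores
    return CVResult(per_fold=per_fold, folds=folds,
                    scores=scores_pool, labels=y_cv)


ABLATION_VARIANTS = ("full", "no_interactions", "mri", "clin", "snp",
                     "mri+clin", "mri+snp", "clin+snp")


def _variant_config(base: ModelConfig, variant: str) -> ModelConfig:
    if variant == "full":
        return base
    if variant == "no_interactions":
        return replace(base, include_intra=False, include_outer=False)
    mods = tuple(variant.split("+"))
    if not set(mods) <= {"mri", "clin", "snp"}:
        raise ConfigurationError(f"unknown ablation variant '{variant}'")
    return replace(base, modalities=mods)


def ablate(cohort: LabeledCohort, variants, model_cfg: ModelConfig,
           train_cfg: TrainConfig, k: int = 10) -> dict:
    """Run cross_validate per variant with shared folds and seeds.

    Returns {'results': {variant: CVResult}, 'table': per-variant mean
    metrics, 'per_fold_auc': fold x variant AUCs for paired tests}.
    """
    variants = list(variants)
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ConfigurationError(f"unknown ablation variant '{v}'")
    y_cv = cohort.labels[cohort.mask("cv")]
    folds = stratified_kfold(y_cv, k=k, seed=train_cfg.seed)
    results = {}
    for v in variants:
        results[v] = cross_validate(
            cohort, _variant_config(model_cfg, v), train_cfg, k=k, folds=folds)
    table = pd.DataFrame({v: results[v].mean for v in variants}).T
    per_fold_auc = pd.DataFrame(
        {v: [m.auc for m in results[v].per_fold] for v in variants})
    return {"results": results, "table": table, "per_fold_auc": per_fold_auc}
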