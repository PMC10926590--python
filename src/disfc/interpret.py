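"""Post-hoc attribution for a trained fusion model.

Two scopes are supported:

* ``scope="fusion"`` attributes the fusion classifier's input
  representation — the imaging embedding, the clinical embedding, their
  flattened outer product, and the genetic embedding — and groups scores
  into {imaging, clinical, imaging-clinical-interaction, genetic}.
* ``scope="clinical"`` attributes the clinical branch's expanded input
  features (raw features plus pairwise product terms).

Methods: ``shap`` is a Monte-Carlo permutation-sampling estimator of
Shapley values with a background reference set; ``permutation`` is the
mean AUC drop when one feature is shuffled across subjects.  Spatial
importance uses occlusion sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from ._autodiff import Tensor, concat
from .datatypes import CLINICAL_FEATURES, VolumeImage
from .errors import DimensionError, DisfcError
from .evalstats import roc_auc
from .fusioncore import DISFCModel, expanded_feature_names, inter_modal_outer

__all__ = [
    "AttributionReport",
    "feature_attributions",
    "volume_saliency",
    "aggregate_by_group",
]


@dataclass
class AttributionReport:
    """Per-feature nonnegative importance scores with a total grouping map."""

    scores: dict
    grouping: dict
    method: str = ""

    def __post_init__(self):
        ungrouped = set(self.scores) - set(self.grouping)
        if ungrouped:
            raise DisfcError(f"features missing from grouping map: "
                             f"{sorted(ungrouped)[:3]}")
        for name, s in self.scores.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite attribution for '{name}'")

    def top(self, n: int = 10) -> list:
        return sorted(self.scores.items(), key=lambda kv: -kv[1])[:n]


def aggregate_by_group(report: AttributionReport) -> dict:
    """Per-group sums; the group totals conserve the per-feature total."""
    groups = {g: 0.0 for g in set(report.grouping.values())}
    for name, score in report.scores.items():
        if name not in report.grouping:
            raise DisfcError(f"feature '{name}' has no group")
        groups[report.grouping[name]] += score
    return groups


# ---------------------------------------------------------------------------
# Feature-space construction
# ---------------------------------------------------------------------------

def _require_trained(model: DISFCModel):
    if not getattr(model, "is_trained", False):
        raise DisfcError("model has not been trained; refusing to attribute")


def _fusion_z(model: DISFCModel, volumes, clinical, snps):
    """Fusion-stage input matrix and (names, grouping)."""
    if set(model.cfg.modalities) != {"mri", "clin", "snp"}:
        raise DisfcError("fusion-scope attribution needs all three modalities")
    model.set_training(False)
    model.forward(volumes=volumes, clinical=clinical, snps=snps)
    emb = {k: v.data for k, v in model._last_embeddings.items()}
    e = model.cfg.embedding_dim
    parts, names, grouping = [], [], {}
    parts.append(emb["mri"])
    names += [f"mri_emb_{i}" for i in range(e)]
    parts.append(emb["clin"])
    names += [f"clin_emb_{i}" for i in range(e)]
    if model.cfg.include_outer:
        parts.append(inter_modal_outer(emb["mri"], emb["clin"]))
        names += [f"mri{i}*clin{j}" for i, j in product(range(e), range(e))]
    parts.append(emb["snp"])
    names += [f"snp_emb_{i}" for i in range(e)]
    for n in names:
        if n.startswith("mri_emb"):
            grouping[n] = "imaging"
        elif n.startswith("clin_emb"):
            grouping[n] = "clinical"
        elif n.startswith("snp_emb"):
            grouping[n] = "genetic"
        else:
            grouping[n] = "imaging-clinical-interaction"
    return np.column_stack(parts), names, grouping


def _fusion_head_fn(model: DISFCModel):
    """Fusion probability as a function of the fusion-stage input matrix."""
    e = model.cfg.embedding_dim
    n_outer = e * e if model.cfg.include_outer else 0

    def f(z: np.ndarray) -> np.ndarray:
        model.set_training(False)
        za = Tensor(z[:, : 2 * e + n_outer])
        zs = Tensor(z[:, 2 * e + n_outer:])
        h = model.fuse_fc1(za)
        return model.fuse_out(concat([h, zs], axis=-1)).sigmoid().data.reshape(-1)

    return f


def _clinical_matrix(model: DISFCModel, clinical):
    from .fusioncore import intra_modal_expand

    x = np.asarray(clinical, dtype=float)
    if model.cfg.include_intra:
        x = intra_modal_expand(x, model.cfg.include_squares)
        names = expanded_feature_names(CLINICAL_FEATURES, model.cfg.include_squares)
    else:
        names = list(CLINICAL_FEATURES)
    grouping = {n: ("clinical-interaction" if "*" in n or "^" in n else "clinical")
                for n in names}
    return x, names, grouping


def _clinical_head_fn(model: DISFCModel):
    def f(xexp: np.ndarray) -> np.ndarray:
        model.set_training(False)
        h = model.clin_fc2(model.clin_fc1(Tensor(xexp)))
        return model.clin_head(h).sigmoid().data.reshape(-1)

    return f


# ---------------------------------------------------------------------------
# Attribution estimators
# ---------------------------------------------------------------------------

def _shapley_sampling(f, X, background, n_permutations, rng):
    """Monte-Carlo Shapley values: mean marginal contribution of each
    feature over random insertion orders, with background replacement."""
    n, d = X.shape
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        bg = background[rng.integers(len(background), size=n)]
        cur = bg.copy()
        prev = f(cur)
        for j in order:
            cur[:, j] = X[:, j]
            new = f(cur)
            phi[:, j] += new - prev
            prev = new
    return phi / n_permutations


def _permutation_importance(f, X, labels, n_repeats, rng):
    base_auc = roc_auc(f(X), labels)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        vals = []
        for _ in range(n_repeats):
            xp = X.copy()
            xp[:, j] = xp[rng.permutation(len(X)), j]
            vals.append(base_auc - roc_auc(f(xp), labels))
        drops[j] = np.mean(vals)
    return np.maximum(drops, 0.0)


def feature_attributions(model: DISFCModel, inputs: dict, background: dict,
                         method: str = "shap", scope: str = "fusion",
                         labels=None, n_permutations: int = 30,
                         n_repeats: int = 10, background_size: int = 50,
                         seed: int = 0) -> AttributionReport:
    """Per-feature importances for the fusion input or the clinical branch.

    `inputs` and `background` map 'volumes'/'clinical'/'snps' to arrays on
    the model's input scales.  `method="shap"` returns mean |Shapley value|
    over the evaluation subjects; `method="permutation"` returns the mean
    AUC drop and requires `labels`.
    """
    _require_trained(model)
    rng = np.random.default_rng(seed)
    if scope == "fusion":
        X, names, grouping = _fusion_z(
            model, inputs.get("volumes"), inputs.get("clinical"),
            inputs.get("snps"))
        B, _, _ = _fusion_z(
            model, background.get("volumes"), background.get("clinical"),
            background.get("snps"))
        f = _fusion_head_fn(model)
    elif scope == "clinical":
        X, names, grouping = _clinical_matrix(model, inputs["clinical"])
        B, _, _ = _clinical_matrix(model, background["clinical"])
        f = _clinical_head_fn(model)
    else:
        raise ValueError(f"unknown scope '{scope}'")
    if len(B) == 0:
        raise DisfcError("background set is empty")
    if len(B) > background_size:
        B = B[rng.permutation(len(B))[:background_size]]

    if method == "shap":
        phi = _shapley_sampling(f, X, B, n_permutations, rng)
        scores = np.abs(phi).mean(axis=0)
    elif method == "permutation":
        if labels is None:
            raise ValueError("permutation importance requires labels")
        scores = _permutation_importance(f, X, np.asarray(labels), n_repeats, rng)
    else:
        raise ValueError(f"unknown attribution method '{method}'")
    return AttributionReport(
        scores=dict(zip(names, scores.astype(float))),
        grouping=grouping, method=method)


# ---------------------------------------------------------------------------
# Occlusion saliency
# ---------------------------------------------------------------------------

def volume_saliency(model: DISFCModel, volume, patch_size: int = 4,
                    stride: int | None = None, method: str = "occlusion"
                    ) -> np.ndarray:
    """Occlusion-sensitivity map for the spatial branch.

    Each patch is replaced by the volume's mean intensity; importance is the
    absolute change of the spatial head's probability, averaged over the
    occlusion windows covering each voxel.  Same shape as the input.
    """
    _require_trained(model)
    if method != "occlusion":
        raise ValueError(f"unknown saliency method '{method}'")
    arr = volume.intensities if isinstance(volume, VolumeImage) else np.asarray(volume)
    arr = np.asarray(arr, dtype=float)
    if any(patch_size > s for s in arr.shape):
        raise DimensionError(
            f"patch size {patch_size} exceeds volume shape {arr.shape}")
    stride = stride or patch_size
    model.set_training(False)

    def spatial_prob(batch):
        emb = model.embed_mri(Tensor(batch[:, None]))
        return model.mri_head(emb).sigmoid().data.reshape(-1)

    p0 = spatial_prob(arr[None])[0]
    fill = arr.mean()
    starts = [
        sorted(set(list(range(0, s - patch_size + 1, stride)) + [s - patch_size]))
        for s in arr.shape
    ]
    positions = list(product(*starts))
    heat = np.zeros(arr.shape)
    counts = np.zeros(arr.shape)
    chunk = 16
    for c0 in range(0, len(positions), chunk):
        batch_pos = positions[c0:c0 + chunk]
        batch = np.repeat(arr[None], len(batch_pos), axis=0)
        for b, (i, j, k) in enumerate(batch_pos):
            batch[b, i:i + patch_size, j:j + patch_size, k:k + patch_size] = fill
        probs = spatial_prob(batch)
        for b, (i, j, k) in enumerate(batch_pos):
            sl = (slice(i, i + patch_size), slice(j, j + patch_size),
                  slice(k, k + patch_size))
            heat[sl] += abs(probs[b] - p0)
            counts[sl] += 1
    return heat / np.maximum(counts, 1)
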