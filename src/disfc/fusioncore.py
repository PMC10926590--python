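"""Dual Interaction Stepwise Fusion Classifier (DISFC).

A three-branch multimodal network for predicting MCI-to-AD conversion from
a 3-D structural MRI volume, 14 baseline clinical features and a selected
SNP allele-count vector.  Each branch compresses its modality into an
8-dimensional embedding with its own auxiliary sigmoid head; the fusion
classifier combines the embeddings stepwise — imaging and clinical first
(joined with their flattened outer product, the inter-modal interaction
module), genetics concatenated second.  The clinical branch sees its raw
features augmented with all pairwise products (the intra-modal interaction
module).

Training minimizes  L = alpha*L_fusion + b1*L_mri + b2*L_clin + b3*L_snp
with binary cross-entropy per head and default weights (1.0, 1.5, 0.5, 0.5).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np

from . import nn
from ._autodiff import Tensor, concat
from .errors import ConfigurationError, DimensionError

__all__ = [
    "LossWeights",
    "ModelConfig",
    "DISFCModel",
    "build_model",
    "intra_modal_expand",
    "expanded_feature_names",
    "inter_modal_outer",
    "separable_conv3d_weight_count",
    "full_conv3d_weight_count",
    "bce_loss",
    "total_loss",
]

MODALITIES = ("mri", "clin", "snp")


@dataclass
class LossWeights:
    """Per-head loss weights: fusion head alpha, then one beta per extractor."""

    alpha: float = 1.0
    beta_mri: float = 1.5
    beta_clin: float = 0.5
    beta_snp: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        for name in ("beta_mri", "beta_clin", "beta_snp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass
class ModelConfig:
    volume_shape: tuple[int, int, int] = (32, 36, 40)
    n_clinical: int = 14
    n_snp_features: int = 49
    stem_channels: int = 8
    stage_channels: tuple[int, int] = (16, 32)
    kernel_size: int = 3
    n_residual_blocks: int = 4
    embedding_dim: int = 8
    branch_hidden_dim: int = 32
    fusion_hidden_dim: int = 16
    dropout_conv: float = 0.1
    dropout_fc: float = 0.2
    l2_strength: float = 1e-4
    activation: str = "relu"
    include_intra: bool = True      # clinical second-order interaction module
    include_outer: bool = True      # imaging-clinical outer-product module
    include_squares: bool = False   # add x_i^2 terms to the intra-modal expansion
    modalities: tuple[str, ...] = MODALITIES

    def __post_init__(self):
        if self.n_residual_blocks < 1:
            raise ConfigurationError("n_residual_blocks must be >= 1")
        if self.embedding_dim < 1:
            raise ConfigurationError("embedding_dim must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be a positive odd integer")
        bad = [m for m in self.modalities if m not in MODALITIES]
        if bad or not self.modalities:
            raise ConfigurationError(f"modalities invalid: {bad or 'empty'}")
        if len(self.volume_shape) != 3 or any(s < 4 for s in self.volume_shape):
            raise ConfigurationError("volume_shape must be 3 dims, each >= 4")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Interaction modules (pure array transforms; applied to normalized inputs)
# ---------------------------------------------------------------------------

def intra_modal_expand(x: np.ndarray, include_squares: bool = False) -> np.ndarray:
    """Append all pairwise products x_i*x_j (i<j, lexicographic) to x.

    Output length d + d(d-1)/2 (plus d more if squares are included).
    Works on a single vector or a (n, d) batch.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    d = x.shape[1]
    if d < 1:
        raise DimensionError("intra_modal_expand requires a non-empty vector")
    pairs = list(combinations(range(d), 2))
    prods = np.stack([x[:, i] * x[:, j] for i, j in pairs], axis=1) if pairs \
        else np.empty((x.shape[0], 0))
    parts = [x, prods]
    if include_squares:
        parts.append(x * x)
    out = np.concatenate(parts, axis=1)
    return out[0] if single else out


def expanded_feature_names(names: list[str], include_squares: bool = False) -> list[str]:
    """Names matching intra_modal_expand's column order."""
    out = list(names)
    out += [f"{a}*{b}" for a, b in combinations(names, 2)]
    if include_squares:
        out += [f"{a}^2" for a in names]
    return out


def inter_modal_outer(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-major flattened outer product u v^T (batched on leading axis)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0 or v.size == 0:
        raise DimensionError("inter_modal_outer requires non-empty inputs")
    if u.ndim == 1 and v.ndim == 1:
        return np.outer(u, v).reshape(-1)
    return np.einsum("ni,nj->nij", u, v).reshape(u.shape[0], -1)


def _outer_tensor(u: Tensor, v: Tensor) -> Tensor:
    """Autodiff version of the batched flattened outer product."""
    n, p = u.shape
    q = v.shape[1]
    out = (u.reshape(n, p, 1) * v.reshape(n, 1, q)).reshape(n, p * q)
    return out


def separable_conv3d_weight_count(c_in: int, c_out: int, k: int) -> int:
    """Weights (no bias) of a depthwise+pointwise separable 3-D convolution."""
    return k**3 * c_in + c_in * c_out


def full_conv3d_weight_count(c_in: int, c_out: int, k: int) -> int:
    """Weights (no bias) of the dense 3-D convolution it replaces."""
    return k**3 * c_in * c_out


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_EPS = 1e-7


def bce_loss(y, yhat):
    """Mean binary cross-entropy; probabilities clipped to [eps, 1-eps].

    Returns a Tensor when `yhat` is a Tensor (for backprop), else a float.
    """
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=float)
    if isinstance(yhat, Tensor):
        if y_arr.reshape(-1).shape[0] != yhat.data.reshape(-1).shape[0]:
            raise DimensionError("y and yhat lengths differ")
        p = yhat.reshape(-1).clip(_EPS, 1.0 - _EPS)
        yv = y_arr.reshape(-1)
        return -(Tensor(yv) * p.log() + Tensor(1.0 - yv) * (1.0 - p).log()).mean()
    p = np.clip(np.asarray(yhat, dtype=float).reshape(-1), _EPS, 1.0 - _EPS)
    yv = y_arr.reshape(-1)
    if yv.shape != p.shape:
        raise DimensionError("y and yhat lengths differ")
    return float(-(yv * np.log(p) + (1 - yv) * np.log(1 - p)).mean())


def total_loss(head_losses, weights: LossWeights | None = None):
    """Weighted sum of the four head losses (fusion, mri, clin, snp).

    `head_losses` is a mapping with those keys or a sequence in that order;
    missing heads (ablated modalities) contribute zero.
    """
    w = weights or LossWeights()
    if not isinstance(head_losses, dict):
        head_losses = dict(zip(("fusion", "mri", "clin", "snp"), head_losses))
    coef = {"fusion": w.alpha, "mri": w.beta_mri, "clin": w.beta_clin, "snp": w.beta_snp}
    total = None
    for name, loss in head_losses.items():
        val = loss.data if isinstance(loss, Tensor) else loss
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"head loss '{name}' is negative")
        term = loss * coef[name]
        total = term if total is None else total + term
    return total


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class DISFCModel(nn.Module):
    """Three feature extractors, auxiliary heads, and the stepwise fusion head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.is_trained = False
        e = cfg.embedding_dim
        k = cfg.kernel_size

        if "mri" in cfg.modalities:
            c1, c2 = cfg.stage_channels
            self.stem = nn.SepConvBlock(1, cfg.stem_channels, k, rng,
                                        dropout=cfg.dropout_conv)
            self.down1 = nn.SepConvBlock(cfg.stem_channels, c1, k, rng,
                                         stride=2, dropout=cfg.dropout_conv)
            self.resgroup = nn.ResidualGroup(c1, c1, k, rng,
                                             n_blocks=cfg.n_residual_blocks,
                                             dropout=cfg.dropout_conv)
            self.down2 = nn.SepConvBlock(c1, c2, k, rng,
                                         stride=2, dropout=cfg.dropout_conv)
            self.mri_fc = nn.Dense(c2, e, rng)
            self.mri_head = nn.Dense(e, 1, rng)

        if "clin" in cfg.modalities:
            d = cfg.n_clinical
            n_in = len(expanded_feature_names([str(i) for i in range(d)],
                                              cfg.include_squares)) \
                if cfg.include_intra else d
            self.clin_in_dim = n_in
            self.clin_fc1 = nn.FCBlock(n_in, cfg.branch_hidden_dim, rng,
                                       dropout=cfg.dropout_fc)
            self.clin_fc2 = nn.Dense(cfg.branch_hidden_dim, e, rng)
            self.clin_head = nn.Dense(e, 1, rng)

        if "snp" in cfg.modalities:
            self.snp_fc1 = nn.FCBlock(cfg.n_snp_features, cfg.branch_hidden_dim,
                                      rng, dropout=cfg.dropout_fc)
            self.snp_fc2 = nn.Dense(cfg.branch_hidden_dim, e, rng)
            self.snp_head = nn.Dense(e, 1, rng)

        if len(cfg.modalities) > 1:
            first, second = cfg.modalities[0], cfg.modalities[1]
            z1 = 2 * e
            if cfg.include_outer and {first, second} == {"mri", "clin"}:
                z1 += e * e
            self.fuse_fc1 = nn.FCBlock(z1, cfg.fusion_hidden_dim, rng,
                                       dropout=cfg.dropout_fc)
            z2 = cfg.fusion_hidden_dim + e * (len(cfg.modalities) - 2)
            self.fuse_out = nn.Dense(z2, 1, rng)

    # -- branch embeddings --------------------------------------------------

    def embed_mri(self, vol: Tensor) -> Tensor:
        h = self.stem(vol)
        h = self.down1(h)
        h = self.resgroup(h)
        h = self.down2(h)
        return self.mri_fc(nn.global_avg_pool(h))

    def embed_clin(self, clin: np.ndarray) -> Tensor:
        x = np.asarray(clin, dtype=float)
        if self.cfg.include_intra:
            x = intra_modal_expand(x, self.cfg.include_squares)
        return self.clin_fc2(self.clin_fc1(Tensor(x)))

    def embed_snp(self, snp: np.ndarray) -> Tensor:
        return self.snp_fc2(self.snp_fc1(Tensor(np.asarray(snp, dtype=float))))

    # -- fusion --------------------------------------------------------------

    def stepwise_fuse(self, embeddings: dict[str, Tensor]) -> Tensor:
        """Stage 1: first two modalities (+ outer product); stage 2: the rest."""
        order = [m for m in self.cfg.modalities]
        ea, eb = embeddings[order[0]], embeddings[order[1]]
        if ea.shape[-1] != eb.shape[-1]:
            raise DimensionError("embedding lengths differ")
        parts = [ea, eb]
        if self.cfg.include_outer and {order[0], order[1]} == {"mri", "clin"}:
            parts.append(_outer_tensor(ea, eb))
        h = self.fuse_fc1(concat(parts, axis=-1))
        rest = [embeddings[m] for m in order[2:]]
        z2 = concat([h] + rest, axis=-1) if rest else h
        return self.fuse_out(z2)

    # -- forward -------------------------------------------------------------

    def forward(self, volumes=None, clinical=None, snps=None) -> dict[str, Tensor]:
        """Return sigmoid outputs for every active head, each shaped (n, 1).

        `volumes` is (n, 1, D, H, W); `clinical` (n, 14) normalized to [0,1];
        `snps` (n, n_snp_features) scaled allele counts.
        """
        embeddings: dict[str, Tensor] = {}
        outputs: dict[str, Tensor] = {}
        if "mri" in self.cfg.modalities:
            embeddings["mri"] = self.embed_mri(Tensor(np.asarray(volumes, dtype=float)))
            outputs["mri"] = self.mri_head(embeddings["mri"]).sigmoid()
        if "clin" in self.cfg.modalities:
            embeddings["clin"] = self.embed_clin(clinical)
            outputs["clin"] = self.clin_head(embeddings["clin"]).sigmoid()
        if "snp" in self.cfg.modalities:
            embeddings["snp"] = self.embed_snp(snps)
            outputs["snp"] = self.snp_head(embeddings["snp"]).sigmoid()
        if len(self.cfg.modalities) > 1:
            outputs["fusion"] = self.stepwise_fuse(embeddings).sigmoid()
        else:
            outputs["fusion"] = outputs[self.cfg.modalities[0]]
        self._last_embeddings = embeddings
        return outputs

    __call__ = forward

    def predict_proba(self, volumes=None, clinical=None, snps=None) -> np.ndarray:
        """Fusion-head conversion probabilities in eval mode, shape (n,)."""
        was_training = self.training
        self.set_training(False)
        try:
            out = self.forward(volumes=volumes, clinical=clinical, snps=snps)
            return out["fusion"].data.reshape(-1)
        finally:
            self.set_training(was_training)

    # -- persistence ----------------------------------------------------------

    def save_weights(self, path):
        arrays = {name: t.data for name, t in self.named_parameters()}
        running = {}
        for name, mod in _iter_modules(self):
            if isinstance(mod, nn.BatchNorm):
                running[f"{name}.running_mean"] = mod.running_mean
                running[f"{name}.running_var"] = mod.running_var
        np.savez(path, __fingerprint__=np.frombuffer(
            self.cfg.fingerprint().encode(), dtype=np.uint8), **arrays, **running)

    def load_weights(self, path):
        data = np.load(path)
        fp = bytes(data["__fingerprint__"]).decode()
        if fp != self.cfg.fingerprint():
            raise ConfigurationError(
                f"checkpoint fingerprint {fp} does not match model config "
                f"{self.cfg.fingerprint()}")
        params = dict(self.named_parameters())
        for name, t in params.items():
            t.data = data[name]
        for name, mod in _iter_modules(self):
            if isinstance(mod, nn.BatchNorm):
                mod.running_mean = data[f"{name}.running_mean"]
                mod.running_var = data[f"{name}.running_var"]
        self.is_trained = True


def _iter_modules(mod: nn.Module, prefix: str = ""):
    yield prefix.rstrip("."), mod
    for name, child in mod._children.items():
        yield from _iter_modules(child, prefix + name + ".")


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> DISFCModel:
    """Construct a DISFC model with seeded He-normal initialization."""
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(seed)
    return DISFCModel(cfg, rng)
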