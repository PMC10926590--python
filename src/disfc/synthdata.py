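"""Synthetic multimodal cohort generator.

Emulates the statistical structure of an MCI-conversion cohort at desk
scale: T1-like volumes with a class-dependent focal intensity loss inside a
fixed ellipsoidal region (an atrophy surrogate with retrievable ground-truth
mask), clinical features whose label signal lives purely in a pairwise
product (class-dependent correlation sign with identical marginals), and
Hardy-Weinberg-conforming genotypes with a small causal subset plus three
planted QC-decoy blocks (low MAF, low call rate, HWE-violating), each
tagged so filter tests have ground truth.

Default cohort proportions emulate a realistic MCI-conversion cohort: 37.3% of the MCI
subjects are progressors, a ~14/252 fraction is held out as an independent
test set, and diagnosed-AD positives (45 per 252 MCI) join only the
training splits.

All randomness derives from one seed; per-subject and per-block substreams
are keyed by counter, not call order, so cohorts are bit-identical across
runs for a fixed seed.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import CLINICAL_FEATURES, GenotypeMatrix, LabeledCohort, VolumeImage
from .errors import ConfigurationError
from .preprocess import DEFAULT_QC, recompute_snp_stats

__all__ = ["SynthConfig", "generate_cohort", "generate_volume",
           "generate_clinical", "generate_genotypes", "roi_mask", "write_cohort"]

# Table-style marginal (mean, SD) used to place continuous features on a
# realistic scale; affine maps do not alter the planted correlation structure.
_FEATURE_SCALE = {
    "age": (73.2, 7.26), "education": (15.9, 2.89), "MMSE": (27.7, 1.80),
    "CDRSB": (1.50, 0.994), "ADAS11": (9.61, 4.24), "ADAS13": (15.4, 6.66),
    "RAVLT_immediate": (35.8, 10.8), "RAVLT_learning": (4.27, 2.65),
    "RAVLT_pct_forgetting": (57.0, 34.7), "mPACCdigit": (-5.53, 4.31),
    "mPACCtrailsB": (-5.19, 4.09), "FAQ": (3.53, 4.51), "LDELTOTAL": (6.57, 4.41),
}

#: Features carrying the planted pure-interaction signal (correlation-sign flip).
INTERACTION_PAIR = ("MMSE", "CDRSB")
#: Features carrying weak main effects.
MAIN_EFFECT_FEATURES = ("ADAS13", "LDELTOTAL")
_MAIN_EFFECT_SHIFT = 0.2  # in SD units

_DECOY_TAGS = ("low_maf", "low_callrate", "hwe_violating")


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort."""

    n_subjects: int = 252
    prevalence: float = 0.373
    volume_shape: tuple[int, int, int] = (32, 36, 40)
    n_clinical: int = 14
    n_snps: int = 300
    n_causal_snps: int = 8
    interaction_strength: float = 0.8
    atrophy_fraction: float = 0.15
    noise_sd: float = 0.1
    seed: int = 0
    missing_clinical_fraction: float = 0.05
    snp_missing_rate: float = 0.01
    n_decoys_per_block: int = 10
    causal_freq_shift: float = 0.12
    test_fraction: float = 14 / 252
    n_train_only_ad: int | None = None  # None: scaled as 45 per 252 MCI subjects

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie strictly in (0, 1)")
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ConfigurationError("volume_shape must have 3 dims, each >= 8")
        if self.n_clinical != len(CLINICAL_FEATURES):
            raise ConfigurationError(
                f"n_clinical must be {len(CLINICAL_FEATURES)} (the baseline feature set)")
        if self.n_causal_snps > self.n_snps:
            raise ConfigurationError("n_causal_snps must not exceed n_snps")
        if self.n_snps < self.n_causal_snps + 3 * self.n_decoys_per_block:
            raise ConfigurationError(
                "n_snps too small for the causal and decoy blocks")
        if self.interaction_strength < 0:
            raise ConfigurationError("interaction_strength must be nonnegative")
        if not (0.0 <= self.atrophy_fraction < 1.0):
            raise ConfigurationError("atrophy_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not (0.0 <= self.missing_clinical_fraction < 1.0):
            raise ConfigurationError("missing_clinical_fraction must lie in [0, 1)")
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigurationError("test_fraction must lie in (0, 1)")

    @property
    def rho(self) -> float:
        """interaction_strength mapped into [0, 1)."""
        return min(float(self.interaction_strength), 0.99)


def _substream(cfg: SynthConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *key])


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def roi_mask(cfg: SynthConfig) -> np.ndarray:
    """Ground-truth ellipsoidal atrophy region (fixed, attribution-testable).

    Centered at fractional position (0.5, 0.45, 0.60) with semi-axes 18% of
    each dimension — a stand-in for a focal medial-temporal region.
    """
    shape = cfg.volume_shape
    center = [0.50 * shape[0], 0.45 * shape[1], 0.60 * shape[2]]
    semi = [max(1.5, 0.18 * s) for s in shape]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return dist <= 1.0


def generate_volume(label: int, cfg: SynthConfig,
                    rng: np.random.Generator) -> VolumeImage:
    """One T1-like volume: smooth background field + noise, with the ROI's
    mean intensity reduced by `atrophy_fraction` for progressors."""
    shape = cfg.volume_shape
    coarse = rng.normal(0.0, 1.0, size=(4, 4, 4))
    zoom = [s / 4 for s in shape]
    smooth = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1], : shape[2]]
    field = 0.6 + 0.12 * smooth
    if label == 1 and cfg.atrophy_fraction > 0:
        mask = roi_mask(cfg)
        field = np.where(mask, field * (1.0 - cfg.atrophy_fraction), field)
    field = field + rng.normal(0.0, cfg.noise_sd, size=shape)
    return VolumeImage(field.astype(np.float32))


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------

def generate_clinical(labels: np.ndarray, cfg: SynthConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Clinical table whose label signal lives in a pairwise product.

    The interaction pair is drawn jointly with correlation +rho for
    progressors and -rho for stable subjects, so both classes share
    identical marginals; two features carry weak main effects; everything
    else (including sex) is label-independent noise.  A configurable
    fraction of continuous entries is set missing.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    rho = cfg.rho
    cont = [c for c in CLINICAL_FEATURES if c != "sex"]
    z = pd.DataFrame(rng.normal(0.0, 1.0, size=(n, len(cont))), columns=cont)

    a, b = INTERACTION_PAIR
    signs = np.where(labels == 1, 1.0, -1.0)
    u = rng.normal(0.0, 1.0, n)
    w = rng.normal(0.0, 1.0, n)
    z[a] = u
    z[b] = signs * rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * w

    for feat in MAIN_EFFECT_FEATURES:
        z[feat] = z[feat] + _MAIN_EFFECT_SHIFT * labels

    if cfg.missing_clinical_fraction > 0:
        mask = rng.random(z.shape) < cfg.missing_clinical_fraction
        z = z.mask(mask)

    out = pd.DataFrame(index=range(n))
    for feat in CLINICAL_FEATURES:
        if feat == "sex":
            out[feat] = np.where(rng.random(n) < 0.623, "M", "F")
        else:
            mu, sd = _FEATURE_SCALE[feat]
            out[feat] = mu + sd * z[feat].to_numpy()
    return out[CLINICAL_FEATURES]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _hwe_draw(rng, n, p):
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    return rng.choice([0.0, 1.0, 2.0], size=n, p=probs)


def _passes_default_qc(col: np.ndarray) -> bool:
    from .preprocess import hwe_exact_pvalue

    obs = col[~np.isnan(col)]
    n_obs = len(obs)
    if n_obs == 0 or n_obs / len(col) < DEFAULT_QC.min_call_rate:
        return False
    alt = obs.sum() / (2 * n_obs)
    if min(alt, 1 - alt) < DEFAULT_QC.min_maf:
        return False
    n1 = int((obs == 1).sum())
    n2 = int((obs == 2).sum())
    return hwe_exact_pvalue(n_obs - n1 - n2, n1, n2) >= DEFAULT_QC.min_hwe_p


def generate_genotypes(labels: np.ndarray, cfg: SynthConfig,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Allele-count matrix with clean HWE SNPs, causal SNPs and decoy blocks.

    Clean and causal SNPs are redrawn until their *realized* statistics pass
    the default QC thresholds (bounded retries, deterministic given the
    stream), so the generator's clean/causal vs decoy tags are exact QC
    ground truth.  Causal SNPs carry a class-conditional allele-frequency
    shift; decoy blocks violate exactly their tagged criterion.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    n_decoy = cfg.n_decoys_per_block
    n_clean = cfg.n_snps - cfg.n_causal_snps - 3 * n_decoy
    cols, tags = [], []

    def draw_clean():
        for _ in range(200):
            p = rng.uniform(0.10, 0.50)
            col = _hwe_draw(rng, n, p)
            n_miss = min(rng.binomial(n, cfg.snp_missing_rate),
                         int(np.floor((1 - DEFAULT_QC.min_call_rate) * n)))
            if n_miss:
                col[rng.choice(n, n_miss, replace=False)] = np.nan
            if _passes_default_qc(col):
                return col
        raise RuntimeError("could not draw a QC-clean SNP")  # pragma: no cover

    for _ in range(n_clean):
        cols.append(draw_clean())
        tags.append("clean")

    for _ in range(cfg.n_causal_snps):
        for _ in range(200):
            p0 = rng.uniform(0.15, 0.40)
            p_by_label = np.clip(p0 + cfg.causal_freq_shift * labels, 0.02, 0.98)
            col = ((rng.random(n) < p_by_label).astype(float)
                   + (rng.random(n) < p_by_label).astype(float))
            if _passes_default_qc(col):
                break
        cols.append(col)
        tags.append("causal")

    # Decoy block 1: rare variants (all heterozygous carriers, so HWE-clean).
    for _ in range(n_decoy):
        col = np.zeros(n)
        n_carriers = max(1, int(round(0.03 * n)))
        col[rng.choice(n, n_carriers, replace=False)] = 1.0
        cols.append(col)
        tags.append("low_maf")

    # Decoy block 2: HWE-conforming but with 10% of calls missing.
    for _ in range(n_decoy):
        for _ in range(200):
            col = _hwe_draw(rng, n, rng.uniform(0.20, 0.40))
            n_miss = int(np.ceil(0.10 * n))
            col[rng.choice(n, n_miss, replace=False)] = np.nan
            obs = col[~np.isnan(col)]
            alt = obs.sum() / (2 * len(obs))
            if min(alt, 1 - alt) >= DEFAULT_QC.min_maf:
                break
        cols.append(col)
        tags.append("low_callrate")

    # Decoy block 3: total heterozygote deficiency (half 0, half 2).
    for _ in range(n_decoy):
        col = np.zeros(n)
        col[rng.permutation(n)[: n // 2]] = 2.0
        cols.append(col)
        tags.append("hwe_violating")

    counts = np.column_stack(cols)
    meta = pd.DataFrame({
        "id": [f"snp{j:05d}" for j in range(counts.shape[1])],
        "chrom": "1",
        "pos": np.arange(1, counts.shape[1] + 1) * 1000,
        "tag": tags,
    })
    gm = GenotypeMatrix(counts=counts, snp_meta=meta,
                        subject_ids=[str(i) for i in range(n)])
    return recompute_snp_stats(gm)


# ---------------------------------------------------------------------------
# Cohort assembly and I/O
# ---------------------------------------------------------------------------

def generate_cohort(cfg: SynthConfig) -> LabeledCohort:
    """Deterministic labeled multimodal cohort.

    Labels are assigned by exact count, round(prevalence * n_subjects),
    shuffled by the seed stream; every subject has all three modalities.
    Diagnosed-AD train-only positives are appended after the MCI subjects.
    """
    n = cfg.n_subjects
    n_ad = cfg.n_train_only_ad
    if n_ad is None:
        n_ad = int(round(45 * n / 252))

    rng_assign = _substream(cfg, 0)
    n_pos = int(round(cfg.prevalence * n))
    labels_mci = np.zeros(n, dtype=int)
    labels_mci[rng_assign.permutation(n)[:n_pos]] = 1

    # Stratified independent-test split of the MCI subjects.
    n_test = max(2, int(round(cfg.test_fraction * n)))
    roles_mci = np.array(["cv"] * n, dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels_mci == cls)
        n_cls_test = max(1, int(round(n_test * len(idx) / n)))
        roles_mci[rng_assign.permutation(idx)[:n_cls_test]] = "test"

    labels = np.concatenate([labels_mci, np.ones(n_ad, dtype=int)])
    roles = np.concatenate([roles_mci, np.array(["train_only_AD"] * n_ad, dtype=object)])
    subject_ids = [f"S{i + 1:04d}" for i in range(n)] + \
        [f"AD{i + 1:04d}" for i in range(n_ad)]

    volumes = [
        generate_volume(int(labels[i]), cfg, _substream(cfg, 1, i))
        for i in range(len(labels))
    ]
    for v, sid in zip(volumes, subject_ids):
        v.subject_id = sid

    clinical = generate_clinical(labels, cfg, _substream(cfg, 2))
    clinical.index = pd.Index(subject_ids)

    genotypes = generate_genotypes(labels, cfg, _substream(cfg, 3))
    genotypes.subject_ids = list(subject_ids)

    return LabeledCohort(
        subject_ids=subject_ids, volumes=volumes, clinical=clinical,
        genotypes=genotypes, labels=labels, roles=roles,
    )


def write_cohort(cohort: LabeledCohort, directory) -> dict:
    """Write NIfTI volumes, clinical CSV, VCF genotypes, labels CSV and a
    checksum manifest; returns the manifest (also saved as manifest.json)."""
    from . import io as disfc_io

    return disfc_io.write_cohort(cohort, directory)
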