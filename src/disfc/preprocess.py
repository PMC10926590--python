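"""Per-modality preprocessing.

Volumes: center crop to a global target shape, then max-min scaling to [0,1].
Clinical: binary sex encoding, mean imputation and min-max scaling, with the
imputation/scaling statistics fitted on the training split only and reused
(leakage-free) on held-out data.
Genetics: quality control on call rate, minor allele frequency and the exact
Hardy-Weinberg test; modal-genotype imputation; a knowledge-driven SNP list
filter; and L1-logistic (Lasso) selection bisected to an exact active-set
size (default 49 features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .datatypes import CLINICAL_FEATURES, GenotypeMatrix, VolumeImage
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionError,
    SchemaError,
)

__all__ = [
    "QCThresholds",
    "DEFAULT_QC",
    "ClinicalScaler",
    "crop_volume",
    "crop_reduction_fraction",
    "normalize_volume",
    "preprocess_clinical",
    "hwe_exact_pvalue",
    "recompute_snp_stats",
    "qc_filter_snps",
    "impute_genotypes",
    "knowledge_filter",
    "lasso_select",
]


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def crop_volume(v: VolumeImage, target_shape) -> VolumeImage:
    """Center-crop to `target_shape`; contents are a contiguous sub-grid."""
    target_shape = tuple(int(t) for t in target_shape)
    src = v.shape
    if len(target_shape) != 3:
        raise DimensionError("target_shape must have 3 dimensions")
    for axis, (s, t) in enumerate(zip(src, target_shape)):
        if t > s:
            raise DimensionError(
                f"target size {t} exceeds source size {s} on axis {axis}")
        if t < 1:
            raise DimensionError(f"target size must be positive on axis {axis}")
    starts = [(s - t) // 2 for s, t in zip(src, target_shape)]
    sl = tuple(slice(a, a + t) for a, t in zip(starts, target_shape))
    return VolumeImage(v.intensities[sl].copy(), v.spacing_mm, v.subject_id)


def crop_reduction_fraction(src_shape, dst_shape) -> float:
    """Fraction of total voxel volume removed by cropping: 1 - prod(dst)/prod(src)."""
    src = np.asarray(src_shape, dtype=float)
    dst = np.asarray(dst_shape, dtype=float)
    if np.any(src <= 0) or np.any(dst <= 0):
        raise DimensionError("shapes must be positive")
    return float(1.0 - dst.prod() / src.prod())


def normalize_volume(v: VolumeImage) -> VolumeImage:
    """Voxelwise max-min scaling to [0, 1]."""
    x = v.intensities.astype(np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateInputError(
            f"volume '{v.subject_id}' is constant; max-min scaling undefined")
    return VolumeImage((x - lo) / (hi - lo), v.spacing_mm, v.subject_id)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

@dataclass
class ClinicalScaler:
    """Imputation means and min-max bounds fitted on a training split."""

    means: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray


def _encode_clinical(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in CLINICAL_FEATURES if c not in table.columns]
    if missing:
        raise SchemaError(f"clinical table is missing column '{missing[0]}'")
    df = table[CLINICAL_FEATURES].copy()
    sex = df["sex"]
    if sex.dtype == object:
        mapped = sex.map({"F": 0.0, "M": 1.0})
        bad = sex.notna() & mapped.isna()
        if bad.any():
            raise SchemaError(f"unrecognized sex value {sex[bad].iloc[0]!r}")
        df["sex"] = mapped
    return df.astype(float).to_numpy()


def preprocess_clinical(
    table: pd.DataFrame, fit_stats: ClinicalScaler | None = None
) -> tuple[np.ndarray, ClinicalScaler]:
    """Encode, impute and scale the 14 clinical features to [0, 1].

    When `fit_stats` is None the imputation means and min-max bounds are
    fitted on `table` (the training split); otherwise they are reused and
    out-of-range held-out values are clipped to [0, 1].
    """
    x = _encode_clinical(table)
    if fit_stats is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(x, axis=0)
        if np.any(np.isnan(means)):
            col = CLINICAL_FEATURES[int(np.argmax(np.isnan(means)))]
            raise SchemaError(f"column '{col}' has no observed values to impute from")
        xi = np.where(np.isnan(x), means, x)
        mins, maxs = xi.min(axis=0), xi.max(axis=0)
        fit_stats = ClinicalScaler(means=means, mins=mins, maxs=maxs)
    else:
        xi = np.where(np.isnan(x), fit_stats.means, x)
    span = fit_stats.maxs - fit_stats.mins
    span = np.where(span == 0, 1.0, span)
    scaled = np.clip((xi - fit_stats.mins) / span, 0.0, 1.0)
    return scaled, fit_stats


# ---------------------------------------------------------------------------
# Genetic QC
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """SNP retention thresholds: call rate, minor allele frequency, HWE p."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 1e-6

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name} must lie in [0, 1)")


DEFAULT_QC = QCThresholds()


def hwe_exact_pvalue(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the probabilities of configurations no more probable than the
    observed one (the standard exact HWE formulation).
    """
    n_aa_hom, n_het, n_bb_hom = int(n_aa_hom), int(n_het), int(n_bb_hom)
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise ValueError("at least one genotype observation required")
    rare = min(2 * n_aa_hom + n_het, 2 * n_bb_hom + n_het)
    if rare == 0:
        return 1.0

    # Unnormalized probabilities over het counts with the parity of `rare`,
    # built by the two-sided recurrence from the distribution's interior.
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het >= 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (
            4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het + 2 <= rare:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / (
            (het + 2) * (het + 1))
        het += 2
    total = sum(probs.values())
    obs = probs[n_het] / total
    return float(min(1.0, sum(p for p in probs.values() if p / total <= obs * (1 + 1e-12)) / total))


def recompute_snp_stats(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Recompute call_rate, maf and hwe_p columns from the counts."""
    counts = gm.counts
    n = counts.shape[0]
    observed = ~np.isnan(counts)
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / n
    with np.errstate(invalid="ignore"):
        n_het = np.nansum(counts == 1, axis=0)
        n_hom2 = np.nansum(counts == 2, axis=0)
    alt_freq = np.where(n_obs > 0, (n_het + 2 * n_hom2) / np.maximum(2 * n_obs, 1), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    hwe = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if n_obs[j] == 0:
            hwe[j] = 1.0
            continue
        n2 = int(n_hom2[j])
        n1 = int(n_het[j])
        n0 = int(n_obs[j]) - n1 - n2
        hwe[j] = hwe_exact_pvalue(n0, n1, n2)
    meta = gm.snp_meta.copy()
    meta["call_rate"] = call_rate
    meta["maf"] = maf
    meta["hwe_p"] = hwe
    return GenotypeMatrix(counts=counts, snp_meta=meta, subject_ids=gm.subject_ids)


def qc_filter_snps(
    gm: GenotypeMatrix, thresholds: QCThresholds = DEFAULT_QC
) -> tuple[GenotypeMatrix, dict]:
    """Retain SNPs passing all three QC criteria; report removals per criterion.

    The criteria form a conjunction, so their order cannot change the
    surviving set.  Statistics are recomputed from the counts first.
    """
    gm = recompute_snp_stats(gm)
    meta = gm.snp_meta
    pass_cr = meta["call_rate"].to_numpy() >= thresholds.min_call_rate
    pass_maf = meta["maf"].to_numpy() >= thresholds.min_maf
    pass_hwe = meta["hwe_p"].to_numpy() >= thresholds.min_hwe_p
    keep = pass_cr & pass_maf & pass_hwe
    report = {
        "n_input": gm.n_snps,
        "n_kept": int(keep.sum()),
        "removed_call_rate": int((~pass_cr).sum()),
        "removed_maf": int((~pass_maf).sum()),
        "removed_hwe": int((~pass_hwe).sum()),
    }
    return gm.take_snps(np.flatnonzero(keep)), report


def impute_genotypes(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-SNP modal genotype.

    Ties between modes resolve to the lower allele count.  A SNP with no
    observed calls is an error (it should have failed call-rate QC).
    """
    counts = gm.counts.copy()
    for j in range(counts.shape[1]):
        col = counts[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss.all():
            raise DegenerateInputError(
                f"SNP '{gm.snp_meta['id'].iloc[j]}' has no observed genotypes")
        tallies = [(col == g).sum() for g in (0.0, 1.0, 2.0)]
        mode = float(int(np.argmax(tallies)))  # argmax takes the lowest on ties
        col[miss] = mode
    return GenotypeMatrix(counts=counts, snp_meta=gm.snp_meta.copy(),
                          subject_ids=list(gm.subject_ids))


def knowledge_filter(gm: GenotypeMatrix, snp_ids) -> GenotypeMatrix:
    """Restrict to a knowledge-driven SNP ID list, preserving matrix order."""
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise SchemaError("knowledge SNP list is empty")
    wanted = set(snp_ids)
    present = gm.snp_meta["id"].isin(wanted).to_numpy()
    absent = wanted - set(gm.snp_meta["id"])
    if absent:
        warnings.warn(
            f"{len(absent)} knowledge-list SNP IDs absent from matrix "
            f"(e.g. {sorted(absent)[:3]})", stacklevel=2)
    if not present.any():
        raise SchemaError("no knowledge-list SNP IDs found in the matrix")
    return gm.take_snps(np.flatnonzero(present))


# ---------------------------------------------------------------------------
# Lasso-to-k selection
# ---------------------------------------------------------------------------

def _l1_active_set(xs: np.ndarray, y: np.ndarray, c: float) -> np.ndarray:
    model = LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", max_iter=5000, tol=1e-9,
        random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(xs, y)
    return np.flatnonzero(np.abs(model.coef_[0]) > 1e-10)


def lasso_select(X: np.ndarray, y: np.ndarray, k: int = 49) -> np.ndarray:
    """Select column indices via L1-penalized logistic regression.

    The penalty is found by bisection so the active set has exactly `k`
    members; when `k` falls inside a jump of the regularization path, the
    nearest achievable size is used, preferring fewer than `k`.
    Deterministic for fixed inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, m = X.shape
    if not (1 <= k <= m):
        raise ValueError(f"k must lie in [1, {m}], got {k}")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if k == m:
        return np.arange(m)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (X - X.mean(axis=0)) / sd

    lo, hi = 1e-6, 1.0
    for _ in range(60):
        if len(_l1_active_set(xs, y, hi)) >= k:
            break
        hi *= 4.0
    best: np.ndarray = np.array([], dtype=int)
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        active = _l1_active_set(xs, y, mid)
        if len(active) == k:
            return np.sort(active)
        if len(active) < k:
            if len(active) > len(best):
                best = active
            lo = mid
        else:
            hi = mid
    if len(best) == 0:
        best = _l1_active_set(xs, y, hi)[:k]
    return np.sort(best)
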