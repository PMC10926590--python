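"""Core in-memory containers shared across modules.

Genotypes are held as allele counts {0, 1, 2} with NaN for missing calls;
clinical tables are pandas DataFrames with the 14 canonical baseline
feature columns; volumes carry their voxel spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, SchemaError

#: The 14 baseline clinical features: demographics plus cognitive test scores
#: (MMSE, CDR sum-of-boxes, ADAS-Cog 11/13, Rey Auditory Verbal Learning Test,
#: modified PACC composites, Functional Activity Questionnaire, delayed recall).
CLINICAL_FEATURES = [
    "age",
    "sex",
    "education",
    "MMSE",
    "CDRSB",
    "ADAS11",
    "ADAS13",
    "RAVLT_immediate",
    "RAVLT_learning",
    "RAVLT_pct_forgetting",
    "mPACCdigit",
    "mPACCtrailsB",
    "FAQ",
    "LDELTOTAL",
]

SNP_META_COLUMNS = ["id", "chrom", "pos", "call_rate", "maf", "hwe_p"]


@dataclass
class VolumeImage:
    """A 3-D intensity grid with voxel spacing (mm) and its subject ID."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise DimensionError("VolumeImage requires a 3-D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("VolumeImage intensities must be finite")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive reals")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs allele counts with per-SNP metadata.

    `counts` is float with entries in {0, 1, 2} or NaN (missing call).
    `snp_meta` has one row per SNP column, in column order, with at least
    id/chrom/pos; call_rate/maf/hwe_p are recomputable from the counts
    (see preprocess.recompute_snp_stats).  An optional `tag` column labels
    planted QC decoys in synthetic data.
    """

    counts: np.ndarray
    snp_meta: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise DimensionError("genotype counts must be 2-D (subjects x SNPs)")
        if len(self.snp_meta) != self.counts.shape[1]:
            raise SchemaError("snp_meta row count must equal SNP column count")
        if len(self.subject_ids) != self.counts.shape[0]:
            raise SchemaError("subject_ids length must equal subject row count")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype counts must be in {0,1,2} or NaN")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def take_snps(self, col_idx) -> "GenotypeMatrix":
        col_idx = np.asarray(col_idx)
        return GenotypeMatrix(
            counts=self.counts[:, col_idx].copy(),
            snp_meta=self.snp_meta.iloc[col_idx].reset_index(drop=True),
            subject_ids=list(self.subject_ids),
        )


@dataclass
class LabeledCohort:
    """A complete multimodal cohort: one entry per subject in every container.

    Roles: 'cv' (cross-validation pool), 'test' (independent test set) and
    'train_only_AD' (diagnosed-AD positives used only for training, to
    counter class imbalance; always labeled 1).
    """

    subject_ids: list[str]
    volumes: list[VolumeImage]
    clinical: pd.DataFrame
    genotypes: GenotypeMatrix
    labels: np.ndarray
    roles: np.ndarray

    def __post_init__(self):
        n = len(self.subject_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        self.roles = np.asarray(self.roles, dtype=object)
        if not (len(self.volumes) == len(self.clinical) == n
                == self.genotypes.n_subjects == len(self.labels) == len(self.roles)):
            raise SchemaError("all cohort containers must share one subject list")
        if list(self.clinical.index) != list(self.subject_ids):
            raise SchemaError("clinical table index must equal subject_ids")
        if list(self.genotypes.subject_ids) != list(self.subject_ids):
            raise SchemaError("genotype subject_ids must equal cohort subject_ids")
        bad_roles = set(self.roles) - {"cv", "test", "train_only_AD"}
        if bad_roles:
            raise SchemaError(f"unknown roles: {sorted(bad_roles)}")
        if np.any(self.labels[self.roles == "train_only_AD"] != 1):
            raise SchemaError("train_only_AD subjects must all be labeled 1")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def mask(self, role: str) -> np.ndarray:
        return self.roles == role
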