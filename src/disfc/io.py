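"""Standard-format I/O: NIfTI volumes, clinical CSV, VCF genotypes, cohorts.

Genotype VCFs use a GT-only FORMAT; multi-allelic sites are skipped with a
warning (allele-count encoding is biallelic).  Cohort directories hold one
NIfTI per subject, a clinical CSV keyed by subject_id, a VCF, a labels CSV
and a JSON manifest with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    CLINICAL_FEATURES,
    GenotypeMatrix,
    LabeledCohort,
    VolumeImage,
)
from .errors import FormatError, SchemaError

__all__ = [
    "read_nifti", "write_nifti", "read_clinical_csv", "write_clinical_csv",
    "read_vcf", "write_vcf", "write_cohort", "read_cohort",
]


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti(v: VolumeImage, path) -> Path:
    path = Path(path)
    affine = np.diag([*v.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(v.intensities.astype(np.float32), affine), path)
    return path


def read_nifti(path, subject_id: str | None = None) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # corrupt header / unreadable
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return VolumeImage(data, spacing, sid)


# ---------------------------------------------------------------------------
# Clinical CSV
# ---------------------------------------------------------------------------

def write_clinical_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = table.copy()
    out.insert(0, "subject_id", table.index)
    out.to_csv(path, index=False)
    return path


def read_clinical_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"clinical CSV not found: {path}")
    df = pd.read_csv(path)
    if df.columns[0] != "subject_id":
        raise SchemaError("first column of a clinical CSV must be 'subject_id'")
    missing = [c for c in CLINICAL_FEATURES if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical CSV is missing column '{missing[0]}'")
    df = df.set_index("subject_id")
    df.index = df.index.astype(str)
    return df[CLINICAL_FEATURES]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> Path:
    """Emit a minimal VCFv4.2 with GT-only FORMAT from allele counts."""
    path = Path(path)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(str(c) for c in gm.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.subject_ids) + "\n")
        meta = gm.snp_meta
        for j in range(gm.n_snps):
            gts = "\t".join(
                "./." if np.isnan(c) else gt_map[c] for c in gm.counts[:, j])
            fh.write(f"{meta['chrom'].iloc[j]}\t{meta['pos'].iloc[j]}\t"
                     f"{meta['id'].iloc[j]}\tA\tG\t.\t.\t.\tGT\t{gts}\n")
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF into allele counts; multi-allelic sites are skipped.

    GT fields 0/0, 0/1, 1/1 (phased separators accepted) map to 0, 1, 2;
    ./. maps to missing.  Statistics columns are recomputed from counts.
    """
    from cyvcf2 import VCF

    from .preprocess import recompute_snp_stats

    path = Path(path)
    if not path.exists():
        raise FormatError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    cols, ids, chroms, poss = [], [], [], []
    n_multi = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) > 1:
            n_multi += 1
            continue
        cols.append(gt_map[np.asarray(var.gt_types)])
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic sites in {path}",
                      stacklevel=2)
    if not cols:
        raise FormatError(f"no biallelic variants found in {path}")
    gm = GenotypeMatrix(
        counts=np.column_stack(cols),
        snp_meta=pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss}),
        subject_ids=samples,
    )
    return recompute_snp_stats(gm)


# ---------------------------------------------------------------------------
# Cohort directories
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort: LabeledCohort, directory) -> dict:
    directory = Path(directory)
    vol_dir = directory / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for v in cohort.volumes:
        files.append(write_nifti(v, vol_dir / f"{v.subject_id}.nii.gz"))
    files.append(write_clinical_csv(cohort.clinical, directory / "clinical.csv"))
    files.append(write_vcf(cohort.genotypes, directory / "genotypes.vcf"))
    labels = pd.DataFrame({
        "subject_id": cohort.subject_ids,
        "label": cohort.labels,
        "role": cohort.roles,
    })
    labels_path = directory / "labels.csv"
    labels.to_csv(labels_path, index=False)
    files.append(labels_path)
    manifest = {
        "n_subjects": cohort.n_subjects,
        "n_snps": cohort.genotypes.n_snps,
        "volume_shape": list(cohort.volumes[0].shape),
        "files": {
            str(f.relative_to(directory)): _sha256(f) for f in sorted(files)
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_cohort(directory) -> LabeledCohort:
    directory = Path(directory)
    labels = pd.read_csv(directory / "labels.csv")
    subject_ids = [str(s) for s in labels["subject_id"]]
    volumes = [
        read_nifti(directory / "volumes" / f"{sid}.nii.gz", subject_id=sid)
        for sid in subject_ids
    ]
    clinical = read_clinical_csv(directory / "clinical.csv").loc[subject_ids]
    genotypes = read_vcf(directory / "genotypes.vcf")
    order = [genotypes.subject_ids.index(sid) for sid in subject_ids]
    genotypes = GenotypeMatrix(
        counts=genotypes.counts[order],
        snp_meta=genotypes.snp_meta,
        subject_ids=subject_ids,
    )
    return LabeledCohort(
        subject_ids=subject_ids,
        volumes=volumes,
        clinical=clinical,
        genotypes=genotypes,
        labels=labels["label"].to_numpy(),
        roles=labels["role"].to_numpy(),
    )
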