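"""VCF ingestion: genotype dosage matrices, minor-allele frequencies, rarity filters.

Genotypes are read into an ``n_samples x m_variants`` dosage matrix counting
copies of the *minor* allele in the analysis sample. Sites whose ALT-allele
frequency exceeds 0.5 are recoded (``d -> 2 - d``) and flagged; missing
genotypes are excluded from the MAF denominator and then mean-imputed so
downstream linear algebra sees a complete matrix. Multiallelic records are
split into one biallelic record per ALT allele, with the remaining ALT
alleles treated as REF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger("binkat.variant_io")

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "read_variants",
    "compute_maf",
    "filter_functional",
    "filter_rare",
    "subset_variants",
    "load_annotation_sidecar",
    "annotate_variants",
]


@dataclass
class VariantRecord:
    """One biallelic variant after multiallelic splitting."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    vid: str
    ref: str
    alt: str
    function_class: str = "unknown"
    maf: float = float("nan")
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.vid:
            raise ValueError("variant identifier must be non-empty")


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with missingness mask.

    ``dosage[i, j]`` is the number of minor-allele copies carried by sample
    ``i`` at variant ``j``; entries flagged in ``missing_mask`` hold the
    column-mean imputation ``2 * maf_j`` once :func:`compute_maf` has run.
    """

    dosage: np.ndarray
    missing_mask: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]


def read_variants(
    vcf_path: str | Path,
    sample_subset: Sequence[str] | None = None,
    function_tag: str = "FUNC",
    sidecar: str | Path | None = None,
) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a VCF into variant records plus a minor-allele dosage matrix.

    Multiallelic records are split per ALT allele. Function classes come from
    the ``function_tag`` INFO field; a sidecar TSV (``vid<TAB>function_class``)
    overrides the INFO tag where both are present. Records without any
    annotation get ``function_class = "unknown"``. MAFs are computed (and
    dosages minor-allele oriented) before returning, restricted to
    ``sample_subset`` when given.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(str(vcf_path))
    vcf = VCF(str(vcf_path), gts012=False)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in vcf.samples]
        if missing:
            raise KeyError(f"samples absent from VCF header: {missing}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)
    n = len(samples)

    records: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    missing_cols: list[np.ndarray] = []
    for var in vcf:
        try:
            gts = var.genotypes  # [[a0, a1, phased], ...]
            alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int32)
        except Exception:  # malformed genotype field: skip, keep going
            logger.warning("skipping malformed record at %s:%s", var.CHROM, var.POS)
            continue
        if alleles.shape[0] != n:
            logger.warning("skipping record at %s:%s (ploidy/sample mismatch)", var.CHROM, var.POS)
            continue
        miss = (alleles < 0).any(axis=1)
        for k, alt in enumerate(var.ALT, start=1):
            vid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
            if len(var.ALT) > 1:
                vid = f"{vid}_{alt}" if var.ID else f"{var.CHROM}:{var.POS}:{alt}"
            func = var.INFO.get(function_tag)
            records.append(
                VariantRecord(
                    chrom=str(var.CHROM),
                    pos=int(var.POS),
                    vid=vid,
                    ref=str(var.REF),
                    alt=str(alt),
                    function_class=str(func) if func is not None else "unknown",
                )
            )
            dosage_cols.append((alleles == k).sum(axis=1).astype(float))
            missing_cols.append(miss.copy())

    m = len(records)
    dosage = np.column_stack(dosage_cols) if m else np.zeros((n, 0))
    missing = np.column_stack(missing_cols) if m else np.zeros((n, 0), dtype=bool)
    geno = GenotypeMatrix(dosage=dosage, missing_mask=missing, sample_ids=samples)

    if sidecar is not None:
        annotate_variants(records, load_annotation_sidecar(sidecar))

    geno, records = compute_maf(geno, records)
    return records, geno


def compute_maf(
    geno: GenotypeMatrix, variants: list[VariantRecord]
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Compute per-variant MAFs, orienting dosages to the minor allele.

    For each column: the allele frequency is computed over non-missing
    entries only; if it exceeds 0.5 the column is recoded ``d -> 2 - d`` and
    the record flagged ``flipped``; missing entries are then imputed with the
    column mean ``2 * maf``. Columns with no called genotype are dropped with
    a warning. Idempotent: the mask is retained, so a second call leaves both
    dosages and MAFs unchanged.
    """
    if geno.n_variants != len(variants):
        raise ValueError("genotype matrix and variant list are out of step")
    dosage = geno.dosage
    mask = geno.missing_mask
    n_called = (~mask).sum(axis=0)

    keep = n_called > 0
    if not keep.all():
        for j in np.flatnonzero(~keep):
            logger.warning("dropping %s: all genotypes missing", variants[j].vid)
        dosage = dosage[:, keep]
        mask = mask[:, keep]
        variants = [v for v, k in zip(variants, keep) if k]
        n_called = n_called[keep]

    called = np.where(mask, 0.0, dosage)
    freq = called.sum(axis=0) / (2.0 * n_called)
    flip = freq > 0.5
    if flip.any():
        cols = np.flatnonzero(flip)
        dosage[:, cols] = np.where(mask[:, cols], dosage[:, cols], 2.0 - dosage[:, cols])
        freq[cols] = 1.0 - freq[cols]
    maf = freq
    # mean imputation: expected minor-allele dosage given the observed MAF
    if mask.any():
        imput = np.broadcast_to(2.0 * maf, dosage.shape)
        dosage[mask] = imput[mask]

    for j, v in enumerate(variants):
        v.maf = float(maf[j])
        if flip[j]:
            v.flipped = True

    return GenotypeMatrix(dosage=dosage, missing_mask=mask, sample_ids=geno.sample_ids), variants


def filter_functional(
    variants: Sequence[VariantRecord], allowed_classes: Iterable[str]
) -> np.ndarray:
    """Indices of variants whose function class is in ``allowed_classes``."""
    allowed = set(allowed_classes)
    idx = np.array(
        [j for j, v in enumerate(variants) if v.function_class in allowed], dtype=int
    )
    if idx.size == 0:
        logger.warning("functional filter retained no variants")
    return idx


def filter_rare(variants: Sequence[VariantRecord], maf_threshold: float) -> np.ndarray:
    """Indices of polymorphic variants with ``0 < maf < maf_threshold``."""
    return np.array(
        [j for j, v in enumerate(variants) if 0.0 < v.maf < maf_threshold], dtype=int
    )


def subset_variants(
    geno: GenotypeMatrix, variants: Sequence[VariantRecord], idx: np.ndarray
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Column-subset a genotype matrix and its variant list together."""
    idx = np.asarray(idx, dtype=int)
    return (
        GenotypeMatrix(
            dosage=geno.dosage[:, idx],
            missing_mask=geno.missing_mask[:, idx],
            sample_ids=geno.sample_ids,
        ),
        [variants[j] for j in idx],
    )


def load_annotation_sidecar(path: str | Path) -> dict[str, str]:
    """Read a ``vid<TAB>function_class`` sidecar table (header required)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            return mapping
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            vid, func = line.split("\t")[:2]
            mapping[vid] = func
    return mapping


def annotate_variants(
    variants: Sequence[VariantRecord], mapping: Mapping[str, str]
) -> None:
    """Apply sidecar annotations in place; the sidecar wins over INFO tags."""
    for v in variants:
        if v.vid in mapping:
            v.function_class = mapping[v.vid]
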