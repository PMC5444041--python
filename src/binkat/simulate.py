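"""Self-consistent synthetic study generator.

Produces everything a run needs — VCF with per-sample genotypes, functional
annotation sidecar, BED/membership knowledge files for all five binning
levels, a phenotype + covariate table, and a machine-readable truth ledger —
with the statistical structure the analysis assumes: rare variants (MAF
drawn uniformly below 0.05) in Hardy–Weinberg proportions without linkage
disequilibrium, and a quantitative trait built as covariate effects plus
sparse per-variant genetic effects plus Gaussian noise.

Defaults mirror a single-cohort WGS endophenotype study: 750 samples, a
handful of covariates (three continuous, one binary), unit noise, and
per-allele effect sizes of 0.25 for causal variants (half the variants of a
causal feature, same- or mixed-sign).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, VariantRecord, compute_maf

logger = logging.getLogger("binkat.simulate")

__all__ = [
    "GeneSpec",
    "CausalSpec",
    "SimulationConfig",
    "Study",
    "build_layout",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_study",
    "write_fixture",
]

DEFAULT_CLASS_PROBS: dict[str, float] = {
    "nonsynonymous": 0.80,
    "stop-gain": 0.05,
    "splicing": 0.15,
}


@dataclass(frozen=True)
class GeneSpec:
    name: str
    chrom: str
    n_variants: int


@dataclass(frozen=True)
class CausalSpec:
    """A feature carrying genetic signal: which, how much, what sign pattern."""

    feature_id: str
    fraction: float = 0.5  # fraction of the feature's variants that are causal
    beta: float = 0.25  # per-minor-allele effect on the trait
    sign: str = "same"  # "same" or "mixed" (alternating +/-)


@dataclass
class SimulationConfig:
    seed: int
    n_samples: int = 750
    # layout knobs (used when `genes` is not given explicitly)
    n_genes: int = 12
    variants_per_gene: int = 8
    genes_per_chromosome: int = 4
    n_pathways: int = 3
    genes_per_pathway: int = 4
    n_protein_families: int = 3
    genes_per_family: int = 3
    n_ecrs: int = 4
    n_regulatory: int = 4
    genes: tuple[GeneSpec, ...] | None = None
    maf_range: tuple[float, float] = (0.001, 0.049)
    missing_rate: float = 0.0
    class_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    class_overrides: Mapping[str, Sequence[str]] = field(default_factory=dict)
    causal: tuple[CausalSpec, ...] = ()
    n_covariates: int = 4  # last one binary, the rest standard normal
    covariate_effects: tuple[float, ...] = (0.4, 0.3, -0.2, 0.25)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi < 0.5")
        if len(self.covariate_effects) != self.n_covariates:
            raise ValueError("covariate_effects length must equal n_covariates")
        for spec in self.causal:
            if spec.sign not in ("same", "mixed"):
                raise ValueError(f"causal sign must be 'same' or 'mixed', got {spec.sign!r}")


@dataclass
class Layout:
    genes: list[GeneSpec]
    gene_regions: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end) 0-based half-open
    ecrs: dict[str, tuple[str, int, int]]
    regulatory: dict[str, tuple[str, int, int]]
    pathways: dict[str, list[str]]
    protein_families: dict[str, list[str]]


@dataclass
class Study:
    """A complete simulated study plus its generative truth."""

    config: SimulationConfig
    layout: Layout
    variants: list[VariantRecord]
    geno: GenotypeMatrix
    phenotype: np.ndarray
    covariates: pd.DataFrame
    ledger: dict


_GENE_SPAN = 200  # bp of gene region per variant slot


def build_layout(cfg: SimulationConfig) -> Layout:
    """Deterministic multi-level feature layout for the configured genes.

    Genes are tiled left to right along numbered chromosomes. Each ECR spans
    the right half of one gene and the left half of the next gene on the
    same chromosome (so ECRs overlap gene boundaries, and a variant can sit
    in a gene and an ECR simultaneously); regulatory regions cover whole
    gene bodies of every third gene. Pathways partition the genes in order;
    protein families tile them with stride ``genes_per_family``.
    """
    if cfg.genes is not None:
        genes = list(cfg.genes)
    else:
        genes = [
            GeneSpec(
                name=f"GENE{i:02d}",
                chrom=str(i // cfg.genes_per_chromosome + 1),
                n_variants=cfg.variants_per_gene,
            )
            for i in range(cfg.n_genes)
        ]

    gene_regions: dict[str, tuple[str, int, int]] = {}
    cursor: dict[str, int] = {}
    for g in genes:
        start = cursor.get(g.chrom, 10_000)
        end = start + g.n_variants * _GENE_SPAN
        gene_regions[g.name] = (g.chrom, start, end)
        cursor[g.chrom] = end + 5_000

    ecrs: dict[str, tuple[str, int, int]] = {}
    k = 0
    for i in range(len(genes) - 1):
        if k >= cfg.n_ecrs:
            break
        a, b = genes[i], genes[i + 1]
        if a.chrom != b.chrom:
            continue
        _, a0, a1 = gene_regions[a.name]
        _, b0, b1 = gene_regions[b.name]
        ecrs[f"ecr_chr{a.chrom}_band{k}"] = (a.chrom, (a0 + a1) // 2, (b0 + b1) // 2)
        k += 1

    regulatory: dict[str, tuple[str, int, int]] = {}
    for k, g in enumerate(genes[:: max(1, len(genes) // max(cfg.n_regulatory, 1))]):
        if k >= cfg.n_regulatory:
            break
        chrom, s, e = gene_regions[g.name]
        regulatory[f"reg{k}"] = (chrom, max(0, s - 500), e)

    pathways: dict[str, list[str]] = {}
    for p in range(cfg.n_pathways):
        members = [g.name for g in genes[p * cfg.genes_per_pathway : (p + 1) * cfg.genes_per_pathway]]
        if members:
            pathways[f"pathKEGG{p}"] = members

    families: dict[str, list[str]] = {}
    for f in range(cfg.n_protein_families):
        members = [g.name for g in genes[f * cfg.genes_per_family : (f + 1) * cfg.genes_per_family]]
        if members:
            families[f"pfam{f:03d}"] = members

    return Layout(
        genes=genes,
        gene_regions=gene_regions,
        ecrs=ecrs,
        regulatory=regulatory,
        pathways=pathways,
        protein_families=families,
    )


def simulate_genotypes(
    cfg: SimulationConfig, layout: Layout | None = None
) -> tuple[list[VariantRecord], GenotypeMatrix, Layout]:
    """Draw variant records and a dosage matrix for the configured layout.

    Per variant: MAF uniform on ``maf_range``; dosages binomial(2, MAF)
    independently across samples (Hardy–Weinberg, no LD); positions uniform
    without replacement inside the host gene region; function classes from
    ``class_probs`` unless the gene has an explicit override list.
    """
    layout = layout or build_layout(cfg)
    rng = np.random.default_rng([cfg.seed, 11])
    n = cfg.n_samples
    classes = list(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    rs_counter = 1000
    for g in layout.genes:
        chrom, start, end = layout.gene_regions[g.name]
        positions = np.sort(rng.choice(np.arange(start + 1, end + 1), size=g.n_variants, replace=False))
        override = cfg.class_overrides.get(g.name)
        if override is not None and len(override) != g.n_variants:
            raise ValueError(f"class override for {g.name} must list {g.n_variants} classes")
        for k, pos in enumerate(positions):
            maf = float(rng.uniform(*cfg.maf_range))
            dos = rng.binomial(2, maf, size=n).astype(float)
            if override is not None:
                func = override[k]
            else:
                func = classes[int(rng.choice(len(classes), p=probs))]
            if rng.uniform() < 0.8:
                rs_counter += int(rng.integers(1, 5000))
                vid = f"rs{rs_counter}"
            else:
                vid = f"{chrom}:{int(pos)}"
            rec = VariantRecord(
                chrom=chrom,
                pos=int(pos),
                vid=vid,
                ref="A",
                alt="G",
                function_class=func,
            )
            rec.true_maf = maf  # generating frequency, for truth-ledger checks
            variants.append(rec)
            cols.append(dos)

    dosage = np.column_stack(cols) if cols else np.zeros((n, 0))
    missing = np.zeros_like(dosage, dtype=bool)
    if cfg.missing_rate > 0:
        missing = rng.uniform(size=dosage.shape) < cfg.missing_rate
    geno = GenotypeMatrix(
        dosage=dosage,
        missing_mask=missing,
        sample_ids=[f"S{i:04d}" for i in range(n)],
    )
    return variants, geno, layout


def _variants_of_feature(
    feature_id: str, layout: Layout, variants: Sequence[VariantRecord]
) -> list[int]:
    """Indices of variants inside a feature, resolved from the layout truth."""
    regions: list[tuple[str, int, int]]
    if feature_id in layout.gene_regions:
        regions = [layout.gene_regions[feature_id]]
    elif feature_id in layout.ecrs:
        regions = [layout.ecrs[feature_id]]
    elif feature_id in layout.regulatory:
        regions = [layout.regulatory[feature_id]]
    elif feature_id in layout.pathways:
        regions = [layout.gene_regions[g] for g in layout.pathways[feature_id]]
    elif feature_id in layout.protein_families:
        regions = [layout.gene_regions[g] for g in layout.protein_families[feature_id]]
    else:
        raise ValueError(f"causal feature {feature_id!r} not present in the layout")
    idx = []
    for j, v in enumerate(variants):
        for chrom, s, e in regions:
            if v.chrom == chrom and s < v.pos <= e:
                idx.append(j)
                break
    return idx


def simulate_phenotype(
    geno: GenotypeMatrix,
    cfg: SimulationConfig,
    variants: Sequence[VariantRecord],
    layout: Layout,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Quantitative trait: covariate effects + planted variant effects + noise.

    ``y_i = sum_k gamma_k c_ik + sum_{causal j} beta_j g_ij + eps_i`` with
    ``eps ~ N(0, noise_sd^2)``. The "mixed" sign pattern alternates the sign
    of beta across the causal variants of a feature. Returns the trait, the
    covariate table, and a truth ledger recording every causal variant and
    effect.
    """
    rng = np.random.default_rng([cfg.seed, 22])
    n = geno.n_samples
    ncov = cfg.n_covariates
    cov = rng.standard_normal((n, ncov))
    if ncov >= 1:
        cov[:, -1] = rng.integers(0, 2, size=n).astype(float)  # binary covariate
    cov_df = pd.DataFrame(cov, columns=[f"cov{k+1}" for k in range(ncov)])
    cov_df.insert(0, "sample_id", geno.sample_ids)

    y = cov @ np.asarray(cfg.covariate_effects, dtype=float)
    causal_rows: list[dict] = []
    for spec in cfg.causal:
        idx = _variants_of_feature(spec.feature_id, layout, variants)
        k = max(1, int(round(spec.fraction * len(idx))))
        chosen = sorted(rng.choice(idx, size=min(k, len(idx)), replace=False).tolist())
        for rank, j in enumerate(chosen):
            beta = spec.beta if (spec.sign == "same" or rank % 2 == 0) else -spec.beta
            y = y + beta * geno.dosage[:, j]
            causal_rows.append(
                {
                    "feature_id": spec.feature_id,
                    "variant_id": variants[j].vid,
                    "variant_index": j,
                    "beta": beta,
                }
            )
    y = y + rng.normal(0.0, cfg.noise_sd, size=n)

    ledger = {
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "covariate_effects": list(cfg.covariate_effects),
        "causal_variants": causal_rows,
    }
    return y, cov_df, ledger


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["class_probs"] = dict(cfg.class_probs)
    d["class_overrides"] = {k: list(v) for k, v in cfg.class_overrides.items()}
    return d


def simulate_study(cfg: SimulationConfig) -> Study:
    """Generate a full study and record the filter-stage truth counts.

    The ledger's ``counts`` block holds the numbers a faithful pipeline run
    must report: variants generated, variants in functional classes, and
    polymorphic variants with sample MAF strictly below 0.05.
    """
    variants, geno, layout = simulate_genotypes(cfg)
    y, cov_df, ledger = simulate_phenotype(geno, cfg, variants, layout)

    # empirical MAFs on an independent copy, so the returned matrix stays raw
    geno_copy = GenotypeMatrix(
        dosage=geno.dosage.copy(), missing_mask=geno.missing_mask.copy(),
        sample_ids=list(geno.sample_ids),
    )
    import copy as _copy

    _, recs = compute_maf(geno_copy, _copy.deepcopy(variants))
    functional = set(DEFAULT_CLASS_PROBS) | {
        c for ov in cfg.class_overrides.values() for c in ov
    } | set(cfg.class_probs)
    n_func = sum(1 for v in recs if v.function_class in functional)
    n_rare = sum(
        1 for v in recs if v.function_class in functional and 0.0 < v.maf < 0.05
    )
    ledger["counts"] = {
        "variants_read": len(variants),
        "functional": n_func,
        "rare": n_rare,
    }
    return Study(
        config=cfg,
        layout=layout,
        variants=variants,
        geno=geno,
        phenotype=y,
        covariates=cov_df,
        ledger=ledger,
    )


def write_fixture(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write the study to disk as pipeline-ready flat files.

    Emits: ``study.vcf`` (GT genotypes, FUNC INFO tag), ``annotation.tsv``
    sidecar, ``gene.bed`` / ``ecr.bed`` / ``regulatory.bed``,
    ``pathway.tsv`` / ``protein_family.tsv`` memberships,
    ``phenotype.tsv`` and ``ledger.json`` + ``causal.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    geno, variants, layout = study.geno, study.variants, study.layout
    order = sorted(
        range(len(variants)), key=lambda j: (_chrom_num(variants[j].chrom), variants[j].pos)
    )

    vcf_path = out / "study.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chrom_max: dict[str, int] = {}
        for v in variants:
            chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos)
        for chrom in sorted(chrom_max, key=_chrom_num):
            fh.write(f"##contig=<ID={chrom},length={chrom_max[chrom] + 10_000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in order:
            v = variants[j]
            col = geno.dosage[:, j]
            miss = geno.missing_mask[:, j]
            gts = [
                "./." if miss[i] else gt_codes[int(round(col[i]))]
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t.\t"
                f"FUNC={v.function_class}\tGT\t" + "\t".join(gts) + "\n"
            )
    paths["vcf"] = vcf_path

    ann_path = out / "annotation.tsv"
    with open(ann_path, "w") as fh:
        fh.write("vid\tfunction_class\n")
        for j in order:
            fh.write(f"{variants[j].vid}\t{variants[j].function_class}\n")
    paths["annotation"] = ann_path

    def _write_bed(name: str, regions: Mapping[str, tuple[str, int, int]]) -> Path:
        p = out / f"{name}.bed"
        with open(p, "w") as fh:
            for fid in sorted(regions):
                chrom, s, e = regions[fid]
                fh.write(f"{chrom}\t{s}\t{e}\t{fid}\n")
        return p

    paths["gene"] = _write_bed("gene", layout.gene_regions)
    paths["ecr"] = _write_bed("ecr", layout.ecrs)
    paths["regulatory"] = _write_bed("regulatory", layout.regulatory)

    def _write_membership(name: str, groups: Mapping[str, Sequence[str]]) -> Path:
        p = out / f"{name}.tsv"
        with open(p, "w") as fh:
            for gid in sorted(groups):
                for gene in groups[gid]:
                    fh.write(f"{gene}\t{gid}\n")
        return p

    paths["pathway"] = _write_membership("pathway", layout.pathways)
    paths["protein_family"] = _write_membership("protein_family", layout.protein_families)

    pheno_path = out / "phenotype.tsv"
    tbl = study.covariates.copy()
    tbl.insert(1, "trait", study.phenotype)
    tbl.to_csv(pheno_path, sep="\t", index=False, float_format="%.10g")
    paths["phenotype"] = pheno_path

    ledger_path = out / "ledger.json"
    with open(ledger_path, "w") as fh:
        json.dump(study.ledger, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["ledger"] = ledger_path

    causal_path = out / "causal.tsv"
    with open(causal_path, "w") as fh:
        fh.write("feature_id\tvariant_id\tbeta\n")
        for row in study.ledger["causal_variants"]:
            fh.write(f"{row['feature_id']}\t{row['variant_id']}\t{row['beta']:.6g}\n")
    paths["causal"] = causal_path

    return paths


def _chrom_num(label: str) -> tuple:
    from .knowledge import chrom_sort_key

    return chrom_sort_key(label)
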