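"""One-command orchestration: filter -> bin per level -> test -> FDR -> reports.

The workflow mirrors the standard multi-level rare-variant scan: read the
VCF restricted to the complete-case sample intersection, compute MAFs on
that analysis set, keep functional rare variants, bin them at each
requested level, run the chosen bin-level test, adjust p-values with
Benjamini–Hochberg *within each level*, and write per-level result tables,
a combined summary, a Manhattan-ready table, filter-stage counts, and a
leave-one-out influence report for every feature passing the FDR threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binning, knowledge, stats, variant_io

logger = logging.getLogger("binkat.pipeline")

__all__ = ["RunConfig", "RunResult", "run", "summarize", "parse_kv_config"]

LEVEL_ALIASES = {"pfam": "protein_family", "protein-family": "protein_family"}


@dataclass
class RunConfig:
    vcf: Path
    phenotype_table: Path
    out_dir: Path
    pheno_col: str
    covar_cols: tuple[str, ...]
    knowledge_files: Mapping[str, Path]  # positional level -> BED
    membership_files: Mapping[str, Path] = field(default_factory=dict)
    levels: tuple[str, ...] = ("gene",)
    maf_threshold: float = 0.05
    min_bin_size: int = 5
    test: str = "skat"  # skat | burden | wilcoxon
    weighting: str = "madsen-browning"  # madsen-browning | none
    fdr_alpha: float = 0.05
    functional_classes: tuple[str, ...] | None = None  # None: every annotated class
    function_tag: str = "FUNC"
    sidecar: Path | None = None
    sample_id_col: str = "sample_id"
    group_col: str | None = None  # required for test="wilcoxon"
    top_k: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        self.levels = tuple(LEVEL_ALIASES.get(l, l) for l in self.levels)
        if self.test not in ("skat", "burden", "wilcoxon"):
            raise ValueError(f"unknown test {self.test!r}")
        for level in self.levels:
            if level in knowledge.POSITIONAL_LEVELS and level not in self.knowledge_files:
                raise ValueError(f"level {level!r} requested but no BED file given")
            if level in knowledge.GROUP_LEVELS and level not in self.membership_files:
                raise ValueError(f"level {level!r} requested but no membership file given")


@dataclass
class RunResult:
    counts: dict
    results: dict[str, pd.DataFrame]
    paths: dict[str, Path]


_RESULT_COLUMNS = [
    "level",
    "feature_id",
    "n_variants",
    "test",
    "statistic",
    "p_value",
    "fdr_q",
    "p_method",
]


def run(cfg: RunConfig) -> RunResult:
    """Execute the full binning-and-testing workflow for one configuration."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pheno = pd.read_csv(cfg.phenotype_table, sep="\t", dtype={cfg.sample_id_col: str})
    needed = [cfg.pheno_col, *cfg.covar_cols]
    if cfg.group_col:
        needed.append(cfg.group_col)
    missing_cols = [c for c in needed if c not in pheno.columns]
    if missing_cols:
        raise KeyError(f"phenotype table lacks columns: {missing_cols}")
    pheno = pheno.dropna(subset=needed)  # complete cases only

    from cyvcf2 import VCF

    vcf_samples = VCF(str(cfg.vcf)).samples
    table_samples = set(pheno[cfg.sample_id_col])
    analysis_samples = [s for s in vcf_samples if s in table_samples]
    if not analysis_samples:
        raise ValueError("no overlap between VCF samples and phenotype table")
    pheno = pheno.set_index(cfg.sample_id_col).loc[analysis_samples]

    variants, geno = variant_io.read_variants(
        cfg.vcf,
        sample_subset=analysis_samples,
        function_tag=cfg.function_tag,
        sidecar=cfg.sidecar,
    )
    counts: dict = {"samples": len(analysis_samples), "variants_read": len(variants)}

    if cfg.functional_classes is None:
        allowed = {v.function_class for v in variants} - {"unknown"}
    else:
        allowed = set(cfg.functional_classes)
    func_idx = variant_io.filter_functional(variants, allowed)
    geno_f, variants_f = variant_io.subset_variants(geno, variants, func_idx)
    counts["functional"] = len(variants_f)

    rare_idx = variant_io.filter_rare(variants_f, cfg.maf_threshold)
    geno_r, variants_r = variant_io.subset_variants(geno_f, variants_f, rare_idx)
    counts["rare"] = len(variants_r)
    logger.info("filter chain: %s", counts)

    kb = knowledge.load_knowledge(cfg.knowledge_files, cfg.membership_files)

    y = pheno[cfg.pheno_col].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(pheno))] + [pheno[c].to_numpy(dtype=float) for c in cfg.covar_cols]
    )
    null = stats.fit_null_model(y, X)
    groups = (
        pheno[cfg.group_col].to_numpy(dtype=int) if cfg.group_col is not None else None
    )

    results: dict[str, pd.DataFrame] = {}
    manhattan_rows: list[dict] = []
    counts["binned"] = {}
    for level in cfg.levels:
        bins = binning.build_bins(
            variants_r, geno_r, kb, level,
            min_bin_size=cfg.min_bin_size, weighting=cfg.weighting,
        )
        counts["binned"][level] = len(bins)
        if not bins:
            logger.warning("level %s: no bins; skipped", level)
            continue
        rows = []
        for b in bins:
            if cfg.test == "skat":
                res = stats.skat_test(null, b, geno_r)
            elif cfg.test == "burden":
                res = stats.burden_test(b, geno_r, y, X)
            else:
                if groups is None:
                    raise ValueError("test='wilcoxon' requires group_col")
                res = stats.wilcoxon_burden_test(b, geno_r, groups)
            rows.append(res)
        qvals = stats.bh_fdr([r.p_value for r in rows])
        for r, qv in zip(rows, qvals):
            r.fdr_q = float(qv)
        df = pd.DataFrame(
            [
                {
                    "level": r.level,
                    "feature_id": r.feature_id,
                    "n_variants": r.n_variants,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "fdr_q": r.fdr_q,
                    "p_method": r.p_method,
                }
                for r in rows
            ],
            columns=_RESULT_COLUMNS,
        ).sort_values(["p_value", "feature_id"], kind="mergesort").reset_index(drop=True)
        results[level] = df
        path = out / f"results_{level}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[f"results_{level}"] = path

        for b in bins:
            chrom, pos = _first_region(kb, level, b.feature_id)
            p = df.loc[df.feature_id == b.feature_id, "p_value"].iloc[0]
            manhattan_rows.append(
                {
                    "level": level,
                    "feature_id": b.feature_id,
                    "chrom": chrom,
                    "pos": pos,
                    "neglog10_p": -np.log10(p),
                }
            )

        # influence analysis for FDR-significant features
        sig = df[(df.fdr_q < cfg.fdr_alpha) & (df.n_variants >= 2)]
        bin_by_id = {b.feature_id: b for b in bins}
        for fid in sig.feature_id:
            loo = stats.leave_one_out(null, bin_by_id[fid], geno_r, variants_r)
            func_by_vid = {v.vid: v.function_class for v in variants_r}
            loo_path = out / f"loo_{level}_{_safe_name(fid)}.tsv"
            with open(loo_path, "w") as fh:
                fh.write("variant_id\tp_without_variant\tfunction_class\n")
                for vid, pv in loo:
                    fh.write(f"{vid}\t{pv:.6g}\t{func_by_vid.get(vid, 'unknown')}\n")
            paths[f"loo_{level}_{fid}"] = loo_path

    if results:
        combined = pd.concat(results.values(), ignore_index=True)
        combined_path = out / "results_combined.tsv"
        combined.to_csv(combined_path, sep="\t", index=False, float_format="%.6g")
        paths["combined"] = combined_path

    manhattan = pd.DataFrame(
        manhattan_rows, columns=["level", "feature_id", "chrom", "pos", "neglog10_p"]
    )
    manhattan_path = out / "manhattan.tsv"
    manhattan.to_csv(manhattan_path, sep="\t", index=False, float_format="%.6g")
    paths["manhattan"] = manhattan_path

    counts_path = out / "counts.json"
    with open(counts_path, "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["counts"] = counts_path

    return RunResult(counts=counts, results=results, paths=paths)


def _first_region(kb: knowledge.KnowledgeBase, level: str, fid: str) -> tuple[str, int]:
    feat = kb.features_by_level[level][fid]
    if level in knowledge.GROUP_LEVELS:
        genes = kb.features_by_level.get("gene", {})
        regions = [r for g in feat.member_genes if g in genes for r in genes[g].regions]
    else:
        regions = feat.regions
    if not regions:
        return ("NA", 0)
    chrom, start, _ = min(regions, key=lambda r: (knowledge.chrom_sort_key(r[0]), r[1]))
    return (chrom, start + 1)  # report 1-based


def _safe_name(fid: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_.") else "_" for c in fid)


def summarize(results_dir: str | Path, top: int = 10) -> dict[str, pd.DataFrame]:
    """Top-K table per level from a completed run directory.

    q-values are the ones computed over the full per-level result set at run
    time, not recomputed on the truncated listing. Ties in p are broken by
    feature_id (already encoded in the stored ordering).
    """
    results_dir = Path(results_dir)
    out: dict[str, pd.DataFrame] = {}
    for path in sorted(results_dir.glob("results_*.tsv")):
        if path.name == "results_combined.tsv":
            continue
        level = path.stem[len("results_") :]
        df = pd.read_csv(path, sep="\t")
        out[level] = df.head(top)
    return out


def parse_kv_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = line.split("=", 1)
            cfg[key.strip()] = val.strip().strip('"').strip("'")
    return cfg
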