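"""Aggregate filtered rare variants into weighted per-feature bins.

A bin is one biological feature's set of rare variants at one level, with
per-variant Madsen–Browning weights ``w = 1 / sqrt(maf * (1 - maf))`` that
up-weight the rarest variants. Bins below the minimum size are discarded.
A variant inside several overlapping features contributes to every one of
their bins, and to each level independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .knowledge import GROUP_LEVELS, KnowledgeBase, chrom_sort_key, query_point
from .variant_io import GenotypeMatrix, VariantRecord

logger = logging.getLogger("binkat.binning")

__all__ = ["Bin", "build_bins", "madsen_browning_weights", "write_bin_report"]


@dataclass
class Bin:
    feature_id: str
    level: str
    variant_indices: np.ndarray  # indices into the filtered variant list
    weights: np.ndarray

    @property
    def size(self) -> int:
        return int(self.variant_indices.size)


def madsen_browning_weights(mafs: Sequence[float]) -> np.ndarray:
    """Inverse-frequency weights ``1 / sqrt(maf * (1 - maf))``.

    Strictly decreasing in MAF on (0, 0.5]; a MAF outside that interval
    violates the upstream rare-variant contract and is an error.
    """
    maf = np.asarray(mafs, dtype=float)
    if maf.size and (np.any(maf <= 0.0) or np.any(maf > 0.5)):
        raise ValueError("Madsen-Browning weights require MAF in (0, 0.5]")
    return 1.0 / np.sqrt(maf * (1.0 - maf))


def _feature_sort_key(kb: KnowledgeBase, level: str, feature_id: str) -> tuple:
    """Sort bins by (chromosome of first region, feature_id); group features
    inherit the earliest region among their member genes."""
    feat = kb.features_by_level[level][feature_id]
    if level in GROUP_LEVELS:
        genes = kb.features_by_level.get("gene", {})
        regions = [
            r for g in feat.member_genes if g in genes for r in genes[g].regions
        ]
    else:
        regions = feat.regions
    if not regions:
        return ((2, 0, ""), 0, feature_id)
    first = min(regions, key=lambda r: (chrom_sort_key(r[0]), r[1]))
    return (chrom_sort_key(first[0]), first[1], feature_id)


def build_bins(
    variants: Sequence[VariantRecord],
    geno: GenotypeMatrix,
    kb: KnowledgeBase,
    level: str,
    min_bin_size: int = 5,
    weighting: str = "madsen-browning",
) -> list[Bin]:
    """One bin per feature at ``level`` containing >= ``min_bin_size`` of the
    (already functional- and rarity-filtered) variants.

    ``weighting`` is ``"madsen-browning"`` or ``"none"`` (all weights 1, for
    sensitivity analysis). Output order is deterministic: (chromosome of the
    feature's first region, feature_id).
    """
    if weighting not in ("madsen-browning", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    members: dict[str, list[int]] = {}
    for j, v in enumerate(variants):
        for fid in query_point(kb, v.chrom, v.pos, level):
            members.setdefault(fid, []).append(j)

    bins: list[Bin] = []
    for fid, idx in members.items():
        if len(idx) < min_bin_size:
            continue
        idx_arr = np.asarray(idx, dtype=int)
        mafs = [variants[j].maf for j in idx]
        weights = (
            madsen_browning_weights(mafs)
            if weighting == "madsen-browning"
            else np.ones(len(idx))
        )
        bins.append(Bin(feature_id=fid, level=level, variant_indices=idx_arr, weights=weights))

    bins.sort(key=lambda b: _feature_sort_key(kb, level, b.feature_id))
    if not bins:
        logger.warning("no bins of size >= %d at level %s", min_bin_size, level)
    return bins


def write_bin_report(
    bins: Sequence[Bin], variants: Sequence[VariantRecord], path: str | Path
) -> None:
    """TSV listing of every bin: level, feature, size, member variant ids."""
    with open(path, "w") as fh:
        fh.write("level\tfeature_id\tsize\tvariant_ids\n")
        for b in bins:
            vids = ",".join(variants[j].vid for j in b.variant_indices)
            fh.write(f"{b.level}\t{b.feature_id}\t{b.size}\t{vids}\n")
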