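"""Flat-file biological knowledge store for multi-level variant binning.

Feature definitions are consumed from plain files — BED4 for positional
levels (genes, evolutionary conserved regions, regulatory regions) and
two-column ``gene<TAB>group`` membership tables for group levels (pathways,
protein families). Coordinates are BED half-open 0-based on disk and VCF
1-based at query time; the conversion happens inside :func:`query_point`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from intervaltree import IntervalTree

logger = logging.getLogger("binkat.knowledge")

POSITIONAL_LEVELS = ("gene", "ecr", "regulatory")
GROUP_LEVELS = ("pathway", "protein_family")
LEVELS = POSITIONAL_LEVELS + GROUP_LEVELS

__all__ = [
    "Feature",
    "KnowledgeBase",
    "KnowledgeFileError",
    "load_knowledge",
    "query_point",
    "chrom_sort_key",
    "POSITIONAL_LEVELS",
    "GROUP_LEVELS",
    "LEVELS",
]


class KnowledgeFileError(ValueError):
    """A knowledge flat file is malformed (reported with file and line)."""


@dataclass
class Feature:
    feature_id: str
    level: str
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    member_genes: list[str] = field(default_factory=list)
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.display_name:
            self.display_name = self.feature_id


@dataclass
class KnowledgeBase:
    features_by_level: dict[str, dict[str, Feature]]
    interval_index: dict[tuple[str, str], IntervalTree]
    gene_to_groups: dict[str, dict[str, set[str]]]  # level -> gene -> group ids

    def features(self, level: str) -> list[Feature]:
        return list(self.features_by_level.get(level, {}).values())


def chrom_sort_key(label: str) -> tuple:
    """Natural ordering for chromosome labels (1..22, X, Y, MT, then others)."""
    name = label[3:] if label.lower().startswith("chr") else label
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


def _load_bed(path: Path, level: str) -> dict[str, Feature]:
    features: dict[str, Feature] = {}
    seen: set[tuple[str, str, int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise KnowledgeFileError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, fid = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise KnowledgeFileError(
                    f"{path}:{lineno}: non-integer coordinates ({start_s!r}, {end_s!r})"
                ) from exc
            if start >= end:
                raise KnowledgeFileError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            key = (fid, chrom, start, end)
            if key in seen:  # duplicate rows collapse silently
                continue
            seen.add(key)
            features.setdefault(fid, Feature(feature_id=fid, level=level)).regions.append(
                (chrom, start, end)
            )
    return features


def _load_membership(path: Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise KnowledgeFileError(f"{path}:{lineno}: expected gene<TAB>group")
            rows.append((parts[0], parts[1]))
    return rows


def load_knowledge(
    level_files: Mapping[str, str | Path],
    membership_files: Mapping[str, str | Path] | None = None,
) -> KnowledgeBase:
    """Build a knowledge base from BED and membership flat files.

    ``level_files`` maps positional levels to BED4 paths; ``membership_files``
    maps group levels to ``gene<TAB>group`` tables. Group levels require the
    gene level to be loaded so that memberships resolve to genomic intervals.
    Memberships naming unknown genes are dropped with a warning; groups left
    with no resolvable member gene are removed entirely.
    """
    membership_files = membership_files or {}
    features_by_level: dict[str, dict[str, Feature]] = {}
    index: dict[tuple[str, str], IntervalTree] = {}

    for level, path in level_files.items():
        if level not in POSITIONAL_LEVELS:
            raise ValueError(f"unknown positional level {level!r}; expected one of {POSITIONAL_LEVELS}")
        feats = _load_bed(Path(path), level)
        features_by_level[level] = feats
        for feat in feats.values():
            for chrom, start, end in feat.regions:
                index.setdefault((level, chrom), IntervalTree()).addi(start, end, feat.feature_id)

    gene_to_groups: dict[str, dict[str, set[str]]] = {}
    if membership_files:
        genes = features_by_level.get("gene")
        if genes is None:
            raise ValueError("group levels require a gene-level BED file")
        for level, path in membership_files.items():
            if level not in GROUP_LEVELS:
                raise ValueError(f"unknown group level {level!r}; expected one of {GROUP_LEVELS}")
            groups: dict[str, Feature] = {}
            g2g: dict[str, set[str]] = {}
            for gene_id, group_id in _load_membership(Path(path)):
                if gene_id not in genes:
                    logger.warning(
                        "%s: membership names gene %r absent from gene BED; skipped", level, gene_id
                    )
                    continue
                feat = groups.setdefault(group_id, Feature(feature_id=group_id, level=level))
                if gene_id not in feat.member_genes:
                    feat.member_genes.append(gene_id)
                g2g.setdefault(gene_id, set()).add(group_id)
            empty = [gid for gid, f in groups.items() if not f.member_genes]
            for gid in empty:
                logger.warning("%s: group %s has no resolvable member genes; dropped", level, gid)
                del groups[gid]
            features_by_level[level] = groups
            gene_to_groups[level] = g2g

    return KnowledgeBase(
        features_by_level=features_by_level,
        interval_index=index,
        gene_to_groups=gene_to_groups,
    )


def query_point(kb: KnowledgeBase, chrom: str, pos_1based: int, level: str) -> set[str]:
    """Feature ids at ``level`` whose extent contains a 1-based VCF position.

    Positional levels are answered from the interval index at 0-based
    coordinate ``pos_1based - 1``; group levels resolve through the genes
    containing the position.
    """
    if level in POSITIONAL_LEVELS:
        tree = kb.interval_index.get((level, chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos_1based - 1)}
    if level in GROUP_LEVELS:
        hits: set[str] = set()
        g2g = kb.gene_to_groups.get(level, {})
        for gene_id in query_point(kb, chrom, pos_1based, "gene"):
            hits |= g2g.get(gene_id, set())
        return hits
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
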