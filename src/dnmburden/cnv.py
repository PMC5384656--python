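"""Interval algebra for CNVR novelty classification against a reference.

A query copy-number-variable region (CNVR) is *shared* with a reference
collection (e.g. the common-variant catalogue of a structural-variant
database) when at least 80% of its bases are covered by the union of
same-type reference records, otherwise it is *novel*.  Deletions are
compared only against reference deletions and duplications only against
duplications.  Coverage is measured against the merged union of reference
records, which makes the classification invariant to reference record order
and to splitting reference intervals into touching pieces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet, canonical_symbol
from .types import GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_THRESHOLD = 0.8


@dataclass(frozen=True)
class ClassifierConfig:
    """Novelty-classification parameters (threshold is 'at least', i.e. >=)."""

    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError(
                f"coverage_threshold must be in (0, 1], got {self.coverage_threshold}"
            )


@dataclass(frozen=True)
class CNVRClassification:
    interval: GenomicInterval
    coverage_fraction: float
    status: str  # 'shared' or 'novel'


def merge_union(
    intervals: Iterable[GenomicInterval],
) -> dict[tuple[str, str], np.ndarray]:
    """Union of intervals per (chromosome, svtype).

    Returns, for each key, an ``(k, 2)`` array of sorted, pairwise-disjoint
    ``[start, end)`` pairs; touching intervals are merged.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault((iv.chrom, iv.svtype), []).append((iv.start, iv.end))
    out = {}
    for key, pairs in grouped.items():
        pairs.sort()
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[key] = np.asarray(merged, dtype=np.int64)
    return out


def coverage_fraction(query: GenomicInterval, reference_union: np.ndarray) -> float:
    """Fraction of the query's bases covered by a pre-merged reference union."""
    if reference_union is None or len(reference_union) == 0:
        return 0.0
    starts = reference_union[:, 0]
    ends = reference_union[:, 1]
    covered = np.clip(
        np.minimum(ends, query.end) - np.maximum(starts, query.start), 0, None
    ).sum()
    return float(covered) / query.length


def classify_cnvrs(
    queries: Sequence[GenomicInterval],
    reference: Iterable[GenomicInterval],
    config: ClassifierConfig | float | None = None,
) -> list[CNVRClassification]:
    """Classify each query CNVR as shared with, or novel to, the reference.

    Type-matched: a deletion query is covered only by reference deletions, a
    duplication only by reference duplications.  A query is shared iff its
    covered fraction is at least the threshold.  An empty reference for a
    type present in the queries makes all queries of that type novel, with a
    logged warning.
    """
    if config is None:
        config = ClassifierConfig()
    elif not isinstance(config, ClassifierConfig):
        config = ClassifierConfig(coverage_threshold=float(config))
    union = merge_union(reference)
    ref_types = {svtype for _, svtype in union}
    missing = {q.svtype for q in queries} - ref_types
    for svtype in sorted(missing):
        logger.warning(
            "no reference intervals of type %r: all such queries are novel", svtype
        )
    out = []
    for q in queries:
        frac = coverage_fraction(q, union.get((q.chrom, q.svtype)))
        status = "shared" if frac >= config.coverage_threshold else "novel"
        out.append(CNVRClassification(interval=q, coverage_fraction=frac, status=status))
    return out


def classification_counts(
    classifications: Iterable[CNVRClassification],
) -> dict[str, dict[str, int]]:
    """Shared/novel tallies per svtype."""
    counts: dict[str, dict[str, int]] = {}
    for c in classifications:
        per = counts.setdefault(c.interval.svtype, {"shared": 0, "novel": 0})
        per[c.status] += 1
    return counts


def genes_in_regions(
    regions: Sequence[GenomicInterval],
    gene_table: pd.DataFrame,
    label: str = "region_genes",
) -> GeneSet:
    """Genes overlapping any region by at least one base (deduplicated).

    ``gene_table`` has columns chrom, start, end, gene with 0-based
    half-open coordinates; a gene abutting a region end (gene start ==
    region end) does not overlap.
    """
    genes = set()
    chroms = gene_table["chrom"].map(normalize_chrom).to_numpy()
    starts = gene_table["start"].to_numpy(dtype=np.int64)
    ends = gene_table["end"].to_numpy(dtype=np.int64)
    symbols = gene_table["gene"].to_numpy()
    for region in regions:
        hit = (chroms == region.chrom) & (starts < region.end) & (ends > region.start)
        genes.update(canonical_symbol(g) for g in symbols[hit])
    return GeneSet(label=label, genes=frozenset(genes), source_count=len(regions))
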