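"""Deleteriousness filtering and gene-set characterization.

A de novo mutation is *nonsynonymous* when its consequence is missense,
nonsense or frameshift.  It is *deleterious* when it is a frameshift (always)
or a missense/nonsense variant with CADD phred strictly greater than the
cutoff (default 20, i.e. the top 1% most deleterious substitutions
genome-wide).  The genes hit by deleterious mutations in a cohort form a
gene set that is then characterized three ways:

* CNV / deletion / duplication intolerance vs the genome background
  (Wilcoxon rank-sum),
* mouse-ortholog viability composition and a lethal-vs-viable Fisher's
  exact enrichment between two sets,
* phenotype-term over-representation (hypergeometric test with
  Benjamini-Hochberg FDR across terms).

The enrichment here is a generic hypergeometric + BH reimplementation
("EnrichR-analogous"); it does not reproduce any external tool's combined
score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .burden import rank_sum_test
from .types import (
    NONSYNONYMOUS_CONSEQUENCES,
    DeNovoMutation,
    GeneAnnotation,
    TestResult,
)

logger = logging.getLogger(__name__)

DEFAULT_CADD_CUTOFF = 20.0


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols with its source record count."""

    label: str
    genes: frozenset[str]
    source_count: int = 0
    #: mutations that passed the filter but carried no gene symbol
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("gene-set label must be nonempty")

    def __len__(self) -> int:
        return len(self.genes)


def canonical_symbol(gene: str) -> str:
    """Case-insensitive, whitespace-stripped gene-symbol matching."""
    return gene.strip().upper()


# ---------------------------------------------------------------------------
# Filters


def is_nonsynonymous(m: DeNovoMutation) -> bool:
    """True iff the mutation is protein-altering (missense/nonsense/frameshift)."""
    return m.consequence in NONSYNONYMOUS_CONSEQUENCES


def is_deleterious(m: DeNovoMutation, cadd_cutoff: float = DEFAULT_CADD_CUTOFF) -> bool:
    """Deleteriousness rule for a nonsynonymous mutation.

    Frameshift indels are deleterious unconditionally.  Missense and
    nonsense variants require CADD phred strictly greater than the cutoff;
    a missing CADD score on a non-frameshift variant is not deleterious.
    Calling this on a non-nonsynonymous mutation is an error.
    """
    if not is_nonsynonymous(m):
        raise ValueError(
            f"is_deleterious is defined only for nonsynonymous mutations, "
            f"got consequence {m.consequence!r}"
        )
    if m.consequence == "frameshift":
        return True
    return m.cadd_phred is not None and m.cadd_phred > cadd_cutoff


def extract_gene_set(
    mutations: Iterable[DeNovoMutation],
    label: str,
    cadd_cutoff: float = DEFAULT_CADD_CUTOFF,
) -> GeneSet:
    """Unique genes hit by deleterious nonsynonymous mutations in one cohort.

    ``source_count`` is the number of passing mutations; recurrently hit
    genes are deduplicated, so ``len(set) <= source_count``.  Passing
    mutations that lack a gene symbol are counted in ``n_unassigned`` but
    excluded from the set.
    """
    genes = set()
    n_pass = 0
    n_unassigned = 0
    for m in mutations:
        if not is_nonsynonymous(m) or not is_deleterious(m, cadd_cutoff):
            continue
        n_pass += 1
        if m.gene:
            genes.add(canonical_symbol(m.gene))
        else:
            n_unassigned += 1
    return GeneSet(
        label=label,
        genes=frozenset(genes),
        source_count=n_pass,
        n_unassigned=n_unassigned,
    )


# ---------------------------------------------------------------------------
# Intolerance


_SCORE_ATTR = {
    "cnv": "cnv_intolerance",
    "del": "del_intolerance",
    "dup": "dup_intolerance",
}


def compare_intolerance(
    gene_set: GeneSet,
    annotation: Sequence[GeneAnnotation],
    score: str = "cnv",
    background: GeneSet | None = None,
) -> TestResult:
    """Rank-sum comparison of a set's intolerance scores vs a background.

    ``score`` selects the combined-CNV, deletion or duplication intolerance.
    With ``background=None`` the genome background is used: all annotated
    genes excluding the set's own members (to avoid self-comparison).  Genes
    missing the score are dropped, with the dropped count reported.
    """
    attr = _SCORE_ATTR.get(score)
    if attr is None:
        raise ValueError(f"score must be one of {sorted(_SCORE_ATTR)}, got {score!r}")
    by_gene = {canonical_symbol(a.gene): getattr(a, attr) for a in annotation}
    set_genes = {canonical_symbol(g) for g in gene_set.genes}
    set_scores = [by_gene[g] for g in sorted(set_genes) if g in by_gene]
    if background is None:
        bg_scores = [v for g, v in sorted(by_gene.items()) if g not in set_genes]
    else:
        bg_genes = {canonical_symbol(g) for g in background.genes}
        bg_scores = [by_gene[g] for g in sorted(bg_genes) if g in by_gene]
    n_dropped = sum(1 for v in set_scores if math.isnan(v)) + sum(
        1 for v in bg_scores if math.isnan(v)
    )
    set_scores = [v for v in set_scores if not math.isnan(v)]
    bg_scores = [v for v in bg_scores if not math.isnan(v)]
    if len(set_scores) < 2:
        raise ValueError(
            f"gene set {gene_set.label!r} has < 2 genes with a {score} intolerance score"
        )
    if not bg_scores:
        raise ValueError("background has no scored genes")
    result = rank_sum_test(set_scores, bg_scores)
    result.extra.update(
        score=score,
        n_dropped_unscored=n_dropped,
        set_median=float(np.median(set_scores)),
        background_median=float(np.median(bg_scores)),
    )
    return result


# ---------------------------------------------------------------------------
# Viability


def viability_composition(
    gene_set: GeneSet, annotation: Sequence[GeneAnnotation]
) -> tuple[dict[str, float], int]:
    """Proportions of lethal / subviable / viable genes in a set.

    Proportions are over set genes with a known viability class and sum to 1
    when any is known; the count of unknown (or unannotated) genes is
    returned alongside.  An empty known denominator yields NaN proportions.
    """
    by_gene = {canonical_symbol(a.gene): a.viability for a in annotation}
    tallies = {"lethal": 0, "subviable": 0, "viable": 0}
    unknown = 0
    for g in gene_set.genes:
        v = by_gene.get(canonical_symbol(g), "unknown")
        if v in tallies:
            tallies[v] += 1
        else:
            unknown += 1
    known = sum(tallies.values())
    if known == 0:
        return {k: float("nan") for k in tallies}, unknown
    return {k: v / known for k, v in tallies.items()}, unknown


def viability_enrichment(
    set_a: GeneSet, set_b: GeneSet, annotation: Sequence[GeneAnnotation]
) -> TestResult:
    """Fisher's exact test on lethal-vs-viable counts of two gene sets.

    Subviable and unknown genes are excluded from the 2x2 table.  A margin
    that is entirely zero (no lethal gene anywhere, or no viable gene
    anywhere, or an empty set) is degenerate and raises.
    """
    by_gene = {canonical_symbol(a.gene): a.viability for a in annotation}

    def tally(s: GeneSet) -> tuple[int, int]:
        lethal = sum(1 for g in s.genes if by_gene.get(canonical_symbol(g)) == "lethal")
        viable = sum(1 for g in s.genes if by_gene.get(canonical_symbol(g)) == "viable")
        return lethal, viable

    (la, va), (lb, vb) = tally(set_a), tally(set_b)
    table = np.array([[la, va], [lb, vb]])
    for axis, name in ((0, "lethal/viable class"), (1, "gene set")):
        sums = table.sum(axis=axis)
        if (sums == 0).any():
            which = ("lethal", "viable") if axis == 0 else (set_a.label, set_b.label)
            zero = which[int(np.flatnonzero(sums == 0)[0])]
            raise ValueError(f"degenerate 2x2 margin: no counts for {zero!r} ({name})")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        method="fisher-exact",
        statistic=float(odds),
        p_value=float(p),
        n_group1=la + va,
        n_group2=lb + vb,
        extra={"table": [[la, va], [lb, vb]]},
    )


# ---------------------------------------------------------------------------
# Phenotype enrichment


def phenotype_enrichment(
    gene_set: GeneSet,
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of phenotype terms in a gene set.

    For each term with at least one set member, the one-sided hypergeometric
    tail probability of observing at least the seen overlap is computed,
    then Benjamini-Hochberg adjusted across the tested terms.  Returns a
    DataFrame (term, overlap, term_size, set_size, universe_size, p_value,
    fdr) sorted by raw p.
    """
    if not term_map:
        raise ValueError("empty phenotype term map")
    universe = {canonical_symbol(g) for g in universe}
    set_genes = {canonical_symbol(g) for g in gene_set.genes} & universe
    M = len(universe)
    n = len(set_genes)
    rows = []
    for term in sorted(term_map):
        term_genes = {canonical_symbol(g) for g in term_map[term]} & universe
        k = len(term_genes & set_genes)
        if k == 0:
            continue
        K = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "set_size": n,
                "universe_size": M,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "set_size", "universe_size", "p_value"],
    )
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
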