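"""Developmental expression trajectories and the fetal-propensity statistic.

The expression input is a gene x developmental-stage matrix (neocortical
stages ordered in developmental time, each tagged early_fetal / later_fetal
/ postnatal).  Two complementary views are computed:

* **Trajectories** on stage-normalized values (per-gene z-score across
  stages by default): the stage-wise mean +/- SEM over a gene set shows
  whether the set's expression is biased toward early fetal development.
* **beta**, the fetal expression propensity of a single gene, computed on
  the *raw* (unnormalized) values: the ratio of its mean expression over
  the early-fetal stages to its mean over the postnatal stages.  beta > 1
  indicates fetal-biased expression.  Per-gene beta collections of two gene
  sets are compared by Wilcoxon rank-sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .burden import rank_sum_test
from .genesets import GeneSet, canonical_symbol
from .types import ExpressionMatrix, TestResult

logger = logging.getLogger(__name__)


@dataclass
class TrajectorySummary:
    """Per-stage mean and SEM of normalized expression over a gene set."""

    stages: list[str]
    mean: np.ndarray
    sem: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stages, "mean": self.mean, "sem": self.sem}
        )


@dataclass(frozen=True)
class ExpressionPropensity:
    """A gene's fetal-vs-postnatal expression ratio (beta)."""

    gene: str
    beta: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive when defined, got {self.beta}")


def normalize_stages(matrix: ExpressionMatrix, scheme: str = "zscore") -> ExpressionMatrix:
    """Normalize each gene's expression across developmental stages.

    ``zscore`` (default): per-gene z-score with sample SD (n-1).  ``minmax``:
    per-gene scaling to [0, 1].  Genes with zero cross-stage variance are set
    to all-zero and flagged on the returned matrix.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("normalization needs at least two stages")
    values = df.to_numpy(dtype=float)
    if scheme == "zscore":
        center = values.mean(axis=1, keepdims=True)
        scale = values.std(axis=1, ddof=1, keepdims=True)
    elif scheme == "minmax":
        center = values.min(axis=1, keepdims=True)
        scale = values.max(axis=1, keepdims=True) - center
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    flat = scale[:, 0] == 0
    scale[flat] = 1.0
    out = (values - center) / scale
    out[flat] = 0.0
    flagged = frozenset(df.index[flat])
    if flagged:
        logger.info("normalize_stages: %d constant gene row(s) flagged", len(flagged))
    return ExpressionMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns),
        matrix.epochs,
        normalized=True,
        flagged_genes=flagged,
    )


def trajectory(gene_set: GeneSet | Iterable[str], matrix: ExpressionMatrix) -> TrajectorySummary:
    """Stage-wise mean and SEM of (normalized) expression over a gene set."""
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else set(gene_set)
    genes = {canonical_symbol(g) for g in genes}
    present = [g for g in matrix.values.index if g in genes]
    if len(present) < 2:
        raise ValueError(
            f"trajectory needs >= 2 set genes present in the matrix, got {len(present)}"
        )
    sub = matrix.values.loc[present].to_numpy(dtype=float)
    mean = sub.mean(axis=0)
    sem = sub.std(axis=0, ddof=1) / np.sqrt(sub.shape[0])
    return TrajectorySummary(
        stages=list(matrix.values.columns), mean=mean, sem=sem, n_genes=len(present)
    )


def beta_score(
    gene: str,
    matrix: ExpressionMatrix,
    early_epoch: str = "early_fetal",
    postnatal_epoch: str = "postnatal",
) -> ExpressionPropensity | None:
    """Fetal expression propensity of one gene on the raw matrix.

    beta = mean(early-fetal stages) / mean(postnatal stages).  Returns None
    (the gene is excluded and should be counted by the caller) when the
    postnatal mean is zero; raises when the gene is absent from the matrix.
    """
    if matrix.normalized:
        raise ValueError("beta is defined on the raw (unnormalized) matrix")
    gene = canonical_symbol(gene)
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    early = matrix.epoch_stages(early_epoch)
    post = matrix.epoch_stages(postnatal_epoch)
    if not early or not post:
        raise ValueError("both the early-fetal and postnatal epochs must be nonempty")
    row = matrix.values.loc[gene]
    post_mean = float(row[post].mean())
    if post_mean == 0:
        return None
    return ExpressionPropensity(gene=gene, beta=float(row[early].mean()) / post_mean)


def beta_scores(
    genes: Iterable[str], matrix: ExpressionMatrix, *, skip_absent: bool = False
) -> tuple[list[ExpressionPropensity], int]:
    """Per-gene beta for a collection; returns (scores, n_excluded).

    ``n_excluded`` counts genes with a zero postnatal mean (beta undefined).
    With ``skip_absent`` genes missing from the matrix are skipped silently
    instead of raising.
    """
    scores = []
    excluded = 0
    for g in genes:
        if skip_absent and canonical_symbol(g) not in matrix.values.index:
            continue
        s = beta_score(g, matrix)
        if s is None:
            excluded += 1
        else:
            scores.append(s)
    if excluded:
        logger.info("beta_scores: %d gene(s) with zero postnatal mean excluded", excluded)
    return scores, excluded


def compare_beta(
    betas_a: Sequence[ExpressionPropensity | float],
    betas_b: Sequence[ExpressionPropensity | float],
) -> TestResult:
    """Rank-sum comparison of two per-gene beta collections.

    Also reports each group's median beta and fraction of genes with
    beta > 1 (the in-text fetal-bias summary).
    """
    a = np.array([b.beta if isinstance(b, ExpressionPropensity) else float(b) for b in betas_a])
    b = np.array([x.beta if isinstance(x, ExpressionPropensity) else float(x) for x in betas_b])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both beta collections must be nonempty")
    result = rank_sum_test(a, b)
    result.extra.update(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        fraction_gt1_a=float(np.mean(a > 1)),
        fraction_gt1_b=float(np.mean(b > 1)),
    )
    return result
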