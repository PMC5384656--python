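"""Core domain types for trio-based de novo mutation analysis.

The package models a whole-genome-sequenced parent-offspring trio cohort in
which each newborn genome carries a countable burden of de novo mutations
(variants absent from both parents).  Types here are deliberately small,
immutable records; all computation lives in the analysis modules.

Coordinate conventions
----------------------
Mutation positions are 1-based (VCF convention).  Genomic intervals are
0-based half-open (BED convention).  Conversion happens only at I/O
boundaries.  Chromosome labels are stored without a ``chr`` prefix; the
autosome set is ``{"1", ..., "22"}``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Gestational-age cutoff (weeks) below which a birth is preterm.
PRETERM_CUTOFF_WEEKS = 37.0

#: Plausible gestational-age range accepted at read time (weeks).
GESTATIONAL_AGE_RANGE = (20.0, 45.0)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

VARIANT_CLASSES = ("SNV", "indel")
CONSEQUENCES = ("synonymous", "missense", "nonsense", "frameshift", "noncoding", "other")
#: Protein-altering consequence classes (missense, nonsense, frameshift).
NONSYNONYMOUS_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift"})
VIABILITY_CLASSES = ("lethal", "subviable", "viable", "unknown")
SVTYPES = ("deletion", "duplication")
PARENTAL_ORIGINS = ("paternal", "maternal", "unknown")

EPOCHS = ("early_fetal", "later_fetal", "postnatal")


def normalize_chrom(label: object) -> str:
    """Strip an optional ``chr`` prefix from a chromosome label."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass(frozen=True)
class TrioRecord:
    """One family: parental ages (years), gestational age (weeks)."""

    family_id: str
    paternal_age: float
    maternal_age: float
    gestational_age: float

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be nonempty")
        if not self.paternal_age > 0:
            raise ValueError(f"{self.family_id}: paternal_age must be > 0")
        if not self.maternal_age > 0:
            raise ValueError(f"{self.family_id}: maternal_age must be > 0")

    @property
    def preterm(self) -> bool:
        """True iff gestational age is strictly below 37 weeks."""
        return self.gestational_age < PRETERM_CUTOFF_WEEKS


@dataclass(frozen=True)
class DeNovoMutation:
    """One de novo variant call in a newborn genome.

    ``pos`` is 1-based.  ``cadd_phred`` and ``gene`` may be absent (``None``);
    a missing CADD score never counts as deleterious for SNVs.
    """

    subject_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    consequence: str = "other"
    cadd_phred: float | None = None
    gene: str | None = None
    parental_origin: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.variant_class == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(
                f"SNV must have single-base ref/alt, got {self.ref!r}>{self.alt!r}"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.cadd_phred is not None and not self.cadd_phred >= 0:
            raise ValueError(f"cadd_phred must be >= 0, got {self.cadd_phred}")
        if self.parental_origin not in PARENTAL_ORIGINS:
            raise ValueError(f"unknown parental_origin {self.parental_origin!r}")

    @property
    def autosomal(self) -> bool:
        return self.chrom in AUTOSOMES


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene dosage-sensitivity scores and mouse-ortholog viability.

    Intolerance scores quantify selective depletion of copy-number variants
    (combined, deletion-specific, duplication-specific) in large human
    cohorts; higher means less tolerated.  ``viability`` is the phenotype of
    the homozygous mouse knockout of the gene's ortholog.  Scores may be NaN
    when the gene is unscored.
    """

    gene: str
    cnv_intolerance: float = float("nan")
    del_intolerance: float = float("nan")
    dup_intolerance: float = float("nan")
    viability: str = "unknown"
    phenotype_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")
        if self.viability not in VIABILITY_CLASSES:
            raise ValueError(f"unknown viability class {self.viability!r}")


class ExpressionMatrix:
    """Gene-by-developmental-stage expression values with epoch tags.

    Stages are ordered (developmental time) and each carries an epoch label
    from ``early_fetal`` / ``later_fetal`` / ``postnatal``.  Raw matrices are
    nonnegative; normalized matrices (per-gene z-scores) may be negative and
    are marked with ``normalized=True``.
    """

    def __init__(
        self,
        values,  # pandas DataFrame, index = genes, columns = stage labels
        epochs: Mapping[str, str],
        normalized: bool = False,
        flagged_genes: frozenset[str] = frozenset(),
    ) -> None:
        import pandas as pd

        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        if values.shape[1] < 1:
            raise ValueError("expression matrix needs at least one stage")
        missing = [s for s in values.columns if s not in epochs]
        if missing:
            raise ValueError(f"stages without epoch tag: {missing}")
        bad = {e for e in epochs.values() if e not in EPOCHS}
        if bad:
            raise ValueError(f"unknown epochs: {sorted(bad)}")
        if not normalized and (values.to_numpy() < 0).any():
            raise ValueError("raw expression values must be nonnegative")
        self.values = values
        self.epochs = dict(epochs)
        self.normalized = normalized
        #: Genes whose cross-stage variance was zero at normalization time.
        self.flagged_genes = frozenset(flagged_genes)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    def epoch_stages(self, epoch: str) -> list[str]:
        """Stage labels belonging to one developmental epoch, in order."""
        return [s for s in self.values.columns if self.epochs[s] == epoch]


@dataclass(frozen=True)
class GenomicInterval:
    """Typed 0-based half-open region (deletion or duplication CNVR)."""

    chrom: str
    start: int
    end: int
    svtype: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class ReplicationTimingTrack:
    """Piecewise-constant genome annotation of DNA replication timing.

    Stored per chromosome as sorted, non-overlapping ``[start, end)``
    segments with a timing value each.
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, float]]) -> None:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            chrom = normalize_chrom(chrom)
            if not 0 <= start < end:
                raise ValueError(f"bad segment [{start}, {end}) on {chrom}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, segs in per_chrom.items():
            segs.sort()
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping timing segments on {chrom}")
            arr = np.asarray(segs, dtype=float)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]
            self._values[chrom] = arr[:, 2]

    def mean_over(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Base-weighted mean timing over ``[start, end)``.

        Returns ``(mean, covered_bases)``; mean is NaN when no base of the
        window is covered by the track.
        """
        chrom = normalize_chrom(chrom)
        start = max(start, 0)
        if chrom not in self._starts or start >= end:
            return float("nan"), 0
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        total = 0.0
        covered = 0
        while i < len(starts) and starts[i] < end:
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                total += values[i] * ov
                covered += int(ov)
            i += 1
        if covered == 0:
            return float("nan"), 0
        return total / covered, covered


@dataclass
class TestResult:
    """Carrier for a reported test statistic.

    ``extra`` holds method-specific summaries (e.g. group medians).
    """

    method: str
    statistic: float
    p_value: float
    n_group1: int
    n_group2: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_group1": int(self.n_group1),
            "n_group2": int(self.n_group2),
        }
        if self.extra:
            d["extra"] = {k: _jsonable(v) for k, v in sorted(self.extra.items())}
        return d


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (set, frozenset)):
        return sorted(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
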