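"""Synthetic trio-cohort generator emulating the study's statistical structure.

The generator produces every input the analysis consumes — trio tables,
per-subject de novo mutation lists, gene annotations, a developmental
expression matrix and query/reference interval collections with known
ground truth — so the full pipeline is testable without any external
download.

Burden model
------------
Paternal age is truncated-normal (mean 33.5 y, SD 5.8, minimum 18); maternal
age is drawn correlated with paternal age (default r = 0.7).  Each genome's
de novo mutation count is Poisson with rate

    lambda = a + b * (paternal_age - mean) + delta * 1[preterm]

floored at one mutation.  Defaults reproduce the study conditions: baseline
``a`` = 43.86 mutations per term genome, preterm shift ``delta`` = 2.22
(46.08 - 43.86), and the paternal-age slope ``b`` solved in closed form so
that the age-burden Pearson correlation is 0.62:

    r^2 = b^2 s^2 / (b^2 s^2 + E[lambda] + delta^2 p (1 - p))
    =>  b = (r / s) * sqrt((E[lambda] + delta^2 p (1 - p)) / (1 - r^2))

with ``s`` the paternal-age SD and ``p`` the preterm fraction (the
delta-variance term is a small refinement over the pure-Poisson form).

About 1 in 50 mutations is exonic; CADD phred scores are drawn from a
two-component mixture so a configurable fraction of missense/nonsense
variants exceeds the deleteriousness cutoff of 20; ~80% of mutations are of
paternal origin.

Determinism: one global seed; each generator derives its own stream through
a fixed, documented offset (numpy ``SeedSequence`` spawn keys), so the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as dio
from .genesets import extract_gene_set
from .types import (
    DeNovoMutation,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    TrioRecord,
)

# Fixed sub-stream offsets (SeedSequence spawn keys) per generator.
STREAM_COHORT = 0
STREAM_MUTATIONS = 1
STREAM_ANNOTATION = 2
STREAM_EXPRESSION = 3
STREAM_INTERVALS = 4
STREAM_REGION_GENES = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


#: Toy autosome map: 22 chromosomes, 10 Mb each (positions are uniform).
TOY_CHROM_LENGTH = 10_000_000

#: Default developmental stages (label, epoch), neocortical ordering.
DEFAULT_STAGES: tuple[tuple[str, str], ...] = (
    ("PCW8-10", "early_fetal"),
    ("PCW12", "early_fetal"),
    ("PCW13", "early_fetal"),
    ("PCW16", "later_fetal"),
    ("PCW17-22", "later_fetal"),
    ("PCW25-26", "later_fetal"),
    ("M4", "postnatal"),
    ("M10", "postnatal"),
    ("M12", "postnatal"),
)


def slope_for_correlation(
    r: float, sigma_age: float, mean_rate: float, extra_variance: float = 0.0
) -> float:
    """Paternal-age slope producing Pearson correlation ``r`` with the count.

    Closed form for a Poisson count whose rate is linear in age:
    Var(count) = E[lambda] + b^2 sigma^2 + extra_variance and
    Cov(age, count) = b sigma^2.
    """
    if not 0 <= r < 1:
        raise ValueError(f"correlation must be in [0, 1), got {r}")
    return (r / sigma_age) * math.sqrt((mean_rate + extra_variance) / (1 - r * r))


@dataclass
class SimulationParams:
    """Study-condition defaults for the synthetic cohort.

    ``age_slope=None`` resolves to the closed-form value for a 0.62
    age-burden correlation under the other defaults.
    """

    n_trios: int = 816
    preterm_fraction: float = 292 / 816
    paternal_age_mean: float = 33.5
    paternal_age_sd: float = 5.8
    paternal_age_min: float = 18.0
    maternal_age_mean: float = 31.4
    maternal_age_sd: float = 4.9
    parental_age_corr: float = 0.7
    # gestational-age mixture (weeks): modes from the observed group means
    ga_term_mode: float = 39.0
    ga_term_sd: float = 1.2
    ga_preterm_mode: float = 33.1
    ga_preterm_sd: float = 1.8
    ga_min: float = 22.7
    ga_max: float = 44.0
    # burden model
    baseline_rate: float = 43.86  # expected mutations per term genome
    age_slope: float | None = None  # mutations per year; None = solve for corr 0.62
    target_age_corr: float = 0.62
    preterm_shift: float = 46.08 - 43.86
    # mutation annotation
    exonic_fraction: float = 1 / 50
    consequence_split: dict = field(
        default_factory=lambda: {
            "missense": 0.58,
            "nonsense": 0.06,
            "frameshift": 0.08,
            "synonymous": 0.28,
        }
    )
    deleterious_fraction: float = 0.28  # P(CADD > 20 | missense or nonsense)
    noncoding_indel_fraction: float = 0.017
    paternal_origin_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "preterm_fraction",
            "exonic_fraction",
            "deleterious_fraction",
            "noncoding_indel_fraction",
            "paternal_origin_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if abs(sum(self.consequence_split.values()) - 1) > 1e-9:
            raise ValueError("consequence_split must sum to 1")

    @property
    def resolved_age_slope(self) -> float:
        if self.age_slope is not None:
            return self.age_slope
        p = self.preterm_fraction
        mean_rate = self.baseline_rate + self.preterm_shift * p
        extra = self.preterm_shift**2 * p * (1 - p)
        return slope_for_correlation(
            self.target_age_corr, self.paternal_age_sd, mean_rate, extra
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["resolved_age_slope"] = self.resolved_age_slope
        return json.dumps(d, sort_keys=True, indent=2)


def _truncnorm(rng, mean, sd, lower, upper, size):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(params: SimulationParams) -> tuple[list[TrioRecord], pd.Series]:
    """Simulate trio records and per-subject burden counts.

    Deterministic given ``params.seed``.  Counts are Poisson draws from the
    age- and preterm-dependent rate, floored at 1.  Ages are centered at the
    analytic truncated-normal mean so the term-group expectation equals
    ``baseline_rate`` exactly.
    """
    rng = _rng(params.seed, STREAM_COHORT)
    n = params.n_trios
    a_trunc = (params.paternal_age_min - params.paternal_age_mean) / params.paternal_age_sd
    pat = stats.truncnorm.rvs(
        a_trunc,
        np.inf,
        loc=params.paternal_age_mean,
        scale=params.paternal_age_sd,
        size=n,
        random_state=rng,
    )
    pat_center = float(
        stats.truncnorm.mean(
            a_trunc, np.inf, loc=params.paternal_age_mean, scale=params.paternal_age_sd
        )
    )
    rho = params.parental_age_corr
    noise = rng.standard_normal(n)
    mat = (
        params.maternal_age_mean
        + rho * params.maternal_age_sd / params.paternal_age_sd * (pat - pat_center)
        + params.maternal_age_sd * math.sqrt(1 - rho * rho) * noise
    )
    mat = np.maximum(mat, 16.0)
    preterm = rng.random(n) < params.preterm_fraction
    ga = np.where(
        preterm,
        _truncnorm(rng, params.ga_preterm_mode, params.ga_preterm_sd, params.ga_min, 37.0 - 1e-6, n),
        _truncnorm(rng, params.ga_term_mode, params.ga_term_sd, 37.0, params.ga_max, n),
    )
    b = params.resolved_age_slope
    lam = params.baseline_rate + b * (pat - pat_center) + params.preterm_shift * preterm
    if np.any(lam <= 0):
        raise ValueError(
            "nonpositive Poisson rate for some subject; decrease age_slope or "
            "increase baseline_rate"
        )
    counts = np.maximum(rng.poisson(lam), 1)
    width = len(str(n))
    trios = [
        TrioRecord(
            family_id=f"F{i + 1:0{width}d}",
            paternal_age=float(pat[i]),
            maternal_age=float(mat[i]),
            gestational_age=float(ga[i]),
        )
        for i in range(n)
    ]
    burden = pd.Series(counts, index=[t.family_id for t in trios], name="burden")
    return trios, burden


def simulate_mutations(
    counts: Mapping[str, int],
    gene_universe: Sequence[str],
    params: SimulationParams,
) -> list[DeNovoMutation]:
    """Simulate each subject's mutation list given its burden count.

    Consequences: exonic with probability ``exonic_fraction``, split among
    missense / nonsense / frameshift / synonymous; everything else
    noncoding.  CADD phred for missense/nonsense is a two-component mixture
    (above-20 with probability ``deleterious_fraction``); frameshifts carry
    no CADD score (they are deleterious by rule); parental origin is
    Bernoulli(``paternal_origin_fraction``).
    """
    gene_universe = list(gene_universe)
    if params.exonic_fraction > 0 and not gene_universe:
        raise ValueError("gene universe is empty but exonic_fraction > 0")
    rng = _rng(params.seed, STREAM_MUTATIONS)
    subjects = list(counts)
    n_per = np.array([int(counts[s]) for s in subjects])
    if np.any(n_per < 0):
        raise ValueError("negative mutation count")
    total = int(n_per.sum())
    subj_idx = np.repeat(np.arange(len(subjects)), n_per)
    chroms = rng.integers(1, 23, size=total)
    positions = rng.integers(1, TOY_CHROM_LENGTH + 1, size=total)
    cons_labels = list(params.consequence_split)
    cons_probs = np.array([params.consequence_split[c] for c in cons_labels])
    exonic = rng.random(total) < params.exonic_fraction
    cons_draw = rng.choice(len(cons_labels), size=total, p=cons_probs)
    paternal = rng.random(total) < params.paternal_origin_fraction
    deleterious = rng.random(total) < params.deleterious_fraction
    cadd_low = rng.uniform(0.0, 20.0, size=total)
    cadd_high = 20.0 + rng.exponential(5.0, size=total)
    noncoding_indel = rng.random(total) < params.noncoding_indel_fraction
    gene_idx = rng.integers(0, max(len(gene_universe), 1), size=total)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=total)
    alt_shift = rng.integers(1, 4, size=total)
    out: list[DeNovoMutation] = []
    for i in range(total):
        if exonic[i]:
            consequence = cons_labels[int(cons_draw[i])]
            gene = gene_universe[int(gene_idx[i])]
        else:
            consequence = "noncoding"
            gene = None
        if consequence == "frameshift":
            variant_class = "indel"
            cadd = None
        elif consequence == "noncoding":
            variant_class = "indel" if noncoding_indel[i] else "SNV"
            cadd = None
        else:
            variant_class = "SNV"
            if consequence == "synonymous":
                cadd = float(cadd_low[i] / 2.0)
            else:
                cadd = float(cadd_high[i] if deleterious[i] else cadd_low[i])
        if variant_class == "SNV":
            ref = bases[ref_idx[i]]
            alt = bases[(ref_idx[i] + alt_shift[i]) % 4]
        else:
            ref, alt = ("A", "AT") if paternal[i] else ("AT", "A")
        out.append(
            DeNovoMutation(
                subject_id=subjects[int(subj_idx[i])],
                chrom=str(int(chroms[i])),
                pos=int(positions[i]),
                ref=str(ref),
                alt=str(alt),
                variant_class=variant_class,
                consequence=consequence,
                cadd_phred=cadd,
                gene=gene,
                parental_origin="paternal" if paternal[i] else "maternal",
            )
        )
    return out


#: Mouse-knockout viability composition of the background genome, following
#: the screened proportions 410 lethal / 198 subviable / 1143 viable.
BACKGROUND_VIABILITY = {"lethal": 410 / 1751, "subviable": 198 / 1751, "viable": 1143 / 1751}

NERVOUS_SYSTEM_TERM = "abnormal_nervous_system_development"


def simulate_gene_annotation(
    gene_universe: Sequence[str],
    causal_set: Iterable[str],
    del_shift: float = 0.75,
    lethal_prob_causal: float = 0.45,
    seed: int = 0,
    *,
    known_fraction: float = 0.8,
    n_terms: int = 20,
    background_term_rate: float = 0.02,
    causal_term_rate: float = 0.6,
) -> list[GeneAnnotation]:
    """Simulate per-gene intolerance scores, viability and phenotype terms.

    Background deletion/duplication intolerance are independent standard
    normals (combined CNV intolerance is their scaled sum).  Causal genes
    get a location shift of ``del_shift`` SD on deletion intolerance only,
    an elevated lethal probability, and an enriched nervous-system phenotype
    term — mirroring a dosage-sensitive, developmentally essential set.
    """
    universe = list(gene_universe)
    causal = set(causal_set)
    missing = causal - set(universe)
    if missing:
        raise ValueError(
            f"causal gene(s) not in universe: {', '.join(sorted(missing)[:5])}"
        )
    if del_shift < 0 or lethal_prob_causal < 0:
        raise ValueError("effect sizes must be nonnegative")
    rng = _rng(seed, STREAM_ANNOTATION)
    n = len(universe)
    is_causal = np.array([g in causal for g in universe])
    del_score = rng.standard_normal(n) + del_shift * is_causal
    dup_score = rng.standard_normal(n)
    cnv_score = (del_score + dup_score) / math.sqrt(2)
    known = rng.random(n) < known_fraction
    bg_probs = np.array([BACKGROUND_VIABILITY[c] for c in ("lethal", "subviable", "viable")])
    remaining = 1 - lethal_prob_causal
    causal_probs = np.array(
        [
            lethal_prob_causal,
            remaining * bg_probs[1] / (bg_probs[1] + bg_probs[2]),
            remaining * bg_probs[2] / (bg_probs[1] + bg_probs[2]),
        ]
    )
    classes = np.array(["lethal", "subviable", "viable"])
    draw_bg = rng.choice(3, size=n, p=bg_probs)
    draw_causal = rng.choice(3, size=n, p=causal_probs)
    term_hits = rng.random((n, n_terms)) < background_term_rate
    special = rng.random(n) < np.where(is_causal, causal_term_rate, background_term_rate)
    out = []
    for i, g in enumerate(universe):
        viability = "unknown"
        if known[i]:
            viability = str(classes[draw_causal[i] if is_causal[i] else draw_bg[i]])
        terms = {f"T{j + 1:02d}" for j in np.flatnonzero(term_hits[i])}
        if special[i]:
            terms.add(NERVOUS_SYSTEM_TERM)
        out.append(
            GeneAnnotation(
                gene=g,
                cnv_intolerance=float(cnv_score[i]),
                del_intolerance=float(del_score[i]),
                dup_intolerance=float(dup_score[i]),
                viability=viability,
                phenotype_terms=frozenset(terms),
            )
        )
    return out


def term_map_from_annotation(
    annotation: Sequence[GeneAnnotation],
) -> dict[str, set[str]]:
    """Invert per-gene phenotype terms into a term -> genes map."""
    out: dict[str, set[str]] = {}
    for a in annotation:
        for t in a.phenotype_terms:
            out.setdefault(t, set()).add(a.gene)
    return out


def simulate_expression(
    gene_universe: Sequence[str],
    fetal_biased: Iterable[str],
    stages: Sequence[tuple[str, str]] = DEFAULT_STAGES,
    seed: int = 0,
    *,
    bias: float = 0.8,
    noise_sd: float = 0.1,
    base_level: float = 10.0,
) -> ExpressionMatrix:
    """Simulate a positive gene x stage expression matrix.

    Fetal-biased genes have monotone-decreasing expected expression across
    the stage order (geometric decay with total log-range ``2 * bias``; a
    negative bias yields the mirrored, postnatal-biased profile); all other
    genes are flat.  Values carry multiplicative lognormal noise, so the
    matrix is strictly positive.
    """
    stages = list(stages)
    labels = [s for s, _ in stages]
    epochs = dict(stages)
    if "postnatal" not in epochs.values():
        raise ValueError("no postnatal stage defined; beta would be undefined")
    if "early_fetal" not in epochs.values():
        raise ValueError("no early-fetal stage defined; beta would be undefined")
    universe = list(gene_universe)
    biased = {g for g in fetal_biased}
    missing = biased - set(universe)
    if missing:
        raise ValueError(f"fetal-biased gene(s) not in universe: {sorted(missing)[:5]}")
    rng = _rng(seed, STREAM_EXPRESSION)
    n, S = len(universe), len(labels)
    is_biased = np.array([g in biased for g in universe])
    base = base_level * np.exp(0.5 * rng.standard_normal(n))
    idx = np.arange(S)
    # log-multiplier declines linearly from +bias to -bias across stages
    slope = bias * (1 - 2 * idx / (S - 1)) if S > 1 else np.zeros(1)
    log_mean = np.log(base)[:, None] + np.where(is_biased[:, None], slope[None, :], 0.0)
    values = np.exp(log_mean + noise_sd * rng.standard_normal((n, S)))
    df = pd.DataFrame(values, index=universe, columns=labels)
    return ExpressionMatrix(df, epochs)


def simulate_interval_sets(
    n_query: int,
    n_reference: int,
    shared_fraction: float,
    seed: int = 0,
    *,
    svtype: str = "deletion",
    chrom_offset: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[str]]:
    """Simulate query/reference CNVR collections with known ground truth.

    Shared queries are constructed with 85-100% of their span covered by
    same-type reference records (sometimes split into touching pieces);
    novel queries with 0-60% coverage.  Additional reference records are
    placed away from every query so they cannot disturb the truth labels.
    Returns ``(queries, references, truth)`` with truth labels aligned to
    the queries.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError(f"shared_fraction must be in [0, 1], got {shared_fraction}")
    rng = _rng(seed, STREAM_INTERVALS)
    n_shared = round(shared_fraction * n_query)
    queries: list[GenomicInterval] = []
    references: list[GenomicInterval] = []
    truth: list[str] = []
    slot = 1_000_000  # each query lives in its own 1 Mb slot
    for q in range(n_query):
        chrom = str((q + chrom_offset) % 22 + 1)
        slot_start = (q // 22 + (0 if svtype == "deletion" else 500)) * slot
        length = int(rng.integers(20_000, 200_001))
        start = slot_start + 200_000
        end = start + length
        queries.append(GenomicInterval(chrom=chrom, start=start, end=end, svtype=svtype))
        if q < n_shared:
            covered = int(math.ceil(float(rng.uniform(0.85, 1.0)) * length))
            cov_start = start + int(rng.integers(0, length - covered + 1))
            cov_end = cov_start + covered
            truth.append("shared")
            if covered > 2000 and rng.random() < 0.5:
                cut = cov_start + int(rng.integers(1000, covered - 999))
                references.append(GenomicInterval(chrom, cov_start, cut, svtype))
                references.append(GenomicInterval(chrom, cut, cov_end, svtype))
            else:
                references.append(GenomicInterval(chrom, cov_start, cov_end, svtype))
        else:
            truth.append("novel")
            covered = int(float(rng.uniform(0.0, 0.6)) * length)
            if covered > 0:
                references.append(GenomicInterval(chrom, start, start + covered, svtype))
    # distractor reference records, placed clear of all query zones
    n_extra = max(0, n_reference - len(references))
    for j in range(n_extra):
        chrom = str((j + chrom_offset) % 22 + 1)
        slot_start = (j // 22 + (0 if svtype == "deletion" else 500)) * slot
        start = slot_start + 500_000 + int(rng.integers(0, 300_000))
        references.append(
            GenomicInterval(chrom, start, start + int(rng.integers(1_000, 150_000)), svtype)
        )
    return queries, references, truth


#: CNVR bundle composition: 74 deletions (64 shared / 10 novel) and 57
#: duplications (56 shared / 1 novel).
DGV_BUNDLE_COMPOSITION = {"deletion": (74, 64), "duplication": (57, 56)}


def simulate_cnvr_bundle(
    seed: int = 0, n_reference_extra: int = 200
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[str]]:
    """The study-sized CNVR truth bundle (74 del: 64/10; 57 dup: 56/1)."""
    queries: list[GenomicInterval] = []
    references: list[GenomicInterval] = []
    truth: list[str] = []
    for svtype, (n_q, n_s) in DGV_BUNDLE_COMPOSITION.items():
        q, r, t = simulate_interval_sets(
            n_q,
            n_q + n_reference_extra,
            n_s / n_q,
            seed=seed,
            svtype=svtype,
        )
        queries += q
        references += r
        truth += t
    return queries, references, truth


def simulate_region_genes(
    queries: Sequence[GenomicInterval],
    gene_pool: Sequence[str],
    seed: int = 0,
    genes_per_region: tuple[int, int] = (2, 4),
) -> pd.DataFrame:
    """Place genes from a pool inside each query region (coordinate table).

    Each region receives 2-4 distinct genes drawn without replacement from
    the pool (cycled when exhausted), with coordinates strictly inside the
    region, so every placed gene overlaps its region.
    """
    rng = _rng(seed, STREAM_REGION_GENES)
    pool = list(gene_pool)
    if not pool:
        raise ValueError("empty gene pool")
    perm = [pool[i] for i in rng.permutation(len(pool))]
    rows = []
    cursor = 0
    for region in queries:
        k = int(rng.integers(genes_per_region[0], genes_per_region[1] + 1))
        for _ in range(k):
            gene = perm[cursor % len(perm)]
            cursor += 1
            g_len = max(200, region.length // 10)
            g_start = region.start + int(rng.integers(0, max(region.length - g_len, 1)))
            rows.append(
                {
                    "chrom": region.chrom,
                    "start": g_start,
                    "end": min(g_start + g_len, region.end),
                    "gene": gene,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


# ---------------------------------------------------------------------------
# Full bundle


@dataclass
class SyntheticBundle:
    """Everything the pipeline needs, generated from one seed."""

    params: SimulationParams
    trios: list[TrioRecord]
    burden: pd.Series
    mutations: list[DeNovoMutation]
    annotation: list[GeneAnnotation]
    term_map: dict[str, set[str]]
    expression: ExpressionMatrix
    queries: list[GenomicInterval]
    references: list[GenomicInterval]
    truth: list[str]
    gene_regions: pd.DataFrame
    gene_universe: list[str]


def simulate_bundle(
    params: SimulationParams | None = None, n_genes: int = 2000
) -> SyntheticBundle:
    """Generate the full synthetic analysis bundle.

    The designated *causal* gene set for the annotation shift is the set of
    genes hit by deleterious de novo mutations in the simulated preterm
    group, and the fetal-biased expression set is the genes placed in
    novel deletion CNVRs — so each downstream stage sees the signal the
    study observed.
    """
    if params is None:
        params = SimulationParams()
    universe = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    trios, burden = simulate_cohort(params)
    mutations = simulate_mutations(burden.to_dict(), universe, params)
    preterm_ids = {t.family_id for t in trios if t.preterm}
    ptb_genes = extract_gene_set(
        [m for m in mutations if m.subject_id in preterm_ids], "PTB"
    )
    annotation = simulate_gene_annotation(universe, ptb_genes.genes, seed=params.seed)
    queries, references, truth = simulate_cnvr_bundle(seed=params.seed)
    # region genes come from a reserved slice of the universe so the CNVR
    # stage has its own symbols; novel-deletion genes get the fetal bias
    region_pool = universe[-500:]
    gene_regions = simulate_region_genes(queries, region_pool, seed=params.seed)
    from .cnv import genes_in_regions  # local import avoids a module cycle

    novel_del = [
        q
        for q, t in zip(queries, truth)
        if t == "novel" and q.svtype == "deletion"
    ]
    biased = genes_in_regions(novel_del, gene_regions, label="novel_deletion_genes").genes
    expression = simulate_expression(universe, biased, seed=params.seed)
    return SyntheticBundle(
        params=params,
        trios=trios,
        burden=burden,
        mutations=mutations,
        annotation=annotation,
        term_map=term_map_from_annotation(annotation),
        expression=expression,
        queries=queries,
        references=references,
        truth=truth,
        gene_regions=gene_regions,
        gene_universe=universe,
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write the synthetic bundle as the pipeline's file formats.

    Emits trios.tsv, mutations.tsv, genes.tsv, expression.tsv, query.bed,
    reference.bed, gene_regions.bed, truth.tsv and params.json; returns the
    path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trios": out / "trios.tsv",
        "mutations": out / "mutations.tsv",
        "genes": out / "genes.tsv",
        "expression": out / "expression.tsv",
        "query_bed": out / "query.bed",
        "reference_bed": out / "reference.bed",
        "gene_regions_bed": out / "gene_regions.bed",
        "truth": out / "truth.tsv",
        "params": out / "params.json",
    }
    dio.write_trios(bundle.trios, paths["trios"])
    dio.write_mutations(bundle.mutations, paths["mutations"])
    dio.write_gene_annotations(bundle.annotation, paths["genes"])
    dio.write_expression(bundle.expression, paths["expression"])
    dio.write_intervals(bundle.queries, paths["query_bed"])
    dio.write_intervals(bundle.references, paths["reference_bed"])
    dio.write_gene_regions(bundle.gene_regions, paths["gene_regions_bed"])
    pd.DataFrame(
        {
            "chrom": [q.chrom for q in bundle.queries],
            "start": [q.start for q in bundle.queries],
            "end": [q.end for q in bundle.queries],
            "svtype": [q.svtype for q in bundle.queries],
            "truth": bundle.truth,
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    paths["params"].write_text(bundle.params.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
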