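"""End-to-end orchestration: burden -> gene sets -> expression -> CNV.

``run_all`` executes every analysis stage on either user-supplied files or
an in-memory synthetic bundle, and returns a machine-readable run summary
(a single JSON-serializable document).  Stages whose inputs are missing are
skipped and recorded.  Re-running with identical inputs and seed yields an
identical document; the summary carries input digests, every threshold
actually applied, every test result, gene-set sizes and classification
counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import io as dio
from .burden import (
    age_burden_correlation,
    compare_groups,
    count_burden,
    extreme_load_subset,
    fit_preterm_logistic,
    rank_sum_test,
    residualize_burden,
    stratified_burden,
    timing_context,
)
from .cnv import classification_counts, classify_cnvrs, genes_in_regions
from .config import RunConfig
from .expression import beta_scores, compare_beta, normalize_stages, trajectory
from .genesets import (
    compare_intolerance,
    extract_gene_set,
    phenotype_enrichment,
    viability_composition,
    viability_enrichment,
)
from .simulate import SimulationParams, SyntheticBundle, simulate_bundle

logger = logging.getLogger(__name__)

#: Gestational-age strata (weeks) reported alongside the overall comparison.
DEFAULT_GA_BINS = ((32.0, 37.0), (20.0, 32.0))


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_all(
    config: RunConfig,
    *,
    simulate: bool = False,
    bundle: SyntheticBundle | None = None,
) -> dict:
    """Run every stage and return the run summary document.

    With ``simulate=True`` (or an explicit ``bundle``) all inputs come from
    the synthetic generator seeded by ``config.seed``; supplying file paths
    for the same stages at the same time is contradictory and raises before
    execution.
    """
    if simulate or bundle is not None:
        conflicting = [
            k
            for k in ("trios", "mutations", "genes", "expression", "query_bed")
            if getattr(config, k) is not None
        ]
        if conflicting:
            raise ValueError(
                "contradictory config: simulate mode excludes input paths "
                f"({', '.join(conflicting)})"
            )
        if bundle is None:
            bundle = simulate_bundle(SimulationParams(seed=config.seed))

    logger.info(
        "thresholds: preterm_cutoff=%g weeks, cadd_cutoff=%g, "
        "coverage_threshold=%g, timing_window=%d bp, top_load_fraction=%g",
        config.preterm_cutoff,
        config.cadd_cutoff,
        config.coverage_threshold,
        config.timing_window,
        config.top_load_fraction,
    )
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": "simulate" if bundle is not None else "files",
        "thresholds": {
            "preterm_cutoff": config.preterm_cutoff,
            "cadd_cutoff": config.cadd_cutoff,
            "coverage_threshold": config.coverage_threshold,
            "timing_window": config.timing_window,
            "top_load_fraction": config.top_load_fraction,
        },
        "inputs": {},
        "stages": {},
        "skipped": [],
    }
    if bundle is not None:
        summary["inputs"]["params"] = hashlib.sha256(
            bundle.params.to_json().encode()
        ).hexdigest()[:16]

    # ---------------- load inputs ----------------
    trios = mutations = annotation = term_map = expression = None
    queries = references = gene_regions = timing = None
    if bundle is not None:
        trios, mutations = bundle.trios, bundle.mutations
        annotation, term_map = bundle.annotation, bundle.term_map
        expression = bundle.expression
        queries, references = bundle.queries, bundle.references
        gene_regions = bundle.gene_regions
    else:
        loaders = {
            "trios": (dio.read_trios, "trios"),
            "mutations": (dio.read_mutations, "mutations"),
            "genes": (dio.read_gene_annotations, "genes"),
            "expression": (dio.read_expression, "expression"),
            "query_bed": (dio.read_intervals, "query_bed"),
            "reference_bed": (dio.read_intervals, "reference_bed"),
            "gene_regions_bed": (dio.read_gene_regions, "gene_regions_bed"),
            "timing_track": (dio.read_timing_track, "timing_track"),
        }
        loaded = {}
        for key, (reader, attr) in loaders.items():
            path = getattr(config, attr)
            if path is not None and Path(path).exists():
                loaded[key] = reader(path)
                summary["inputs"][key] = _digest(path)
        trios = loaded.get("trios")
        mutations = loaded.get("mutations")
        annotation = loaded.get("genes")
        expression = loaded.get("expression")
        queries = loaded.get("query_bed")
        references = loaded.get("reference_bed")
        gene_regions = loaded.get("gene_regions_bed")
        timing = loaded.get("timing_track")
        if annotation is not None:
            from .simulate import term_map_from_annotation

            term_map = term_map_from_annotation(annotation)

    # ---------------- burden stage ----------------
    ptb_set = term_set = None
    if trios is not None and mutations is not None:
        summary["stages"]["burden"] = _burden_stage(trios, mutations, config, timing)
        preterm_ids = {t.family_id for t in trios if t.gestational_age < config.preterm_cutoff}
        ptb_set = extract_gene_set(
            [m for m in mutations if m.subject_id in preterm_ids], "PTB", config.cadd_cutoff
        )
        term_set = extract_gene_set(
            [m for m in mutations if m.subject_id not in preterm_ids], "term", config.cadd_cutoff
        )
    else:
        summary["skipped"].append("burden")

    # ---------------- gene-set stage ----------------
    if annotation is not None and ptb_set is not None:
        summary["stages"]["genesets"] = _geneset_stage(
            ptb_set, term_set, annotation, term_map
        )
    else:
        summary["skipped"].append("genesets")

    # ---------------- CNV stage ----------------
    novel_genes = shared_genes = None
    if queries is not None and references is not None:
        stage, novel_genes, shared_genes = _cnv_stage(
            queries, references, gene_regions, config
        )
        if bundle is not None:
            truth = bundle.truth
            predicted = stage.pop("_predicted")
            stage["truth_accuracy"] = float(
                np.mean([p == t for p, t in zip(predicted, truth)])
            )
        else:
            stage.pop("_predicted")
        summary["stages"]["cnv"] = stage
    else:
        summary["skipped"].append("cnv")

    # ---------------- expression stage ----------------
    if expression is not None:
        summary["stages"]["expression"] = _expression_stage(
            expression, config, ptb_set, novel_genes, shared_genes
        )
    else:
        summary["skipped"].append("expression")

    summary["skipped"] = sorted(summary["skipped"])
    return summary


def _burden_stage(trios, mutations, config: RunConfig, timing) -> dict:
    burden = count_burden(mutations, trios)
    labels = {t.family_id: t.gestational_age < config.preterm_cutoff for t in trios}
    ids = [t.family_id for t in trios]
    values = burden[ids].to_numpy(dtype=float)
    is_preterm = np.array([labels[i] for i in ids])
    stage: dict = {
        "n_subjects": len(trios),
        "n_preterm": int(is_preterm.sum()),
        "mean_burden_term": float(values[~is_preterm].mean()),
        "mean_burden_preterm": float(values[is_preterm].mean()),
        "comparison": compare_groups(dict(zip(ids, values)), labels).to_dict(),
    }
    r, r2 = age_burden_correlation(trios, burden)
    stage["paternal_age_correlation"] = {"r": r, "r_squared": r2}
    stage["logistic"] = fit_preterm_logistic(trios, burden).to_dict()
    for which in ("paternal", "maternal"):
        ages = np.array(
            [t.paternal_age if which == "paternal" else t.maternal_age for t in trios]
        )
        resid = residualize_burden(values, ages)
        stage[f"residual_{which}"] = compare_groups(
            dict(zip(ids, resid)), labels
        ).to_dict()
    top = extreme_load_subset(burden.to_dict(), config.top_load_fraction)
    stage["extreme_load"] = {"n": len(top)}
    top_trios = [t for t in trios if t.family_id in top]
    top_pre = [t for t in top_trios if labels[t.family_id]]
    top_term = [t for t in top_trios if not labels[t.family_id]]
    if top_pre and top_term:
        stage["extreme_load"]["paternal_age_comparison"] = rank_sum_test(
            [t.paternal_age for t in top_pre], [t.paternal_age for t in top_term]
        ).to_dict()
        stage["extreme_load"]["maternal_age_comparison"] = rank_sum_test(
            [t.maternal_age for t in top_pre], [t.maternal_age for t in top_term]
        ).to_dict()
    stage["stratified"] = [
        s.to_dict()
        for s in stratified_burden(
            trios, burden.to_dict(), DEFAULT_GA_BINS, term_cutoff=config.preterm_cutoff
        )
    ]
    if timing is not None:
        ctx = timing_context(mutations, timing, config.timing_window)
        grp = np.array([labels.get(m.subject_id, False) for m in mutations])
        ok = ~np.isnan(ctx)
        if ok.any() and grp[ok].any() and (~grp[ok]).any():
            stage["timing_comparison"] = rank_sum_test(
                ctx[ok & grp], ctx[ok & ~grp], method="normal"
            ).to_dict()
    return stage


def _geneset_stage(ptb_set, term_set, annotation, term_map) -> dict:
    stage: dict = {
        "set_sizes": {
            "PTB": {"genes": len(ptb_set), "mutations": ptb_set.source_count},
            "term": {"genes": len(term_set), "mutations": term_set.source_count},
        }
    }
    intolerance = {}
    for label, gs in (("PTB", ptb_set), ("term", term_set)):
        per = {}
        for score in ("cnv", "del", "dup"):
            try:
                per[score] = compare_intolerance(gs, annotation, score).to_dict()
            except ValueError as exc:
                per[score] = {"error": str(exc)}
        intolerance[label] = per
    stage["intolerance"] = intolerance
    composition = {}
    for label, gs in (("PTB", ptb_set), ("term", term_set)):
        props, unknown = viability_composition(gs, annotation)
        composition[label] = {"proportions": props, "n_unknown": unknown}
    stage["viability_composition"] = composition
    try:
        stage["viability_enrichment"] = viability_enrichment(
            ptb_set, term_set, annotation
        ).to_dict()
    except ValueError as exc:
        stage["viability_enrichment"] = {"error": str(exc)}
    if term_map:
        universe = [a.gene for a in annotation]
        enr = phenotype_enrichment(ptb_set, term_map, universe)
        stage["phenotype_enrichment_top"] = enr.head(5).to_dict(orient="records")
    return stage


def _cnv_stage(queries, references, gene_regions, config: RunConfig):
    classifications = classify_cnvrs(queries, references, config.coverage_threshold)
    counts = classification_counts(classifications)
    stage = {
        "counts": counts,
        "_predicted": [c.status for c in classifications],
    }
    novel_genes = shared_genes = None
    if gene_regions is not None and len(gene_regions):
        novel_del = [
            c.interval
            for c in classifications
            if c.status == "novel" and c.interval.svtype == "deletion"
        ]
        shared_del = [
            c.interval
            for c in classifications
            if c.status == "shared" and c.interval.svtype == "deletion"
        ]
        novel_genes = genes_in_regions(novel_del, gene_regions, "novel_deletion_genes")
        shared_genes = genes_in_regions(shared_del, gene_regions, "shared_deletion_genes")
        stage["novel_deletion_genes"] = len(novel_genes)
        stage["shared_deletion_genes"] = len(shared_genes)
    return stage, novel_genes, shared_genes


def _expression_stage(expression, config: RunConfig, ptb_set, novel_genes, shared_genes) -> dict:
    stage: dict = {}
    normalized = normalize_stages(expression, config.normalization)
    if ptb_set is not None and len(ptb_set) >= 2:
        try:
            traj = trajectory(ptb_set, normalized)
            stage["ptb_trajectory"] = {
                "stages": traj.stages,
                "mean": [float(x) for x in traj.mean],
                "sem": [float(x) for x in traj.sem],
                "n_genes": traj.n_genes,
            }
        except ValueError as exc:
            stage["ptb_trajectory"] = {"error": str(exc)}
    traj_all = trajectory(expression.genes, normalized)
    stage["transcriptome_trajectory"] = {
        "stages": traj_all.stages,
        "mean": [float(x) for x in traj_all.mean],
        "sem": [float(x) for x in traj_all.sem],
        "n_genes": traj_all.n_genes,
    }
    if novel_genes is not None and shared_genes is not None:
        b_novel, excl_n = beta_scores(novel_genes.genes, expression, skip_absent=True)
        b_shared, excl_s = beta_scores(shared_genes.genes, expression, skip_absent=True)
        if b_novel and b_shared:
            stage["beta_comparison"] = compare_beta(b_novel, b_shared).to_dict()
            stage["beta_comparison"]["n_excluded_zero_postnatal"] = excl_n + excl_s
    return stage


def summary_json(summary: Mapping) -> str:
    """Deterministic serialization of a run summary."""
    return json.dumps(summary, sort_keys=True, indent=2)
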