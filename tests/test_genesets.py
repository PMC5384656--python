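"""Deleteriousness filter, gene-set extraction, intolerance/viability
contrasts and hypergeometric phenotype enrichment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import comb

from dnmburden.genesets import (
    GeneSet,
    bh_fdr,
    compare_intolerance,
    extract_gene_set,
    is_deleterious,
    is_nonsynonymous,
    phenotype_enrichment,
    viability_composition,
    viability_enrichment,
)
from dnmburden.types import GeneAnnotation


class TestFilters:
    @pytest.mark.parametrize(
        "consequence,expected",
        [("missense", True), ("nonsense", True), ("frameshift", True),
         ("synonymous", False), ("noncoding", False), ("other", False)],
    )
    def test_nonsynonymous_definition(self, mutation_factory, consequence, expected):
        assert is_nonsynonymous(mutation_factory(consequence=consequence)) is expected

    def test_frameshift_deleterious_without_cadd(self, mutation_factory):
        m = mutation_factory(consequence="frameshift", cadd=None,
                             variant_class="indel", ref="A", alt="AT")
        assert is_deleterious(m)

    def test_cadd_cutoff_is_strict(self, mutation_factory):
        assert not is_deleterious(mutation_factory(consequence="missense", cadd=20.0))
        assert is_deleterious(mutation_factory(consequence="missense", cadd=20.01))

    def test_nonsense_high_cadd_deleterious(self, mutation_factory):
        assert is_deleterious(mutation_factory(consequence="nonsense", cadd=35.0))

    def test_missing_cadd_on_snv_not_deleterious(self, mutation_factory):
        assert not is_deleterious(mutation_factory(consequence="missense", cadd=None))

    def test_error_on_synonymous(self, mutation_factory):
        with pytest.raises(ValueError, match="nonsynonymous"):
            is_deleterious(mutation_factory(consequence="synonymous", cadd=30.0))

    def test_filter_monotone_in_cutoff(self, mutation_factory, rng):
        muts = [
            mutation_factory(consequence=rng.choice(["missense", "nonsense", "frameshift"]),
                             cadd=None if i % 7 == 0 else float(rng.uniform(0, 40)))
            for i in range(80)
        ]
        muts = [m for m in muts if m.consequence != "frameshift" or True]
        sizes = []
        for cutoff in (0.0, 10.0, 20.0, 30.0, 1e9):
            passing = {
                i for i, m in enumerate(muts)
                if m.consequence == "frameshift" or (m.cadd_phred or 0) > cutoff
            }
            check = {i for i, m in enumerate(muts) if is_deleterious(m, cutoff)}
            assert check == passing
            sizes.append(check)
        for small, large in zip(sizes[1:], sizes):
            assert small <= large
        # at cutoff -> infinity only frameshifts remain
        assert all(muts[i].consequence == "frameshift" for i in sizes[-1])


class TestExtractGeneSet:
    def test_recurrent_gene_deduplicated(self, mutation_factory):
        muts = [mutation_factory(gene="SCN2A", cadd=30.0),
                mutation_factory(gene="scn2a", cadd=25.0)]
        gs = extract_gene_set(muts, "PTB")
        assert gs.source_count == 2 and len(gs) == 1

    def test_no_deleterious_mutations_empty_set(self, mutation_factory):
        gs = extract_gene_set([mutation_factory(cadd=5.0)], "PTB")
        assert len(gs) == 0 and gs.source_count == 0

    def test_missing_gene_counted_not_included(self, mutation_factory):
        gs = extract_gene_set([mutation_factory(gene=None, cadd=30.0)], "PTB")
        assert len(gs) == 0 and gs.n_unassigned == 1 and gs.source_count == 1

    def test_cardinality_bound(self, mutation_factory, rng):
        muts = [mutation_factory(gene=f"G{rng.integers(0, 20)}", cadd=float(rng.uniform(0, 40)))
                for _ in range(60)]
        gs = extract_gene_set(muts, "x")
        assert len(gs) <= gs.source_count


def annotation_from_scores(scores, score="del"):
    field = {"cnv": "cnv_intolerance", "del": "del_intolerance", "dup": "dup_intolerance"}[score]
    return [GeneAnnotation(gene=g, **{field: v}) for g, v in scores.items()]


class TestCompareIntolerance:
    def test_exact_enumeration_oracle(self):
        # set scores {5,6,7} vs background {1,2,3,4}: brute force over C(7,3)
        scores = {"A": 5.0, "B": 6.0, "C": 7.0, "D": 1.0, "E": 2.0, "F": 3.0, "G": 4.0}
        gs = GeneSet("s", frozenset({"A", "B", "C"}))
        res = compare_intolerance(gs, annotation_from_scores(scores), "del")
        pooled = np.array([5, 6, 7, 1, 2, 3, 4], dtype=float)
        ranks = stats.rankdata(pooled)
        mu = 3 * 8 / 2
        obs = abs(ranks[:3].sum() - mu)
        hits = sum(
            abs(ranks[list(c)].sum() - mu) >= obs - 1e-9
            for c in itertools.combinations(range(7), 3)
        )
        assert res.p_value == pytest.approx(hits / comb(7, 3))

    def test_constant_scores_p_one(self):
        scores = {f"G{i}": 3.0 for i in range(10)}
        gs = GeneSet("s", frozenset({"G0", "G1", "G2"}))
        res = compare_intolerance(gs, annotation_from_scores(scores), "del")
        assert res.p_value == 1.0

    def test_unscored_genes_dropped_and_counted(self):
        scores = {"A": 1.0, "B": float("nan"), "C": 2.0, "D": 3.0, "E": 4.0}
        gs = GeneSet("s", frozenset({"A", "B", "C"}))
        res = compare_intolerance(gs, annotation_from_scores(scores), "del")
        assert res.extra["n_dropped_unscored"] == 1
        assert res.n_group1 == 2

    def test_all_set_genes_unscored_raises(self):
        scores = {"A": float("nan"), "B": float("nan"), "C": 1.0}
        gs = GeneSet("s", frozenset({"A", "B"}))
        with pytest.raises(ValueError, match="< 2 genes"):
            compare_intolerance(gs, annotation_from_scores(scores), "del")

    def test_null_p_values_roughly_uniform(self, rng):
        # random draws from the background: KS against uniform over 60 seeds
        ps = []
        for _ in range(60):
            scores = {f"G{i}": float(v) for i, v in enumerate(rng.standard_normal(120))}
            members = rng.choice(120, size=10, replace=False)
            gs = GeneSet("s", frozenset(f"G{i}" for i in members))
            ps.append(compare_intolerance(gs, annotation_from_scores(scores), "del").p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestViability:
    def annotation(self):
        return [
            GeneAnnotation("A", viability="lethal"),
            GeneAnnotation("B", viability="lethal"),
            GeneAnnotation("C", viability="viable"),
            GeneAnnotation("D", viability="unknown"),
        ]

    def test_composition_over_known_genes(self):
        gs = GeneSet("s", frozenset({"A", "B", "C", "D"}))
        props, unknown = viability_composition(gs, self.annotation())
        assert props == pytest.approx({"lethal": 2 / 3, "subviable": 0.0, "viable": 1 / 3})
        assert unknown == 1

    def test_empty_intersection_flagged(self):
        gs = GeneSet("s", frozenset({"Z1", "Z2"}))
        props, unknown = viability_composition(gs, self.annotation())
        assert all(math.isnan(v) for v in props.values())
        assert unknown == 2

    def test_control_like_set_all_viable(self):
        annotation = [GeneAnnotation(f"V{i}", viability="viable") for i in range(5)]
        gs = GeneSet("GoNL", frozenset(a.gene for a in annotation))
        props, _ = viability_composition(gs, annotation)
        assert props == {"lethal": 0.0, "subviable": 0.0, "viable": 1.0}

    def test_fisher_matches_hypergeometric_enumeration(self):
        # table [[7,10],[5,40]]: two-sided p by summing hypergeometric
        # probabilities of all tables (with fixed margins) no more likely
        annotation = (
            [GeneAnnotation(f"A{i}", viability="lethal") for i in range(7)]
            + [GeneAnnotation(f"B{i}", viability="viable") for i in range(10)]
            + [GeneAnnotation(f"C{i}", viability="lethal") for i in range(5)]
            + [GeneAnnotation(f"D{i}", viability="viable") for i in range(40)]
        )
        set_a = GeneSet("a", frozenset([f"A{i}" for i in range(7)] + [f"B{i}" for i in range(10)]))
        set_b = GeneSet("b", frozenset([f"C{i}" for i in range(5)] + [f"D{i}" for i in range(40)]))
        res = viability_enrichment(set_a, set_b, annotation)
        n_lethal, row_a, total = 12, 17, 62
        rv = stats.hypergeom(total, n_lethal, row_a)
        p_obs = rv.pmf(7)
        p_manual = sum(
            rv.pmf(k)
            for k in range(max(0, row_a + n_lethal - total), min(row_a, n_lethal) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(p_manual)

    def test_identical_proportions_p_one(self):
        annotation = (
            [GeneAnnotation(f"A{i}", viability="lethal") for i in range(5)]
            + [GeneAnnotation(f"B{i}", viability="viable") for i in range(5)]
            + [GeneAnnotation(f"C{i}", viability="lethal") for i in range(10)]
            + [GeneAnnotation(f"D{i}", viability="viable") for i in range(10)]
        )
        set_a = GeneSet("a", frozenset([f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]))
        set_b = GeneSet("b", frozenset([f"C{i}" for i in range(10)] + [f"D{i}" for i in range(10)]))
        assert viability_enrichment(set_a, set_b, annotation).p_value == pytest.approx(1.0)

    def test_zero_lethal_margin_raises(self):
        annotation = (
            [GeneAnnotation(f"B{i}", viability="viable") for i in range(10)]
            + [GeneAnnotation(f"D{i}", viability="viable") for i in range(40)]
        )
        set_a = GeneSet("a", frozenset(f"B{i}" for i in range(10)))
        set_b = GeneSet("b", frozenset(f"D{i}" for i in range(40)))
        with pytest.raises(ValueError, match="lethal"):
            viability_enrichment(set_a, set_b, annotation)


class TestPhenotypeEnrichment:
    def test_hand_computed_hypergeometric_tail(self):
        # universe 20, term size 5, set size 5, overlap 4
        universe = [f"G{i}" for i in range(20)]
        term_map = {"T1": universe[:5]}
        gs = GeneSet("s", frozenset(universe[:4] + [universe[10]]))
        df = phenotype_enrichment(gs, term_map, universe)
        expected = (comb(5, 4) * comb(15, 1) + comb(5, 5) * comb(15, 0)) / comb(20, 5)
        assert df.loc[0, "p_value"] == pytest.approx(expected)

    def test_fully_contained_term_is_top_hit(self):
        universe = [f"G{i}" for i in range(50)]
        term_map = {"hit": universe[:5], "other": universe[10:30]}
        gs = GeneSet("s", frozenset(universe[:5]))
        df = phenotype_enrichment(gs, term_map, universe)
        assert df.iloc[0]["term"] == "hit"
        assert df.iloc[0]["p_value"] == df["p_value"].min()

    def test_disjoint_set_empty_result(self):
        universe = [f"G{i}" for i in range(20)]
        gs = GeneSet("s", frozenset({"G15"}))
        df = phenotype_enrichment(gs, {"T1": universe[:5]}, universe)
        assert len(df) == 0

    def test_empty_map_raises(self):
        with pytest.raises(ValueError, match="empty"):
            phenotype_enrichment(GeneSet("s", frozenset({"A"})), {}, ["A"])


class TestBH:
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_bh_monotone_and_bounded(self, ps):
        adj = bh_fdr(ps)
        assert (adj <= 1 + 1e-12).all()
        order = np.argsort(ps, kind="mergesort")
        sorted_adj = adj[order]
        assert (np.diff(sorted_adj) >= -1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()
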