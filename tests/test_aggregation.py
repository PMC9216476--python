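"""Decision trees, harmonization, metascores and the full pipeline."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oligoscore.aggregate import (
    compute_metascores,
    final_tree,
    fun_tree,
    harmonize_gene_scores,
    merge_cross_article,
    score_pipeline,
)
from oligoscore.config import ScoringConfig
from oligoscore.knowledge import AnnotationStore, KnowledgeScores
from oligoscore.knowledge_enums import StatReason
from oligoscore.manual import ManualScores
from oligoscore.model import (
    CombinationEntry,
    Disease,
    EvidenceRecord,
    ExperimentDesign,
    ExperimentOutcome,
    GeneFunctionalEvidence,
    Reference,
    Variant,
)

# Hand-transcribed expected outputs, written independently of the
# implementation: FUN by (gene, var); FINAL by (genetic, fun) with
# genetic = max(fam, stat).
FUN_EXPECTED = {
    (0, 0): 0, (0, 1): 0, (0, 2): 0, (0, 3): 0,
    (1, 0): 0, (1, 1): 1, (1, 2): 2, (1, 3): 2,
    (2, 0): 0, (2, 1): 2, (2, 2): 2, (2, 3): 2,
    (3, 0): 0, (3, 1): 2, (3, 2): 2, (3, 3): 3,
}
FINAL_BY_GENETIC = {
    (0, 0): 0, (0, 1): 0, (0, 2): 0, (0, 3): 0,
    (1, 0): 0, (1, 1): 1, (1, 2): 1, (1, 3): 2,
    (2, 0): 0, (2, 1): 1, (2, 2): 2, (2, 3): 3,
    (3, 0): 0, (3, 1): 1, (3, 2): 2, (3, 3): 3,
}


class TestFunTree:
    def test_matches_hand_transcribed_table(self):
        for (g, v), expected in FUN_EXPECTED.items():
            assert fun_tree(g, v) == expected, (g, v)

    @pytest.mark.parametrize(
        "g, v, expected", [(3, 3, 3), (2, 1, 2), (0, 3, 0), (1, 1, 1)]
    )
    def test_reference_points(self, g, v, expected):
        assert fun_tree(g, v) == expected

    def test_monotone_in_each_argument(self):
        for g, v in itertools.product(range(4), range(4)):
            if g < 3:
                assert fun_tree(g + 1, v) >= fun_tree(g, v)
            if v < 3:
                assert fun_tree(g, v + 1) >= fun_tree(g, v)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fun_tree(4, 0)


class TestFinalTree:
    def test_matches_hand_transcribed_table(self):
        for fam, stat, fun in itertools.product(range(4), range(3), range(4)):
            expected = FINAL_BY_GENETIC[(max(fam, stat), fun)]
            assert final_tree(fam, stat, fun) == expected, (fam, stat, fun)

    @pytest.mark.parametrize(
        "fam, stat, fun, expected",
        [(2, 0, 3, 3), (0, 1, 2, 1), (0, 0, 0, 0), (3, 2, 3, 3)],
    )
    def test_reference_points(self, fam, stat, fun, expected):
        assert final_tree(fam, stat, fun) == expected

    def test_monotone_in_each_argument(self):
        for fam, stat, fun in itertools.product(range(4), range(3), range(4)):
            if fam < 3:
                assert final_tree(fam + 1, stat, fun) >= final_tree(fam, stat, fun)
            if stat < 2:
                assert final_tree(fam, stat + 1, fun) >= final_tree(fam, stat, fun)
            if fun < 3:
                assert final_tree(fam, stat, fun + 1) >= final_tree(fam, stat, fun)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            final_tree(0, 3, 0)


manual_scores = st.builds(
    ManualScores,
    fam=st.integers(0, 3),
    stat=st.integers(0, 2),
    gene=st.integers(0, 3),
    var=st.integers(0, 3),
)


class TestMergeAndHarmonize:
    def test_cross_article_maximum(self):
        merged = merge_cross_article(
            [ManualScores(1, 0, 1, 0), ManualScores(2, 1, 0, 3)]
        )
        assert merged == ManualScores(2, 1, 1, 3)

    def test_single_article_unchanged(self):
        s = ManualScores(1, 2, 3, 0)
        assert merge_cross_article([s]) == s

    def test_three_article_variant_maximum(self):
        merged = merge_cross_article(
            [ManualScores(var=0), ManualScores(var=1), ManualScores(var=3)]
        )
        assert merged.var == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_cross_article([])

    @given(st.lists(manual_scores, min_size=1, max_size=5))
    def test_semilattice_laws(self, scores):
        merged = merge_cross_article(scores)
        # idempotent
        assert merge_cross_article([merged]) == merged
        assert merge_cross_article(scores + scores) == merged
        # commutative
        assert merge_cross_article(list(reversed(scores))) == merged
        # associative: fold pairwise in any grouping
        if len(scores) >= 3:
            left = merge_cross_article(
                [merge_cross_article(scores[:2])] + scores[2:]
            )
            right = merge_cross_article(
                scores[:1] + [merge_cross_article(scores[1:])]
            )
            assert left == right == merged

    def test_gene_pair_harmonized_to_corpus_maximum(self):
        manual = {
            "OLI1": ManualScores(gene=1),
            "OLI2": ManualScores(gene=3),
            "OLI3": ManualScores(gene=2),
        }
        keys = {"OLI1": ("GA", "GB"), "OLI2": ("GA", "GB"), "OLI3": ("GC", "GD")}
        harmonized = harmonize_gene_scores(manual, keys)
        assert harmonized == {("GA", "GB"): 3, ("GC", "GD"): 2}


def knowledge(stat=(0, StatReason.INSUFFICIENT_INFORMATION), gene=None, var=None):
    return KnowledgeScores(
        stat_value=stat[0], stat_reason=stat[1], gene=gene, var=var
    )


class TestMetascores:
    def test_population_panel_presence_overrides_manual_stat(self):
        ss = compute_metascores(
            ManualScores(stat=2),
            harmonized_gene=0,
            knowledge=knowledge(stat=(0, StatReason.PRESENT_IN_POPULATION_PANEL)),
        )
        assert ss.stat_meta == 0

    def test_gene_meta_takes_knowledge_maximum(self):
        ss = compute_metascores(
            ManualScores(gene=1), harmonized_gene=1, knowledge=knowledge(gene=2)
        )
        assert ss.gene_meta == 2

    def test_unassigned_knowledge_falls_back_to_manual(self):
        ss = compute_metascores(
            ManualScores(var=1), harmonized_gene=0, knowledge=knowledge(var=None)
        )
        assert ss.var_meta == 1

    def test_harmonized_below_manual_rejected(self):
        with pytest.raises(ValueError):
            compute_metascores(
                ManualScores(gene=2), harmonized_gene=1, knowledge=knowledge()
            )

    knowledge_strategy = st.builds(
        KnowledgeScores,
        stat_value=st.just(0),
        stat_reason=st.sampled_from(
            [
                StatReason.PRESENT_IN_POPULATION_PANEL,
                StatReason.CLINICAL_RELEVANCE_MISSING,
                StatReason.INSUFFICIENT_INFORMATION,
            ]
        ),
        gene=st.one_of(st.none(), st.integers(0, 2)),
        var=st.one_of(st.none(), st.integers(0, 1)),
    ) | st.builds(
        KnowledgeScores,
        stat_value=st.just(1),
        stat_reason=st.just(StatReason.ASSIGNED),
        gene=st.one_of(st.none(), st.integers(0, 2)),
        var=st.one_of(st.none(), st.integers(0, 1)),
    )

    @given(manual_scores, st.integers(0, 3), knowledge_strategy)
    def test_metascore_dominance(self, manual, extra_gene, know):
        harmonized = max(manual.gene, extra_gene)
        ss = compute_metascores(manual, harmonized, know)
        assert ss.gene_meta >= ss.gene_manual_harmonized >= manual.gene
        assert ss.var_meta >= manual.var
        if know.stat_reason is StatReason.PRESENT_IN_POPULATION_PANEL:
            assert ss.stat_meta == 0
        else:
            assert ss.stat_meta >= manual.stat
        assert ss.fun_meta >= ss.fun_manual


class TestPipeline:
    def _entry(self, cid, genes):
        return CombinationEntry(
            combination_id=cid,
            variants=tuple(
                Variant(local_id=f"{cid}.v{i}", gene_symbol=g, notation=f"c.{i}A>G")
                for i, g in enumerate(genes, start=1)
            ),
            disease=Disease(name="d"),
            references=(Reference(f"PUB_{cid}", 2010),),
        )

    def test_empty_evidence_scores_zero(self):
        entry = self._entry("OLI1", ["GA", "GB"])
        record = EvidenceRecord("OLI1", entry.references[0], "c1")
        ss = score_pipeline([record], [entry], AnnotationStore())["OLI1"]
        assert (
            ss.manual,
            ss.fun_meta,
            ss.final_meta,
        ) == (ManualScores(0, 0, 0, 0), 0, 0)
        assert ss.knowledge.stat_reason is StatReason.INSUFFICIENT_INFORMATION

    def test_gene_harmonization_spans_combinations_and_symbol_order(self):
        # two distinct combinations over the same gene pair, with the gene
        # symbols curated in opposite orders: both get the best GENEmanual
        strong_gene = GeneFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
        )
        e1 = self._entry("OLI1", ["GA", "GB"])
        e2 = self._entry("OLI2", ["GB", "GA"])
        r1 = EvidenceRecord(
            "OLI1", e1.references[0], "c1", gene_functional=strong_gene
        )
        r2 = EvidenceRecord("OLI2", e2.references[0], "c1")
        scores = score_pipeline([r1, r2], [e1, e2], AnnotationStore())
        assert scores["OLI1"].gene_manual_harmonized == 3
        assert scores["OLI2"].gene_manual_harmonized == 3
        assert scores["OLI2"].manual.gene == 0

    def test_cross_article_merge_feeds_trees(self):
        entry = self._entry("OLI1", ["GA", "GB"])
        a1 = Reference("PUB_a", 2010)
        a2 = Reference("PUB_b", 2015)
        entry = CombinationEntry(
            combination_id="OLI1",
            variants=entry.variants,
            disease=entry.disease,
            references=(a1, a2),
        )
        strong_gene = GeneFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
        )
        r1 = EvidenceRecord("OLI1", a1, "c1", gene_functional=strong_gene)
        r2 = EvidenceRecord("OLI1", a2, "c1")
        ss = score_pipeline([r1, r2], [entry], AnnotationStore())["OLI1"]
        assert ss.manual.gene == 3  # maximum across the two articles

    def test_unknown_combination_rejected(self):
        entry = self._entry("OLI1", ["GA", "GB"])
        record = EvidenceRecord("OLI9", Reference("PUB9", 2010), "c1")
        with pytest.raises(KeyError):
            score_pipeline([record], [entry], AnnotationStore())
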