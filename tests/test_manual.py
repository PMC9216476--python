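"""Manual scoring rules: level assignment, caps and monotonicity."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import enumerate_control_evidence
from oligoscore.manual import (
    ManualScores,
    score_familial,
    score_gene_manual,
    score_manual,
    score_statistical,
    score_variant_manual,
)
from oligoscore.model import (
    CarrierStatus,
    ControlEvidence,
    ControlSource,
    Degree,
    DIRECT_RELATIONSHIPS,
    EvidenceRecord,
    ExperimentDesign,
    ExperimentOutcome,
    GeneFunctionalEvidence,
    GeneRelationship,
    PedigreeEvidence,
    Phenotype,
    Reference,
    Relative,
    VariantFunctionalEvidence,
)

H, A = Phenotype.HEALTHY, Phenotype.AFFECTED
U = Phenotype.UNKNOWN
NC, FC, PC = (
    CarrierStatus.NON_CARRIER,
    CarrierStatus.FULL_CARRIER,
    CarrierStatus.PARTIAL_CARRIER,
)
F, S = Degree.FIRST, Degree.SECOND


def pedigree(*relatives, complete=True):
    return PedigreeEvidence(relatives=tuple(relatives), coverage_complete=complete)


class TestFamilial:
    @pytest.mark.parametrize(
        "ped, expected",
        [
            # perfect segregation with healthy relatives at both degrees
            (pedigree(Relative(F, H, NC), Relative(F, A, FC), Relative(S, H, PC)), 3),
            # no relatives at all
            (pedigree(), 0),
            # first- and second-degree informative but segregation incomplete
            (
                pedigree(
                    Relative(F, H, PC), Relative(S, H, PC), Relative(S, H, NC),
                    complete=False,
                ),
                2,
            ),
            # two first-degree relatives, perfect segregation, no second degree
            (pedigree(Relative(F, H, NC), Relative(F, A, FC)), 2),
            # exactly one healthy genotyped first-degree relative
            (pedigree(Relative(F, H, NC)), 1),
            # affected partial carrier contradicts the model: imperfect,
            # two first-degree relatives -> weak
            (pedigree(Relative(F, H, NC), Relative(F, A, PC)), 1),
            # a single affected genotyped relative alone is not enough
            (pedigree(Relative(F, A, FC)), 0),
            # uninformative relatives contribute nothing
            (pedigree(Relative(F, H, CarrierStatus.UNKNOWN), Relative(F, U, NC)), 0),
        ],
    )
    def test_levels(self, ped, expected):
        assert score_familial(ped) == expected

    def test_healthy_partial_carrier_consistent_with_oligogenic_model(self):
        # a healthy carrier of a sub-combination does not break perfection
        ped = pedigree(Relative(F, H, PC), Relative(F, A, FC), Relative(S, H, NC))
        assert score_familial(ped) == 3

    @given(
        st.lists(
            st.builds(
                Relative,
                st.sampled_from([F, S]),
                st.sampled_from([H, A, U]),
                st.sampled_from(list(CarrierStatus)),
            ),
            max_size=6,
        ),
        st.builds(
            Relative,
            st.sampled_from([F, S]),
            st.sampled_from([H, A]),
            st.sampled_from([NC, FC, PC]),
        ),
        st.booleans(),
    )
    def test_adding_consistent_relative_never_lowers(self, base, extra, complete):
        if not extra.consistent:
            return
        before = score_familial(pedigree(*base, complete=complete))
        after = score_familial(pedigree(*base, extra, complete=complete))
        assert after >= before


class TestStatistical:
    def test_explicit_absence_with_quality_gates(self):
        assert (
            score_statistical(
                ControlEvidence(
                    source=ControlSource.COHORT,
                    explicit=True,
                    size_sufficient=True,
                    ethnicity_matched=True,
                    phenotypes_known=True,
                    combination_absent=True,
                )
            )
            == 2
        )

    def test_implicit_absence_is_weak(self):
        assert (
            score_statistical(
                ControlEvidence(
                    source=ControlSource.PUBLIC_DB,
                    size_sufficient=True,
                    ethnicity_matched=True,
                    phenotypes_known=True,
                    combination_absent=True,
                )
            )
            == 1
        )

    def test_no_control_data(self):
        assert score_statistical(ControlEvidence()) == 0

    def test_missing_quality_gate_zeroes_score(self):
        assert (
            score_statistical(
                ControlEvidence(
                    source=ControlSource.COHORT,
                    explicit=True,
                    size_sufficient=True,
                    ethnicity_matched=False,
                    phenotypes_known=True,
                    combination_absent=True,
                )
            )
            == 0
        )

    def test_never_exceeds_two_exhaustively(self):
        values = {score_statistical(c) for c in enumerate_control_evidence()}
        assert values == {0, 1, 2}
        assert max(values) == 2

    def test_sequencing_similarity_not_gating(self):
        base = dict(
            source=ControlSource.COHORT,
            explicit=True,
            size_sufficient=True,
            ethnicity_matched=True,
            phenotypes_known=True,
            combination_absent=True,
        )
        assert score_statistical(
            ControlEvidence(sequencing_similar=False, **base)
        ) == score_statistical(ControlEvidence(sequencing_similar=True, **base))


def all_gene_states():
    rel_pool = [
        frozenset(),
        frozenset({GeneRelationship.RELEVANT_PATHWAYS_FOR_PHENOTYPE}),
        frozenset({GeneRelationship.AFFECTING_SAME_TISSUE}),
        frozenset({GeneRelationship.DIRECTLY_INTERACTING}),
        frozenset({GeneRelationship.SAME_PROTEIN_COMPLEX, GeneRelationship.CO_EXPRESSION}),
        frozenset(
            {
                GeneRelationship.SAME_PATHWAY,
                GeneRelationship.RELEVANT_PATHWAYS_FOR_PHENOTYPE,
            }
        ),
        frozenset({GeneRelationship.MONOGENIC_EXPERIMENTS_ONLY}),
    ]
    for design, outcome, rel, shown in itertools.product(
        ExperimentDesign, ExperimentOutcome, rel_pool, [False, True]
    ):
        if (design is ExperimentDesign.NONE) != (outcome is ExperimentOutcome.NONE):
            continue
        yield GeneFunctionalEvidence(
            experiment_design=design,
            experiment_outcome=outcome,
            relationship_types=rel,
            phenotype_relevance_shown=shown,
        )


def gene_oracle(g: GeneFunctionalEvidence) -> int:
    """Independent re-statement of the gene rule: collect the level granted
    by each criterion, take the maximum, then apply the negative cap."""
    levels = [0]
    experimental = g.experiment_design is not ExperimentDesign.NONE
    if (
        g.experiment_design is ExperimentDesign.SINGLE_AND_JOINT
        and g.experiment_outcome is ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE
    ):
        levels.append(3)
    if experimental and g.experiment_outcome in (
        ExperimentOutcome.EFFECT_SHOWN,
        ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
    ):
        levels.append(2)
    if g.relationship_types & DIRECT_RELATIONSHIPS and g.phenotype_relevance_shown:
        levels.append(2)
    if GeneRelationship.RELEVANT_PATHWAYS_FOR_PHENOTYPE in g.relationship_types:
        levels.append(1)
    if (
        GeneRelationship.AFFECTING_SAME_TISSUE in g.relationship_types
        and g.phenotype_relevance_shown
    ):
        levels.append(1)
    level = max(levels)
    if g.experiment_outcome is ExperimentOutcome.NEGATIVE:
        level = min(level, 1)
    return level


class TestGeneManual:
    @pytest.mark.parametrize(
        "evidence, expected",
        [
            (
                GeneFunctionalEvidence(
                    experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
                    experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
                ),
                3,
            ),
            (
                GeneFunctionalEvidence(
                    relationship_types=frozenset({GeneRelationship.SAME_PATHWAY}),
                    phenotype_relevance_shown=True,
                ),
                2,
            ),
            (
                GeneFunctionalEvidence(
                    relationship_types=frozenset(
                        {GeneRelationship.RELEVANT_PATHWAYS_FOR_PHENOTYPE}
                    )
                ),
                1,
            ),
            (
                # negative joint experiment caps an otherwise-moderate case
                GeneFunctionalEvidence(
                    experiment_design=ExperimentDesign.JOINT_ONLY,
                    experiment_outcome=ExperimentOutcome.NEGATIVE,
                    relationship_types=frozenset({GeneRelationship.SAME_PATHWAY}),
                    phenotype_relevance_shown=True,
                ),
                1,
            ),
            (GeneFunctionalEvidence(), 0),
        ],
    )
    def test_levels(self, evidence, expected):
        assert score_gene_manual(evidence) == expected

    def test_matches_independent_oracle_over_state_space(self):
        for state in all_gene_states():
            assert score_gene_manual(state) == gene_oracle(state), state

    def test_design_upgrade_never_lowers(self):
        for state in all_gene_states():
            if state.experiment_design is ExperimentDesign.JOINT_ONLY:
                upgraded = GeneFunctionalEvidence(
                    experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
                    experiment_outcome=state.experiment_outcome,
                    relationship_types=state.relationship_types,
                    phenotype_relevance_shown=state.phenotype_relevance_shown,
                )
                assert score_gene_manual(upgraded) >= score_gene_manual(state)


def all_variant_states():
    for design, outcome in itertools.product(ExperimentDesign, ExperimentOutcome):
        if (design is ExperimentDesign.NONE) != (outcome is ExperimentOutcome.NONE):
            continue
        for flags in itertools.product([False, True], repeat=4):
            yield VariantFunctionalEvidence(
                experiment_design=design,
                experiment_outcome=outcome,
                all_predicted_pathogenic=flags[0],
                mixed_experiment_and_prediction=flags[1],
                insilico_joint_effect_clear=flags[2],
                negative_result_present=flags[3],
            )


def variant_oracle(v: VariantFunctionalEvidence) -> int:
    levels = [0]
    experimental = v.experiment_design is not ExperimentDesign.NONE
    if (
        v.experiment_design is ExperimentDesign.SINGLE_AND_JOINT
        and v.experiment_outcome is ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE
    ):
        levels.append(3)
    if experimental and v.experiment_outcome in (
        ExperimentOutcome.EFFECT_SHOWN,
        ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
    ):
        levels.append(2)
    if v.insilico_joint_effect_clear:
        levels.append(2)
    if v.all_predicted_pathogenic or v.mixed_experiment_and_prediction:
        levels.append(1)
    if experimental and v.experiment_outcome is ExperimentOutcome.PROMISING_INCONCLUSIVE:
        levels.append(1)
    level = max(levels)
    if v.negative_result_present:
        level = min(level, 1)
    return level


class TestVariantManual:
    @pytest.mark.parametrize(
        "evidence, expected",
        [
            (
                VariantFunctionalEvidence(
                    experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
                    experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
                ),
                3,
            ),
            (VariantFunctionalEvidence(all_predicted_pathogenic=True), 1),
            (VariantFunctionalEvidence(insilico_joint_effect_clear=True), 2),
            (VariantFunctionalEvidence(), 0),
            (
                VariantFunctionalEvidence(
                    experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
                    experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
                    negative_result_present=True,
                ),
                1,
            ),
        ],
    )
    def test_levels(self, evidence, expected):
        assert score_variant_manual(evidence) == expected

    def test_matches_independent_oracle_over_state_space(self):
        for state in all_variant_states():
            assert score_variant_manual(state) == variant_oracle(state), state


class TestScoreManual:
    def test_empty_evidence_all_zero(self):
        r = EvidenceRecord("OLI1", Reference("PUB1", 2000), "c1")
        assert score_manual(r) == ManualScores(0, 0, 0, 0)

    def test_trigenic_cardiomyopathy_profile(self, worked_examples):
        # incomplete pedigree over both degrees + in-vivo synergy of the
        # triple mutant: moderate familial, strong gene and variant scores
        scores = score_manual(worked_examples["OLI606"].records[0])
        assert scores == ManualScores(fam=2, stat=0, gene=3, var=3)

    def test_cohort_hypothyroidism_profile(self, worked_examples):
        scores = score_manual(worked_examples["OLI474"].records[0])
        assert scores == ManualScores(fam=0, stat=1, gene=2, var=1)
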