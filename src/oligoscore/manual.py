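"""Manual confidence scores: evidence strength judged solely from the article.

Four per-evidence scores on the ordinal scale Absent/Weak/Moderate/Strong
(0/1/2/3):

* ``FAMmanual``  — pedigree segregation of the combination (0-3),
* ``STATmanual`` — control-cohort / database absence evidence (0-2; capped
  at 2 because cohort studies cannot control environmental background the
  way pedigrees can),
* ``GENEmanual`` — functional relationship of the genes (0-3),
* ``VARmanual``  — joint functional effect of the variants (0-3).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
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
    VariantFunctionalEvidence,
)


@dataclass(frozen=True)
class ManualScores:
    fam: int = 0
    stat: int = 0
    gene: int = 0
    var: int = 0

    def __post_init__(self):
        if not (0 <= self.fam <= 3 and 0 <= self.stat <= 2
                and 0 <= self.gene <= 3 and 0 <= self.var <= 3):
            raise ValueError(f"manual scores out of range: {self}")


def score_familial(p: PedigreeEvidence) -> int:
    """Grade pedigree segregation evidence (FAMmanual, 0-3).

    Strong (3): informative *healthy* relatives at both first and second
    degree, with perfect segregation.  Moderate (2): two or more
    informative first-degree relatives with perfect segregation, or
    imperfect segregation spanning first- and second-degree relatives.
    Weak (1): exactly one informative healthy first-degree relative, or
    imperfect segregation with two or more informative first-degree
    relatives.  Otherwise 0.
    """
    inf = p.informative_relatives
    first = [r for r in inf if r.degree is Degree.FIRST]
    second = [r for r in inf if r.degree is Degree.SECOND]
    perfect = p.segregation_perfect
    healthy_first = any(r.phenotype is Phenotype.HEALTHY for r in first)
    healthy_second = any(r.phenotype is Phenotype.HEALTHY for r in second)

    if perfect and healthy_first and healthy_second:
        return 3
    if (perfect and len(first) >= 2) or (not perfect and first and second):
        return 2
    if (len(first) == 1 and healthy_first) or (not perfect and len(first) >= 2):
        return 1
    return 0


def score_statistical(c: ControlEvidence) -> int:
    """Grade control-cohort / database evidence (STATmanual, 0-2).

    Requires a control source, demonstrated absence of the combination in
    controls, and the three quality gates (sufficient size, matched
    ethnicity, known control phenotypes).  Explicit absence checking earns
    2, implicit 1.  Similar sequencing technology is "preferable" and is
    recorded but not gating; shared-variant support flags are contextual
    only and never raise the score.
    """
    if c.source is ControlSource.NONE:
        return 0
    if not c.combination_absent:
        return 0
    if not (c.size_sufficient and c.ethnicity_matched and c.phenotypes_known):
        return 0
    return 2 if c.explicit else 1


def score_gene_manual(g: GeneFunctionalEvidence) -> int:
    """Grade gene-level functional evidence (GENEmanual, 0-3).

    Strong (3): synergistic or additive effect shown with both single and
    joint gene knockouts.  Moderate (2): an effect of the gene combination
    shown experimentally without the full synergy comparison, or a direct
    gene relationship (same pathway, direct interaction, same protein
    complex) with shown phenotype relevance.  Weak (1): pathway relevance
    for the phenotype, or shared tissue with shown phenotype relevance.
    A negative experimental outcome caps the score at 1: relevance of the
    genes may remain, but synergy is contradicted.
    """
    d, o = g.experiment_design, g.experiment_outcome
    rel = g.relationship_types
    score = 0
    if d is ExperimentDesign.SINGLE_AND_JOINT and o is ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE:
        score = 3
    elif d is not ExperimentDesign.NONE and o in (
        ExperimentOutcome.EFFECT_SHOWN,
        ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
    ):
        score = 2
    elif (rel & DIRECT_RELATIONSHIPS) and g.phenotype_relevance_shown:
        score = 2
    elif GeneRelationship.RELEVANT_PATHWAYS_FOR_PHENOTYPE in rel or (
        GeneRelationship.AFFECTING_SAME_TISSUE in rel and g.phenotype_relevance_shown
    ):
        score = 1
    if o is ExperimentOutcome.NEGATIVE:
        score = min(score, 1)
    return score


def score_variant_manual(v: VariantFunctionalEvidence) -> int:
    """Grade variant-level functional evidence (VARmanual, 0-3).

    Strong (3): synergistic/additive effect with single and multiple
    mutants.  Moderate (2): an experimental effect of the combination
    without the synergy comparison, or a clear in-silico joint effect.
    Weak (1): all variants predicted pathogenic, experiments mixed with
    predictions, or promising-but-inconclusive single-mutant experiments.
    A reported negative result caps the score at 1.
    """
    d, o = v.experiment_design, v.experiment_outcome
    score = 0
    if d is ExperimentDesign.SINGLE_AND_JOINT and o is ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE:
        score = 3
    elif (
        d is not ExperimentDesign.NONE
        and o in (ExperimentOutcome.EFFECT_SHOWN, ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE)
    ) or v.insilico_joint_effect_clear:
        score = 2
    elif (
        v.all_predicted_pathogenic
        or v.mixed_experiment_and_prediction
        or (d is not ExperimentDesign.NONE and o is ExperimentOutcome.PROMISING_INCONCLUSIVE)
    ):
        score = 1
    if v.negative_result_present:
        score = min(score, 1)
    return score


def score_manual(r: EvidenceRecord) -> ManualScores:
    """Apply all four manual scoring rules to one evidence record."""
    return ManualScores(
        fam=score_familial(r.pedigree),
        stat=score_statistical(r.statistical),
        gene=score_gene_manual(r.gene_functional),
        var=score_variant_manual(r.variant_functional),
    )
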