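"""Synthetic curation corpora with planted ground-truth scores.

The generator works *backwards* from target score levels to evidence: for
each combination it samples a target level per evidence type and then
constructs an evidence payload (and annotation-store rows) that realizes
exactly that level under the scoring rules.  This guarantees every rule
branch is exercised and gives an exact oracle: running the scoring
pipeline on a generated corpus must reproduce the planted scores with
zero mismatches.

Default level distributions are skewed toward absent/weak evidence, the
regime seen in real curated corpora of oligogenic combinations, where
most source articles are cohort studies or case reports focused on
genetic rather than functional evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .aggregate import ScoreSet, compute_metascores
from .config import ScoringConfig
from .knowledge import AnnotationStore, KnowledgeScores, PredictorCalls
from .knowledge_enums import MutationTaster, Polyphen, Sift, StatReason
from .manual import ManualScores
from .model import (
    CarrierStatus,
    CnvChange,
    CnvDetail,
    CombinationEntry,
    ControlEvidence,
    ControlSource,
    Coordinates,
    CoordinateFlag,
    Degree,
    Disease,
    EvidenceRecord,
    ExperimentDesign,
    ExperimentOutcome,
    GeneFunctionalEvidence,
    GeneRelationship,
    PedigreeEvidence,
    Phenotype,
    Reference,
    Relative,
    Variant,
    VariantClass,
    VariantFunctionalEvidence,
    Zygosity,
)

#: Target labels for the statistical knowledge outcome.
STAT_K_TARGETS = ("assigned", "present", "relevance_missing", "insufficient")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    ``target_level_distribution`` holds one categorical distribution per
    evidence type; manual types map integer levels to probabilities,
    knowledge types additionally admit the label ``"unassigned"`` (gene,
    var) and the four statistical outcomes.  ``boundary_rate`` is the
    probability of planting threshold-boundary annotation values (PPI
    confidence exactly at the threshold, CADD Phred exactly at the
    threshold) where doing so does not change the planted level.
    """

    n_combinations: int = 100
    genes_per_combination_distribution: Dict[int, float] = field(
        default_factory=lambda: {2: 0.8, 3: 0.15, 4: 0.05}
    )
    target_level_distribution: Dict[str, Dict[Union[int, str], float]] = field(
        default_factory=lambda: {
            "fam": {0: 0.5, 1: 0.2, 2: 0.2, 3: 0.1},
            "stat": {0: 0.5, 1: 0.3, 2: 0.2},
            "gene": {0: 0.3, 1: 0.3, 2: 0.3, 3: 0.1},
            "var": {0: 0.3, 1: 0.4, 2: 0.2, 3: 0.1},
            "stat_k": {
                "assigned": 0.35,
                "present": 0.15,
                "relevance_missing": 0.2,
                "insufficient": 0.3,
            },
            "gene_k": {0: 0.25, 1: 0.25, 2: 0.3, UNASSIGNED: 0.2},
            "var_k": {0: 0.3, 1: 0.4, UNASSIGNED: 0.3},
        }
    )
    cnv_fraction: float = 0.05
    multi_article_fraction: float = 0.2
    boundary_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        dists: List[Dict] = [self.genes_per_combination_distribution]
        dists += list(self.target_level_distribution.values())
        for dist in dists:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities must sum to 1, got {total}")
        for key in ("fam", "stat", "gene", "var", "stat_k", "gene_k", "var_k"):
            if key not in self.target_level_distribution:
                raise ValueError(f"missing target distribution for {key!r}")
        tld = self.target_level_distribution
        if any(level not in (0, 1, 2, 3) for level in tld["fam"]):
            raise ValueError("fam targets must be integer levels 0-3")
        if any(level not in (0, 1, 2) for level in tld["stat"]):
            raise ValueError("stat targets above 2 are unreachable")
        if any(level not in (0, 1, 2, 3) for level in tld["gene"]):
            raise ValueError("gene targets must be integer levels 0-3")
        if any(level not in (0, 1, 2, 3) for level in tld["var"]):
            raise ValueError("var targets must be integer levels 0-3")
        if any(level not in (0, 1, 2, UNASSIGNED) for level in tld["gene_k"]):
            raise ValueError("gene_k targets must be 0-2 or 'unassigned'")
        if any(level not in (0, 1, UNASSIGNED) for level in tld["var_k"]):
            raise ValueError("var_k targets must be 0, 1 or 'unassigned'")
        if any(t not in STAT_K_TARGETS for t in tld["stat_k"]):
            raise ValueError(f"stat_k targets must be among {STAT_K_TARGETS}")
        if any(k < 2 for k in self.genes_per_combination_distribution):
            raise ValueError("combinations need at least 2 genes")


@dataclass(frozen=True)
class PlantedCombination:
    """Ground truth for one generated combination: the sampled target
    levels and the score vector they imply under aggregation."""

    manual: ManualScores
    knowledge: KnowledgeScores
    scoreset: ScoreSet


PlantedTruth = Dict[str, PlantedCombination]


def _sample(rng: np.random.Generator, dist: Dict):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


# ---------------------------------------------------------------------------
# Constructive inverses of the manual scoring rules
# ---------------------------------------------------------------------------

def pedigree_for_level(level: int, rng: np.random.Generator) -> PedigreeEvidence:
    """Build a pedigree scoring exactly ``level`` under the familial rule."""
    H, A = Phenotype.HEALTHY, Phenotype.AFFECTED
    NC, FC, PC = (
        CarrierStatus.NON_CARRIER,
        CarrierStatus.FULL_CARRIER,
        CarrierStatus.PARTIAL_CARRIER,
    )
    first, second = Degree.FIRST, Degree.SECOND
    if level == 0:
        return PedigreeEvidence()
    if level == 1:
        if rng.random() < 0.5:
            # exactly one informative healthy first-degree relative
            return PedigreeEvidence(relatives=(Relative(first, H, NC),))
        # imperfect segregation, >=2 first-degree, no second-degree
        return PedigreeEvidence(
            relatives=(Relative(first, H, NC), Relative(first, A, PC))
        )
    if level == 2:
        if rng.random() < 0.5:
            # perfect segregation over two first-degree relatives only
            return PedigreeEvidence(
                relatives=(Relative(first, H, NC), Relative(first, A, FC))
            )
        # imperfect segregation spanning both degrees (coverage incomplete:
        # some variant's solo effect never observed)
        return PedigreeEvidence(
            relatives=(Relative(first, H, PC), Relative(second, H, NC)),
            coverage_complete=False,
        )
    if level == 3:
        return PedigreeEvidence(
            relatives=(
                Relative(first, H, NC),
                Relative(first, A, FC),
                Relative(second, H, PC),
            )
        )
    raise ValueError(f"unreachable familial level {level}")


def control_for_level(level: int) -> ControlEvidence:
    if level == 0:
        return ControlEvidence()
    return ControlEvidence(
        source=ControlSource.COHORT,
        explicit=level == 2,
        size_sufficient=True,
        ethnicity_matched=True,
        phenotypes_known=True,
        sequencing_similar=level == 2,
        combination_absent=True,
    )


def gene_functional_for_level(
    level: int, rng: np.random.Generator
) -> GeneFunctionalEvidence:
    if level == 0:
        return GeneFunctionalEvidence()
    if level == 1:
        return GeneFunctionalEvidence(
            relationship_types=frozenset(
                {GeneRelationship.RELEVANT_PATHWAYS_FOR_PHENOTYPE}
            )
        )
    if level == 2:
        if rng.random() < 0.5:
            return GeneFunctionalEvidence(
                experiment_design=ExperimentDesign.JOINT_ONLY,
                experiment_outcome=ExperimentOutcome.EFFECT_SHOWN,
            )
        return GeneFunctionalEvidence(
            relationship_types=frozenset({GeneRelationship.DIRECTLY_INTERACTING}),
            phenotype_relevance_shown=True,
        )
    if level == 3:
        return GeneFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
        )
    raise ValueError(f"unreachable gene level {level}")


def variant_functional_for_level(
    level: int, rng: np.random.Generator
) -> VariantFunctionalEvidence:
    if level == 0:
        return VariantFunctionalEvidence()
    if level == 1:
        return VariantFunctionalEvidence(all_predicted_pathogenic=True)
    if level == 2:
        if rng.random() < 0.5:
            return VariantFunctionalEvidence(
                experiment_design=ExperimentDesign.JOINT_ONLY,
                experiment_outcome=ExperimentOutcome.EFFECT_SHOWN,
            )
        return VariantFunctionalEvidence(insilico_joint_effect_clear=True)
    if level == 3:
        return VariantFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
        )
    raise ValueError(f"unreachable variant level {level}")


def record_for_levels(
    cid: str,
    article: Reference,
    levels: ManualScores,
    rng: np.random.Generator,
    curator_id: str = "consensus",
) -> EvidenceRecord:
    """Evidence record realizing exactly the given manual levels."""
    return EvidenceRecord(
        combination_id=cid,
        article=article,
        curator_id=curator_id,
        pedigree=pedigree_for_level(levels.fam, rng),
        statistical=control_for_level(levels.stat),
        gene_functional=gene_functional_for_level(levels.gene, rng),
        variant_functional=variant_functional_for_level(levels.var, rng),
    )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(
    config: GeneratorConfig,
    scoring_config: Optional[ScoringConfig] = None,
) -> Tuple[List[EvidenceRecord], List[CombinationEntry], AnnotationStore, PlantedTruth]:
    """Generate records, entries and annotation store with planted scores.

    Gene symbols are unique per combination, so gene-combination
    harmonization is the identity and the planted scores stay exact; the
    cross-article merge is exercised by emitting, for a fraction of the
    combinations, a second article whose levels never exceed the target.
    """
    scoring_config = scoring_config or ScoringConfig()
    rng = np.random.default_rng(config.seed)
    dists = config.target_level_distribution
    records: List[EvidenceRecord] = []
    entries: List[CombinationEntry] = []
    truth: PlantedTruth = {}
    planted_knowledge: Dict[str, Dict[str, object]] = {}

    for i in range(config.n_combinations):
        cid = f"OLI{i + 1:05d}"
        n_genes = int(_sample(rng, config.genes_per_combination_distribution))
        genes = [f"G{i + 1:05d}{chr(65 + j)}" for j in range(n_genes)]
        is_cnv = rng.random() < config.cnv_fraction
        variants = []
        for j, gene in enumerate(genes):
            # deterministic, corpus-unique position so variant keys never
            # collide between combinations
            pos = 10_000 + i * 100 + j
            if is_cnv and j == 0:
                variants.append(
                    Variant(
                        local_id=f"{cid}.v{j + 1}",
                        gene_symbol=gene,
                        notation=f"del({pos}-{pos + 5000})",
                        variant_class=VariantClass.CNV,
                        zygosity=Zygosity.HETEROZYGOUS,
                        cnv_detail=CnvDetail(pos, pos + 5000, CnvChange.DELETION),
                        coordinate_flag=CoordinateFlag.UNMAPPED,
                    )
                )
            else:
                variants.append(
                    Variant(
                        local_id=f"{cid}.v{j + 1}",
                        gene_symbol=gene,
                        notation=f"c.{pos % 3000 + 1}A>G",
                        variant_class=VariantClass.SNV,
                        zygosity=Zygosity.HETEROZYGOUS,
                        coordinates=Coordinates("GRCh38", f"{j + 1}", pos, "A", "G"),
                        coordinate_flag=CoordinateFlag.MAPPED,
                    )
                )
        article = Reference(
            article_id=f"PUB{i + 1:05d}", year=int(rng.integers(1995, 2022))
        )
        references = [article]

        target = ManualScores(
            fam=int(_sample(rng, dists["fam"])),
            stat=int(_sample(rng, dists["stat"])),
            gene=int(_sample(rng, dists["gene"])),
            var=int(_sample(rng, dists["var"])),
        )
        records.append(record_for_levels(cid, article, target, rng))
        if rng.random() < config.multi_article_fraction:
            second = Reference(
                article_id=f"PUB{i + 1:05d}b", year=int(rng.integers(1995, 2022))
            )
            references.append(second)
            weaker = ManualScores(
                fam=int(rng.integers(0, target.fam + 1)),
                stat=int(rng.integers(0, target.stat + 1)),
                gene=int(rng.integers(0, target.gene + 1)),
                var=int(rng.integers(0, target.var + 1)),
            )
            records.append(record_for_levels(cid, second, weaker, rng))

        entries.append(
            CombinationEntry(
                combination_id=cid,
                variants=tuple(variants),
                disease=Disease(
                    name=f"synthetic disease {i % 40 + 1}",
                    ontology_id=f"SYND:{i % 40 + 1}",
                ),
                references=tuple(references),
            )
        )

        planted_knowledge[cid] = {
            "stat_k": _sample(rng, dists["stat_k"]),
            "gene_k": _sample(rng, dists["gene_k"]),
            "var_k": _sample(rng, dists["var_k"]),
        }
        knowledge = _planted_knowledge_scores(planted_knowledge[cid])
        truth[cid] = PlantedCombination(
            manual=target,
            knowledge=knowledge,
            scoreset=compute_metascores(target, target.gene, knowledge, scoring_config),
        )

    store = generate_store(
        entries,
        planted_knowledge,
        seed=int(rng.integers(0, 2**31 - 1)),
        boundary_rate=config.boundary_rate,
        ppi_threshold=scoring_config.ppi_threshold,
        cadd_threshold=scoring_config.cadd_phred_threshold,
    )
    return records, entries, store, truth


def _planted_knowledge_scores(plan: Dict[str, object]) -> KnowledgeScores:
    stat_map = {
        "assigned": (1, StatReason.ASSIGNED),
        "present": (0, StatReason.PRESENT_IN_POPULATION_PANEL),
        "relevance_missing": (0, StatReason.CLINICAL_RELEVANCE_MISSING),
        "insufficient": (0, StatReason.INSUFFICIENT_INFORMATION),
    }
    stat_value, stat_reason = stat_map[plan["stat_k"]]
    gene_k, var_k = plan["gene_k"], plan["var_k"]
    return KnowledgeScores(
        stat_value=stat_value,
        stat_reason=stat_reason,
        gene=None if gene_k == UNASSIGNED else int(gene_k),
        var=None if var_k == UNASSIGNED else int(var_k),
    )


def generate_store(
    entries: Sequence[CombinationEntry],
    planted_knowledge: Dict[str, Dict[str, object]],
    seed: int = 0,
    boundary_rate: float = 0.1,
    ppi_threshold: float = 0.8,
    cadd_threshold: float = 15.0,
) -> AnnotationStore:
    """Build an annotation store realizing each planted knowledge outcome."""
    rng = np.random.default_rng(seed)
    store = AnnotationStore()

    def pathogenic_calls() -> PredictorCalls:
        if rng.random() < boundary_rate:
            # the CADD threshold itself is a pathogenic call (inclusive)
            return PredictorCalls(cadd_phred=float(cadd_threshold))
        choice = rng.integers(0, 4)
        if choice == 0:
            return PredictorCalls(
                cadd_phred=round(float(rng.uniform(cadd_threshold, 45.0)), 2)
            )
        if choice == 1:
            return PredictorCalls(sift=Sift.DELETERIOUS)
        if choice == 2:
            return PredictorCalls(mutation_taster=MutationTaster.DISEASE_CAUSING)
        return PredictorCalls(polyphen=Polyphen.PROBABLY_DAMAGING)

    def benign_calls() -> PredictorCalls:
        return PredictorCalls(
            cadd_phred=round(float(rng.uniform(0.0, cadd_threshold - 1.0)), 2),
            sift=Sift.TOLERATED,
            mutation_taster=MutationTaster.POLYMORPHISM,
            polyphen=Polyphen.BENIGN,
        )

    for entry in entries:
        cid = entry.combination_id
        plan = planted_knowledge[cid]
        genes = list(entry.gene_symbols)
        variants = list(entry.variants)

        # statistical: panel presence and clinical relevance
        stat_k = plan["stat_k"]
        if stat_k != "insufficient":
            store.population_presence[cid] = stat_k == "present"
        if stat_k in ("assigned", "present"):
            for v in variants:
                store.clinical_relevance[v.key] = True
        elif stat_k == "relevance_missing":
            for j, v in enumerate(variants):
                store.clinical_relevance[v.key] = j != 0

        # gene: PPI edges and pathway rows
        gene_k = plan["gene_k"]
        if gene_k == 2:
            if rng.random() < 0.5:
                # spanning path of qualifying edges (strictly above threshold)
                for a, b in zip(genes, genes[1:]):
                    conf = ppi_threshold + (1.0 - ppi_threshold) * float(
                        rng.uniform(0.05, 1.0)
                    )
                    store.ppi_edges[frozenset((a, b))] = round(min(conf, 1.0), 3)
            else:
                # all genes share one phenotype-relevant pathway
                for g in genes:
                    store.pathway_membership.setdefault(g, set()).add(
                        (f"PWS_{cid}", True)
                    )
        elif gene_k == 1:
            for j, g in enumerate(genes):
                store.pathway_membership.setdefault(g, set()).add(
                    (f"PWR_{cid}_{j}", True)
                )
            if rng.random() < boundary_rate:
                # distractor edge exactly at the threshold: must not qualify
                store.ppi_edges[frozenset(genes[:2])] = float(ppi_threshold)
        elif gene_k == 0:
            for j, g in enumerate(genes):
                store.pathway_membership.setdefault(g, set()).add(
                    (f"PWI_{cid}_{j}", False)
                )
        else:  # unassigned: first gene absent from both tables
            for g in genes[1:]:
                store.pathway_membership.setdefault(g, set()).add((f"PWU_{cid}", False))

        # variant: predictor calls (unassigned leaves all variants call-free)
        var_k = plan["var_k"]
        if var_k == 1:
            for v in variants:
                store.predictor_calls[v.key] = pathogenic_calls()
        elif var_k == 0:
            store.predictor_calls[variants[0].key] = benign_calls()
            for v in variants[1:]:
                store.predictor_calls[v.key] = pathogenic_calls()
    return store
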