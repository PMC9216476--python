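"""Packaged worked-example fixtures.

Three small fixtures exercising characteristic evidence profiles, shipped
as a JSON data file inside the package:

* ``OLI606`` — a trigenic left-ventricular-noncompaction combination
  (MYH7, MRTFB, NKX2-5): pedigree spanning first- and second-degree
  relatives whose healthy members carry only partial combinations, but
  with one variant's solo effect untested (segregation not shown as
  complete); mouse models showing synergy of the triple mutant against
  double and single mutants and wild type.  Expected FINALmeta 3.
* ``OLI474`` — a trigenic congenital-hypothyroidism combination (DUOX2,
  TG, TPO): no usable pedigree, implicit absence in a matched 100-control
  cohort, genes sharing the thyroid-hormone-synthesis process without
  synergy experiments, every variant with at least one pathogenic
  prediction alongside one negative experimental result.  Expected
  STATmeta 1, FUNmeta 2, FINALmeta 1.
* ``OLI302`` — a digenic combination (synthetic stand-in gene symbols):
  weak familial evidence from a single healthy genotyped first-degree
  relative, panel absence with clinically relevant variants, and strong
  functional synergy at both gene and variant level.  Expected
  FAMmanual 1, STATmeta 1, FUNmeta 3.

Variant coordinates and identifiers in these fixtures are synthetic
placeholders; only the evidence structure matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

from .io_report import (
    entry_from_dict,
    entry_to_dict,
    record_from_dict,
    record_to_dict,
    store_from_dict,
    store_to_dict,
)
from .knowledge import AnnotationStore, PredictorCalls
from .knowledge_enums import Polyphen, Sift
from .model import (
    CarrierStatus,
    CombinationEntry,
    ControlEvidence,
    ControlSource,
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

_DATA_FILE = "worked_examples.json"


@dataclass(frozen=True)
class WorkedExample:
    records: Tuple[EvidenceRecord, ...]
    entry: CombinationEntry
    store: AnnotationStore


def _snv(cid: str, idx: int, gene: str, notation: str) -> Variant:
    return Variant(
        local_id=f"{cid}.v{idx}",
        gene_symbol=gene,
        notation=notation,
        variant_class=VariantClass.SNV,
        zygosity=Zygosity.HETEROZYGOUS,
    )


def _build_oli606() -> WorkedExample:
    cid = "OLI606"
    genes = ["MYH7", "MRTFB", "NKX2-5"]
    entry = CombinationEntry(
        combination_id=cid,
        variants=tuple(
            _snv(cid, i + 1, g, n)
            for i, (g, n) in enumerate(
                zip(genes, ["c.2710C>T", "c.101A>G", "c.512G>A"])
            )
        ),
        disease=Disease(name="left ventricular noncompaction"),
        references=(Reference("PUB606", 2016),),
    )
    record = EvidenceRecord(
        combination_id=cid,
        article=entry.references[0],
        curator_id="consensus",
        pedigree=PedigreeEvidence(
            relatives=(
                # asymptomatic father carrying two of the three variants
                Relative(Degree.FIRST, Phenotype.HEALTHY, CarrierStatus.PARTIAL_CARRIER),
                # healthy second-degree relatives with single variants
                Relative(Degree.SECOND, Phenotype.HEALTHY, CarrierStatus.PARTIAL_CARRIER),
                Relative(Degree.SECOND, Phenotype.HEALTHY, CarrierStatus.PARTIAL_CARRIER),
            ),
            # the index variant's solo effect was never observed
            coverage_complete=False,
        ),
        statistical=ControlEvidence(source=ControlSource.NONE),
        gene_functional=GeneFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
            relationship_types=frozenset({GeneRelationship.AFFECTING_SAME_TISSUE}),
            phenotype_relevance_shown=True,
        ),
        variant_functional=VariantFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
        ),
    )
    store = AnnotationStore(
        population_presence={cid: False},
        clinical_relevance={v.key: True for v in entry.variants},
        pathway_membership={g: {("cardiac_muscle_development", True)} for g in genes},
        predictor_calls={
            entry.variants[0].key: PredictorCalls(cadd_phred=24.0),
            entry.variants[1].key: PredictorCalls(cadd_phred=22.3),
            entry.variants[2].key: PredictorCalls(cadd_phred=21.1),
        },
    )
    return WorkedExample(records=(record,), entry=entry, store=store)


def _build_oli474() -> WorkedExample:
    cid = "OLI474"
    genes = ["DUOX2", "TG", "TPO"]
    entry = CombinationEntry(
        combination_id=cid,
        variants=tuple(
            _snv(cid, i + 1, g, n)
            for i, (g, n) in enumerate(
                zip(genes, ["c.2048G>T", "c.274G>A", "c.1117G>T"])
            )
        ),
        disease=Disease(name="congenital hypothyroidism"),
        references=(Reference("PUB474", 2018),),
    )
    record = EvidenceRecord(
        combination_id=cid,
        article=entry.references[0],
        curator_id="consensus",
        # parental genotypes and phenotypes were not clearly described
        pedigree=PedigreeEvidence(),
        statistical=ControlEvidence(
            source=ControlSource.COHORT,
            explicit=False,  # implicit absence in the 100-control cohort
            size_sufficient=True,
            ethnicity_matched=True,
            phenotypes_known=True,
            combination_absent=True,
        ),
        gene_functional=GeneFunctionalEvidence(
            relationship_types=frozenset({GeneRelationship.SAME_PATHWAY}),
            phenotype_relevance_shown=True,
        ),
        variant_functional=VariantFunctionalEvidence(
            all_predicted_pathogenic=True,
            # one variant was shown benign in the article
            negative_result_present=True,
        ),
    )
    store = AnnotationStore(
        population_presence={cid: False},
        clinical_relevance={v.key: True for v in entry.variants},
        pathway_membership={g: {("thyroid_hormone_synthesis", True)} for g in genes},
        predictor_calls={
            entry.variants[0].key: PredictorCalls(cadd_phred=18.4),
            entry.variants[1].key: PredictorCalls(
                cadd_phred=12.0, polyphen=Polyphen.POSSIBLY_DAMAGING
            ),
            entry.variants[2].key: PredictorCalls(cadd_phred=16.2, sift=Sift.DELETERIOUS),
        },
    )
    return WorkedExample(records=(record,), entry=entry, store=store)


def _build_oli302() -> WorkedExample:
    cid = "OLI302"
    genes = ["GENEA", "GENEB"]  # synthetic stand-in symbols
    entry = CombinationEntry(
        combination_id=cid,
        variants=tuple(
            _snv(cid, i + 1, g, n) for i, (g, n) in enumerate(zip(genes, ["c.88C>T", "c.301G>A"]))
        ),
        disease=Disease(name="unspecified digenic disorder"),
        references=(Reference("PUB302", 2004),),
    )
    record = EvidenceRecord(
        combination_id=cid,
        article=entry.references[0],
        curator_id="consensus",
        pedigree=PedigreeEvidence(
            relatives=(
                Relative(Degree.FIRST, Phenotype.HEALTHY, CarrierStatus.NON_CARRIER),
            )
        ),
        statistical=ControlEvidence(source=ControlSource.NONE),
        gene_functional=GeneFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
            relationship_types=frozenset(
                {GeneRelationship.RELEVANT_PATHWAYS_FOR_PHENOTYPE}
            ),
            phenotype_relevance_shown=True,
        ),
        variant_functional=VariantFunctionalEvidence(
            experiment_design=ExperimentDesign.SINGLE_AND_JOINT,
            experiment_outcome=ExperimentOutcome.SYNERGISTIC_OR_ADDITIVE,
        ),
    )
    store = AnnotationStore(
        population_presence={cid: False},
        clinical_relevance={v.key: True for v in entry.variants},
        ppi_edges={frozenset(genes): 0.91},
        pathway_membership={g: {("shared_relevant_process", True)} for g in genes},
        predictor_calls={
            entry.variants[0].key: PredictorCalls(cadd_phred=25.6),
            entry.variants[1].key: PredictorCalls(cadd_phred=19.9),
        },
    )
    return WorkedExample(records=(record,), entry=entry, store=store)


def _build_all() -> Dict[str, WorkedExample]:
    return {
        ex.entry.combination_id: ex
        for ex in (_build_oli606(), _build_oli474(), _build_oli302())
    }


def _to_json_doc(examples: Dict[str, WorkedExample]) -> dict:
    return {
        cid: {
            "records": [record_to_dict(r) for r in ex.records],
            "entry": entry_to_dict(ex.entry),
            "store": store_to_dict(ex.store),
        }
        for cid, ex in sorted(examples.items())
    }


def packaged_worked_examples() -> Dict[str, WorkedExample]:
    """Load the shipped fixtures keyed by combination id."""
    text = resources.files(__package__).joinpath("data", _DATA_FILE).read_text(
        encoding="utf-8"
    )
    doc = json.loads(text)
    return {
        cid: WorkedExample(
            records=tuple(record_from_dict(r) for r in d["records"]),
            entry=entry_from_dict(d["entry"]),
            store=store_from_dict(d["store"]),
        )
        for cid, d in doc.items()
    }


def _regenerate_data_file() -> None:  # pragma: no cover - maintenance helper
    from pathlib import Path

    path = Path(__file__).parent / "data" / _DATA_FILE
    path.parent.mkdir(exist_ok=True)
    path.write_text(
        json.dumps(_to_json_doc(_build_all()), indent=1, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


if __name__ == "__main__":  # pragma: no cover
    _regenerate_data_file()
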