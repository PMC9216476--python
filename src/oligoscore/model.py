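"""Domain model for oligogenic variant-combination curation.

An *oligogenic variant combination* is a set of variants in two or more
genes whose joint presence is proposed to cause or modulate a disease
phenotype.  Each combination is curated from one or more source articles
by (at least) two independent curators, who record structured evidence in
four categories: pedigree segregation, control-cohort statistics,
gene-level functional work and variant-level functional work.  The types
here are the vocabulary for that evidence; the scoring rules live in
:mod:`oligoscore.manual` and :mod:`oligoscore.knowledge`.

All containers are frozen dataclasses so records can be hashed, compared
field-wise (dual-curator reconciliation) and used as dict keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class VariantClass(str, Enum):
    SNV = "snv"
    INDEL = "indel"
    CNV = "cnv"


class CnvChange(str, Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    UNKNOWN = "unknown"


class CoordinateFlag(str, Enum):
    MAPPED = "mapped"
    UNMAPPED = "unmapped"
    MANUAL_REVIEW = "manual_review"


class Degree(str, Enum):
    """Degree of kinship of a relative with respect to the index patient."""

    FIRST = "first"
    SECOND = "second"


class Phenotype(str, Enum):
    AFFECTED = "affected"
    HEALTHY = "healthy"
    UNKNOWN = "unknown"


class CarrierStatus(str, Enum):
    """Genotype of a relative with respect to the variant combination.

    ``FULL_CARRIER`` carries every variant of the combination,
    ``PARTIAL_CARRIER`` a proper non-empty subset, ``NON_CARRIER`` none.
    """

    FULL_CARRIER = "full_carrier"
    PARTIAL_CARRIER = "partial_carrier"
    NON_CARRIER = "non_carrier"
    UNKNOWN = "unknown"


class ControlSource(str, Enum):
    NONE = "none"
    PUBLIC_DB = "public_db"
    COHORT = "cohort"


class SharedVariantRole(str, Enum):
    """Cross-combination support for a single shared variant.

    Admissible only as context alongside primary control evidence; these
    flags never raise a statistical score on their own.
    """

    MODIFIER_ROLE = "modifier_role"
    DOMINANT_ROLE = "dominant_role"
    SEVERITY_MODIFIER = "severity_modifier"


class ExperimentDesign(str, Enum):
    """Which genetic units were perturbed in the functional experiments.

    ``SINGLE_UNITS_ONLY``: each gene/variant tested separately;
    ``JOINT_ONLY``: only the combined knockout/mutant tested;
    ``SINGLE_AND_JOINT``: both, enabling a synergy comparison.
    """

    NONE = "none"
    SINGLE_UNITS_ONLY = "single_units_only"
    JOINT_ONLY = "joint_only"
    SINGLE_AND_JOINT = "single_and_joint"


class ExperimentOutcome(str, Enum):
    NONE = "none"
    SYNERGISTIC_OR_ADDITIVE = "synergistic_or_additive"
    EFFECT_SHOWN = "effect_shown"
    PROMISING_INCONCLUSIVE = "promising_inconclusive"
    NEGATIVE = "negative"


class GeneRelationship(str, Enum):
    """Taxonomy of functional relationships between the genes of a combination."""

    INVOLVED_IN_SAME_DISEASE = "involved_in_same_disease"
    RELEVANT_PATHWAYS_FOR_PHENOTYPE = "relevant_pathways_for_phenotype"
    SAME_PATHWAY = "same_pathway"
    AFFECTING_SAME_TISSUE = "affecting_same_tissue"
    DIRECTLY_INTERACTING = "directly_interacting"
    SAME_PROTEIN_COMPLEX = "same_protein_complex"
    INDIRECTLY_INTERACTING = "indirectly_interacting"
    SIMILAR_FUNCTION = "similar_function"
    CO_LOCALIZATION_OR_SAME_ORGANELLE = "co_localization_or_same_organelle"
    CO_EXPRESSION = "co_expression"
    MONOGENIC_EXPERIMENTS_ONLY = "monogenic_experiments_only"


#: Relationships that count as a *direct* gene relationship for scoring.
DIRECT_RELATIONSHIPS = frozenset(
    {
        GeneRelationship.SAME_PATHWAY,
        GeneRelationship.DIRECTLY_INTERACTING,
        GeneRelationship.SAME_PROTEIN_COMPLEX,
    }
)


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coordinates:
    """Genomic location of a small variant (1-based, inclusive start)."""

    genome_build: str
    chromosome: str
    start: int
    ref: str
    alt: str


@dataclass(frozen=True)
class CnvDetail:
    """Extent of a copy-number variant; 1-based inclusive coordinates."""

    start: int
    end: int
    change: CnvChange


@dataclass(frozen=True)
class Variant:
    local_id: str
    gene_symbol: str
    notation: str
    variant_class: VariantClass = VariantClass.SNV
    zygosity: Zygosity = Zygosity.UNKNOWN
    coordinates: Optional[Coordinates] = None
    cnv_detail: Optional[CnvDetail] = None
    coordinate_flag: CoordinateFlag = CoordinateFlag.UNMAPPED

    @property
    def key(self) -> str:
        """Stable key used to join against annotation tables.

        Coordinate-based when the variant is mapped, otherwise the gene
        symbol plus the curated notation.
        """
        if self.coordinates is not None:
            c = self.coordinates
            return f"{c.genome_build}:{c.chromosome}:{c.start}:{c.ref}:{c.alt}"
        return f"{self.gene_symbol}:{self.notation}"


@dataclass(frozen=True)
class GeneRef:
    symbol: str
    raw_symbol: str


@dataclass(frozen=True)
class Disease:
    name: str
    ontology_id: Optional[str] = None

    @property
    def key(self) -> str:
        return self.ontology_id if self.ontology_id else self.name


@dataclass(frozen=True)
class Reference:
    article_id: str
    year: int


@dataclass(frozen=True)
class Relative:
    degree: Degree
    phenotype: Phenotype
    genotype: CarrierStatus

    @property
    def informative(self) -> bool:
        """A relative contributes to segregation only with both phenotype
        and genotype known."""
        return (
            self.phenotype is not Phenotype.UNKNOWN
            and self.genotype is not CarrierStatus.UNKNOWN
        )

    @property
    def consistent(self) -> bool:
        """Whether this relative's phenotype fits the oligogenic model.

        Full carriers must be affected; non-carriers must be healthy.  A
        *healthy* partial carrier supports oligogenicity (the incomplete
        combination does not cause disease) and is therefore consistent,
        whereas an affected partial carrier contradicts it.  Uninformative
        relatives are vacuously consistent.
        """
        if not self.informative:
            return True
        if self.genotype is CarrierStatus.FULL_CARRIER:
            return self.phenotype is Phenotype.AFFECTED
        return self.phenotype is Phenotype.HEALTHY


@dataclass(frozen=True)
class PedigreeEvidence:
    """Pedigree described in the source article.

    ``coverage_complete`` records whether the pedigree demonstrates the
    individual (in)sufficiency of every variant in the combination.  A
    family where nobody carries one of the variants in isolation leaves
    that variant's solo effect unshown, so segregation cannot be called
    perfect even when every genotyped relative is consistent.
    """

    relatives: Tuple[Relative, ...] = ()
    coverage_complete: bool = True

    @property
    def informative_relatives(self) -> Tuple[Relative, ...]:
        return tuple(r for r in self.relatives if r.informative)

    @property
    def segregation_perfect(self) -> bool:
        """Perfect segregation: every informative relative consistent with
        the oligogenic model and no variant's contribution left untested."""
        return self.coverage_complete and all(
            r.consistent for r in self.informative_relatives
        )


@dataclass(frozen=True)
class ControlEvidence:
    source: ControlSource = ControlSource.NONE
    explicit: bool = False
    size_sufficient: bool = False
    ethnicity_matched: bool = False
    phenotypes_known: bool = False
    sequencing_similar: bool = False
    combination_absent: bool = False
    shared_variant_support: frozenset = frozenset()


@dataclass(frozen=True)
class GeneFunctionalEvidence:
    experiment_design: ExperimentDesign = ExperimentDesign.NONE
    experiment_outcome: ExperimentOutcome = ExperimentOutcome.NONE
    relationship_types: frozenset = frozenset()
    phenotype_relevance_shown: bool = False


@dataclass(frozen=True)
class VariantFunctionalEvidence:
    experiment_design: ExperimentDesign = ExperimentDesign.NONE
    experiment_outcome: ExperimentOutcome = ExperimentOutcome.NONE
    all_predicted_pathogenic: bool = False
    mixed_experiment_and_prediction: bool = False
    insilico_joint_effect_clear: bool = False
    negative_result_present: bool = False


@dataclass(frozen=True)
class EvidenceRecord:
    """One curator's structured evidence for one combination from one article."""

    combination_id: str
    article: Reference
    curator_id: str
    pedigree: PedigreeEvidence = PedigreeEvidence()
    statistical: ControlEvidence = ControlEvidence()
    gene_functional: GeneFunctionalEvidence = GeneFunctionalEvidence()
    variant_functional: VariantFunctionalEvidence = VariantFunctionalEvidence()


def gene_combination_key(symbols: Iterable[str]) -> Tuple[str, ...]:
    """Canonical, order-independent identifier of a gene combination:
    case-normalized, deduplicated, lexicographically sorted."""
    return tuple(sorted({s.upper() for s in symbols}))


@dataclass(frozen=True)
class CombinationEntry:
    """Database-facing entity tying a combination to its variants, genes,
    disease and source references."""

    combination_id: str
    variants: Tuple[Variant, ...]
    disease: Disease
    references: Tuple[Reference, ...]
    genes: Tuple[GeneRef, ...] = ()

    def __post_init__(self):
        if not self.genes:
            object.__setattr__(
                self,
                "genes",
                tuple(
                    GeneRef(symbol=s, raw_symbol=s)
                    for s in sorted({v.gene_symbol for v in self.variants})
                ),
            )

    @property
    def gene_symbols(self) -> Tuple[str, ...]:
        return gene_combination_key(v.gene_symbol for v in self.variants)

    @property
    def gene_combination_id(self) -> str:
        return "+".join(self.gene_symbols)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    field: str
    message: str


def validate_entry(entry: CombinationEntry) -> list[ValidationIssue]:
    """Check every structural invariant of a combination entry.

    Issues are returned, never raised; an empty list means the entry is
    safe to score.
    """
    issues: list[ValidationIssue] = []
    if len(entry.gene_symbols) < 2:
        issues.append(
            ValidationIssue("variants", "fewer than 2 distinct genes in combination")
        )
    for v in entry.variants:
        where = f"variants[{v.local_id}]"
        if v.variant_class is VariantClass.CNV and v.cnv_detail is None:
            issues.append(
                ValidationIssue(f"{where}.cnv_detail", "cnv variant lacks cnv_detail")
            )
        if v.variant_class is not VariantClass.CNV and v.cnv_detail is not None:
            issues.append(
                ValidationIssue(
                    f"{where}.cnv_detail", "cnv_detail present on non-cnv variant"
                )
            )
        if v.cnv_detail is not None and v.cnv_detail.end <= v.cnv_detail.start:
            issues.append(
                ValidationIssue(f"{where}.cnv_detail", "cnv end must exceed start")
            )
        if v.coordinates is None and v.coordinate_flag is CoordinateFlag.MAPPED:
            issues.append(
                ValidationIssue(
                    f"{where}.coordinate_flag", "flagged mapped without coordinates"
                )
            )
        if v.coordinates is not None and v.coordinate_flag is CoordinateFlag.UNMAPPED:
            issues.append(
                ValidationIssue(
                    f"{where}.coordinate_flag", "flagged unmapped despite coordinates"
                )
            )
        if v.coordinates is not None and v.coordinates.start < 1:
            issues.append(
                ValidationIssue(f"{where}.coordinates.start", "position must be >= 1")
            )
    seen = set()
    for r in entry.references:
        if r.article_id in seen:
            issues.append(
                ValidationIssue("references", f"duplicate article_id {r.article_id!r}")
            )
        seen.add(r.article_id)
    return issues


def validate_record(record: EvidenceRecord) -> list[ValidationIssue]:
    """Evidence-payload invariants (design/outcome coupling, source/flag coupling)."""
    issues: list[ValidationIssue] = []
    for name, ev in (
        ("gene_functional", record.gene_functional),
        ("variant_functional", record.variant_functional),
    ):
        if (
            ev.experiment_design is ExperimentDesign.NONE
            and ev.experiment_outcome is not ExperimentOutcome.NONE
        ):
            issues.append(
                ValidationIssue(
                    f"{name}.experiment_outcome",
                    "outcome recorded without an experiment design",
                )
            )
    c = record.statistical
    if c.source is ControlSource.NONE and (
        c.explicit
        or c.size_sufficient
        or c.ethnicity_matched
        or c.phenotypes_known
        or c.sequencing_similar
        or c.combination_absent
        or c.shared_variant_support
    ):
        issues.append(
            ValidationIssue("statistical", "control attributes set with source none")
        )
    return issues


# ---------------------------------------------------------------------------
# Name normalization and coordinate flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationReport:
    """Which raw symbols/diseases passed through unmapped."""

    unmapped_genes: Tuple[str, ...] = ()
    unmapped_diseases: Tuple[str, ...] = ()


def normalize_symbols(
    entry: CombinationEntry,
    gene_map: Mapping[str, str],
    disease_map: Mapping[str, Tuple[str, Optional[str]]],
) -> Tuple[CombinationEntry, NormalizationReport]:
    """Rewrite gene symbols and disease names through curated maps.

    Symbols absent from the map pass through unchanged and are listed in
    the report.  Idempotent: values already in normalized form map to
    themselves on a second pass (they are simply absent from the map).
    """
    unmapped_genes: list[str] = []
    new_variants = []
    for v in entry.variants:
        if v.gene_symbol in gene_map:
            new_variants.append(replace(v, gene_symbol=gene_map[v.gene_symbol]))
        else:
            unmapped_genes.append(v.gene_symbol)
            new_variants.append(v)
    genes = tuple(
        GeneRef(symbol=gene_map.get(g.raw_symbol, g.symbol), raw_symbol=g.raw_symbol)
        for g in entry.genes
    )
    unmapped_diseases: list[str] = []
    disease = entry.disease
    if disease.name in disease_map:
        name, oid = disease_map[disease.name]
        disease = Disease(name=name, ontology_id=oid)
    elif disease.ontology_id is None:
        unmapped_diseases.append(disease.name)
    new_entry = replace(
        entry, variants=tuple(new_variants), genes=genes, disease=disease
    )
    report = NormalizationReport(
        unmapped_genes=tuple(dict.fromkeys(unmapped_genes)),
        unmapped_diseases=tuple(unmapped_diseases),
    )
    return new_entry, report


def flag_coordinates(variant: Variant) -> Variant:
    """Set the coordinate flag from coordinate presence; a curator override
    to ``MANUAL_REVIEW`` is preserved."""
    if variant.coordinate_flag is CoordinateFlag.MANUAL_REVIEW:
        return variant
    flag = (
        CoordinateFlag.MAPPED
        if variant.coordinates is not None
        else CoordinateFlag.UNMAPPED
    )
    return replace(variant, coordinate_flag=flag)


# ---------------------------------------------------------------------------
# Dual-curator reconciliation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConflictReport:
    combination_id: str
    article_id: str
    fields: Tuple[str, ...]


_EVIDENCE_FIELDS = ("pedigree", "statistical", "gene_functional", "variant_functional")


def reconcile_curations(a: EvidenceRecord, b: EvidenceRecord):
    """Compare two curators' records for the same combination and article.

    Returns the first record as consensus when every evidence payload is
    field-wise equal; otherwise a :class:`ConflictReport` naming every
    differing leaf field.  No automatic resolution is attempted — the
    protocol resolves conflicts by curator discussion.
    """
    if a.combination_id != b.combination_id or a.article != b.article:
        raise ValueError("non-comparable records: combination_id/article differ")
    diffs: list[str] = []
    for top in _EVIDENCE_FIELDS:
        pa, pb = getattr(a, top), getattr(b, top)
        if pa == pb:
            continue
        for f in dataclasses.fields(pa):
            if getattr(pa, f.name) != getattr(pb, f.name):
                diffs.append(f"{top}.{f.name}")
    if not diffs:
        return a
    return ConflictReport(
        combination_id=a.combination_id,
        article_id=a.article.article_id,
        fields=tuple(diffs),
    )
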