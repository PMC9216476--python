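"""Knowledge confidence scores computed from local annotation tables.

These scores compensate for information missing from the source article by
consulting external resources, emulated here as local lookup tables:
presence of the joint genotype in a reference population panel, per-variant
clinical assertions, protein-protein interaction confidences, pathway
memberships with curated phenotype-relevance flags, and per-variant calls
from four pathogenicity predictors (CADD, SIFT, MutationTaster, PolyPhen-2).

A knowledge score is *assigned only when information is found for every
unit of the combination*; otherwise it is ``None`` ("unassigned"), which
is distinct from 0: unassigned knowledge falls back to the manual score
during metascore computation, whereas a 0 from population-panel presence
overrides it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Set, Tuple

import networkx as nx

from .config import ScoringConfig
from .knowledge_enums import MutationTaster, Polyphen, Sift, StatReason
from .model import Variant


@dataclass(frozen=True)
class PredictorCalls:
    """Per-variant record of predictor output; ``None``/``ABSENT`` mark
    tools that returned nothing for the variant."""

    cadd_phred: Optional[float] = None
    sift: Sift = Sift.ABSENT
    mutation_taster: MutationTaster = MutationTaster.ABSENT
    polyphen: Polyphen = Polyphen.ABSENT

    @property
    def has_any_call(self) -> bool:
        return (
            self.cadd_phred is not None
            or self.sift is not Sift.ABSENT
            or self.mutation_taster is not MutationTaster.ABSENT
            or self.polyphen is not Polyphen.ABSENT
        )


@dataclass
class AnnotationStore:
    """Local lookup tables standing in for the external resources.

    * ``population_presence``: combination id -> joint genotype seen in the
      reference population panel (keyed by combination, not variant).
    * ``clinical_relevance``: variant key -> disease-relevant assertions
      exist for the variant.
    * ``ppi_edges``: unordered gene pair -> interaction confidence in [0,1].
    * ``pathway_membership``: gene -> set of (pathway id, phenotype-relevant).
    * ``predictor_calls``: variant key -> :class:`PredictorCalls`.

    Absent keys are meaningful: they mean *no information*, not a negative
    answer.
    """

    population_presence: Dict[str, bool] = field(default_factory=dict)
    clinical_relevance: Dict[str, bool] = field(default_factory=dict)
    ppi_edges: Dict[FrozenSet[str], float] = field(default_factory=dict)
    pathway_membership: Dict[str, Set[Tuple[str, bool]]] = field(default_factory=dict)
    predictor_calls: Dict[str, PredictorCalls] = field(default_factory=dict)

    def __post_init__(self):
        for pair, conf in self.ppi_edges.items():
            if not (0.0 <= conf <= 1.0):
                raise ValueError(f"ppi confidence out of [0,1] for {sorted(pair)}: {conf}")

    def gene_known(self, gene: str) -> bool:
        """A gene counts as annotated if any PPI edge or pathway row names it."""
        if gene in self.pathway_membership and self.pathway_membership[gene]:
            return True
        return any(gene in pair for pair in self.ppi_edges)

    # -- TSV persistence --------------------------------------------------

    _FILES = (
        "population_presence.tsv",
        "clinical_relevance.tsv",
        "ppi_edges.tsv",
        "pathways.tsv",
        "predictions.tsv",
    )

    def to_tsv_dir(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "population_presence.tsv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["combination_id", "present"])
            for k in sorted(self.population_presence):
                w.writerow([k, str(self.population_presence[k]).lower()])
        with open(d / "clinical_relevance.tsv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["variant_key", "relevant"])
            for k in sorted(self.clinical_relevance):
                w.writerow([k, str(self.clinical_relevance[k]).lower()])
        with open(d / "ppi_edges.tsv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_a", "gene_b", "confidence"])
            for pair in sorted(self.ppi_edges, key=sorted):
                a, b = sorted(pair)
                w.writerow([a, b, repr(self.ppi_edges[pair])])
        with open(d / "pathways.tsv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene", "pathway_id", "phenotype_relevant"])
            for g in sorted(self.pathway_membership):
                for pid, rel in sorted(self.pathway_membership[g]):
                    w.writerow([g, pid, str(rel).lower()])
        with open(d / "predictions.tsv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["variant_key", "cadd_phred", "sift", "mutation_taster", "polyphen"])
            for k in sorted(self.predictor_calls):
                c = self.predictor_calls[k]
                w.writerow(
                    [
                        k,
                        "" if c.cadd_phred is None else repr(c.cadd_phred),
                        c.sift.value,
                        c.mutation_taster.value,
                        c.polyphen.value,
                    ]
                )

    @classmethod
    def from_tsv_dir(cls, directory) -> "AnnotationStore":
        d = Path(directory)

        def rows(name):
            path = d / name
            if not path.exists():
                return []
            with open(path, encoding="utf-8", newline="") as fh:
                r = csv.reader(fh, delimiter="\t")
                header = next(r, None)
                return list(r)

        store = cls()
        for cid, present in rows("population_presence.tsv"):
            store.population_presence[cid] = present == "true"
        for key, rel in rows("clinical_relevance.tsv"):
            store.clinical_relevance[key] = rel == "true"
        for a, b, conf in rows("ppi_edges.tsv"):
            store.ppi_edges[frozenset((a, b))] = float(conf)
        for g, pid, rel in rows("pathways.tsv"):
            store.pathway_membership.setdefault(g, set()).add((pid, rel == "true"))
        for key, cadd, sift, mt, pp in rows("predictions.tsv"):
            store.predictor_calls[key] = PredictorCalls(
                cadd_phred=float(cadd) if cadd else None,
                sift=Sift(sift),
                mutation_taster=MutationTaster(mt),
                polyphen=Polyphen(pp),
            )
        return store


@dataclass(frozen=True)
class KnowledgeScores:
    """Knowledge score vector; ``gene``/``var`` are ``None`` when unassigned."""

    stat_value: int = 0
    stat_reason: StatReason = StatReason.INSUFFICIENT_INFORMATION
    gene: Optional[int] = None
    var: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.stat_value <= 1:
            raise ValueError("STATknowledge must be 0 or 1")
        if self.gene is not None and not 0 <= self.gene <= 2:
            raise ValueError("GENEknowledge must be in 0-2")
        if self.var is not None and not 0 <= self.var <= 1:
            raise ValueError("VARknowledge must be 0 or 1")


def score_stat_knowledge(
    combination_id: str, variants: Sequence[Variant], store: AnnotationStore
) -> Tuple[int, StatReason]:
    """STATknowledge: panel absence plus clinical relevance of every variant.

    Presence of the joint genotype in the population panel yields
    ``(0, PRESENT_IN_POPULATION_PANEL)`` — the reason that later overrides
    the statistical metascore.  When the combination is absent, a weak
    score (1) requires disease-relevant assertions for *all* variants;
    missing lookups yield ``(0, INSUFFICIENT_INFORMATION)``.
    """
    if combination_id not in store.population_presence:
        return 0, StatReason.INSUFFICIENT_INFORMATION
    if store.population_presence[combination_id]:
        return 0, StatReason.PRESENT_IN_POPULATION_PANEL
    relevance = []
    for v in variants:
        if v.key not in store.clinical_relevance:
            return 0, StatReason.INSUFFICIENT_INFORMATION
        relevance.append(store.clinical_relevance[v.key])
    if all(relevance):
        return 1, StatReason.ASSIGNED
    return 0, StatReason.CLINICAL_RELEVANCE_MISSING


def score_gene_knowledge(
    genes: Sequence[str], store: AnnotationStore, config: ScoringConfig
) -> Optional[int]:
    """GENEknowledge: PPI connectivity and pathway relevance (0-2 or None).

    2 if the genes form a connected network using only interaction edges
    with confidence strictly above the threshold, or if all genes share a
    common pathway flagged relevant for the phenotype; 1 if every gene has
    at least one phenotype-relevant pathway; 0 otherwise.  Unassigned
    (None) when any gene has no entry in either table.
    """
    genes = list(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("gene knowledge scoring needs at least 2 genes")
    if not all(store.gene_known(g) for g in genes):
        return None

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    gene_set = set(genes)
    for pair, conf in store.ppi_edges.items():
        if pair <= gene_set and conf > config.ppi_threshold:
            a, b = sorted(pair)
            graph.add_edge(a, b)
    if nx.is_connected(graph):
        return 2

    relevant_per_gene = [
        {pid for pid, rel in store.pathway_membership.get(g, set()) if rel}
        for g in genes
    ]
    if set.intersection(*relevant_per_gene):
        return 2
    if all(relevant_per_gene):
        return 1
    return 0


def is_pathogenic_call(tool: str, value, config: ScoringConfig) -> bool:
    """Single-tool pathogenicity decision.

    CADD: Phred >= threshold (inclusive); SIFT: deleterious;
    MutationTaster: disease-causing; PolyPhen-2: any accepted damaging
    category.  An absent call is never pathogenic.
    """
    if tool == "cadd":
        return value is not None and float(value) >= config.cadd_phred_threshold
    if tool == "sift":
        return Sift(value) is Sift.DELETERIOUS
    if tool == "mutation_taster":
        return MutationTaster(value) is MutationTaster.DISEASE_CAUSING
    if tool == "polyphen":
        return Polyphen(value) in config.polyphen_accept
    raise ValueError(f"unknown predictor {tool!r}")


def _variant_pathogenic(calls: PredictorCalls, config: ScoringConfig) -> bool:
    return (
        is_pathogenic_call("cadd", calls.cadd_phred, config)
        or is_pathogenic_call("sift", calls.sift, config)
        or is_pathogenic_call("mutation_taster", calls.mutation_taster, config)
        or is_pathogenic_call("polyphen", calls.polyphen, config)
    )


def score_variant_knowledge(
    variants: Sequence[Variant], store: AnnotationStore, config: ScoringConfig
) -> Optional[int]:
    """VARknowledge: predictor consensus over the variants (0, 1 or None).

    1 when every variant has at least one pathogenic call from any of the
    four predictors; 0 when every variant was predicted by some tool but
    at least one has no pathogenic call; unassigned (None) when any
    variant lacks predictions from all tools.
    """
    calls = []
    for v in variants:
        c = store.predictor_calls.get(v.key)
        if c is None or not c.has_any_call:
            return None
        calls.append(c)
    if all(_variant_pathogenic(c, config) for c in calls):
        return 1
    return 0


def score_knowledge(
    combination_id: str,
    variants: Sequence[Variant],
    store: AnnotationStore,
    config: Optional[ScoringConfig] = None,
) -> KnowledgeScores:
    """Compute the full knowledge score vector for one combination."""
    config = config or ScoringConfig()
    stat_value, stat_reason = score_stat_knowledge(combination_id, variants, store)
    genes = list(dict.fromkeys(v.gene_symbol for v in variants))
    return KnowledgeScores(
        stat_value=stat_value,
        stat_reason=stat_reason,
        gene=score_gene_knowledge(genes, store, config),
        var=score_variant_knowledge(variants, store, config),
    )
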