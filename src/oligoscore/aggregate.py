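"""Score harmonization, decision-tree aggregation and metascores.

Harmonization corrects literature bias: a gene combination receives the
best gene-level manual score it obtained in *any* curated article, and a
combination described in several articles receives the per-evidence
maximum over those articles.  Metascores then combine manual and
knowledge scores by taking the per-evidence maximum, with one exception:
presence of the joint genotype in the reference population panel forces
the statistical metascore to 0 regardless of the article's evidence.
The FUN and FINAL decision trees (lookup tables in
:class:`~oligoscore.config.ScoringConfig`) aggregate the per-evidence
levels into the functional and overall confidence levels.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from .config import ScoringConfig
from .knowledge import AnnotationStore, KnowledgeScores, score_knowledge
from .knowledge_enums import StatReason
from .manual import ManualScores, score_manual
from .model import CombinationEntry, EvidenceRecord


@dataclass(frozen=True)
class ScoreSet:
    """Complete score vector for one oligogenic combination."""

    manual: ManualScores
    knowledge: KnowledgeScores
    gene_manual_harmonized: int
    fun_manual: int
    final_manual: int
    stat_meta: int
    gene_meta: int
    var_meta: int
    fun_meta: int
    final_meta: int


def fun_tree(gene_level: int, var_level: int, config: Optional[ScoringConfig] = None) -> int:
    """Joint functional level from gene- and variant-combination levels."""
    config = config or ScoringConfig()
    try:
        return config.fun_table[(gene_level, var_level)]
    except KeyError:
        raise ValueError(f"fun_tree inputs out of range: ({gene_level}, {var_level})")


def final_tree(
    fam: int, stat: int, fun: int, config: Optional[ScoringConfig] = None
) -> int:
    """Overall confidence from familial, statistical and functional levels."""
    config = config or ScoringConfig()
    try:
        return config.final_table[(fam, stat, fun)]
    except KeyError:
        raise ValueError(f"final_tree inputs out of range: ({fam}, {stat}, {fun})")


def merge_cross_article(scores: Sequence[ManualScores]) -> ManualScores:
    """Per-evidence maximum of manual scores across the articles describing
    one combination (max-semilattice merge)."""
    scores = list(scores)
    if not scores:
        raise ValueError("merge_cross_article requires at least one score vector")
    return ManualScores(
        fam=max(s.fam for s in scores),
        stat=max(s.stat for s in scores),
        gene=max(s.gene for s in scores),
        var=max(s.var for s in scores),
    )


def harmonize_gene_scores(
    manual_by_combination: Mapping[str, ManualScores],
    gene_key_by_combination: Mapping[str, Tuple[str, ...]],
) -> Dict[Tuple[str, ...], int]:
    """Best gene-level manual score observed for each canonical gene
    combination across the whole corpus."""
    best: Dict[Tuple[str, ...], int] = defaultdict(int)
    for cid, scores in manual_by_combination.items():
        key = gene_key_by_combination[cid]
        best[key] = max(best[key], scores.gene)
    return dict(best)


def compute_metascores(
    manual: ManualScores,
    harmonized_gene: int,
    knowledge: KnowledgeScores,
    config: Optional[ScoringConfig] = None,
) -> ScoreSet:
    """Combine manual and knowledge scores into the full score vector.

    Per-evidence metascores are maxima of the manual and knowledge sides;
    unassigned knowledge contributes nothing (fallback to manual).  The
    single override: a statistical knowledge score of 0 *because the
    combination is present in the population panel* replaces the manual
    statistical score, forcing the statistical metascore to 0.
    """
    config = config or ScoringConfig()
    if not harmonized_gene >= manual.gene:
        raise ValueError("harmonized gene score cannot be below the manual score")

    if knowledge.stat_reason is StatReason.PRESENT_IN_POPULATION_PANEL:
        stat_meta = 0
    else:
        stat_k = knowledge.stat_value if knowledge.stat_reason is StatReason.ASSIGNED else 0
        stat_meta = max(manual.stat, stat_k)
    gene_meta = max(harmonized_gene, knowledge.gene if knowledge.gene is not None else 0)
    var_meta = max(manual.var, knowledge.var if knowledge.var is not None else 0)

    fun_manual = fun_tree(harmonized_gene, manual.var, config)
    final_manual = final_tree(manual.fam, manual.stat, fun_manual, config)
    fun_meta = fun_tree(gene_meta, var_meta, config)
    final_meta = final_tree(manual.fam, stat_meta, fun_meta, config)
    return ScoreSet(
        manual=manual,
        knowledge=knowledge,
        gene_manual_harmonized=harmonized_gene,
        fun_manual=fun_manual,
        final_manual=final_manual,
        stat_meta=stat_meta,
        gene_meta=gene_meta,
        var_meta=var_meta,
        fun_meta=fun_meta,
        final_meta=final_meta,
    )


def score_pipeline(
    records: Iterable[EvidenceRecord],
    entries: Iterable[CombinationEntry],
    store: AnnotationStore,
    config: Optional[ScoringConfig] = None,
) -> Dict[str, ScoreSet]:
    """Full deterministic scoring pipeline for a corpus.

    Steps: per-record manual scoring, per-combination cross-article merge,
    corpus-wide gene-combination harmonization, knowledge scoring against
    the annotation store, metascore computation.
    """
    config = config or ScoringConfig()
    entries = list(entries)
    entry_by_cid = {e.combination_id: e for e in entries}

    per_combination: Dict[str, list] = defaultdict(list)
    for r in records:
        if r.combination_id not in entry_by_cid:
            raise KeyError(f"record references unknown combination {r.combination_id!r}")
        per_combination[r.combination_id].append(score_manual(r))

    merged = {cid: merge_cross_article(scores) for cid, scores in per_combination.items()}
    gene_keys = {
        cid: entry_by_cid[cid].gene_symbols for cid in merged
    }
    harmonized = harmonize_gene_scores(merged, gene_keys)

    out: Dict[str, ScoreSet] = {}
    for cid, manual in merged.items():
        entry = entry_by_cid[cid]
        knowledge = score_knowledge(cid, entry.variants, store, config)
        out[cid] = compute_metascores(
            manual, harmonized[gene_keys[cid]], knowledge, config
        )
    return out
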