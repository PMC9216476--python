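"""Entity tables, corpus serialization and corpus-level summary reports.

The curated corpus is exposed as six cross-referenced entity tables —
combinations, variants, genes, gene combinations, diseases and references
— serialized as TSV or JSON with a canonical (bit-stable) layout: fixed
column order, rows sorted by primary key, UTF-8, no quoting (tabs,
newlines and backslashes inside fields are backslash-escaped).  Evidence
records are nested and travel as a JSON side file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .aggregate import ScoreSet
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
    GeneRef,
    GeneRelationship,
    PedigreeEvidence,
    Phenotype,
    Reference,
    Relative,
    SharedVariantRole,
    Variant,
    VariantClass,
    VariantFunctionalEvidence,
    Zygosity,
)

# ---------------------------------------------------------------------------
# Canonical TSV dialect
# ---------------------------------------------------------------------------

def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(value: str) -> str:
    out, i = [], 0
    while i < len(value):
        ch = value[i]
        if ch == "\\" and i + 1 < len(value):
            nxt = value[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


TABLE_NAMES = (
    "combinations",
    "variants",
    "genes",
    "gene_combinations",
    "diseases",
    "references",
)

_COLUMNS: Dict[str, List[str]] = {
    "combinations": ["combination_id", "gene_combination_id", "disease_id", "article_ids"],
    "variants": [
        "combination_id", "local_id", "variant_key", "gene_symbol", "notation",
        "variant_class", "zygosity", "coordinate_flag", "genome_build",
        "chromosome", "position", "ref", "alt", "cnv_start", "cnv_end", "cnv_change",
    ],
    "genes": ["symbol", "raw_symbol"],
    "gene_combinations": ["gene_combination_id", "n_genes", "symbols"],
    "diseases": ["disease_id", "name", "ontology_id"],
    "references": ["article_id", "year"],
}

_PRIMARY_KEYS: Dict[str, List[str]] = {
    "combinations": ["combination_id"],
    "variants": ["combination_id", "local_id"],
    "genes": ["symbol"],
    "gene_combinations": ["gene_combination_id"],
    "diseases": ["disease_id"],
    "references": ["article_id"],
}


@dataclass
class EntityTables:
    """The six entity tables as pandas DataFrames (all-string cells)."""

    combinations: pd.DataFrame
    variants: pd.DataFrame
    genes: pd.DataFrame
    gene_combinations: pd.DataFrame
    diseases: pd.DataFrame
    references: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @classmethod
    def from_entries(cls, entries: Sequence[CombinationEntry]) -> "EntityTables":
        comb_rows, var_rows, gene_rows, gc_rows, dis_rows, ref_rows = [], [], {}, {}, {}, {}
        for e in entries:
            comb_rows.append(
                {
                    "combination_id": e.combination_id,
                    "gene_combination_id": e.gene_combination_id,
                    "disease_id": e.disease.key,
                    "article_ids": ";".join(sorted(r.article_id for r in e.references)),
                }
            )
            for v in e.variants:
                c = v.coordinates
                d = v.cnv_detail
                var_rows.append(
                    {
                        "combination_id": e.combination_id,
                        "local_id": v.local_id,
                        "variant_key": v.key,
                        "gene_symbol": v.gene_symbol,
                        "notation": v.notation,
                        "variant_class": v.variant_class.value,
                        "zygosity": v.zygosity.value,
                        "coordinate_flag": v.coordinate_flag.value,
                        "genome_build": c.genome_build if c else "",
                        "chromosome": c.chromosome if c else "",
                        "position": str(c.start) if c else "",
                        "ref": c.ref if c else "",
                        "alt": c.alt if c else "",
                        "cnv_start": str(d.start) if d else "",
                        "cnv_end": str(d.end) if d else "",
                        "cnv_change": d.change.value if d else "",
                    }
                )
            for g in e.genes:
                gene_rows[g.symbol] = {"symbol": g.symbol, "raw_symbol": g.raw_symbol}
            gc_rows[e.gene_combination_id] = {
                "gene_combination_id": e.gene_combination_id,
                "n_genes": str(len(e.gene_symbols)),
                "symbols": ";".join(e.gene_symbols),
            }
            dis_rows[e.disease.key] = {
                "disease_id": e.disease.key,
                "name": e.disease.name,
                "ontology_id": e.disease.ontology_id or "",
            }
            for r in e.references:
                ref_rows[r.article_id] = {
                    "article_id": r.article_id,
                    "year": str(r.year),
                }

        def frame(name, rows):
            df = pd.DataFrame(list(rows), columns=_COLUMNS[name], dtype=str)
            return df.fillna("")

        return cls(
            combinations=frame("combinations", comb_rows),
            variants=frame("variants", var_rows),
            genes=frame("genes", gene_rows.values()),
            gene_combinations=frame("gene_combinations", gc_rows.values()),
            diseases=frame("diseases", dis_rows.values()),
            references=frame("references", ref_rows.values()),
        )

    # -- integrity --------------------------------------------------------

    def check_integrity(self) -> List[str]:
        """Return messages for every dangling foreign key."""
        problems: List[str] = []
        known = {
            "combination": set(self.combinations["combination_id"]),
            "gene": set(self.genes["symbol"]),
            "gene_combination": set(self.gene_combinations["gene_combination_id"]),
            "disease": set(self.diseases["disease_id"]),
            "reference": set(self.references["article_id"]),
        }
        for _, row in self.combinations.iterrows():
            if row["gene_combination_id"] not in known["gene_combination"]:
                problems.append(
                    f"combinations[{row['combination_id']}]: dangling gene_combination_id "
                    f"{row['gene_combination_id']!r}"
                )
            if row["disease_id"] not in known["disease"]:
                problems.append(
                    f"combinations[{row['combination_id']}]: dangling disease_id "
                    f"{row['disease_id']!r}"
                )
            for aid in filter(None, row["article_ids"].split(";")):
                if aid not in known["reference"]:
                    problems.append(
                        f"combinations[{row['combination_id']}]: dangling article_id {aid!r}"
                    )
        for _, row in self.variants.iterrows():
            if row["combination_id"] not in known["combination"]:
                problems.append(
                    f"variants[{row['local_id']}]: dangling combination_id "
                    f"{row['combination_id']!r}"
                )
            if row["gene_symbol"] not in known["gene"]:
                problems.append(
                    f"variants[{row['local_id']}]: dangling gene_symbol "
                    f"{row['gene_symbol']!r}"
                )
        for _, row in self.gene_combinations.iterrows():
            for sym in filter(None, row["symbols"].split(";")):
                if sym not in known["gene"]:
                    problems.append(
                        f"gene_combinations[{row['gene_combination_id']}]: "
                        f"dangling gene symbol {sym!r}"
                    )
        return problems

    # -- reconstruction ---------------------------------------------------

    def to_entries(self) -> List[CombinationEntry]:
        diseases = {
            row["disease_id"]: Disease(
                name=row["name"], ontology_id=row["ontology_id"] or None
            )
            for _, row in self.diseases.iterrows()
        }
        refs = {
            row["article_id"]: Reference(row["article_id"], int(row["year"]))
            for _, row in self.references.iterrows()
        }
        raw_symbols = {
            row["symbol"]: row["raw_symbol"] for _, row in self.genes.iterrows()
        }
        variants_by_cid: Dict[str, List[Variant]] = {}
        for _, row in self.variants.iterrows():
            coords = None
            if row["position"]:
                coords = Coordinates(
                    genome_build=row["genome_build"],
                    chromosome=row["chromosome"],
                    start=int(row["position"]),
                    ref=row["ref"],
                    alt=row["alt"],
                )
            cnv = None
            if row["cnv_change"]:
                cnv = CnvDetail(
                    start=int(row["cnv_start"]),
                    end=int(row["cnv_end"]),
                    change=CnvChange(row["cnv_change"]),
                )
            variants_by_cid.setdefault(row["combination_id"], []).append(
                Variant(
                    local_id=row["local_id"],
                    gene_symbol=row["gene_symbol"],
                    notation=row["notation"],
                    variant_class=VariantClass(row["variant_class"]),
                    zygosity=Zygosity(row["zygosity"]),
                    coordinates=coords,
                    cnv_detail=cnv,
                    coordinate_flag=CoordinateFlag(row["coordinate_flag"]),
                )
            )
        entries = []
        for _, row in self.combinations.iterrows():
            cid = row["combination_id"]
            variants = tuple(variants_by_cid.get(cid, ()))
            genes = tuple(
                GeneRef(symbol=s, raw_symbol=raw_symbols.get(s, s))
                for s in sorted({v.gene_symbol for v in variants})
            )
            entries.append(
                CombinationEntry(
                    combination_id=cid,
                    variants=variants,
                    disease=diseases[row["disease_id"]],
                    references=tuple(
                        refs[a] for a in filter(None, row["article_ids"].split(";"))
                    ),
                    genes=genes,
                )
            )
        return entries


def _canonical_frame(name: str, df: pd.DataFrame) -> Tuple[List[str], pd.DataFrame]:
    known = [c for c in _COLUMNS[name] if c in df.columns]
    extra = sorted(c for c in df.columns if c not in _COLUMNS[name])
    cols = known + extra
    out = df[cols].astype(str)
    if len(out):
        out = out.sort_values(_PRIMARY_KEYS[name], kind="mergesort").reset_index(drop=True)
    return cols, out


def write_tables(tables: EntityTables, destination, format: str = "tsv") -> List[Path]:
    """Serialize the six tables canonically; raises on dangling keys."""
    problems = tables.check_integrity()
    if problems:
        raise ValueError("referential integrity violated:\n" + "\n".join(problems))
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    if format == "tsv":
        for name in TABLE_NAMES:
            cols, df = _canonical_frame(name, tables.table(name))
            lines = ["\t".join(cols)]
            for row in df.itertuples(index=False):
                lines.append("\t".join(_escape(v) for v in row))
            path = dest / f"{name}.tsv"
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
            written.append(path)
    elif format == "json":
        doc = {}
        for name in TABLE_NAMES:
            cols, df = _canonical_frame(name, tables.table(name))
            doc[name] = [dict(zip(cols, row)) for row in df.itertuples(index=False)]
        path = dest / "tables.json"
        path.write_text(
            json.dumps(doc, indent=1, sort_keys=False, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
        written.append(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return written


def read_tables(source, format: str = "tsv") -> EntityTables:
    """Inverse of :func:`write_tables`; raises on malformed rows or
    dangling keys."""
    src = Path(source)
    frames = {}
    if format == "tsv":
        for name in TABLE_NAMES:
            path = src / f"{name}.tsv"
            text = path.read_text(encoding="utf-8")
            lines = text.split("\n")
            if lines and lines[-1] == "":
                lines.pop()
            if not lines:
                raise ValueError(f"{path}: missing header row")
            header = lines[0].split("\t")
            rows = []
            for i, line in enumerate(lines[1:], start=2):
                cells = [_unescape(c) for c in line.split("\t")]
                if len(cells) != len(header):
                    raise ValueError(
                        f"{path}: line {i}: expected {len(header)} fields, got {len(cells)}"
                    )
                rows.append(cells)
            frames[name] = pd.DataFrame(rows, columns=header, dtype=str)
    elif format == "json":
        doc = json.loads((src / "tables.json").read_text(encoding="utf-8"))
        for name in TABLE_NAMES:
            rows = doc.get(name, [])
            cols = list(rows[0].keys()) if rows else _COLUMNS[name]
            frames[name] = pd.DataFrame(rows, columns=cols, dtype=str)
    else:
        raise ValueError(f"unknown format {format!r}")
    for name in TABLE_NAMES:
        if frames[name].empty and not len(frames[name].columns):
            frames[name] = pd.DataFrame(columns=_COLUMNS[name], dtype=str)
    tables = EntityTables(**frames)
    problems = tables.check_integrity()
    if problems:
        raise ValueError("referential integrity violated:\n" + "\n".join(problems))
    return tables


# ---------------------------------------------------------------------------
# Evidence record / annotation store JSON codecs
# ---------------------------------------------------------------------------

def record_to_dict(r: EvidenceRecord) -> dict:
    return {
        "combination_id": r.combination_id,
        "article": {"article_id": r.article.article_id, "year": r.article.year},
        "curator_id": r.curator_id,
        "pedigree": {
            "relatives": [
                {
                    "degree": x.degree.value,
                    "phenotype": x.phenotype.value,
                    "genotype": x.genotype.value,
                }
                for x in r.pedigree.relatives
            ],
            "coverage_complete": r.pedigree.coverage_complete,
        },
        "statistical": {
            "source": r.statistical.source.value,
            "explicit": r.statistical.explicit,
            "size_sufficient": r.statistical.size_sufficient,
            "ethnicity_matched": r.statistical.ethnicity_matched,
            "phenotypes_known": r.statistical.phenotypes_known,
            "sequencing_similar": r.statistical.sequencing_similar,
            "combination_absent": r.statistical.combination_absent,
            "shared_variant_support": sorted(
                s.value for s in r.statistical.shared_variant_support
            ),
        },
        "gene_functional": {
            "experiment_design": r.gene_functional.experiment_design.value,
            "experiment_outcome": r.gene_functional.experiment_outcome.value,
            "relationship_types": sorted(
                t.value for t in r.gene_functional.relationship_types
            ),
            "phenotype_relevance_shown": r.gene_functional.phenotype_relevance_shown,
        },
        "variant_functional": {
            "experiment_design": r.variant_functional.experiment_design.value,
            "experiment_outcome": r.variant_functional.experiment_outcome.value,
            "all_predicted_pathogenic": r.variant_functional.all_predicted_pathogenic,
            "mixed_experiment_and_prediction": r.variant_functional.mixed_experiment_and_prediction,
            "insilico_joint_effect_clear": r.variant_functional.insilico_joint_effect_clear,
            "negative_result_present": r.variant_functional.negative_result_present,
        },
    }


def record_from_dict(d: dict) -> EvidenceRecord:
    ped = d.get("pedigree", {})
    stat = d.get("statistical", {})
    gf = d.get("gene_functional", {})
    vf = d.get("variant_functional", {})
    return EvidenceRecord(
        combination_id=d["combination_id"],
        article=Reference(d["article"]["article_id"], int(d["article"]["year"])),
        curator_id=d.get("curator_id", "consensus"),
        pedigree=PedigreeEvidence(
            relatives=tuple(
                Relative(
                    degree=Degree(x["degree"]),
                    phenotype=Phenotype(x["phenotype"]),
                    genotype=CarrierStatus(x["genotype"]),
                )
                for x in ped.get("relatives", [])
            ),
            coverage_complete=bool(ped.get("coverage_complete", True)),
        ),
        statistical=ControlEvidence(
            source=ControlSource(stat.get("source", "none")),
            explicit=bool(stat.get("explicit", False)),
            size_sufficient=bool(stat.get("size_sufficient", False)),
            ethnicity_matched=bool(stat.get("ethnicity_matched", False)),
            phenotypes_known=bool(stat.get("phenotypes_known", False)),
            sequencing_similar=bool(stat.get("sequencing_similar", False)),
            combination_absent=bool(stat.get("combination_absent", False)),
            shared_variant_support=frozenset(
                SharedVariantRole(s) for s in stat.get("shared_variant_support", [])
            ),
        ),
        gene_functional=GeneFunctionalEvidence(
            experiment_design=ExperimentDesign(gf.get("experiment_design", "none")),
            experiment_outcome=ExperimentOutcome(gf.get("experiment_outcome", "none")),
            relationship_types=frozenset(
                GeneRelationship(t) for t in gf.get("relationship_types", [])
            ),
            phenotype_relevance_shown=bool(gf.get("phenotype_relevance_shown", False)),
        ),
        variant_functional=VariantFunctionalEvidence(
            experiment_design=ExperimentDesign(vf.get("experiment_design", "none")),
            experiment_outcome=ExperimentOutcome(vf.get("experiment_outcome", "none")),
            all_predicted_pathogenic=bool(vf.get("all_predicted_pathogenic", False)),
            mixed_experiment_and_prediction=bool(
                vf.get("mixed_experiment_and_prediction", False)
            ),
            insilico_joint_effect_clear=bool(vf.get("insilico_joint_effect_clear", False)),
            negative_result_present=bool(vf.get("negative_result_present", False)),
        ),
    )


def entry_to_dict(e: CombinationEntry) -> dict:
    def variant_dict(v: Variant) -> dict:
        d: dict = {
            "local_id": v.local_id,
            "gene_symbol": v.gene_symbol,
            "notation": v.notation,
            "variant_class": v.variant_class.value,
            "zygosity": v.zygosity.value,
            "coordinate_flag": v.coordinate_flag.value,
        }
        if v.coordinates:
            c = v.coordinates
            d["coordinates"] = {
                "genome_build": c.genome_build,
                "chromosome": c.chromosome,
                "start": c.start,
                "ref": c.ref,
                "alt": c.alt,
            }
        if v.cnv_detail:
            d["cnv_detail"] = {
                "start": v.cnv_detail.start,
                "end": v.cnv_detail.end,
                "change": v.cnv_detail.change.value,
            }
        return d

    return {
        "combination_id": e.combination_id,
        "variants": [variant_dict(v) for v in e.variants],
        "disease": {"name": e.disease.name, "ontology_id": e.disease.ontology_id},
        "references": [
            {"article_id": r.article_id, "year": r.year} for r in e.references
        ],
    }


def entry_from_dict(d: dict) -> CombinationEntry:
    variants = []
    for vd in d["variants"]:
        coords = None
        if "coordinates" in vd:
            c = vd["coordinates"]
            coords = Coordinates(
                c["genome_build"], c["chromosome"], int(c["start"]), c["ref"], c["alt"]
            )
        cnv = None
        if "cnv_detail" in vd:
            x = vd["cnv_detail"]
            cnv = CnvDetail(int(x["start"]), int(x["end"]), CnvChange(x["change"]))
        variants.append(
            Variant(
                local_id=vd["local_id"],
                gene_symbol=vd["gene_symbol"],
                notation=vd["notation"],
                variant_class=VariantClass(vd.get("variant_class", "snv")),
                zygosity=Zygosity(vd.get("zygosity", "unknown")),
                coordinates=coords,
                cnv_detail=cnv,
                coordinate_flag=CoordinateFlag(vd.get("coordinate_flag", "unmapped")),
            )
        )
    return CombinationEntry(
        combination_id=d["combination_id"],
        variants=tuple(variants),
        disease=Disease(
            name=d["disease"]["name"], ontology_id=d["disease"].get("ontology_id")
        ),
        references=tuple(
            Reference(r["article_id"], int(r["year"])) for r in d["references"]
        ),
    )


def store_to_dict(store: AnnotationStore) -> dict:
    return {
        "population_presence": {
            k: store.population_presence[k] for k in sorted(store.population_presence)
        },
        "clinical_relevance": {
            k: store.clinical_relevance[k] for k in sorted(store.clinical_relevance)
        },
        "ppi_edges": [
            {"gene_a": a, "gene_b": b, "confidence": store.ppi_edges[pair]}
            for pair in sorted(store.ppi_edges, key=sorted)
            for a, b in [sorted(pair)]
        ],
        "pathways": [
            {"gene": g, "pathway_id": pid, "phenotype_relevant": rel}
            for g in sorted(store.pathway_membership)
            for pid, rel in sorted(store.pathway_membership[g])
        ],
        "predictions": {
            k: {
                "cadd_phred": c.cadd_phred,
                "sift": c.sift.value,
                "mutation_taster": c.mutation_taster.value,
                "polyphen": c.polyphen.value,
            }
            for k, c in sorted(store.predictor_calls.items())
        },
    }


def store_from_dict(d: dict) -> AnnotationStore:
    store = AnnotationStore()
    store.population_presence.update(
        {k: bool(v) for k, v in d.get("population_presence", {}).items()}
    )
    store.clinical_relevance.update(
        {k: bool(v) for k, v in d.get("clinical_relevance", {}).items()}
    )
    for e in d.get("ppi_edges", []):
        store.ppi_edges[frozenset((e["gene_a"], e["gene_b"]))] = float(e["confidence"])
    for p in d.get("pathways", []):
        store.pathway_membership.setdefault(p["gene"], set()).add(
            (p["pathway_id"], bool(p["phenotype_relevant"]))
        )
    for k, c in d.get("predictions", {}).items():
        store.predictor_calls[k] = PredictorCalls(
            cadd_phred=None if c.get("cadd_phred") is None else float(c["cadd_phred"]),
            sift=Sift(c.get("sift", "absent")),
            mutation_taster=MutationTaster(c.get("mutation_taster", "absent")),
            polyphen=Polyphen(c.get("polyphen", "absent")),
        )
    return store


def write_corpus(
    directory,
    records: Sequence[EvidenceRecord],
    entries: Sequence[CombinationEntry],
    format: str = "tsv",
) -> None:
    """Write a scoreable corpus: entity tables plus evidence records."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_tables(EntityTables.from_entries(entries), d, format=format)
    recs = sorted(
        (record_to_dict(r) for r in records),
        key=lambda r: (r["combination_id"], r["article"]["article_id"], r["curator_id"]),
    )
    (d / "records.json").write_text(
        json.dumps(recs, indent=1, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def read_corpus(directory, format: str = "tsv"):
    """Inverse of :func:`write_corpus`: (records, entries)."""
    d = Path(directory)
    entries = read_tables(d, format=format).to_entries()
    records = [
        record_from_dict(r)
        for r in json.loads((d / "records.json").read_text(encoding="utf-8"))
    ]
    return records, entries


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

OVERLAP_CATEGORIES = (
    "fam", "stat", "fun", "fam+stat", "fam+fun", "stat+fun", "fam+stat+fun", "none",
)


@dataclass
class SummaryReport:
    """Corpus-level accounting of scores and evidence classes.

    ``evidence_overlap`` counts combinations by which evidence classes are
    present at level >= 1 (familial manual, statistical meta, functional
    meta); ``genetic_functional_heatmap[g][f]`` counts combinations with
    genetic level ``g = max(FAM, STAT)`` and functional level ``f``.
    """

    final_score_distribution: Dict[str, Dict[int, int]]
    evidence_overlap: Dict[str, int]
    genetic_functional_heatmap: List[List[int]]
    relationship_histogram: Dict[str, int]
    corpus_counts: Dict[str, int]

    def to_dict(self) -> dict:
        return {
            "final_score_distribution": {
                k: {str(s): n for s, n in v.items()}
                for k, v in self.final_score_distribution.items()
            },
            "evidence_overlap": dict(self.evidence_overlap),
            "genetic_functional_heatmap": self.genetic_functional_heatmap,
            "relationship_histogram": dict(self.relationship_histogram),
            "corpus_counts": dict(self.corpus_counts),
        }


def summarize(
    scoresets: Mapping[str, ScoreSet],
    entries: Sequence[CombinationEntry],
    records: Sequence[EvidenceRecord] = (),
    score_variant: str = "meta",
) -> SummaryReport:
    """Build the corpus summary; every entry must be scored."""
    if score_variant not in ("manual", "meta"):
        raise ValueError("score_variant must be 'manual' or 'meta'")
    missing = [e.combination_id for e in entries if e.combination_id not in scoresets]
    if missing:
        raise ValueError(f"unscored combinations: {', '.join(sorted(missing))}")

    dist = {"manual": {s: 0 for s in range(4)}, "meta": {s: 0 for s in range(4)}}
    overlap = {k: 0 for k in OVERLAP_CATEGORIES}
    heatmap = [[0] * 4 for _ in range(4)]
    for e in entries:
        ss = scoresets[e.combination_id]
        dist["manual"][ss.final_manual] += 1
        dist["meta"][ss.final_meta] += 1
        present = []
        if ss.manual.fam >= 1:
            present.append("fam")
        if ss.stat_meta >= 1:
            present.append("stat")
        if ss.fun_meta >= 1:
            present.append("fun")
        overlap["+".join(present) if present else "none"] += 1
        if score_variant == "meta":
            genetic = max(ss.manual.fam, ss.stat_meta)
            fun = ss.fun_meta
        else:
            genetic = max(ss.manual.fam, ss.manual.stat)
            fun = ss.fun_manual
        heatmap[genetic][fun] += 1

    rel_hist: Dict[str, int] = {}
    rel_by_cid: Dict[str, set] = {}
    for r in records:
        rel_by_cid.setdefault(r.combination_id, set()).update(
            t.value for t in r.gene_functional.relationship_types
        )
    for cid, types in rel_by_cid.items():
        for t in types:
            rel_hist[t] = rel_hist.get(t, 0) + 1

    counts = {
        "combinations": len(entries),
        "distinct_variants": len({v.key for e in entries for v in e.variants}),
        "distinct_genes": len({s for e in entries for s in e.gene_symbols}),
        "diseases": len({e.disease.key for e in entries}),
        "combinations_gt2_genes": sum(1 for e in entries if len(e.gene_symbols) > 2),
        "combinations_with_cnv": sum(
            1
            for e in entries
            if any(v.variant_class is VariantClass.CNV for v in e.variants)
        ),
    }
    return SummaryReport(
        final_score_distribution=dist,
        evidence_overlap=overlap,
        genetic_functional_heatmap=heatmap,
        relationship_histogram=dict(sorted(rel_hist.items())),
        corpus_counts=counts,
    )
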