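"""Scoring configuration: annotation thresholds and decision-tree tables.

The FUN and FINAL aggregation trees are carried as explicit lookup tables
(input tuple -> level) rather than code, so they can be audited, dumped to
TSV and replaced wholesale.  The default tables implement:

``FUN(gene, var)`` — joint functional level from the gene-combination and
variant-combination levels: 0 when either side is absent; 3 only when both
are strong; 2 when either side reaches at least moderate; else 1.

``FINAL(fam, stat, fun)`` — overall confidence; with
``genetic = max(fam, stat)``: 0 when either the genetic or the functional
side is absent; 3 for strong functional evidence backed by at least
moderate genetic evidence; 2 for moderate-or-better on both sides, or
strong functional evidence on weak genetic evidence; else 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Tuple

import yaml

from .knowledge_enums import Polyphen

FunTable = Dict[Tuple[int, int], int]
FinalTable = Dict[Tuple[int, int, int], int]


def default_fun_table() -> FunTable:
    table: FunTable = {}
    for g in range(4):
        for v in range(4):
            if min(g, v) == 0:
                out = 0
            elif g == 3 and v == 3:
                out = 3
            elif max(g, v) >= 2:
                out = 2
            else:
                out = 1
            table[(g, v)] = out
    return table


def default_final_table() -> FinalTable:
    table: FinalTable = {}
    for fam in range(4):
        for stat in range(3):
            for fun in range(4):
                genetic = max(fam, stat)
                if genetic == 0 or fun == 0:
                    out = 0
                elif fun == 3 and genetic >= 2:
                    out = 3
                elif (fun >= 2 and genetic >= 2) or (fun == 3 and genetic == 1):
                    out = 2
                else:
                    out = 1
                table[(fam, stat, fun)] = out
    return table


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds for knowledge scoring plus the two aggregation trees.

    ``ppi_threshold`` is a *strict* lower bound on interaction confidence
    (an edge at exactly the threshold does not qualify);
    ``cadd_phred_threshold`` is inclusive (a CADD Phred equal to the
    threshold is a pathogenic call).
    """

    ppi_threshold: float = 0.8
    cadd_phred_threshold: float = 15.0
    polyphen_accept: FrozenSet[Polyphen] = frozenset(
        {Polyphen.PROBABLY_DAMAGING, Polyphen.POSSIBLY_DAMAGING}
    )
    fun_table: FunTable = field(default_factory=default_fun_table)
    final_table: FinalTable = field(default_factory=default_final_table)

    def __post_init__(self):
        if self.ppi_threshold <= 0 or self.cadd_phred_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if set(self.fun_table) != {(g, v) for g in range(4) for v in range(4)}:
            raise ValueError("fun_table must cover all (gene, var) tuples in 0-3")
        if set(self.final_table) != {
            (f, s, u) for f in range(4) for s in range(3) for u in range(4)
        }:
            raise ValueError("final_table must cover all (fam, stat, fun) tuples")

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "ppi_threshold": self.ppi_threshold,
            "cadd_phred_threshold": self.cadd_phred_threshold,
            "polyphen_accept": sorted(p.value for p in self.polyphen_accept),
            "fun_table": {
                f"{g},{v}": out for (g, v), out in sorted(self.fun_table.items())
            },
            "final_table": {
                f"{f},{s},{u}": out
                for (f, s, u), out in sorted(self.final_table.items())
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        if "ppi_threshold" in doc:
            kwargs["ppi_threshold"] = float(doc["ppi_threshold"])
        if "cadd_phred_threshold" in doc:
            kwargs["cadd_phred_threshold"] = float(doc["cadd_phred_threshold"])
        if "polyphen_accept" in doc:
            kwargs["polyphen_accept"] = frozenset(
                Polyphen(p) for p in doc["polyphen_accept"]
            )
        if "fun_table" in doc:
            kwargs["fun_table"] = {
                tuple(int(x) for x in k.split(",")): int(v)
                for k, v in doc["fun_table"].items()
            }
        if "final_table" in doc:
            kwargs["final_table"] = {
                tuple(int(x) for x in k.split(",")): int(v)
                for k, v in doc["final_table"].items()
            }
        return cls(**kwargs)

    def dump_tree_tsv(self, which: str) -> str:
        """Render a tree as a TSV audit table (``fun`` or ``final``)."""
        if which == "fun":
            lines = ["gene\tvar\tfun"]
            lines += [
                f"{g}\t{v}\t{out}" for (g, v), out in sorted(self.fun_table.items())
            ]
        elif which == "final":
            lines = ["fam\tstat\tfun\tfinal"]
            lines += [
                f"{f}\t{s}\t{u}\t{out}"
                for (f, s, u), out in sorted(self.final_table.items())
            ]
        else:
            raise ValueError(f"unknown tree {which!r}")
        return "\n".join(lines) + "\n"
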