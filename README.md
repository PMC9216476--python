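# oligoscore

Confidence scoring for **oligogenic variant combinations** — sets of
variants in two or more genes whose joint presence is proposed to cause or
modulate a disease phenotype.

Curators of digenic/oligogenic case reports face a recurring question: how
strong is the evidence that a *combination* of variants, rather than any
single one, drives the phenotype?  `oligoscore` implements a rule-based
curation protocol that answers it with ordinal confidence levels
(Absent/Weak/Moderate/Strong = 0/1/2/3) computed from structured evidence:

* **Manual scores** graded from the source article alone —
  `FAMmanual` (pedigree segregation, 0–3), `STATmanual` (control-cohort /
  database absence, 0–2), `GENEmanual` and `VARmanual` (gene- and
  variant-level functional work, 0–3);
* **Knowledge scores** computed from local annotation tables emulating
  external resources — population-panel presence of the joint genotype,
  per-variant clinical assertions, protein–protein interaction confidences
  (qualifying edges strictly > 0.8), pathway memberships, and calls from
  four pathogenicity predictors (CADD Phred ≥ 15, SIFT, MutationTaster,
  PolyPhen-2 damaging categories);
* **Harmonization** across the corpus — each gene combination receives the
  best `GENEmanual` seen in any article (`GENEmanual_harmonized`), and each
  combination the per-evidence maximum over its articles;
* **Metascores** — per-evidence maxima of manual and knowledge scores
  (`STATmeta`, `GENEmeta`, `VARmeta`), with one override: presence of the
  combination in the population panel forces `STATmeta = 0`;
* **Decision trees** — `FUN = tree(GENE, VAR)` and
  `FINAL = tree(FAM, STAT, FUN)` aggregate the per-evidence levels into the
  functional and overall confidence, requiring both genetic
  (`max(FAM, STAT)`) and functional evidence for any non-zero overall score.

The package also ships a six-table entity model (combinations, variants,
genes, gene combinations, diseases, references) with canonical TSV/JSON
serialization, corpus-level summary reports (score distributions, evidence
overlap, genetic×functional heatmap), a synthetic corpus generator with
planted ground-truth scores, and a CLI.

## Worked example

The package ships three fixtures encoding characteristic evidence
profiles.  `OLI606` is a trigenic left-ventricular-noncompaction
combination (MYH7, MRTFB, NKX2-5): healthy relatives at first and second
degree carry only partial combinations, but one variant's solo effect was
never tested, so segregation is not shown as complete (moderate
`FAMmanual`); mouse models show synergy of the triple mutant over double
and single mutants (strong gene- and variant-level scores).

```sh
python - <<'EOF'
from oligoscore import packaged_worked_examples, write_corpus
ex = packaged_worked_examples()["OLI606"]
write_corpus("demo/corpus", ex.records, [ex.entry])
ex.store.to_tsv_dir("demo/store")
EOF
oligoscore score --corpus demo/corpus --store demo/store
```

prints (selected columns):

```
combination_id  fam_manual  stat_manual  gene_manual  var_manual  stat_meta  fun_meta  final_meta
OLI606          2           0            3            3           1          3         3
```

Moderate familial evidence (2) plus strong functional synergy (`FUNmeta`
3) is enough for the overall `FINALmeta` of 3: strong confidence that the
three variants act jointly.  The same fixture in pure library form:

```python
from oligoscore import packaged_worked_examples, score_pipeline
ex = packaged_worked_examples()["OLI606"]
scores = score_pipeline(ex.records, [ex.entry], ex.store)["OLI606"]
print(scores.final_meta)   # 3
```

Other CLI subcommands: `validate` (entity/evidence invariants), `report`
(summary JSON), `fixtures` (synthetic corpus with planted truth, seeded),
`trees` (dump the decision trees as TSV audit tables).

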