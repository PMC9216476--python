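# Methods

## The scoring model

`oligoscore` grades the evidence that a combination of variants in two or
more genes jointly causes a disease phenotype.  All scores are ordinal
levels on a common scale — Absent (0), Weak (1), Moderate (2), Strong (3)
— and the protocol's central premise is that a confident oligogenic claim
needs *both* genetic evidence (segregation or statistics) and functional
evidence (joint effect of the genes and variants).  Scores are computed in
five deterministic stages: per-article manual scoring, cross-article
merging, corpus-wide gene harmonization, knowledge scoring from annotation
tables, and metascore aggregation through two decision trees.

### Manual scores

**Familial (`FAMmanual`, 0–3).**  A relative is *informative* when both
phenotype and genotype (full / partial / non-carrier of the combination)
are known.  Segregation is *perfect* when every informative full carrier
is affected, every informative non-carrier is healthy, a healthy *partial*
carrier counts as consistent (the incomplete combination not causing
disease is exactly the oligogenic expectation; an affected partial carrier
breaks perfection), and the pedigree's coverage is complete.  The
`coverage_complete` flag is our answer to a representational gap: a family
in which nobody carries one variant in isolation leaves that variant's
solo effect unshown, which the carrier-class vocabulary alone cannot
express — with the flag false, segregation is never perfect.  Levels:
3 = healthy informative relatives at both degrees with perfect
segregation; 2 = two or more informative first-degree relatives with
perfect segregation, or imperfect segregation spanning both degrees;
1 = exactly one informative healthy first-degree relative, or imperfect
segregation with at least two first-degree relatives; 0 otherwise.  A
single *affected* genotyped relative alone scores 0 (an affected carrier
adds nothing about the combination's necessity).

**Statistical (`STATmanual`, 0–2).**  Requires a control source,
demonstrated absence of the combination in controls, and three quality
gates (sufficient size, matched ethnicity, known control phenotypes);
explicit absence checking scores 2, implicit 1.  The ceiling is 2 by
design: cohort studies cannot control environmental background the way
pedigrees can.  Similar sequencing technology is recorded but not gating
("preferably" in the protocol), and cross-combination shared-variant flags
are contextual only — they never raise the score by themselves.

**Gene functional (`GENEmanual`, 0–3)** and **variant functional
(`VARmanual`, 0–3).**  Strong requires the full synergy comparison
(single *and* joint perturbations, synergistic or additive outcome);
moderate an experimental effect without that comparison, a direct gene
relationship (same pathway, direct interaction, same complex) with shown
phenotype relevance, or a clear in-silico joint effect; weak covers
pathway/tissue relevance (genes) and all-variants-predicted-pathogenic,
mixed experiment/prediction, or promising-but-inconclusive experiments
(variants).  A negative experimental result caps either score at 1:
relevance may remain, synergy is contradicted.  The experimental moderate
branch accepts any non-none design (not only joint-only/single-only), so
that upgrading a design never lowers a score — monotonicity under
evidence strengthening is enforced by tests.

### Knowledge scores

Knowledge scores compensate for information missing from the article by
consulting annotation tables (local TSV emulations of a population panel,
clinical assertion database, PPI database, pathway databases and four
predictors).  A knowledge score is **assigned only when information exists
for every unit of the combination**; otherwise it is *unassigned*, which
is distinct from 0 (unassigned falls back to the manual score during
aggregation).

* `STATknowledge` (0–1): 1 when the joint genotype is absent from the
  population panel and every variant has disease-relevant assertions; 0
  with reason codes otherwise.  Panel membership is keyed by combination
  (joint genotype), not by individual variants.  When the panel lookup
  says *present*, that verdict wins even if relevance rows are missing —
  presence is the one fact that must propagate to the metascore override.
* `GENEknowledge` (0–2): 2 when the genes form a connected network using
  only interaction edges with confidence **strictly greater than** 0.8
  (an edge at exactly the threshold does not qualify), or when all genes
  share a common phenotype-relevant pathway (for >2-gene combinations we
  require one pathway common to all genes, the conservative reading);
  1 when every gene has at least one phenotype-relevant pathway;
  0 otherwise.  Pathway relevance for the phenotype is a curated boolean
  in the store, mirroring manual screening; no automated matching.
* `VARknowledge` (0–1): 1 when every variant has at least one pathogenic
  call — CADD Phred **≥ 15** (the threshold itself passes), SIFT
  deleterious, MutationTaster disease-causing, or PolyPhen-2
  possibly/probably damaging.

### Harmonization and metascores

Cross-article merging takes the per-evidence maximum over all articles
describing a combination; gene harmonization assigns each canonical gene
combination (case-normalized, sorted symbol tuple) the best `GENEmanual`
observed anywhere in the corpus.  Both are max-semilattice operations
(idempotent, commutative, associative), verified by property tests.

Metascores are per-evidence maxima of the manual and knowledge sides,
with a single override: a `STATknowledge` of 0 *because the combination is
present in the population panel* replaces `STATmanual`, forcing
`STATmeta = 0`.  `GENEmeta` uses the harmonized gene score;
`FUNmanual`/`FINALmanual` are likewise computed from the harmonized gene
score (recalculated after harmonization).

### Decision trees

The trees are shipped as explicit lookup tables (auditable, dumpable as
TSV, replaceable wholesale through `ScoringConfig`), generated from these
closed forms:

* `FUN(gene, var)`: 0 if either side is 0; 3 only if both are 3; 2 if
  either side is ≥ 2; else 1.  Strong functional confidence demands
  strength of *both* the gene and the variant side.
* `FINAL(fam, stat, fun)` with `genetic = max(fam, stat)`: 0 if genetic or
  functional evidence is absent; 3 if `fun = 3` and `genetic ≥ 2`; 2 if
  both sides are ≥ 2, or `fun = 3` with `genetic = 1`; else 1.

These forms satisfy every constraint the protocol states — the published
level descriptions, the worked-example outcomes encoded in the packaged
fixtures, and strong-overall requiring strong functional plus
at-least-moderate genetic evidence.  Two cells are genuine choices not
pinned by any stated example: `FINAL(genetic=1, fun=3) = 2` (strong
functional proof lifts weak genetics to moderate, not strong) and the
symmetric treatment of `fun ≥ 2, genetic ≥ 2` cells; both are visible in
the tree audit dump (`oligoscore trees`).  Both trees are monotone
non-decreasing in every argument, checked exhaustively.

## Synthetic corpora and what they show

The generator works backwards from sampled target levels to evidence — a
constructive inverse of the rules (e.g. target `FAM = 3` emits a perfect
pedigree with healthy relatives at both degrees).  This guarantees branch
coverage and an exact oracle: the pipeline must reproduce the planted
scores with zero mismatches.  Defaults: 100 combinations (1000 in the
acceptance-scale test), 80/15/5% digenic/trigenic/four-gene, 5% CNV
combinations, 20% described by a second (never stronger) article, level
distributions skewed toward absent/weak evidence as in real curated
corpora, and a 10% rate of threshold-boundary annotation values (PPI
confidence exactly 0.8, CADD exactly 15) planted where they must not flip
the outcome.  Gene symbols are unique per combination so harmonization is
the identity there; cross-combination harmonization is exercised by
dedicated fixtures instead.

What passing these tests does **not** show: the generator plants evidence
that cleanly realizes one rule branch per evidence type, so it says
nothing about free-text interpretation, conflicting evidence *within* one
article, HGVS/coordinate correctness, or the realism of annotation values
— coordinates, confidences and predictor scores are placeholders.

## Numerical and degenerate-input choices

* PPI boundary strict (`> 0.8`), CADD boundary inclusive (`≥ 15`), as the
  protocol prints them.
* Score containers validate their ranges on construction; tree lookups
  raise on out-of-range inputs rather than clamping.
* `merge_cross_article` of an empty list, knowledge scoring of fewer than
  two genes, and metascores with a harmonized gene score below the manual
  one all raise.
* Dual-curator reconciliation returns a field-level diff and never
  auto-resolves: the protocol resolves disagreements by discussion, and no
  tie-break rule is defined.
* TSV serialization is canonical — fixed column order, rows sorted by
  primary key, backslash-escaped tabs/newlines, UTF-8 — so write∘read∘write
  is byte-stable and testable by exact diff.  Excel export is deliberately
  omitted (format variance defeats byte-exact testing).

## Known limitations

* The decision trees are reconstructions from stated constraints, not a
  transcription of a published table; the two unpinned cells noted above
  carry design risk, which is why the trees live in data.
* `GENEknowledge` for >2-gene combinations uses the all-genes-common
  pathway reading; a per-pair reading would be more permissive.
* No HGVS parsing, liftover or live identifier resolution: variant keys
  are coordinate-based when mapped, otherwise symbol+notation strings.
* Evidence enters as structured records; extracting them from article text
  is out of scope.
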