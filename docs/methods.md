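# Methods

## Problem and model

`convergene` prioritizes cancer genes in cohorts too small for
background-mutation-rate statistics. Its working assumption is the linear
aetiology of most driver models: DNA-level variation (copy number, point
mutation, rearrangement) propagates to transcription and ultimately to
phenotype, so independent evidence types converging on one gene are less
likely to be noise than any single call. The pipeline therefore filters
each platform separately with conventional quality rules and then asks a
purely set-theoretic question: which genes accumulate at least
`min_alteration_types` distinct alteration mechanisms, within or across
samples?

This design deliberately trades sensitivity for specificity: a gene
altered only ever by one mechanism (for example, pure amplification) is
invisible to it, which is a known limitation of convergence filtering
rather than a defect of the implementation.

## Coordinate and naming conventions

All intervals are 0-based half-open internally. BED input is taken as-is;
GTF and VCF/MAF positions (1-based) are shifted at ingest and never again.
Chromosome names are normalized by stripping a leading `chr`. Gene
identity is `gene_id`; symbols may collide and are only logged. Variant
identity is the tuple (sample, chrom, pos, ref, alt); multi-allelic VCF
rows are split per alternate allele so the key is total.

## Stage definitions and parameters

All thresholds live in `PipelineConfig` and are passed as one object;
defaults in parentheses.

**Copy number.** A segment is *focal* iff its length is strictly less than
`focal_max_length` (10 Mb); a segment of exactly the threshold is
arm-level, because the downstream filter is the strict "shorter than".
Arm-scale events are treated as non-specific and generate no gene calls.
Focal segments call *amplified* at copy number ≥ `amp_min_copies` (3) and
*deleted* at ≤ `del_max_copies` (1) around `neutral_copies` (2). These
baselines are configurable because hyperploid genomes (the motivating cell
lines average ~62–66 chromosomes) may warrant a per-sample ploidy
baseline; no published integer cutoff exists for that situation, so the
defaults are the explicit diploid reading. Gene assignment is any-overlap
(≥ 1 bp, the default of standard interval annotators);
`min_overlap_fraction` can demand more. A gene hit by several focal
segments in one sample takes the segment with the largest
|copy − neutral|, ties broken toward amplification and then the leftmost
segment; discordant amp+del overlaps are resolved the same way and flagged
`;mixed` in the provenance key so they stay auditable.

**Expression.** `log_expr = log10(FPKM + 1)`; below `expr_noise_floor`
(0.1) a transcript is *not expressed* and excluded from ranking. Among the
expressed genes of each sample the percentile is
`100·(rank−1)/(n−1)`, with ties given the mean percentile of their rank
span and a single expressed gene pinned to 50. *High* is strictly above
`high_percentile` (60), *low* strictly below `low_percentile` (40). With
this formula the endpoints reach exactly 0 and 100, so on n distinct
values the expected class fractions are 0.40 / 0.40 / 0.20 (on 100
distinct values: 40 high, 40 low, 20 intermediate, as the brute-force rank
enumeration in the test suite confirms). Ranking is per sample — each
transcriptome is binned against itself, the only option without paired
normals — and depends on ranks only, hence is invariant under strictly
monotone transforms.

**Variants.** The cascade order is: effect (synonymous/other dropped) →
coverage ≥ `min_coverage` (5; "below 5×" is strict) → germline subtraction
(dbSNP member without COSMIC membership dropped) → prediction vote
(≥ `min_deleterious_votes` (2) of `n_predictors` (3) tools scoring
deleterious; a missing verdict is not a vote) → exome/transcriptome
cross-validation on the full identity key → non-empty gene assignment.
Truncating effects (nonsense, frameshift, splice) bypass the vote because
missense predictors do not score them; silently discarding them would drop
exactly the class of stop-gain drivers convergence analysis is meant to
catch. The passed set is order-invariant (the predicates are independent);
only the reason labels depend on the documented order, and each rejected
record carries the first failing reason. Position-only cross-validation is
available (`match_positions_only`) for callers with inconsistent indel
normalization.

**Fusions.** Kept at ≥ `min_fusion_read_pairs` (10) spanning pairs. Kept
fusions become one event per partner (one total for a read-through). By
default fusion events do **not** count toward the prioritization tally —
the three-step scheme names copy number, expression and mutation — but
`count_fusions_in_integration` adds them for users who want the fourth
mechanism.

**Integration.** Step 1 requires *same-sample* concordance
(amplified+high or deleted+low): the dosage correlation is a per-sample
statement, and cross-sample combinations are exactly what step 3 exists
for. Step 2 admits a gene on a filtered mutation with a detectable
transcript (the expression noise floor doubles as the detectability cut)
or, failing that, a focal copy-number call anywhere in the cohort.
"Detectable" is evidence, not an alteration: only cnv, expression-change,
mutation (and optionally fusion) events count toward `n_types`, otherwise
every expressed mutated gene would trivially reach two types. Step 3
pools each candidate's events over all samples — including expression
high/low calls for genes that entered via step 2, so a mutated and
over-expressed but copy-neutral gene is prioritized. The candidate
universe is the *union* of the step-1 and step-2 lists.

**Cohort mode.** Per gene, each per-type frequency is the fraction of
samples with ≥ 1 event of that type; the cumulative frequency is the
fraction with ≥ 1 event of any type (set union, never a sum), so
`max(per-type) ≤ cumulative ≤ min(1, Σ per-type)` always holds. Genes pass
the cohort filter at mutation frequency ≥ `cohort_min_mutation_freq`
(0.03). The three-class typology is an explicit operationalization of
what is usually a visual judgment: *mutation_dominant* when mutation
frequency ≥ `class_dominance_ratio` (3.0) × dosage frequency (union of
cnv and expression), *cnv_expression_dominant* in the mirror case,
otherwise *mixed*; 0/0 is mixed. Raw frequencies are always reported so a
different ratio can be applied post hoc.

## Synthetic cohort generator

The generator emulates a four-sample hyperploid cell-line study: 2000
genes on five 50-Mb chromosomes (non-overlapping, one gene per slot with a
12-kb guard margin), FPKM drawn log-normal (ln-space μ = 2.0, σ = 1.2;
median ≈ 7 FPKM) for expressed genes and uniform below the noise floor for
the `frac_not_expressed` = 0.25 silent fraction, exome depth Poisson
around 80×, and variant tables carrying the same annotation columns real
MAF-like inputs would.

Truth is planted by construction. Twenty multi-altered genes cycle
through five patterns (amp+high same sample; del+low same sample;
mutation in one sample with amp+high in another; mutation plus
dosage-silent amplification across samples; mutation plus over-expression
copy-neutral), covering both within-sample and across-sample convergence
and every admission route of steps 1–2. One hundred single-altered decoys
receive exactly one passing event each; decoys are *collision-free* —
mutated decoys are pinned to intermediate expression in every sample, and
CNV decoys to intermediate expression in the affected sample — so no decoy
can reach a second alteration type through background fluctuation, which
is what makes exact precision/recall = 1 a meaningful end-to-end check
rather than a tautology. Clean genes carry only records built to fail one
specific filter (dbSNP-only, 1–4× coverage, insufficient deleterious
votes, missing transcriptome twin, synonymous effect, unassigned gene,
neutral-copy focal segments, arm-scale segments, < 10-read-pair fusions),
so every filter's pass *and* fail behaviour is observable in one default
cohort. Planted expression levels are drawn relative to the empirical
background distribution of their sample (above its maximum for "high",
just above the floor for "low", at its median for "intermediate") and the
generator re-runs the real stage classifiers before returning, refusing
any cohort whose plants would not survive their own filters.

Each data type draws from its own random stream spawned from the master
seed, so adding a data type never perturbs another's draws; all outputs
are byte-deterministic given the seed.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: linkage and recurrent breakpoints
(segments are placed per gene), expression covariance between samples and
genes, mutational signatures and indel alignment ambiguity, ploidy
heterogeneity (the neutral baseline is global), and allele-specific
expression loss in cross-validation.

## Numerical and degenerate-input choices

- Percentile ties take the mean of their rank span; an all-tied sample is
  entirely intermediate; a sample with a single expressed gene yields
  percentile 50. A sample with *no* expressed gene is an error naming the
  sample rather than a silent skip.
- `not_expressed` records carry percentile NaN (they never enter the
  ranking); NaN compares false against both thresholds.
- Floats are serialized with `repr` (shortest exact form) and parsed in
  round-trip mode, so write→read is field-identical and repeated runs are
  byte-identical.
- Output tables are sorted on raw field values (numeric-aware), with a
  `#` header carrying the package version and a config hash.
- Empty inputs yield empty outputs everywhere except where a statistic
  becomes undefined (no samples in cohort mode, no expressed genes in a
  sample), which raise.

## Problem sizes

The test suite and the acceptance script run the full default study
(4 × 2000 genes) end to end, the interval oracle at 200 segments × 2000
genes over 20 seeds, expression calibration at 10,000 values per sample,
and 100 random event matrices for the union oracle; the whole suite
completes in well under a minute on one CPU, which is the scale this
package targets.

## Known limitations

- Single-mechanism drivers are out of reach by design.
- LOH and allelic imbalance are not modelled; copy number is total.
- Catalog membership (dbSNP/COSMIC) is consumed from input columns or a
  user-supplied positions file, never queried live, so results inherit the
  caller's catalog versions.
- The cohort-mode typology ratio (3.0) is a reporting convention, not an
  inferred quantity; sensitivity analyses should vary it.
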