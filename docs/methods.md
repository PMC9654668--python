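# Methods

## The model

`varenrich` implements group-level variant enrichment analysis (VEA) for
whole-exome variant calls. Given a study group of individuals, the variants
**shared** by its members (the *group-common* set) are intersected with
pathway gene sets, and each pathway's share of the common variants is
compared with the pathway's share of variants in a large reference
population (e.g. gnomAD non-Finnish Europeans). For pathway *P*:

- *a* — group-common variants in genes of *P*;
- *n1* — group-common variants in any pathway-annotated gene;
- *c* — distinct background variants in genes of *P*;
- *n2* — distinct background variants over the whole pathway universe
  (one constant for all pathways).

The reported **fold enrichment** is the ratio of ratios
`(a/n1) / (c/n2)` — the group VariantRatio over the background BgRatio.
Published group-level VEA tables label this column "OR"; it is *not* the
cross-product odds ratio `(a/(n1−a))/(c/(n2−c))` (for one published row the
two give 2.63 vs 2.67), and the package emits the cross-product OR as a
separate column for comparison. The significance test is the one-sided
Fisher exact (hypergeometric upper tail)

P(X ≥ a),  X ~ Hypergeom(N = n1 + n2, K = a + c, n = n1),

i.e. enrichment only; a two-sided option exists. P-values are adjusted by
Benjamini–Hochberg step-up across all *tested* pathways. Pathways with
c = 0 are untestable (the fold is undefined) and are excluded before the
adjustment so the multiple-testing universe contains only tested
hypotheses. A pathway is *called* enriched when adj. p < α (default 0.05)
**and** fold > 1.

### Confidence intervals

Two interval methods are pluggable:

- `katz` (default): the Katz log-ratio interval for a ratio of two
  independent binomial proportions,
  `exp(ln fold ± z·sqrt(1/a − 1/n1 + 1/c − 1/n2))`.
- `conditional`: the conditional exact odds-ratio interval of the table
  `[[a, n1], [c, n2]]` — note the *totals*, not the complements, in the
  second column. This is what `fisher.test(matrix(c(a, n1, c, n2)))` in R
  computes when an enrichment pipeline passes (count, total) pairs
  directly, and it reproduces the intervals in published group-level VEA
  tables to the printed precision on essentially every row. Because
  n1 ≪ n2 and a ≪ n1 in practice, its point estimate is numerically close
  to the fold; residual differences beyond the second decimal between
  solvers (R vs scipy) occur on extreme small-count rows.

The Katz default was chosen because it estimates the quantity actually
reported (the rate ratio) with a closed form; `conditional` exists for
compatibility with reports produced the R way.

### Counting conventions

- The background total n2 covers the *pathway universe* only; variants in
  genes belonging to no pathway are excluded, which is what makes a single
  denominator valid for every row.
- A variant in a gene shared by k pathways counts once in each of the k
  per-pathway counts but once in the total — overlapping gene sets
  genuinely share evidence (published tables show near-identical rows for
  near-identical gene sets).
- n1 follows the same convention by default (`denominator: universe`);
  `all` counts every group-common variant instead. Which convention
  produced any given published n1 is generally not recoverable, so both are
  provided.
- Group-common defaults to the strict intersection across members
  (`share_rule: all`); `min_share` with a threshold k relaxes this.

## Quality and artifact filtering

Records are kept when genotype quality GQ > 30 **and** alt-allele depth
AD > 10, with *strict* inequalities (a record at GQ = 30 is excluded);
thresholds are configurable. Formalin-fixed (FFPE) DNA yields artificial
C>T / G>A substitutions; SNV records with those allele pairs are flagged
`ffpe_suspect`. The default keeps them (`ffpe_mode: flag`) because flagged
records are still real observations under review; `drop` removes them for
sensitivity analysis. Indels are never FFPE-flagged. Filters apply per
sample record, before any cross-sample merging.

## Synthetic data generator

The generator produces inputs with the statistical structure the analysis
assumes, so every stage is testable offline:

- **Pathway database** — `n_pathways` gene sets drawn from a shared pool;
  sampling is without replacement within a pathway, with replacement across
  pathways, so gene sets overlap as real pathway databases do.
- **Background** — per-gene variant counts are Poisson with Gamma(1.2)
  gene-specific rates (few hot genes, many cold) scaled so the expected
  universe total hits `background_total`; aggregation to pathway counts
  uses the same shared-gene convention as the analysis.
- **Cohorts** — each group has a *core* variant set present in every
  member plus *private* variants per member, drawn per gene with
  probabilities proportional to the background rates. `core_share` is the
  probability that a cohort variant is core, so the expected core size is
  `core_share/(1−core_share) · n_members · private_rate`. Planted
  enrichment multiplies the per-gene probability of a planted pathway's
  genes (×m, normalised), affecting core and private draws alike; the
  planted pathway ids are returned as ground truth.
- **Record noise** — GQ/AD are drawn so a configurable fraction of records
  fails the strict filters (`quality_fail_rate`), and allele pairs are
  C>T or G>A with probability `ffpe_rate`.

One integer seed drives everything through a `numpy` `SeedSequence` whose
children are consumed in fixed order (pathway DB, background, then one per
group), giving byte-identical outputs per (spec, seed). Run manifests carry
a timestamp and are the one output excluded from byte-reproducibility.

### Default scale

The desk-scale preset — 200 pathways of 10–40 genes over a 2,000-gene
pool, background total 2×10⁴, groups CTRL 5 / LC 7 / MPM 7 — keeps a full
simulate-and-analyse cycle near 0.1 s while matching the *shape* of real
group-level WES runs: the realised group-common total over the background
total (~1,100/20,000) sits on the same scale as published runs (thousands
over ~1.8×10⁵). `core_share = 0.4` and `private_rate = 300` produce that
core size; `quality_fail_rate = 0.02` and `ffpe_rate = 0.10` are modest
noise levels for deduplicated, recalibrated FFPE exomes.

### What the generator does not emulate

No sequence-level realism: no reads, no alignment error, no realistic
site-frequency spectrum, no linkage disequilibrium, no per-individual
relatedness, and gene "coordinates" are synthetic windows. Passing
calibration tests therefore shows the *statistical pipeline* is correct
under its own assumptions (independent Poisson-ish counts, background
proportionality), not that real exomes satisfy those assumptions.

## Calibration experiments

Two seeded experiments characterise the method at the default scale:

- **Null calibration** — groups of 7 with no planted signal; the fraction
  of runs making ≥ 1 enrichment call at FDR < 0.05 stays below the nominal
  0.05 (typically ~0.015; the discrete exact test is conservative).
- **Planted recovery** — ×3 rate inflation on 5 pathways of ≥ 15 genes,
  groups of 7: ~93% of planted pathways are recovered at FDR < 0.05.
  Precision is computed after setting aside calls in pathways that share
  genes with planted ones: such pathways carry genuinely inflated rates
  (the multiplier acts on genes, and gene sets overlap), so they are true
  discoveries of the generative model, not type-I errors — the same
  phenomenon as near-identical pathway rows sharing counts in real
  reports. Precision so defined is ~99–100%; clean false positives match
  the BH guarantee.

Replicate counts (500 null, 100 recovery) put the Monte-Carlo standard
error well below the margins being tested while keeping the experiments in
the one-minute range.

## Numerical choices and edge cases

- `fold = 0` when a = 0 (no interval is reported; p = 1 by definition of
  the upper tail). c = 0 or n1 = 0 raise instead, since the ratio is
  undefined — callers decide policy, and `run_vea`'s policy is exclusion
  with a log entry.
- BH adjustment uses `statsmodels` (`fdr_bh`); tests pin it to the
  hand-written step-up definition at 1e−12.
- The hypergeometric tail uses `scipy.stats.hypergeom.sf`; tests pin it to
  exact integer enumeration at 1e−12 on all tables with n1 + n2 ≤ 60.
- Ties in adj. p are broken by pathway id, so output ordering is total and
  deterministic. Venn region keys are sorted label tuples.
- Variant keys order as (chrom lexicographic, pos, ref, alt); `chr10`
  sorts before `chr2`, which is irrelevant to the statistics.
- Serialised results carry display columns (2-decimal folds, 3-significant
  scientific p-values) plus full-precision companions; the reader
  reconstructs records exactly from the latter.

## Known limitations

- Adjusted p-values from published tables are not reproducible from the
  printed rows alone: they depend on the full set of tested pathways,
  which reports do not print.
- The intersection sharing rule is brittle to one low-coverage member;
  `min_share` mitigates but its k is a judgement call.
- Gene-level annotation granularity only: no transcript or consequence
  awareness; a variant maps to exactly one gene symbol.
- The background is an opaque counts table; provenance and version
  resolution of the reference population are the caller's responsibility.
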