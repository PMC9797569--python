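# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the numerical conventions that make
every run reproducible.

## Co-dependency mapping

Genetic co-dependency between two genes is a significant Spearman
correlation of their knockout fitness profiles across cell lines.
Correlations use average ranks for ties and pairwise-complete
observations; each pair records its own n. The p-value is the
t-distribution approximation t = ρ√((n−2)/(1−ρ²)) with df = n−2 (exact
permutation is impractical at genome scale; the test suite keeps a
brute-force rank oracle for verification). |ρ| = 1 maps to p = 0.

Pairs with fewer than `min_pairs` (default 20) joint observations, or a
constant vector, are *excluded* from the Benjamini–Hochberg family rather
than assigned p = 1: an undefined test carries no evidence and assigning
it a p-value would dilute the FDR. For the same reason the query's
trivial self-correlation (ρ = 1, p = 0) is reported but kept out of the
BH family — a guaranteed rejection at rank 1 would halve the effective
threshold for the next-smallest p and inflate the null false-call rate
to roughly 2α.

Essentiality uses strict thresholds: effect < −0.5 per line counts as
essential, < −1.0 as a strong cytotoxic effect; a gene is called
essential when its *median* effect is below −0.5. A median of exactly
−0.5 is therefore not essential. Per-lineage summaries are restricted to
lineages with at least 5 cell lines. Ranks by median break ties by gene
id so they always form a permutation.

Correlation matrices are clustered with average linkage on
1 − correlation distance (the linkage/metric pair is not dictated by the
analysis itself; average linkage is the common default for correlation
heatmaps and is deterministic here, with ties resolved by scipy's
index-order convention). Missing correlations contribute distance 1
(i.e. correlation 0) to the clustering only.

## Survival stratification scan

For one gene in one cancer type the cohort is split at every percentile
k = 10…50 into a bottom-k% tail and a top-k% tail; the middle is
excluded. Percentiles use the nearest-rank definition (m = ⌈kn/100⌉
samples per tail); samples tied at a boundary value go to the low/inner
side, and a sample qualifying for both tails (odd n at k = 50) goes to
low. A single-cutpoint mode (low = bottom k%, high = rest, k = 10…90) is
available behind `mode="single-cut"`.

Splits are dropped when their sample partition duplicates an earlier
percentile (heavily tied expression makes adjacent k identical) or when
either group has fewer than 10 *events* (not samples). The retained
splits are tested with the Mantel–Haenszel log-rank statistic with the
standard tie-corrected variance Vⱼ = n₁ⱼn₂ⱼdⱼ(nⱼ−dⱼ)/(nⱼ²(nⱼ−1)); when
ΣV = 0 the statistic is defined as χ² = 0, p = 1. BH adjustment runs over
the retained tests *within* the scan, and the lowest-p split is selected;
a pooled (across genes/cancer types) adjustment is available via
`global_fdr` for analyses that select many gene–cancer pairs.

The reported effect size is the signed log2 event-rate ratio
(O/E)_high / (O/E)_low. This is an estimate of the hazard ratio under
proportional hazards, but a *shrunken* one when follow-up is nearly
complete: with almost all subjects experiencing the event, O is pinned
at the group sizes and the O/E contrast compresses. At the generators'
default 30% censoring the mean log2 ratio tracks the planted log2 hazard
ratio to within about 0.15 at HR = 3 and n = 500; with zero censoring it
underestimates by about 0.25. An alternative effect based on the ratio
of median survival times is available (`effect="median"`). Ratios with a
zero observed or expected count in either group are reported as missing
rather than ±∞.

## Pre-ranked enrichment

The ranked list orders genes by descending metric, ties broken by gene
id for cross-platform determinism. The running sum increments at a hit
by |metric|^w / Σ_hits|metric|^w (w = 1, the pre-ranked convention) and
decrements at a miss by 1/(N − n_set); ES is the extremum of maximal
absolute deviation, with exact ties resolved to the positive extremum.
The leading edge is the hit genes at or before a positive peak (at or
after a negative one).

The null is a plain gene-label permutation: for each distinct set size,
`n_perm` random position-sets, shared across sets of equal size. p =
(1 + #{|null ES| ≥ |ES|, same sign}) / (1 + #same-sign nulls), so p is
floored at about 2/n_perm (only same-sign permutations enter the
denominator); NES = ES / mean(|null ES| of the same sign). With the
default n_perm = 1000 the floor is ≈ 0.002, small enough that a single
strongly enriched set among ~20 survives BH at q < 0.1; fewer than ~300
permutations cannot clear that bar, which is why low n_perm values are
recorded as a warning on the result. The adaptive multilevel splitting
refinement used by some implementations is deliberately out of scope: at
the set counts this package targets, fixed-n permutation resolution is
sufficient.

Scaled NES multiplies NES by max|metric| of the ranked list. Query genes
with uniformly weak correlation profiles otherwise produce NES values on
the same scale as strongly correlated ones; the scaling makes enrichment
magnitudes comparable across queries. It preserves within-list ordering
and leaves p and q untouched.

## Drug-response cleaning and signatures

Duplicate (drug, line) entries are resolved by the range rule: if
max − min across *all* replicates exceeds 0.2 AUC the pair is removed
outright (irreconcilable measurements), otherwise the arithmetic mean is
used; a range of exactly 0.2 averages. The coverage filter then drops
drugs measured in fewer than 70% of the cell lines present anywhere in
the table (strict <, so 70.0% is kept); the two steps are idempotent.
Drug rankings ascend by median AUC — low AUC means strong growth
inhibition — with tied medians sharing the minimum rank.

Drug–drug similarity is pairwise Spearman over jointly measured lines
(≥ 20), BH-adjusted over the upper triangle, clustered with the same
machinery as gene correlation matrices; each drug also reports its
highest-ρ partner. Sensitivity signatures correlate each gene's
expression with the drug's AUC over matched lines; sensitivity = ρ < 0
with q < 0.1, resistance = ρ > 0 with q < 0.1. Enrichment runs on −ρ so
positive NES reads as "expression of this set marks sensitivity".

## Synthetic data: what it emulates, and what it does not

`simulate_gene_effect` — module genes are loading·F + √(1−loading²)·ε
around their mean, with a shared per-line factor F, so the expected
pairwise Pearson correlation is loading² (Spearman of a bivariate
Gaussian is slightly lower, (6/π)·asin(r/2); at loading 0.8 the observed
within-module Spearman averages ≈ 0.62 against the Pearson target 0.64).
Planted essential genes have mean −1.5, all others 0, with sd 0.3 —
cleanly separated across the −0.5/−1.0 thresholds. `loading=0` is the
null branch with no modules.

`simulate_survival` — expression is Gaussian (mean 8, sd 1.5, a
log2-expression-like scale); event times are exponential with baseline
hazard 1/500 days⁻¹, multiplied by the planted hazard ratio above the
planted percentile. Censoring is exponential with its rate solved
(Brent) so the expected censored fraction equals `censor_rate`; the
default 0.3 reflects typical progression-free follow-up in tumour
cohorts. Exponential times make the log-rank test optimal, so recovery
tests are sharp rather than flattered.

`simulate_drug_response` — cluster drugs share a latent per-line factor
(within-cluster correlation 0.8); AUC = clip(0.55 + 0.12·latent) to
[0, 1]. Each cluster's first drug gets signature genes whose expression
is ±effect_size-correlated with its latent AUC, on a log2(TPM+1)-like
scale (mean 5, sd 1.5, clipped at 0). A `dup_fraction` of entries is
emitted twice, half of the duplicates discordant by 0.25 AUC so the
dedup rule has true positives.

`simulate_genesets` — a Gaussian metric per universe gene; a planted
pool gets `shift` added, enriched sets sample from the pool, others from
the whole universe. The metric is returned in the truth object so
recovery can be scored.

All generators derive independent streams from one integer seed via
`numpy.random.SeedSequence` and are bit-reproducible.

What the generators do **not** emulate: the heavy left tail and
copy-number artefacts of real effect-score distributions, lineage-specific
dependency structure, non-proportional hazards or informative censoring,
dose–response curve fitting noise, and overlapping/correlated gene sets.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under its stated assumptions, not robustness to
every pathology of consortium data.

## Problem sizes and defaults

Default study conditions used by the demo, tests and acceptance script:
co-dependency recovery at loading 0.8 with 500 lines; cutpoint recovery
at HR 3, n = 500, 50 replicates; null calibration at 150–200 replicates
per stage; end-to-end drug signature/enrichment recovery over 25
replicates at effect size 0.7 with 300 lines. These sizes keep a full
run in the low minutes on one CPU while leaving each planted signal
either comfortably detectable (recovery) or absent by construction
(calibration).

Key defaults: α = 0.1 everywhere; `min_pairs` = 20; essential/strong
thresholds −0.5/−1.0; duplicate AUC range 0.2; coverage 70%;
`min_events` = 10; scan percentiles 10…50; gene-set size window 5…500;
n_perm = 1000.

## Known limitations

- The t-approximation p-value for Spearman is asymptotic; at n close to
  `min_pairs` it is mildly conservative in the tails.
- The scan's best-split p-value is selection-biased by construction
  (minimum over ~40 correlated tests); the within-scan BH keeps the
  *best-q* calibrated at the replicate level, which is what the null
  simulation checks.
- The log2 event-rate ratio is a shrunken hazard-ratio estimate at low
  censoring (see above); it is an association effect size, not a Cox
  coefficient.
- Gene-permutation GSEA nulls ignore inter-gene correlation; with
  strongly correlated ranking metrics the q-values are anti-conservative,
  as with any pre-ranked gene-permutation implementation.
- No Cox regression, covariate adjustment, or interval censoring; no
  dose–response refitting from raw viability data.
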