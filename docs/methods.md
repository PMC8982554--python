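# Methods

## Scope and data model

The package analyses paired tumor/normal expression over multiple cancer
cohorts. Inputs are BED enhancer coordinates (0-based half-open), RPKM-scale
features × samples TSV matrices for enhancers and genes, a pre-collapsed
one-TSS-per-gene annotation table, a 1-based SNP table (VCF position
convention, converted to 0-based on ingest), JASPAR-style PFMs, GMT gene
sets, and FASTA sequences for extended enhancer regions. All coordinate
inputs must share one genome assembly; the SNP-mapping stage checks declared
assembly tags and refuses mixed inputs rather than lifting coordinates —
assembly conversion is an external, upstream concern.

Enhancers are treated as unstranded (eRNA transcription is bidirectional)
and their center is the floor of the interval midpoint, so all windows are
symmetric and deterministic. Gene promoters are strand-aware: TSS −500 bp to
+1000 bp on the plus strand, mirrored on the minus strand, clamped at
position 0. When a gene has several isoforms the caller must collapse them
to one representative TSS before input; the package does not choose one.

## Differential expression

Candidate features must be expressed (strictly above the `expressed_threshold`,
default 0) in at least `prevalence_min` = 10% of a cohort's tumor samples
*or* of its normal samples — the OR keeps features silenced in tumors
testable as down-regulation events. The boundary is inclusive (1 of 10
samples qualifies).

The test statistic is a two-sided t-test on the RPKM-scale values. Welch's
unequal-variance form with Satterthwaite degrees of freedom is the default
because tumor and normal sample sets are unpaired and of different sizes in
real cohorts; a pooled-variance Student variant is available via
`t_test: student`. Degenerate inputs follow fixed conventions: two constant
equal groups give p = 1, two constant unequal groups give p = 0. Fold change
uses group means with pseudocount 0.01 (guards against zero means on
dropout-heavy features without materially moving moderate expression
values). Multiple testing is controlled by Benjamini–Hochberg within one
cohort and one feature class — enhancers and genes are adjusted separately
so the much larger gene family cannot swamp enhancer discoveries. The call
rule is exactly: up iff log2FC ≥ 1 and q < 0.05; down iff log2FC ≤ −1 and
q < 0.05.

Per-cohort calls and unique features are both reported: a feature DE in
several cohorts contributes one call per cohort but one unique feature, and
the two counts answer different questions.

## Expression breadth

A feature counts as expressed in a cohort when it passes the same 10%
prevalence rule restricted to that cohort and condition — one criterion for
candidate filtering and breadth, by design, so the two stages cannot
disagree about what "expressed" means. Expressed in exactly 1 of the
configured cohorts ⇒ tissue-specific; in all ⇒ ubiquitous; otherwise other.
Features expressed nowhere are excluded from classification and reported
separately. Tumor and normal panels are classified independently.
Percentages in summary tables are rounded half-up (2 decimals for the
regulated-vs-ubiquitous cross-tabulation, 1 for cohort SNP shares) to match
conventional reporting.

## Enhancer–target linkage

Candidates: gene promoter overlaps the ±`link_window` (100 kb) region around
the enhancer center, half-open semantics throughout, found via an interval
tree and verified in tests against a quadratic all-pairs oracle. The
coexpression screen uses Spearman correlation over the cohort's tumor
samples (`link_samples: all` pools tumor + normal instead; tumor-only is the
default because linkage is asked about the tumor state). The screen is
one-sided positive (ρ ≥ 0.3) — enhancers are modeled as positive regulators —
with `corr_mode: abs` available. P-values: exact permutation enumeration for
n ≤ 10 samples, t approximation with n − 2 df above; BH across all candidate
pairs of one cohort. Pairs with zero rank variance (e.g. an all-zero feature
within the cohort) have no defined rank correlation and are dropped with a
logged count.

The regulated/nonregulated comparison uses a two-sided Wilcoxon rank-sum
test on per-enhancer mean tumor expression; expression values are heavily
right-skewed and the rank test needs no distributional assumption. Identical
constant groups return p = 1 by convention.

## Over-representation

Exact hypergeometric upper tail P(X ≥ k) (scipy's log-space survival
function; validated in tests against exact rational arithmetic and literal
draw enumeration), BH across the sets that intersect the universe. The
universe defaults to the genes passing the candidate prevalence filter —
testable genes, not the whole annotation — matching standard ORA practice;
callers can pass any universe.

## Allele-specific TFBS scoring

PFM counts become probabilities with a pseudocount (default 0.8) distributed
by the background composition; scores are log2(p/background) sums over a
window. For a SNP at offset i, every window of length L with offset in
[i−L+1, i] on either strand is scored (the reverse strand via the
reverse-complemented matrix), and the best window score is retained per
allele. Windows containing ambiguous bases are skipped and logged; zero
probability cells are floored at −60 bits so they can never win.

Significance: the exact distribution of a single window score under the
background model, obtained by convolving per-column score distributions
with column scores rounded to a `score_granularity` = 10⁻³-bit grid (≤ L/2
grid cells of end-to-end rounding, i.e. ≤ 0.015 bits at L = 30; the
exhaustive-enumeration tests use exactly this slack). The tail function is
monotone non-increasing, total mass 1 within 10⁻⁹, and PWMs up to length 30
are supported before the grid refuses and suggests a coarser granularity.

A binding call is "best SNP-overlapping window has tail probability ≤
`tfbs_p_max`" (default 10⁻⁴) for one allele. Gain = the alternate allele
calls and the reference does not; loss = the reverse; everything else is
retained as unchanged. This per-allele exact scheme is a deliberate design:
it is simpler than importance-sampled score-change p-values, exactly
testable by enumeration, and antisymmetric under allele swap by
construction. SNPs mapping into several (extended, ±0.5 kb) enhancers
produce independent event rows. Reported summaries count distinct TFs with
gain or loss per SNP, per enhancer and overall, plus per-cohort SNP shares
when the SNP table carries a cohort column.

## Synthetic data generator

The generator emulates the *structure* of the real study — 13 paired
tumor/normal cohorts (default labels are TCGA-style codes), RPKM-like
continuous non-negative expression, enhancer/TSS geometry on synthetic
chromosomes, eQTL-style SNPs with cohort labels, motif models and gene
sets — with planted, recoverable effects:

- **Noise model:** values are log-normal, exp(meanlog + sdlog·z) with
  meanlog 1.0 and sdlog 1.0 (median ~2.7, long right tail — the shape of
  RPKM data; a count model would be wrong for a continuous input). Random
  dropout (probability 0.2 per cell) sets values to zero.
- **DE:** a fraction (0.1) of features is DE with tumor mean scaled by
  2^(±2). Dropout rescales both group means equally, so the planted log2FC
  is preserved in expectation. Planted DE features are shared across cohorts
  (same sign everywhere); the truth object still records per-cohort sets.
- **Linked pairs:** 5% of enhancers are paired with one distance-eligible
  gene each; the pair's latent Gaussians share a factor with Pearson
  correlation 2·sin(π·ρ/6) so the *rank* correlation of the generated
  values is the requested ρ (default 0.6). Dropout is not applied to these
  features: zeroing 20% of each member's values would collapse the realized
  Spearman correlation to ≈0.24 and break the generator's contract of
  delivering pairs at ρ. Linked features are planted DE first, so pairs are
  discoverable by the DE→linkage chain.
- **Gene sets:** random sets plus one set seeded with half of the planted
  linked genes.
- **SNPs:** loss SNPs embed a motif consensus and mutate its most
  informative position to the least-favoured base; gain SNPs embed the
  1-mismatch motif so the alternate allele restores the consensus; neutral
  SNPs sit at least one motif length from any embedded motif. Generated
  motifs are 8–9 bp with a 0.9-dominant base per column: a single-base
  change can only flip a p ≤ 10⁻⁴ binding call when the consensus sits near
  that threshold, which bounds the usable motif information — the generator
  deliberately emulates compact core motifs in that regime and refuses
  motifs where the construction cannot work.

Everything is deterministic for a fixed seed (one `default_rng` per
generator, child seeds spawned via `SeedSequence`).

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: tissue-specific baseline expression (every
synthetic feature is expressed in all cohorts, so the breadth spectrum of
real enhancers, where most features are ubiquitous but a visible minority is
tissue-specific, collapses to "all ubiquitous"; breadth logic is instead
tested on constructed matrices), batch effects and cohort-size imbalance,
copy-number confounding of expression, linkage disequilibrium among SNPs,
and any built-in expression difference between regulated and nonregulated
enhancers (the rank-sum comparison is null on synthetic data and its
calibration, not its effect size, is what is tested).

## Benchmarks and calibration

`enhancerlink.evaluation` scores the stages against planted truth. Problem
sizes were chosen for estimate precision at desk scale: the recovery study
uses 500 enhancers / 1000 genes over 13 cohorts of 50+50 samples (650
planted enhancer-cohort DE events, binomial se ≈ 0.01); link recovery uses
a second study with 100 tumor samples per cohort because correlation power
is pinned to n = 100 while DE power is pinned to n = 50/50 — one study
cannot hold both sample sizes. Link recovery feeds the linkage stage from
the planted DE lists, isolating the distance + coexpression screen from DE
calling errors. Measured at the packaged seeds: DE enhancer sensitivity
0.915 at empirical FDR 0.018 (gene-class sensitivity is 0.861 — genes have
the same per-feature power but a smaller share of dropout-exempt linked
features); link sensitivity 1.00 at FDR 0.00; planted gene-set q ≈ 5·10⁻³⁴;
20/20 disruptive SNPs recovered with 0/20 neutral SNPs misclassified.

Calibration: on null data (no planted effects) the Welch test on log-normal
values is mildly conservative — type-I error 0.042 at nominal 0.05 over
10 000 features, a known property of the t reference distribution under
heavy skew at n = 50 — and the rank-sum comparison rejects at 0.047 over
1000 null simulations.

## Known limitations

- The t-test on raw RPKM values is not the most powerful choice under
  log-normal noise (a log-scale test would be, absent dropout); it is kept
  because it is the field's convention for this analysis type.
- Exact Spearman permutation p-values are enumerated up to n = 10
  (3.6 M permutations, chunked); above that the t approximation is used.
- The TFBS null is per single window; no correction for the number of
  windows scanned per SNP is applied, matching the per-allele call design.
- LiftOver, survival analysis, Hi-C-based target assignment and live
  pathway-database access are out of scope by design.
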