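# enhancerlink

Enhancers transcribe short enhancer RNAs (eRNAs) whose abundance tracks
enhancer activity, so tumor/normal eRNA expression matrices can be mined the
same way gene expression is. `enhancerlink` implements a pan-cancer enhancer
analysis over paired tumor/normal cohorts: it calls differentially expressed
(DE) enhancers and genes, classifies how broadly each enhancer is expressed
across cancer types, links DE enhancers to DE target genes by genomic
distance plus coexpression, tests the linked genes for gene-set
over-representation, and scores SNPs inside DE enhancers for allele-specific
gain or loss of transcription-factor binding sites (TFBS). It is written for
regulatory-genomics analysts who have FANTOM-style enhancer coordinates,
RPKM-scale expression matrices, and eQTL-style SNP tables, and want the whole
chain as a tested, reproducible library instead of a one-off script stack.

## The statistics at the core

**Differential expression.** Within a cohort, a feature is testable when it
is expressed (value > 0) in at least 10% of tumor or of normal samples. With
group means x̄_t, x̄_n and pseudocount c = 0.01,

    log2FC = log2((x̄_t + c) / (x̄_n + c)),

p from a two-sided Welch t-test, q by Benjamini–Hochberg within cohort and
feature class; DE requires |log2FC| ≥ 1 and q < 0.05.

**Target linkage.** A DE gene is a candidate target of a DE enhancer when its
promoter — TSS −0.5 kb to +1 kb, strand-aware — overlaps the ±100 kb window
around the enhancer center (all intervals 0-based half-open). Candidates are
screened by Spearman correlation over the cohort's tumor samples at
ρ ≥ 0.3 with BH q < 0.05 across the cohort's candidate pairs; the p-value is
an exact permutation tail for n ≤ 10 and the t approximation with n−2 df
otherwise. DE enhancers with ≥ 1 link are "regulated"; regulated vs
nonregulated expression is compared with a two-sided Wilcoxon rank-sum test.

**Over-representation.** For a query of n genes in a universe of N
containing a set of K, the enrichment p-value is the exact hypergeometric
upper tail P(X ≥ k), BH-corrected across sets.

**Allele-specific TFBS scoring.** Each SNP×motif pair is scored by the best
log2-odds PWM window over both strands among all windows covering the SNP,
once per allele. Significance comes from the exact distribution of the
single-window score under the background model, computed by per-position
convolution on a 10⁻³-bit grid. A site is *gained* when only the alternate
allele's best window is significant at p ≤ 10⁻⁴, *lost* in the mirror case.

A synthetic-data module generates 13-cohort tumor/normal studies with
planted DE features, planted enhancer–gene correlations (Gaussian copula,
sine transform to target Spearman ρ), a planted enriched gene set, and
motif-disrupting SNPs, so the whole pipeline is testable offline.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
```

which prints, for the packaged study (seed 7, 13 cohorts, 50 tumor + 50
normal samples each, 500 enhancers, 1000 genes):

```
enhancers: 606 DE calls across cohorts (319 up, 287 down); 61 unique DE enhancers of 500 candidates
genes: 1145 DE calls across cohorts (578 up, 567 down); 126 unique DE genes of 1000 candidates
```

606 cohort-level calls collapse to 61 unique enhancers because a feature DE
in several cancers is counted once per cohort; both numbers are reported
throughout. Continuing with `analysis/04_link_targets.py` and
`analysis/05_enrichment.py`:

```
298 links from 466 candidate pairs; 28 unique linked DE genes
planted set 'pathway_14': k=26/50, q=4.9e-34
```

i.e. 298 enhancer–gene pairs survive the distance + coexpression screen, and
the gene set seeded with linked genes is recovered with overwhelming
significance. `analysis/06_snp_tfbs.py` then maps SNPs into the DE
enhancers and reports per-SNP gain/loss TF counts, and
`analysis/07_benchmark.py` scores every stage against the planted truth
(DE enhancer sensitivity 0.915 at empirical FDR 0.018; link sensitivity 1.00
at n = 100; 100% of planted disruptive SNPs recovered).

The same stages are available as a CLI (`enhancerlink simulate | de |
breadth | link | enrich | snp-tfbs | run-all`); `run-all` drives everything
from one flat config file and writes a manifest with input checksums so
reruns are byte-identical.

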