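#!/usr/bin/env python
"""Generate the synthetic 13-cohort tumor/normal study used by the analysis.

Writes enhancer BED, TSS table, sample sheet, expression matrices, SNP
table, motif PFMs, gene sets, enhancer sequences and the ground-truth JSON
under results/simdata/.
"""

from pathlib import Path

from enhancerlink.simulate import generate_dataset

OUT = Path("results/simdata")
SEED = 7

ds = generate_dataset(OUT, seed=SEED, n_genes=1000, n_enhancers=500)
truth = ds["truth"]
print(f"wrote synthetic study to {OUT} (seed {SEED})")
print(f"  {len(ds['enhancers'])} enhancers, {len(ds['genes'])} genes, "
      f"{ds['sheet']['tissue'].nunique()} cohorts, "
      f"{len(ds['sheet'])} samples")
print(f"  planted per cohort: {len(truth.de_enhancers['BLCA'])} DE enhancers, "
      f"{len(truth.de_genes['BLCA'])} DE genes")
print(f"  planted: {len(truth.linked_pairs)} enhancer-gene pairs (rho 0.6), "
      f"enriched set {truth.enriched_set_name!r}, "
      f"{len(truth.disruptive_snps)} disruptive + {len(truth.neutral_snp_ids)} neutral SNPs")
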