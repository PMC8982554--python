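#!/usr/bin/env python
"""Score SNPs inside extended DE enhancers for TFBS gain/loss.

SNPs are mapped into DE enhancer regions extended by 0.5 kb on each side;
each mapped SNP is scored against every motif (best log-odds window over
both strands, ref vs alt allele) with exact background p-values; a binding
call flipping between alleles is a gain or loss event.
"""

from pathlib import Path

import pandas as pd

from enhancerlink import io as elio
from enhancerlink.config import PipelineConfig
from enhancerlink.simulate import SimulationTruth
from enhancerlink.tfbs import classify_all, map_snps, summarize_events

SIM = Path("results/simdata")
OUT = Path("results/06_tfbs")
OUT.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()
enhancers = elio.read_enhancer_bed(SIM / "enhancers.bed")
snps, snp_cohorts = elio.read_snp_table(SIM / "snps.tsv")
pwms = elio.read_pfm(SIM / "motifs.pfm", pseudocount=cfg.pfm_pseudocount)
sequences = elio.read_sequences_fasta(SIM / "enhancer_sequences.fa")
de_e = pd.read_csv("results/02_de/de_enhancers.tsv", sep="\t")
de_ids = set(de_e.loc[de_e["call"] != "ns", "feature_id"])
de_enhancers = [e for e in enhancers if e.id in de_ids]

mapped = map_snps(snps, de_enhancers, cfg)
events = classify_all(mapped, sequences, pwms, cfg)
elio.write_records_tsv(events, OUT / "tfbs_events.tsv")
summary = summarize_events(events, snp_cohorts=snp_cohorts)
elio.write_records_tsv(summary["per_snp"], OUT / "tfbs_per_snp.tsv")
elio.write_records_tsv(summary["per_enhancer"], OUT / "tfbs_per_enhancer.tsv")

print(f"{len({s.rs_id for s, _ in mapped})} of {len(snps)} SNPs map into "
      f"{len({e for _, e in mapped})} extended DE enhancers")
print(f"{summary['n_affected_tfs']} TFs gain or lose a binding site across "
      f"{summary['n_snps_with_effect']} SNPs "
      f"({(events['classification'] == 'gain').sum()} gain / "
      f"{(events['classification'] == 'loss').sum()} loss events)")
if "cohort_proportions" in summary:
    elio.write_records_tsv(summary["cohort_proportions"],
                           OUT / "snp_cohort_proportions.tsv")
    top = summary["cohort_proportions"].iloc[0]
    print(f"most-affected cohort: {top['cohort']} "
          f"({int(top['n_snps'])} SNPs, {top['percent']}%)")

truth = SimulationTruth.from_json(SIM / "truth.json")
by_key = {(r.rs_id, r.tf_name): r.classification for r in events.itertuples(index=False)}
scored = [(rs, tf, exp) for rs, tf, exp in truth.disruptive_snps if (rs, tf) in by_key]
correct = sum(1 for rs, tf, exp in scored if by_key[(rs, tf)] == exp)
print(f"planted disruptive SNPs inside DE enhancers: {correct}/{len(scored)} "
      "called as planted")
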