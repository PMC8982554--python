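#!/usr/bin/env python
"""Link DE enhancers to DE target genes and partition them.

For each cohort, a DE gene whose promoter (TSS -0.5 kb / +1 kb) falls inside
the +/-100 kb window around a DE enhancer's center is a candidate target;
candidates are screened at Spearman corr >= 0.3, BH q < 0.05 over the
cohort's tumor samples. Enhancers with >= 1 surviving link are "regulated";
their expression is compared with the nonregulated group (Wilcoxon
rank-sum), and the regulated set is cross-tabulated against breadth.
"""

from pathlib import Path

import pandas as pd

from enhancerlink import io as elio
from enhancerlink.breadth import cross_tabulate_breadth_vs_regulation
from enhancerlink.config import PipelineConfig
from enhancerlink.linking import (candidate_pairs, compare_regulated_vs_nonregulated,
                                  link_targets, partition_regulated)

SIM = Path("results/simdata")
OUT = Path("results/04_links")
OUT.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()
sheet = elio.read_sample_sheet(SIM / "samples.tsv")
expr_e = elio.read_expression_tsv(SIM / "enhancer_expression.tsv")
expr_g = elio.read_expression_tsv(SIM / "gene_expression.tsv")
genes = elio.read_gene_table(SIM / "genes.tsv")
enhancers = {e.id: e for e in elio.read_enhancer_bed(SIM / "enhancers.bed")}
de_e = pd.read_csv("results/02_de/de_enhancers.tsv", sep="\t")
de_g = pd.read_csv("results/02_de/de_genes.tsv", sep="\t")

link_frames, part_rows, cmp_rows = [], [], []
for cohort in sorted(sheet["tissue"].unique()):
    e_ids = sorted(de_e.loc[(de_e["cohort"] == cohort) & (de_e["call"] != "ns"),
                            "feature_id"])
    g_ids = de_g.loc[(de_g["cohort"] == cohort) & (de_g["call"] != "ns"),
                     "feature_id"].tolist()
    cand = candidate_pairs([enhancers[i] for i in e_ids], g_ids, genes, cfg)
    links = link_targets(cand, expr_e, expr_g, sheet, cohort, cfg)
    link_frames.append(links)
    regulated, nonregulated = partition_regulated(e_ids, links)
    part_rows += [(cohort, i, "regulated") for i in regulated]
    part_rows += [(cohort, i, "nonregulated") for i in nonregulated]
    if regulated and nonregulated:
        cmp_rows.append(compare_regulated_vs_nonregulated(
            expr_e, regulated, nonregulated, sheet, cohort))

links = pd.concat([f for f in link_frames if not f.empty], ignore_index=True)
partition = pd.DataFrame(part_rows, columns=["cohort", "enhancer_id", "group"])
comparison = pd.DataFrame(cmp_rows)
elio.write_records_tsv(links, OUT / "links.tsv")
elio.write_records_tsv(partition, OUT / "partition.tsv")
elio.write_records_tsv(comparison, OUT / "regulated_vs_nonregulated.tsv")

n_links = int(links["linked"].sum())
print(f"{n_links} links from {len(links)} candidate pairs; "
      f"{links.loc[links['linked'], 'gene_id'].nunique()} unique linked DE genes")
print(f"partition: {(partition['group'] == 'regulated').sum()} regulated / "
      f"{(partition['group'] == 'nonregulated').sum()} nonregulated DE enhancer calls")
if not comparison.empty:
    sig = (comparison["p"] < 0.05).sum()
    print(f"regulated vs nonregulated expression: p < 0.05 in "
          f"{sig} of {len(comparison)} comparable cohorts")

breadth = pd.read_csv("results/03_breadth/breadth.tsv", sep="\t")
tumor_breadth = breadth[breadth["condition"] == "tumor"]
regulated_ids = sorted(set(partition.loc[partition["group"] == "regulated",
                                         "enhancer_id"])
                       & set(tumor_breadth["feature_id"]))
if regulated_ids:
    num, den, pct = cross_tabulate_breadth_vs_regulation(tumor_breadth, regulated_ids)
    elio.write_records_tsv(pd.DataFrame([{"n_regulated_ubiquitous": num,
                                          "n_regulated": den,
                                          "percent_ubiquitous": pct}]),
                           OUT / "regulated_breadth_crosstab.tsv")
    print(f"{num} of {den} regulated DE enhancers are ubiquitous ({pct}%)")
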