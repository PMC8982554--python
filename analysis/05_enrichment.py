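#!/usr/bin/env python
"""Gene-set over-representation of the linked DE genes.

Query = genes linked to a DE enhancer in any cohort; universe = genes
passing the candidate prevalence filter in any cohort; statistic = exact
upper-tail hypergeometric with BH across sets.
"""

from pathlib import Path

import pandas as pd

from enhancerlink import io as elio
from enhancerlink.config import PipelineConfig
from enhancerlink.de import filter_candidates
from enhancerlink.enrichment import run_enrichment
from enhancerlink.simulate import SimulationTruth

SIM = Path("results/simdata")
OUT = Path("results/05_enrichment")
OUT.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()
sheet = elio.read_sample_sheet(SIM / "samples.tsv")
expr_g = elio.read_expression_tsv(SIM / "gene_expression.tsv")
gene_sets = elio.read_gmt(SIM / "gene_sets.gmt")
links = pd.read_csv("results/04_links/links.tsv", sep="\t")

universe: set = set()
for cohort in sorted(sheet["tissue"].unique()):
    universe.update(filter_candidates(expr_g, sheet, cohort, cfg))
query = sorted(links.loc[links["linked"], "gene_id"].unique())

records = run_enrichment(query, gene_sets, sorted(universe), cfg)
elio.write_records_tsv(records, OUT / "enrichment.tsv")

sig = records[records["significant"]]
print(f"query {len(query)} linked DE genes against {len(records)} sets "
      f"(universe {len(universe)}): {len(sig)} significant at q < 0.05")
truth = SimulationTruth.from_json(SIM / "truth.json")
row = records[records["set_name"] == truth.enriched_set_name]
if not row.empty:
    print(f"planted set {truth.enriched_set_name!r}: "
          f"k={int(row['k'].iloc[0])}/{int(row['K'].iloc[0])}, "
          f"q={row['q'].iloc[0]:.3g}")
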