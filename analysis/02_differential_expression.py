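#!/usr/bin/env python
"""Call differentially expressed enhancers and genes per cohort.

For every cohort, features expressed in >= 10% of tumor or normal samples
are tested (Welch t on RPKM-scale values, BH within cohort x feature class)
and called DE at |log2FC| >= 1, q < 0.05. Reports both per-cohort call
multiplicities and unique-feature counts, which differ whenever a feature
is DE in several cohorts.
"""

from pathlib import Path

import pandas as pd

from enhancerlink import io as elio
from enhancerlink.config import PipelineConfig
from enhancerlink.de import call_de

SIM = Path("results/simdata")
OUT = Path("results/02_de")
OUT.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()
sheet = elio.read_sample_sheet(SIM / "samples.tsv")
for label, path in (("enhancer", "enhancer_expression.tsv"),
                    ("gene", "gene_expression.tsv")):
    expr = elio.read_expression_tsv(SIM / path)
    records = pd.concat([call_de(expr, sheet, c, cfg)
                         for c in sorted(sheet["tissue"].unique())],
                        ignore_index=True)
    elio.write_records_tsv(records, OUT / f"de_{label}s.tsv")
    calls = records[records["call"] != "ns"]
    print(f"{label}s: {len(calls)} DE calls across cohorts "
          f"({(calls['call'] == 'up').sum()} up, {(calls['call'] == 'down').sum()} down); "
          f"{calls['feature_id'].nunique()} unique DE {label}s "
          f"of {records['feature_id'].nunique()} candidates")
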