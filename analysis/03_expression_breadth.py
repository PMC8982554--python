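#!/usr/bin/env python
"""Classify enhancer expression breadth across the 13 cohorts.

An enhancer is tissue-specific when expressed (>= 10% prevalence) in exactly
one cohort, ubiquitous when expressed in all, other in between; tumor and
normal panels are classified separately.
"""

from pathlib import Path

import pandas as pd

from enhancerlink import io as elio
from enhancerlink.breadth import breadth_distribution, expression_breadth
from enhancerlink.config import PipelineConfig

SIM = Path("results/simdata")
OUT = Path("results/03_breadth")
OUT.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()
sheet = elio.read_sample_sheet(SIM / "samples.tsv")
expr = elio.read_expression_tsv(SIM / "enhancer_expression.tsv")
n_cohorts = sheet["tissue"].nunique()

frames, dist_rows = [], []
for condition in ("tumor", "normal"):
    records, unexpressed = expression_breadth(expr, sheet, cfg, condition)
    frames.append(records)
    cat, counts = breadth_distribution(records, n_cohorts=n_cohorts)
    for n, prop in counts.items():
        dist_rows.append((condition, n, prop))
    print(f"{condition}: {len(records)} enhancers classified "
          f"({len(unexpressed)} expressed nowhere); "
          f"tissue-specific {cat['tissue_specific']:.1%}, "
          f"other {cat['other']:.1%}, ubiquitous {cat['ubiquitous']:.1%}")

elio.write_records_tsv(pd.concat(frames, ignore_index=True), OUT / "breadth.tsv")
elio.write_records_tsv(pd.DataFrame(dist_rows,
                                    columns=["condition", "n_cohorts_expressed",
                                             "proportion"]),
                       OUT / "breadth_distribution.tsv")
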