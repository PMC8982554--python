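"""Gene-set over-representation analysis (hypergeometric upper tail).

The query (linked DE genes) is intersected with the universe (genes passing
the candidate prevalence filter, by default); each gene set is likewise
intersected; the enrichment p-value is the exact upper-tail hypergeometric
probability P(X >= k) of drawing at least k set members in a query of size n
from a universe of size N containing K members, followed by BH across sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .config import PipelineConfig
from .de import bh_adjust
from .errors import ValidationError
from .records import GeneSet

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["set_name", "k", "K", "n", "N", "p", "q", "significant"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeom(N, K, n), computed in log
    space via the survival function."""
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    if K > N or n > N:
        raise ValidationError("need K <= N and n <= N")
    if k > min(K, n):
        raise ValidationError("need k <= min(K, n)")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def run_enrichment(query: Iterable[str], gene_sets: Sequence[GeneSet],
                   universe: Iterable[str], cfg: PipelineConfig) -> pd.DataFrame:
    """One record per gene set with non-empty universe intersection, BH across
    retained sets, sorted by (q, p, set_name)."""
    uni = set(universe)
    q_genes = set(query) & uni
    if not q_genes:
        raise ValidationError("query is empty after intersection with the universe")
    rows = []
    for gs in gene_sets:
        members = gs.members & uni
        if not members:
            logger.info("gene set %s dropped: no overlap with universe", gs.name)
            continue
        k = len(q_genes & members)
        rows.append((gs.name, k, len(members), len(q_genes), len(uni),
                     hypergeom_upper(k, len(members), len(q_genes), len(uni))))
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < cfg.q_max
    return df.sort_values(["q", "p", "set_name"]).reset_index(drop=True)
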