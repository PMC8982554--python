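"""Expression-breadth classification across cohorts.

A feature counts as expressed in a cohort (for one condition, tumor or
normal) when it passes the same prevalence rule used for candidate
filtering, restricted to that cohort's samples of that condition. Features
expressed in exactly one cohort are tissue-specific, in all cohorts
ubiquitous, otherwise other; features expressed nowhere are excluded from
classification and reported separately.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .de import _prevalent, cohort_samples
from .errors import ValidationError

BREADTH_COLUMNS = ["feature_id", "condition", "n_expressed", "category"]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (matches printed-percentage style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_breadth(n_expressed: int, n_cohorts: int) -> str:
    if not (1 <= n_expressed <= n_cohorts):
        raise ValidationError("classified features need 1 <= n_expressed <= n_cohorts")
    if n_expressed == 1:
        return "tissue_specific"
    if n_expressed == n_cohorts:
        return "ubiquitous"
    return "other"


def expression_breadth(expr: pd.DataFrame, sheet: pd.DataFrame, cfg: PipelineConfig,
                       condition: str) -> tuple[pd.DataFrame, list[str]]:
    """Classify every feature's breadth for one condition.

    Returns (records, unexpressed_ids): records hold the features expressed
    in >= 1 cohort; unexpressed_ids are the rest.
    """
    if condition not in ("tumor", "normal"):
        raise ValidationError(f"unknown condition {condition!r}")
    cohorts = sorted(sheet["tissue"].unique())
    if len(cohorts) < 2:
        raise ValidationError("breadth classification needs >= 2 cohorts")
    expressed = np.zeros(len(expr), dtype=int)
    for cohort in cohorts:
        ids = cohort_samples(sheet, cohort, condition)
        if not ids:
            raise ValidationError(f"cohort {cohort!r} has no {condition} samples")
        expressed += _prevalent(expr[ids].to_numpy(), cfg.expressed_threshold, cfg.prevalence_min)
    mask = expressed >= 1
    records = pd.DataFrame({
        "feature_id": expr.index[mask],
        "condition": condition,
        "n_expressed": expressed[mask],
        "category": [classify_breadth(n, len(cohorts)) for n in expressed[mask]],
    }, columns=BREADTH_COLUMNS)
    unexpressed = expr.index[~mask].tolist()
    return records.reset_index(drop=True), unexpressed


def breadth_distribution(records: pd.DataFrame,
                         n_cohorts: int | None = None) -> tuple[pd.Series, pd.Series]:
    """Per-category and per-count proportions; each sums to 1."""
    if records.empty:
        raise ValidationError("breadth_distribution needs >= 1 record")
    if n_cohorts is None:
        n_cohorts = int(records["n_expressed"].max())
    total = len(records)
    cat = records["category"].value_counts() / total
    cat = cat.reindex(["tissue_specific", "other", "ubiquitous"], fill_value=0.0)
    counts = records["n_expressed"].value_counts() / total
    counts = counts.reindex(range(1, n_cohorts + 1), fill_value=0.0).sort_index()
    return cat, counts


def cross_tabulate_breadth_vs_regulation(records: pd.DataFrame,
                                         regulated_ids) -> tuple[int, int, float]:
    """How many regulated DE enhancers are ubiquitously expressed.

    Returns (numerator, denominator, percentage); the percentage is rounded
    half-up to 2 decimals (3662 of 4540 -> 80.66).
    """
    regulated = list(dict.fromkeys(regulated_ids))
    known = set(records["feature_id"])
    missing = [r for r in regulated if r not in known]
    if missing:
        raise ValidationError(f"regulated ids missing from breadth records: {missing[:5]}")
    ubiq = set(records.loc[records["category"] == "ubiquitous", "feature_id"])
    numerator = sum(1 for r in regulated if r in ubiq)
    denominator = len(regulated)
    if denominator == 0:
        raise ValidationError("no regulated enhancers supplied")
    pct = round_half_up(100.0 * numerator / denominator, 2)
    return numerator, denominator, pct
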