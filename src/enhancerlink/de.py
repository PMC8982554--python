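"""Prevalence filtering and tumor-vs-normal differential expression calling.

Within one cohort, a feature is a candidate when it is expressed (value
strictly above ``expressed_threshold``) in at least ``prevalence_min`` of the
tumor samples or of the normal samples. For each candidate the group means
give log2FC = log2((mean_t + c) / (mean_n + c)), a two-sided t-test (Welch by
default) gives p, and Benjamini-Hochberg within the cohort x feature-class
family gives q. A feature is called up when log2FC >= log2fc_min and
q < q_max, down when log2FC <= -log2fc_min and q < q_max, otherwise ns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import ValidationError

DE_COLUMNS = ["feature_id", "cohort", "mean_tumor", "mean_normal", "log2fc", "p", "q", "call"]


def cohort_samples(sheet: pd.DataFrame, cohort: str, condition: str) -> list[str]:
    sub = sheet[(sheet["tissue"] == cohort) & (sheet["condition"] == condition)]
    return sub["sample_id"].tolist()


def _prevalent(values: np.ndarray, threshold: float, prevalence_min: float) -> np.ndarray:
    """Row mask: expressed in at least prevalence_min of the columns.

    The boundary is inclusive (1 of 10 samples passes at 10%); a small
    epsilon guards against float rounding of count/n.
    """
    n = values.shape[1]
    counts = (values > threshold).sum(axis=1)
    return counts + 1e-9 >= prevalence_min * n


def filter_candidates(expr: pd.DataFrame, sheet: pd.DataFrame, cohort: str,
                      cfg: PipelineConfig) -> list[str]:
    """Feature ids expressed in >= prevalence_min of tumor OR normal samples."""
    t_ids = cohort_samples(sheet, cohort, "tumor")
    n_ids = cohort_samples(sheet, cohort, "normal")
    if not t_ids or not n_ids:
        raise ValidationError(f"cohort {cohort!r} has no tumor or no normal samples")
    keep = (_prevalent(expr[t_ids].to_numpy(), cfg.expressed_threshold, cfg.prevalence_min)
            | _prevalent(expr[n_ids].to_numpy(), cfg.expressed_threshold, cfg.prevalence_min))
    return expr.index[keep].tolist()


def log2_fold_change(mean_t, mean_n, pseudocount: float):
    """log2((mean_t + c) / (mean_n + c)); antisymmetric under group swap."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    mt = np.asarray(mean_t, dtype=float)
    mn = np.asarray(mean_n, dtype=float)
    if np.any(mt < 0) or np.any(mn < 0):
        raise ValidationError("group means must be >= 0")
    out = np.log2((mt + pseudocount) / (mn + pseudocount))
    return float(out) if out.ndim == 0 else out


def welch_t_test(x, y, equal_var: bool = False) -> float:
    """Two-sided t-test p-value (Welch-Satterthwaite by default).

    Conventions for degenerate input: both groups constant and equal -> p = 1;
    both constant and unequal -> p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t-test needs >= 2 samples per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    return float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def _t_test_matrix(xs: np.ndarray, ys: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided t-test with the same degenerate-input conventions
    as :func:`welch_t_test`."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(xs, ys, axis=1, equal_var=equal_var).pvalue
    p = np.asarray(p, dtype=float)
    flat = (np.ptp(xs, axis=1) == 0) & (np.ptp(ys, axis=1) == 0)
    if flat.any():
        equal = xs[:, 0] == ys[:, 0]
        p[flat & equal] = 1.0
        p[flat & ~equal] = 0.0
    return p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(expr: pd.DataFrame, sheet: pd.DataFrame, cohort: str, cfg: PipelineConfig,
            candidates: list[str] | None = None) -> pd.DataFrame:
    """Differential-expression records for one cohort.

    ``candidates`` defaults to :func:`filter_candidates`; q-values are BH
    within this call (one cohort, one feature class).
    """
    if candidates is None:
        candidates = filter_candidates(expr, sheet, cohort, cfg)
    t_ids = cohort_samples(sheet, cohort, "tumor")
    n_ids = cohort_samples(sheet, cohort, "normal")
    if len(t_ids) < 2 or len(n_ids) < 2:
        raise ValidationError(f"cohort {cohort!r} needs >= 2 tumor and >= 2 normal samples")
    sub = expr.loc[candidates]
    xs = sub[t_ids].to_numpy(dtype=float)
    ys = sub[n_ids].to_numpy(dtype=float)
    if xs.shape[0] == 0:
        return pd.DataFrame(columns=DE_COLUMNS)
    mean_t = xs.mean(axis=1)
    mean_n = ys.mean(axis=1)
    lfc = log2_fold_change(mean_t, mean_n, cfg.pseudocount)
    p = _t_test_matrix(xs, ys, equal_var=(cfg.t_test == "student"))
    q = bh_adjust(p)
    call = np.where((lfc >= cfg.log2fc_min) & (q < cfg.q_max), "up",
                    np.where((lfc <= -cfg.log2fc_min) & (q < cfg.q_max), "down", "ns"))
    return pd.DataFrame({
        "feature_id": candidates,
        "cohort": cohort,
        "mean_tumor": mean_t,
        "mean_normal": mean_n,
        "log2fc": lfc,
        "p": p,
        "q": q,
        "call": call,
    }, columns=DE_COLUMNS)


def de_feature_ids(de_records: pd.DataFrame) -> list[str]:
    """Feature ids called up or down, in record order."""
    mask = de_records["call"] != "ns"
    return de_records.loc[mask, "feature_id"].tolist()
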