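"""Enhancer-to-target-gene linkage by genomic distance plus coexpression.

A DE gene is a candidate target of a DE enhancer when its strand-aware
promoter overlaps the +/-100 kb window around the enhancer center. Candidate
pairs are screened by Spearman correlation across the cohort's (tumor, by
default) samples at corr >= 0.3 with BH q < 0.05 across all of the cohort's
candidate pairs. DE enhancers with at least one surviving link are
"regulated", the rest "nonregulated"; the two groups' expression levels are
compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .config import PipelineConfig
from .de import bh_adjust, cohort_samples
from .errors import ValidationError
from .intervals import Enhancer, GeneAnnotation, enhancer_window, promoter_region

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["enhancer_id", "gene_id", "cohort", "distance", "rho", "p", "q", "linked"]


def candidate_pairs(de_enhancers: Sequence[Enhancer], de_gene_ids: Iterable[str],
                    annotations: Sequence[GeneAnnotation], cfg: PipelineConfig) -> pd.DataFrame:
    """Distance-eligible (enhancer, gene) pairs for one cohort's DE features.

    Emitted iff the gene promoter overlaps the enhancer window (half-open
    semantics). DE genes without an annotation are skipped with a warning.
    Rows are sorted by (enhancer_id, distance, gene_id).
    """
    ann = {g.id: g for g in annotations}
    trees: dict[str, IntervalTree] = {}
    tss: dict[str, int] = {}
    n_missing = 0
    for gid in de_gene_ids:
        gene = ann.get(gid)
        if gene is None:
            logger.warning("no annotation for DE gene %s; skipped", gid)
            n_missing += 1
            continue
        prom = promoter_region(gene, cfg)
        trees.setdefault(prom.chrom, IntervalTree()).addi(prom.start, prom.end, gid)
        tss[gid] = gene.tss
    if n_missing:
        logger.warning("%d DE genes lacked annotations", n_missing)
    rows = []
    for e in de_enhancers:
        win = enhancer_window(e, cfg)
        tree = trees.get(win.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(win.start, win.end):
            gid = hit.data
            rows.append((e.id, gid, abs(tss[gid] - e.center)))
    df = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "distance"])
    return df.sort_values(["enhancer_id", "distance", "gene_id"]).reset_index(drop=True)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all n! orderings of one rank vector."""
    n = rx.size
    rxc = rx - rx.mean()
    norm = np.linalg.norm(rxc) * np.linalg.norm(ry - ry.mean())
    hits = 0
    total = 0
    chunk: list[tuple] = []

    def flush(chunk):
        nonlocal hits, total
        perms = np.array(chunk, dtype=float)
        rhos = (perms - ry.mean()) @ rxc / norm
        hits += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += len(chunk)

    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return hits / total


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return np.minimum(p, 1.0)


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of midranks (ties allowed). For
    n <= exact_max_n the p-value is the exact permutation tail over all n!
    orderings; for larger n the t approximation with n-2 df is used.
    Raises when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("spearman needs two equal-length vectors, n >= 4")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("zero rank variance: Spearman undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(_t_approx_p(np.array([rho]), n)[0])
    return rho, p


def link_targets(candidates: pd.DataFrame, enh_expr: pd.DataFrame, gene_expr: pd.DataFrame,
                 sheet: pd.DataFrame, cohort: str, cfg: PipelineConfig,
                 exact_max_n: int = 10) -> pd.DataFrame:
    """Screen candidate pairs by coexpression in one cohort.

    Correlations are computed over the cohort's tumor samples (or all of its
    samples with ``link_samples: all``); BH is applied across all of the
    cohort's candidate pairs; ``linked`` follows the corr >= corr_min and
    q < link_q_max rule (|corr| with ``corr_mode: abs``). Pairs whose rank
    variance vanishes are dropped with a logged reason.
    """
    if candidates.empty:
        return pd.DataFrame(columns=LINK_COLUMNS)
    samples = cohort_samples(sheet, cohort, "tumor")
    if cfg.link_samples == "all":
        samples = samples + cohort_samples(sheet, cohort, "normal")
    missing = [s for s in samples if s not in enh_expr.columns or s not in gene_expr.columns]
    if missing:
        raise ValidationError(f"cohort {cohort!r}: samples missing from matrices: {missing[:5]}")
    n = len(samples)
    if n < 4:
        raise ValidationError(f"cohort {cohort!r}: need >= 4 samples for correlation")

    eids = candidates["enhancer_id"].unique().tolist()
    gids = candidates["gene_id"].unique().tolist()
    re_ = stats.rankdata(enh_expr.loc[eids, samples].to_numpy(dtype=float), axis=1)
    rg = stats.rankdata(gene_expr.loc[gids, samples].to_numpy(dtype=float), axis=1)

    def standardize(r: np.ndarray) -> np.ndarray:
        c = r - r.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(c, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            z = c / norm
        z[norm[:, 0] == 0] = np.nan
        return z

    ze = standardize(re_)
    zg = standardize(rg)
    ei = pd.Index(eids).get_indexer(candidates["enhancer_id"])
    gi = pd.Index(gids).get_indexer(candidates["gene_id"])
    rho = np.einsum("ij,ij->i", ze[ei], zg[gi])

    ok = np.isfinite(rho)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("cohort %s: dropped %d pairs with zero rank variance", cohort, n_dropped)
    out = candidates.loc[ok].copy()
    rho = np.clip(rho[ok], -1.0, 1.0)
    if n <= exact_max_n:
        p = np.array([
            spearman(enh_expr.loc[r.enhancer_id, samples], gene_expr.loc[r.gene_id, samples],
                     exact_max_n=exact_max_n)[1]
            for r in out.itertuples(index=False)
        ])
    else:
        p = _t_approx_p(rho, n)
    q = bh_adjust(p)
    screen = np.abs(rho) if cfg.corr_mode == "abs" else rho
    out["cohort"] = cohort
    out["rho"] = rho
    out["p"] = p
    out["q"] = q
    out["linked"] = (screen >= cfg.corr_min) & (q < cfg.link_q_max)
    return out[LINK_COLUMNS].reset_index(drop=True)


def partition_regulated(de_enhancer_ids: Iterable[str],
                        links: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split DE enhancers into regulated (>= 1 link) and nonregulated."""
    ids = list(dict.fromkeys(de_enhancer_ids))
    linked = set(links.loc[links["linked"], "enhancer_id"]) if not links.empty else set()
    regulated = [i for i in ids if i in linked]
    nonregulated = [i for i in ids if i not in linked]
    return regulated, nonregulated


def compare_regulated_vs_nonregulated(enh_expr: pd.DataFrame, regulated: Sequence[str],
                                      nonregulated: Sequence[str], sheet: pd.DataFrame,
                                      cohort: str) -> dict:
    """Two-sided Wilcoxon rank-sum on per-enhancer mean tumor expression."""
    if not len(regulated) or not len(nonregulated):
        raise ValidationError(f"cohort {cohort!r}: both groups must be non-empty")
    samples = cohort_samples(sheet, cohort, "tumor")
    x = enh_expr.loc[list(regulated), samples].mean(axis=1).to_numpy()
    y = enh_expr.loc[list(nonregulated), samples].mean(axis=1).to_numpy()
    if np.ptp(np.concatenate([x, y])) == 0:
        stat, p = 0.0, 1.0
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "cohort": cohort,
        "statistic": stat,
        "p": p,
        "median_regulated": float(np.median(x)),
        "median_nonregulated": float(np.median(y)),
        "n_regulated": len(x),
        "n_nonregulated": len(y),
    }
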