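"""Benchmarking against planted ground truth and statistical calibration.

These helpers run the analysis stages on a synthetic study (see
:mod:`enhancerlink.simulate`) and score the results against its
:class:`~enhancerlink.simulate.SimulationTruth`: sensitivity and empirical
FDR of DE calls and enhancer-gene links, recovery of the planted enriched
gene set, gain/loss classification of planted SNPs, and the type-I error of
the DE caller and the regulated-vs-nonregulated comparison under null data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .de import call_de, de_feature_ids, filter_candidates
from .enrichment import run_enrichment
from .linking import candidate_pairs, compare_regulated_vs_nonregulated, link_targets
from .simulate import TruthSpec, generate_expression, generate_layout, make_sample_sheet
from .tfbs import classify_all, map_snps


def run_synthetic_study(ds: dict, cfg: PipelineConfig) -> dict:
    """DE calling and linkage on a generated dataset, per cohort."""
    sheet = ds["sheet"]
    cohorts = sorted(sheet["tissue"].unique())
    enhancer_by_id = {e.id: e for e in ds["enhancers"]}
    de_enh, de_gene, link_frames = [], [], []
    universe: set[str] = set()
    for cohort in cohorts:
        cand_g = filter_candidates(ds["gene_expression"], sheet, cohort, cfg)
        universe.update(cand_g)
        rec_e = call_de(ds["enhancer_expression"], sheet, cohort, cfg)
        rec_g = call_de(ds["gene_expression"], sheet, cohort, cfg, candidates=cand_g)
        de_enh.append(rec_e)
        de_gene.append(rec_g)
        e_ids = de_feature_ids(rec_e)
        g_ids = de_feature_ids(rec_g)
        cand = candidate_pairs([enhancer_by_id[i] for i in e_ids], g_ids,
                               ds["genes"], cfg)
        if not cand.empty:
            link_frames.append(link_targets(cand, ds["enhancer_expression"],
                                            ds["gene_expression"], sheet, cohort, cfg))
    links = (pd.concat(link_frames, ignore_index=True) if link_frames
             else pd.DataFrame(columns=["enhancer_id", "gene_id", "cohort",
                                        "distance", "rho", "p", "q", "linked"]))
    return {
        "de_enhancers": pd.concat(de_enh, ignore_index=True),
        "de_genes": pd.concat(de_gene, ignore_index=True),
        "links": links,
        "universe": sorted(universe),
    }


def de_recovery(de_records: pd.DataFrame, truth_by_cohort: dict) -> dict:
    """Per-(cohort, feature) sensitivity and empirical FDR of DE calls."""
    calls = de_records[de_records["call"] != "ns"]
    called = {(r.cohort, r.feature_id): r.call for r in calls.itertuples(index=False)}
    hits = total = 0
    truth_keys = set()
    for cohort, planted in truth_by_cohort.items():
        for fid, lfc in planted.items():
            truth_keys.add((cohort, fid))
            want = "up" if lfc > 0 else "down"
            hits += called.get((cohort, fid)) == want
            total += 1
    n_calls = len(called)
    false = sum(1 for key in called if key not in truth_keys)
    return {
        "sensitivity": hits / total if total else float("nan"),
        "fdr": false / n_calls if n_calls else 0.0,
        "n_planted": total,
        "n_calls": n_calls,
    }


def link_recovery(ds: dict, cfg: PipelineConfig) -> dict:
    """Linkage sensitivity/FDR with candidates taken from the planted DE
    lists, isolating the distance + coexpression screen from DE calling."""
    truth = ds["truth"]
    sheet = ds["sheet"]
    enhancer_by_id = {e.id: e for e in ds["enhancers"]}
    planted = {(e, g) for e, g, _ in truth.linked_pairs}
    hits = total = n_linked = false = 0
    for cohort in sorted(sheet["tissue"].unique()):
        de_e = [enhancer_by_id[i] for i in sorted(truth.de_enhancers[cohort])]
        de_g = sorted(truth.de_genes[cohort])
        cand = candidate_pairs(de_e, de_g, ds["genes"], cfg)
        links = link_targets(cand, ds["enhancer_expression"], ds["gene_expression"],
                             sheet, cohort, cfg)
        got = set(zip(links.loc[links["linked"], "enhancer_id"],
                      links.loc[links["linked"], "gene_id"]))
        hits += len(got & planted)
        false += len(got - planted)
        n_linked += len(got)
        total += len(planted)
    return {
        "sensitivity": hits / total if total else float("nan"),
        "fdr": false / n_linked if n_linked else 0.0,
        "n_planted": total,
        "n_links": n_linked,
    }


def enrichment_recovery(study: dict, ds: dict, cfg: PipelineConfig) -> dict:
    """q-value of the planted enriched set given the recovered linked genes."""
    links = study["links"]
    query = sorted(links.loc[links["linked"], "gene_id"].unique())
    res = run_enrichment(query, ds["gene_sets"], study["universe"], cfg)
    row = res[res["set_name"] == ds["truth"].enriched_set_name]
    q = float(row["q"].iloc[0]) if not row.empty else float("nan")
    return {"q_planted": q, "significant": bool(q < cfg.q_max), "n_query": len(query)}


def tfbs_recovery(ds: dict, cfg: PipelineConfig) -> dict:
    """Fraction of planted gain/loss SNPs called as planted, and fraction of
    neutral SNPs with any spurious gain/loss event."""
    truth = ds["truth"]
    mapped = map_snps(ds["snps"], ds["enhancers"], cfg)
    events = classify_all(mapped, ds["sequences"], ds["pwms"], cfg)
    by_key = {(r.rs_id, r.tf_name): r.classification for r in events.itertuples(index=False)}
    correct = 0
    for rs, tf, expected in truth.disruptive_snps:
        correct += by_key.get((rs, tf)) == expected
    flagged = set(events.loc[events["classification"] != "unchanged", "rs_id"])
    neutral_bad = sum(1 for rs in truth.neutral_snp_ids if rs in flagged)
    n_dis = len(truth.disruptive_snps)
    n_neu = len(truth.neutral_snp_ids)
    return {
        "disruptive_accuracy": correct / n_dis if n_dis else float("nan"),
        "neutral_misclassified": neutral_bad / n_neu if n_neu else 0.0,
        "n_disruptive": n_dis,
        "n_neutral": n_neu,
    }


def null_type_i_error(n_features: int = 10_000, n_per_group: int = 50,
                      seed: int = 0, cfg: PipelineConfig | None = None,
                      alpha: float = 0.05) -> dict:
    """Fraction of raw DE p-values below alpha on a no-effect simulation."""
    cfg = cfg or PipelineConfig()
    genes, enhancers = generate_layout(10, n_features, n_chroms=4,
                                       chrom_length=60_000_000,
                                       enhancer_width=200, seed=seed)
    sheet = make_sample_sheet(["NULL"], n_tumor=n_per_group, n_normal=n_per_group)
    spec = TruthSpec(frac_de=0.0, n_linked_pairs=0)
    expr_e, _, _ = generate_expression(genes, enhancers, sheet, spec, seed=seed, cfg=cfg)
    rec = call_de(expr_e, sheet, "NULL", cfg)
    return {"type_i_error": float((rec["p"] < alpha).mean()), "n_features": len(rec)}


def comparison_rejection_rate(n_sims: int = 1000, n_per_group: int = 30,
                              n_samples: int = 10, seed: int = 0,
                              alpha: float = 0.05) -> dict:
    """Rejection rate of the regulated-vs-nonregulated rank-sum comparison
    when both groups are drawn from the same distribution."""
    rng = np.random.default_rng(seed)
    sheet = pd.DataFrame({
        "sample_id": [f"t{i}" for i in range(n_samples)],
        "tissue": "NULL",
        "condition": "tumor",
    })
    ids = [f"r{i}" for i in range(n_per_group)] + [f"n{i}" for i in range(n_per_group)]
    rejections = 0
    for _ in range(n_sims):
        vals = np.exp(1.0 + rng.standard_normal((2 * n_per_group, n_samples)))
        expr = pd.DataFrame(vals, index=ids, columns=sheet["sample_id"])
        res = compare_regulated_vs_nonregulated(expr, ids[:n_per_group],
                                                ids[n_per_group:], sheet, "NULL")
        rejections += res["p"] < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}
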