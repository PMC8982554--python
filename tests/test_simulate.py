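"""Generator determinism, planted effects, and construction guarantees."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhancerlink.config import PipelineConfig
from enhancerlink.errors import ValidationError
from enhancerlink.intervals import enhancer_window, intervals_overlap, promoter_region
from enhancerlink.simulate import (SimulationTruth, TruthSpec, generate_dataset,
                                   generate_expression, generate_gene_sets,
                                   generate_layout, generate_pwms,
                                   generate_snps_and_sequences, make_sample_sheet)
from enhancerlink.tfbs import classify_snp


class TestLayout:
    def test_deterministic_for_fixed_seed(self):
        a = generate_layout(50, 30, seed=1)
        b = generate_layout(50, 30, seed=1)
        assert a == b

    def test_single_forced_pair_is_distance_eligible(self, cfg):
        genes, enhancers = generate_layout(1, 1, seed=3, proximity_fraction=1.0)
        assert intervals_overlap(enhancer_window(enhancers[0], cfg),
                                 promoter_region(genes[0], cfg))

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="too small"):
            generate_layout(10, 1000, n_chroms=1, chrom_length=100_000)

    def test_enhancers_do_not_overlap(self):
        _, enhancers = generate_layout(10, 200, n_chroms=2, seed=5)
        by_chrom: dict = {}
        for e in enhancers:
            by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))


@pytest.fixture(scope="module")
def one_cohort():
    genes, enhancers = generate_layout(100, 100, seed=2)
    sheet = make_sample_sheet(["ONLY"], n_tumor=200, n_normal=200)
    expr_e, expr_g, truth = generate_expression(genes, enhancers, sheet,
                                                TruthSpec(), seed=2)
    return sheet, expr_e, expr_g, truth


class TestExpression:
    def test_planted_log2fc_recovered_at_large_n(self, one_cohort):
        sheet, expr_e, _, truth = one_cohort
        tumor = sheet.loc[sheet["condition"] == "tumor", "sample_id"]
        normal = sheet.loc[sheet["condition"] == "normal", "sample_id"]
        errs = []
        for fid, lfc in truth.de_enhancers["ONLY"].items():
            emp = np.log2((expr_e.loc[fid, tumor].mean() + 0.01)
                          / (expr_e.loc[fid, normal].mean() + 0.01))
            errs.append(emp - lfc)
        assert abs(np.mean(errs)) < 0.3

    def test_planted_spearman_near_rho(self, one_cohort):
        sheet, expr_e, expr_g, truth = one_cohort
        tumor = sheet.loc[sheet["condition"] == "tumor", "sample_id"]
        rhos = [stats.spearmanr(expr_e.loc[e, tumor], expr_g.loc[g, tumor]).statistic
                for e, g, _ in truth.linked_pairs]
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.1)

    def test_zero_rho_pair_uncorrelated(self):
        genes, enhancers = generate_layout(50, 50, seed=4)
        sheet = make_sample_sheet(["ONLY"], n_tumor=100, n_normal=2)
        expr_e, expr_g, truth = generate_expression(
            genes, enhancers, sheet, TruthSpec(rho=0.0), seed=4)
        tumor = sheet.loc[sheet["condition"] == "tumor", "sample_id"]
        e, g, _ = truth.linked_pairs[0]
        rho = stats.spearmanr(expr_e.loc[e, tumor], expr_g.loc[g, tumor]).statistic
        assert abs(rho) < 0.25

    def test_zero_de_fraction_empties_truth(self):
        genes, enhancers = generate_layout(20, 20, seed=5)
        sheet = make_sample_sheet(["A"], n_tumor=5, n_normal=5)
        _, _, truth = generate_expression(genes, enhancers, sheet,
                                          TruthSpec(frac_de=0.0), seed=5)
        assert all(not v for v in truth.de_enhancers.values())
        assert all(not v for v in truth.de_genes.values())

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValidationError, match="rho"):
            TruthSpec(rho=1.0)

    def test_values_nonnegative_and_finite(self, one_cohort):
        _, expr_e, expr_g, _ = one_cohort
        for df in (expr_e, expr_g):
            arr = df.to_numpy()
            assert np.isfinite(arr).all() and (arr >= 0).all()


class TestSnpsAndSequences:
    def test_deterministic_for_fixed_seed(self, cfg):
        _, enhancers = generate_layout(5, 5, seed=6)
        pwms = generate_pwms(3, seed=6)
        a = generate_snps_and_sequences(enhancers, pwms, 4, 4, seed=6, cfg=cfg)
        b = generate_snps_and_sequences(enhancers, pwms, 4, 4, seed=6, cfg=cfg)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_loss_construction_classified_loss(self, cfg):
        _, enhancers = generate_layout(5, 5, seed=7)
        pwms = generate_pwms(2, seed=7)
        sequences, snps, disruptive, _ = generate_snps_and_sequences(
            enhancers, pwms, 2, 0, seed=7, cfg=cfg)
        rs, tf, expected = disruptive[0]
        assert expected == "loss"
        snp = next(s for s in snps if s.rs_id == rs)
        eid = next(e.id for e in enhancers
                   if sequences[e.id][0].start <= snp.pos0 < sequences[e.id][0].end
                   and sequences[e.id][0].chrom == snp.chrom)
        region, seq = sequences[eid]
        events = classify_snp(snp, eid, region, seq, pwms, cfg)
        got = events.set_index("tf_name").loc[tf, "classification"]
        assert got == "loss"

    def test_motif_longer_than_window_rejected(self, cfg):
        _, enhancers = generate_layout(2, 2, seed=8, enhancer_width=1000)
        small_cfg = PipelineConfig(snp_flank=0)
        long_pwm = generate_pwms(1, length_range=(8, 8), seed=8)
        # shrink the region below motif length via a tiny enhancer
        from enhancerlink.intervals import Enhancer, GenomicInterval
        tiny = [Enhancer("t1", GenomicInterval("chr1", 100, 104))]
        with pytest.raises(ValidationError, match="longer"):
            generate_snps_and_sequences(tiny, long_pwm, 1, 0, seed=8, cfg=small_cfg)


class TestGeneSets:
    def test_enriched_set_overlaps_special_genes(self):
        gene_ids = [f"g{i}" for i in range(200)]
        special = gene_ids[:20]
        sets, name = generate_gene_sets(gene_ids, special, seed=9)
        enriched = next(s for s in sets if s.name == name)
        assert len(enriched.members & set(special)) >= 10


class TestFullDataset:
    def test_byte_identical_truth_and_matrices(self, tmp_path):
        a = generate_dataset(tmp_path / "a", seed=13, n_genes=60, n_enhancers=30,
                             n_tumor=4, n_normal=4, n_disruptive=4, n_neutral=4)
        b = generate_dataset(tmp_path / "b", seed=13, n_genes=60, n_enhancers=30,
                             n_tumor=4, n_normal=4, n_disruptive=4, n_neutral=4)
        pd.testing.assert_frame_equal(a["enhancer_expression"], b["enhancer_expression"])
        assert a["truth"].linked_pairs == b["truth"].linked_pairs
        assert (tmp_path / "a" / "truth.json").read_text() == \
               (tmp_path / "b" / "truth.json").read_text()

    def test_truth_round_trips_through_json(self, tmp_path, small_ds_dir):
        path = small_ds_dir["paths"]["truth"]
        truth = SimulationTruth.from_json(path)
        assert truth.linked_pairs == small_ds_dir["truth"].linked_pairs
        assert truth.de_enhancers == small_ds_dir["truth"].de_enhancers

    def test_planted_ids_exist_in_layout(self, small_ds):
        truth = small_ds["truth"]
        eids = {e.id for e in small_ds["enhancers"]}
        gids = {g.id for g in small_ds["genes"]}
        for cohort_des in truth.de_enhancers.values():
            assert set(cohort_des) <= eids
        for e, g, _ in truth.linked_pairs:
            assert e in eids and g in gids
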