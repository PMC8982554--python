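"""Candidate-pair geometry, Spearman screening, partition and group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerlink.errors import ValidationError
from enhancerlink.intervals import (Enhancer, GeneAnnotation, GenomicInterval,
                                    enhancer_window, intervals_overlap,
                                    promoter_region)
from enhancerlink.linking import (candidate_pairs, compare_regulated_vs_nonregulated,
                                  link_targets, partition_regulated, spearman)


def random_features(rng, n, chroms=("chr1", "chr2"), span=2_000_000):
    enhancers = [Enhancer(f"e{i}", GenomicInterval(str(rng.choice(chroms)),
                                                   s := int(rng.integers(0, span)), s + 500))
                 for i in range(n)]
    genes = [GeneAnnotation(f"g{i}", f"G{i}", str(rng.choice(chroms)),
                            int(rng.integers(2000, span)),
                            str(rng.choice(["+", "-"])))
             for i in range(n)]
    return enhancers, genes


def brute_force_pairs(enhancers, genes, cfg):
    out = set()
    for e in enhancers:
        win = enhancer_window(e, cfg)
        for g in genes:
            if intervals_overlap(win, promoter_region(g, cfg)):
                out.add((e.id, g.id))
    return out


class TestCandidatePairs:
    def test_promoter_inside_window_emitted(self, cfg):
        e = Enhancer("e1", GenomicInterval("chr1", 1_000_000, 1_001_000))
        g = GeneAnnotation("g1", "G1", "chr1", 1_050_000, "+")
        pairs = candidate_pairs([e], ["g1"], [g], cfg)
        assert pairs.iloc[0].tolist() == ["e1", "g1", 49_500]

    def test_abutting_promoter_not_emitted(self, cfg):
        # enhancer window ends at 1_100_500; a + strand promoter starting
        # exactly there ([window_end, ...)) must not overlap
        e = Enhancer("e1", GenomicInterval("chr1", 1_000_000, 1_001_000))
        g = GeneAnnotation("g1", "G1", "chr1", 1_100_500 + cfg.promoter_upstream, "+")
        assert candidate_pairs([e], ["g1"], [g], cfg).empty

    def test_missing_annotation_skipped_with_warning(self, cfg, caplog):
        e = Enhancer("e1", GenomicInterval("chr1", 0, 1000))
        with caplog.at_level("WARNING"):
            pairs = candidate_pairs([e], ["ghost"], [], cfg)
        assert pairs.empty and "ghost" in caplog.text

    def test_matches_quadratic_oracle(self, cfg):
        rng = np.random.default_rng(42)
        enhancers, genes = random_features(rng, 200)
        pairs = candidate_pairs(enhancers, [g.id for g in genes], genes, cfg)
        got = set(zip(pairs["enhancer_id"], pairs["gene_id"]))
        assert got == brute_force_pairs(enhancers, genes, cfg)

    def test_sorted_by_enhancer_then_distance(self, cfg):
        rng = np.random.default_rng(1)
        enhancers, genes = random_features(rng, 150)
        pairs = candidate_pairs(enhancers, [g.id for g in genes], genes, cfg)
        key = list(zip(pairs["enhancer_id"], pairs["distance"], pairs["gene_id"]))
        assert key == sorted(key)


def oracle_spearman_p(x, y):
    """Independent exhaustive-permutation oracle (corrcoef per permutation)."""
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        hits += abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12
        total += 1
    return rho_obs, hits / total


class TestSpearman:
    def test_monotone_increasing_gives_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 11.0]
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 11.0]
        rho, _ = spearman(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_with_ties_matches_permutation_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]  # one tie
        y = [3.0, 1.0, 5.0, 2.0, 4.0]
        rho, p = spearman(x, y)
        rho_o, p_o = oracle_spearman_p(x, y)
        assert rho == pytest.approx(rho_o)
        assert p == pytest.approx(p_o, abs=0.02)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValidationError, match="rank variance"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=9, unique=True),
           st.lists(st.integers(-50, 50), min_size=9, max_size=9, unique=True))
    @settings(deadline=None, max_examples=30)
    def test_invariant_to_monotone_transforms(self, x, y):
        y = [float(v) for v in y[:len(x)]]
        x = [float(v) for v in x]
        rho, p = spearman(x, y)
        rho2, p2 = spearman(np.exp(np.asarray(x) / 50), [v ** 3 for v in y])
        assert rho == pytest.approx(rho2, abs=1e-9)
        assert p == pytest.approx(p2, abs=1e-9)

    def test_equals_itself_on_ranks(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = spearman(x, y)
        rho2, p2 = spearman(pd.Series(x).rank(), pd.Series(y).rank())
        assert (rho, p) == (pytest.approx(rho2), pytest.approx(p2))


class TestLinkTargets:
    def test_linked_flag_matches_threshold_rule(self, cfg, small_ds):
        truth = small_ds["truth"]
        enh = {e.id: e for e in small_ds["enhancers"]}
        de_e = [enh[i] for i in sorted(truth.de_enhancers["BRCA"])]
        cand = candidate_pairs(de_e, sorted(truth.de_genes["BRCA"]),
                               small_ds["genes"], cfg)
        links = link_targets(cand, small_ds["enhancer_expression"],
                             small_ds["gene_expression"], small_ds["sheet"],
                             "BRCA", cfg)
        expected = (links["rho"] >= cfg.corr_min) & (links["q"] < cfg.link_q_max)
        assert links["linked"].equals(expected)

    def test_planted_pairs_recovered_in_one_cohort(self, cfg, small_ds):
        truth = small_ds["truth"]
        enh = {e.id: e for e in small_ds["enhancers"]}
        de_e = [enh[i] for i in sorted(truth.de_enhancers["BRCA"])]
        cand = candidate_pairs(de_e, sorted(truth.de_genes["BRCA"]),
                               small_ds["genes"], cfg)
        links = link_targets(cand, small_ds["enhancer_expression"],
                             small_ds["gene_expression"], small_ds["sheet"],
                             "BRCA", cfg)
        planted = {(e, g) for e, g, _ in truth.linked_pairs}
        got = set(zip(links.loc[links["linked"], "enhancer_id"],
                      links.loc[links["linked"], "gene_id"]))
        # n = 20 tumor samples gives ~85% per-pair power at rho = 0.6; the
        # strict n = 100 recovery bound is checked in the acceptance suite
        assert len(got & planted) >= 0.5 * len(planted)
        assert not got - set(zip(cand["enhancer_id"], cand["gene_id"]))

    def test_zero_variance_pair_dropped(self, cfg, small_ds, caplog):
        expr_e = small_ds["enhancer_expression"].copy()
        first = expr_e.index[0]
        expr_e.loc[first] = 0.0
        cand = pd.DataFrame({"enhancer_id": [first],
                             "gene_id": [small_ds["gene_expression"].index[0]],
                             "distance": [1000]})
        with caplog.at_level("WARNING"):
            links = link_targets(cand, expr_e, small_ds["gene_expression"],
                                 small_ds["sheet"], "BRCA", cfg)
        assert links.empty and "zero rank variance" in caplog.text


class TestPartition:
    def test_no_links_means_all_nonregulated(self):
        links = pd.DataFrame(columns=["enhancer_id", "linked"])
        reg, nonreg = partition_regulated(["e1", "e2"], links)
        assert reg == [] and nonreg == ["e1", "e2"]

    def test_partition_conserves_and_disjoint(self):
        links = pd.DataFrame({"enhancer_id": ["e1", "e3", "e3"],
                              "linked": [True, True, False]})
        reg, nonreg = partition_regulated(["e1", "e2", "e3"], links)
        assert reg == ["e1", "e3"] and nonreg == ["e2"]
        assert not set(reg) & set(nonreg)


class TestGroupComparison:
    def make_expr(self, values, sheet):
        return pd.DataFrame(values, columns=sheet["sample_id"])

    def test_identical_single_values_give_p_one(self):
        sheet = pd.DataFrame({"sample_id": ["t1", "t2"], "tissue": "A",
                              "condition": "tumor"})
        expr = pd.DataFrame([[2.0, 2.0], [2.0, 2.0]], index=["e1", "e2"],
                            columns=["t1", "t2"])
        res = compare_regulated_vs_nonregulated(expr, ["e1"], ["e2"], sheet, "A")
        assert res["p"] == 1.0

    def test_empty_group_rejected_naming_cohort(self):
        sheet = pd.DataFrame({"sample_id": ["t1"], "tissue": "KIRC",
                              "condition": "tumor"})
        expr = pd.DataFrame([[1.0]], index=["e1"], columns=["t1"])
        with pytest.raises(ValidationError, match="KIRC"):
            compare_regulated_vs_nonregulated(expr, ["e1"], [], sheet, "KIRC")

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(0)
        n = 50
        sheet = pd.DataFrame({"sample_id": [f"t{i}" for i in range(10)],
                              "tissue": "A", "condition": "tumor"})
        reg = np.exp(rng.normal(1.0, 1, (n, 10)) + 1.0)
        nonreg = np.exp(rng.normal(1.0, 1, (n, 10)))
        expr = pd.DataFrame(np.vstack([reg, nonreg]),
                            index=[f"r{i}" for i in range(n)] + [f"n{i}" for i in range(n)],
                            columns=sheet["sample_id"])
        res = compare_regulated_vs_nonregulated(
            expr, [f"r{i}" for i in range(n)], [f"n{i}" for i in range(n)], sheet, "A")
        assert res["p"] < 0.05
        assert res["median_regulated"] > res["median_nonregulated"]
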