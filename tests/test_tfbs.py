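"""PWM scoring, exact score-null distribution, SNP mapping and gain/loss calls."""

import numpy as np
import pandas as pd
import pytest

from enhancerlink.errors import ValidationError
from enhancerlink.intervals import Enhancer, GenomicInterval
from enhancerlink.records import Pwm, Snp
from enhancerlink.tfbs import (best_snp_score, classify_snp, map_snps,
                               pwm_log_odds, revcomp, score_null_distribution,
                               snp_cohort_proportions, summarize_events)

UNIFORM = np.full(4, 0.25)


def make_pwm(rows, name="TF1"):
    return Pwm(name, np.array(rows, dtype=float), UNIFORM)


@pytest.fixture(scope="module")
def strong_pwm():
    """8-column motif, one dominant base per column (consensus ACGTACGT)."""
    rows = []
    for b in "ACGTACGT":
        row = [0.1 / 3] * 4
        row["ACGT".index(b)] = 0.9
        rows.append(row)
    return make_pwm(rows)


class TestLogOdds:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = make_pwm([[0.25] * 4] * 3)
        for w in ("AAA", "ACG", "TTT"):
            assert pwm_log_odds(pwm, w) == pytest.approx(0.0)

    def test_consensus_is_sum_of_column_maxima(self, strong_pwm):
        expected = float(np.log2(strong_pwm.probs.max(axis=1) / 0.25).sum())
        assert pwm_log_odds(strong_pwm, "ACGTACGT") == pytest.approx(expected)

    def test_window_length_must_match(self, strong_pwm):
        with pytest.raises(ValidationError, match="length"):
            pwm_log_odds(strong_pwm, "ACGT")

    def test_ambiguous_base_rejected(self, strong_pwm):
        with pytest.raises(ValidationError, match="ambiguous"):
            pwm_log_odds(strong_pwm, "ACGTACGN")

    def test_revcomp(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AACG") == "CGTT"


class TestBestSnpScore:
    def test_matches_exhaustive_scan_both_strands(self):
        pwm = make_pwm([[0.7, 0.1, 0.1, 0.1],
                        [0.1, 0.7, 0.1, 0.1],
                        [0.1, 0.1, 0.7, 0.1]])
        seq = "TTACGG"
        snp_offset = 2
        scores = []
        for o in range(len(seq) - 3 + 1):
            if not (o <= snp_offset < o + 3):
                continue
            w = seq[o:o + 3]
            scores += [pwm_log_odds(pwm, w), pwm_log_odds(pwm, revcomp(w))]
        assert best_snp_score(pwm, seq, snp_offset) == pytest.approx(max(scores))

    def test_no_complete_window_returns_nan(self, strong_pwm):
        assert np.isnan(best_snp_score(strong_pwm, "ACGTA", 2))  # seq shorter than motif


class TestScoreNullDistribution:
    def test_length_one_pwm_has_four_weighted_scores(self):
        pwm = make_pwm([[0.4, 0.3, 0.2, 0.1]])
        dist = score_null_distribution(pwm)
        support = dist.support[dist.pmf > 0]
        expected = sorted(np.log2(np.array([0.4, 0.3, 0.2, 0.1]) / 0.25))
        assert np.allclose(sorted(support), expected, atol=2e-3)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_total_mass_is_one(self, strong_pwm):
        assert score_null_distribution(strong_pwm).total_mass == pytest.approx(1.0, abs=1e-9)

    def test_tail_is_monotone_nonincreasing(self, strong_pwm):
        dist = score_null_distribution(strong_pwm)
        xs = np.linspace(dist.support[0] - 1, dist.support[-1] + 1, 200)
        sf = [dist.sf(x) for x in xs]
        assert all(a >= b - 1e-15 for a, b in zip(sf, sf[1:]))

    def test_matches_exhaustive_enumeration(self, strong_pwm):
        # all 4^8 windows, scored exactly; compare tails with a Levy-style
        # slack of one grid cell per column for the discretization
        L = len(strong_pwm)
        lom = np.log2(strong_pwm.probs / 0.25)
        grids = np.array(np.meshgrid(*[range(4)] * L, indexing="ij")).reshape(L, -1)
        scores = lom[np.arange(L)[:, None], grids].sum(axis=0)
        dist = score_null_distribution(strong_pwm)
        slack = L * dist.granularity
        for q in np.quantile(scores, [0.01, 0.1, 0.5, 0.9, 0.99, 0.9999]):
            enum_tail = (scores >= q - 1e-12).mean()
            assert dist.sf(q + slack) - 1e-12 <= enum_tail <= dist.sf(q - slack) + 1e-12

    def test_overlong_pwm_rejected(self):
        pwm = make_pwm([[0.25] * 4] * 31)
        with pytest.raises(ValidationError, match="<= 30"):
            score_null_distribution(pwm)

    def test_grid_overflow_suggests_coarser_granularity(self, strong_pwm):
        with pytest.raises(ValidationError, match="coarser"):
            score_null_distribution(strong_pwm, granularity=1e-9, max_cells=1000)


class TestMapSnps:
    def enhancer(self):
        return Enhancer("e1", GenomicInterval("chr1", 1000, 2000))

    def test_one_based_boundary_mapping(self, cfg):
        # extended region [500, 2500): 1-based 501 maps, 2501 does not
        inside = Snp("rs_in", "chr1", 501, "A", "G")
        outside = Snp("rs_out", "chr1", 2501, "A", "G")
        got = map_snps([inside, outside], [self.enhancer()], cfg)
        assert [(s.rs_id, e) for s, e in got] == [("rs_in", "e1")]

    def test_assembly_mismatch_rejected(self, cfg):
        with pytest.raises(ValidationError, match="assembly"):
            map_snps([], [self.enhancer()], cfg, snp_assembly="GRCh38",
                     enhancer_assembly="hg19")

    def test_multi_mapping_emits_all_pairs(self, cfg):
        e2 = Enhancer("e2", GenomicInterval("chr1", 1500, 2600))
        snp = Snp("rs1", "chr1", 1700, "A", "G")
        got = map_snps([snp], [self.enhancer(), e2], cfg)
        assert {(s.rs_id, e) for s, e in got} == {("rs1", "e1"), ("rs1", "e2")}

    def test_matches_quadratic_oracle(self, cfg):
        rng = np.random.default_rng(7)
        enhancers = [Enhancer(f"e{i}", GenomicInterval(f"chr{rng.integers(1, 3)}",
                                                       s := int(rng.integers(0, 500_000)),
                                                       s + 800))
                     for i in range(200)]
        snps = [Snp(f"rs{i}", f"chr{rng.integers(1, 3)}",
                    int(rng.integers(1, 500_000)), "A", "G") for i in range(1000)]
        got = {(s.rs_id, e) for s, e in map_snps(snps, enhancers, cfg)}
        want = set()
        for s in snps:
            for e in enhancers:
                ext_start = max(0, e.interval.start - cfg.snp_flank)
                ext_end = e.interval.end + cfg.snp_flank
                if s.chrom == e.interval.chrom and ext_start <= s.pos0 < ext_end:
                    want.add((s.rs_id, e.id))
        assert got == want


class TestClassifySnp:
    def setup_case(self, strong_pwm):
        region = GenomicInterval("chr1", 1000, 1040)
        seq = list("T" * 40)
        seq[10:18] = "ACGTACGT"  # embedded consensus
        return region, "".join(seq)

    def test_loss_called_when_alt_destroys_consensus(self, cfg, strong_pwm):
        region, seq = self.setup_case(strong_pwm)
        snp = Snp("rs1", "chr1", 1011, "A", "T")  # first consensus base
        events = classify_snp(snp, "e1", region, seq, [strong_pwm], cfg)
        assert events.iloc[0]["classification"] == "loss"
        assert events.iloc[0]["delta"] < 0

    def test_allele_swap_flips_loss_to_gain(self, cfg, strong_pwm):
        region, seq = self.setup_case(strong_pwm)
        broken = seq[:10] + "T" + seq[11:]
        snp = Snp("rs1", "chr1", 1011, "T", "A")
        events = classify_snp(snp, "e1", region, broken, [strong_pwm], cfg)
        assert events.iloc[0]["classification"] == "gain"

    def test_delta_antisymmetric_under_allele_swap(self, cfg, strong_pwm):
        region, seq = self.setup_case(strong_pwm)
        fwd = classify_snp(Snp("rs1", "chr1", 1011, "A", "T"), "e1", region, seq,
                           [strong_pwm], cfg)
        broken = seq[:10] + "T" + seq[11:]
        rev = classify_snp(Snp("rs1", "chr1", 1011, "T", "A"), "e1", region, broken,
                           [strong_pwm], cfg)
        assert fwd.iloc[0]["delta"] == pytest.approx(-rev.iloc[0]["delta"])
        assert fwd.iloc[0]["ref_p"] == pytest.approx(rev.iloc[0]["alt_p"])

    def test_ref_mismatch_rejected_naming_snp(self, cfg, strong_pwm):
        region, seq = self.setup_case(strong_pwm)
        snp = Snp("rs77", "chr1", 1011, "G", "T")
        with pytest.raises(ValidationError, match="rs77"):
            classify_snp(snp, "e1", region, seq, [strong_pwm], cfg)

    def test_unchanged_when_no_window_overlaps(self, cfg, strong_pwm):
        # region shorter than the motif: no complete window exists
        region = GenomicInterval("chr1", 1000, 1005)
        snp = Snp("rs1", "chr1", 1003, "A", "G")
        events = classify_snp(snp, "e1", region, "TTATT", [strong_pwm], cfg)
        row = events.iloc[0]
        assert row["classification"] == "unchanged" and row["delta"] == 0.0


class TestSummaries:
    def events(self):
        return pd.DataFrame({
            "rs_id": ["rs1", "rs1", "rs1", "rs2"],
            "tf_name": ["A", "B", "C", "A"],
            "enhancer_id": ["e1", "e1", "e1", "e2"],
            "ref_best": 0.0, "alt_best": 0.0, "delta": 0.0,
            "ref_p": 1.0, "alt_p": 1.0,
            "classification": ["gain", "gain", "loss", "unchanged"],
        })

    def test_distinct_tf_counts_per_snp(self):
        out = summarize_events(self.events())
        per_snp = out["per_snp"].set_index("rs_id")["n_tfs"]
        assert per_snp["rs1"] == 3 and per_snp["rs2"] == 0
        assert out["n_affected_tfs"] == 3
        assert out["n_snps_with_effect"] == 1

    def test_no_events_all_zero(self):
        empty = self.events().iloc[:0]
        out = summarize_events(empty)
        assert out["n_affected_tfs"] == 0 and out["per_snp"].empty

    def test_cohort_proportions_printed_arithmetic(self):
        counts = {"KIRC": 21, "BRCA": 12, "LUAD": 11, "COAD": 10, "LIHC": 8,
                  "STAD": 5, "THCA": 3, "ESCA": 2, "HNSC": 1, "BLCA": 1}
        table = snp_cohort_proportions(counts)
        assert table["n_snps"].sum() == 74
        kirc = table.set_index("cohort").loc["KIRC", "percent"]
        assert kirc == 28.4

    def test_proportions_sum_to_about_hundred(self):
        table = snp_cohort_proportions({"A": 3, "B": 3, "C": 1})
        assert table["percent"].sum() == pytest.approx(100, abs=0.2)
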