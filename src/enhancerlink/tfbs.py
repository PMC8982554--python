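"""Allele-specific PWM scoring of SNPs inside extended enhancer regions.

Each SNP x TF pair is scored by the best log2-odds PWM match over every
window (both strands) that overlaps the SNP, once with the reference allele
and once with the alternate. Per-allele significance comes from the exact
distribution of the single-window score under the background model, computed
by position-wise convolution on a fixed score grid. A binding site is
"gained" when only the alternate allele's best window is significant at
``tfbs_p_max`` and "lost" in the mirror case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .breadth import round_half_up
from .config import PipelineConfig
from .errors import ValidationError
from .intervals import Enhancer, GenomicInterval, extend_enhancer
from .records import BASE_INDEX, Pwm, Snp

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["rs_id", "tf_name", "enhancer_id", "ref_best", "alt_best",
                 "delta", "ref_p", "alt_p", "classification"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# finite stand-in for log2(0) cells; far below any plausible binding score
_NEG_INF_BITS = -60.0


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _finite_log_odds(pwm: Pwm) -> np.ndarray:
    lom = pwm.log_odds
    return np.where(np.isfinite(lom), lom, _NEG_INF_BITS)


def pwm_log_odds(pwm: Pwm, window: str) -> float:
    """Sum of per-position log2(p/background) for one window of PWM length."""
    if len(window) != len(pwm):
        raise ValidationError(f"window length {len(window)} != PWM length {len(pwm)}")
    try:
        idx = [BASE_INDEX[b] for b in window.upper()]
    except KeyError as exc:
        raise ValidationError(f"ambiguous base in window {window!r}") from exc
    lom = _finite_log_odds(pwm)
    return float(lom[np.arange(len(pwm)), idx].sum())


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the single-window PWM score under background,
    discretized on a grid of ``granularity`` bits per cell."""

    granularity: float
    min_int: int
    pmf: np.ndarray  # probability of score == (min_int + i) * granularity

    def __post_init__(self) -> None:
        object.__setattr__(self, "_tail", np.cumsum(self.pmf[::-1])[::-1])

    @property
    def support(self) -> np.ndarray:
        return (self.min_int + np.arange(self.pmf.size)) * self.granularity

    @property
    def total_mass(self) -> float:
        return float(self.pmf.sum())

    def sf(self, score: float) -> float:
        """P(single-window score >= ``score``) on the grid; monotone
        non-increasing in ``score``."""
        idx = int(round(score / self.granularity)) - self.min_int
        if idx <= 0:
            return 1.0
        if idx >= self.pmf.size:
            return 0.0
        return float(self._tail[idx])


def score_null_distribution(pwm: Pwm, granularity: float = 1e-3,
                            max_cells: int = 50_000_000) -> ScoreDistribution:
    """Convolve per-column score distributions into the exact window-score
    null, with per-column scores rounded to the grid."""
    L = len(pwm)
    if L > 30:
        raise ValidationError("score_null_distribution supports PWM length <= 30")
    lom = _finite_log_odds(pwm)
    col_ints = np.round(lom / granularity).astype(np.int64)  # L x 4
    span = int((col_ints.max(axis=1) - col_ints.min(axis=1)).sum()) + 1
    if span > max_cells:
        raise ValidationError(
            f"score grid needs {span} cells; increase granularity (coarser grid)")
    pmf = np.array([1.0])
    min_int = 0
    bg = pwm.background
    for i in range(L):
        lo = int(col_ints[i].min())
        col = np.zeros(int(col_ints[i].max()) - lo + 1)
        for b in range(4):
            col[col_ints[i, b] - lo] += bg[b]
        pmf = np.convolve(pmf, col)
        min_int += lo
    return ScoreDistribution(granularity, min_int, pmf)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for base, i in BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def best_snp_score(pwm: Pwm, seq: str, snp_offset: int) -> float:
    """Best log-odds over all windows (both strands) overlapping position
    ``snp_offset`` of ``seq``; NaN when no complete window overlaps it.
    Windows containing ambiguous bases are skipped with a log message."""
    L = len(pwm)
    lo = max(0, snp_offset - L + 1)
    hi = min(len(seq) - L, snp_offset)
    if hi < lo:
        return float("nan")
    lom = _finite_log_odds(pwm)
    lom_rc = lom[::-1, ::-1]  # score of the reverse complement read forward
    enc = _encode(seq)
    best = -np.inf
    skipped = 0
    pos = np.arange(L)
    for o in range(lo, hi + 1):
        window = enc[o:o + L]
        if (window < 0).any():
            skipped += 1
            continue
        fwd = lom[pos, window].sum()
        rev = lom_rc[pos, window].sum()
        best = max(best, fwd, rev)
    if skipped:
        logger.info("skipped %d windows with ambiguous bases near offset %d", skipped, snp_offset)
    return float(best) if np.isfinite(best) else float("nan")


def map_snps(snps: Sequence[Snp], enhancers: Sequence[Enhancer], cfg: PipelineConfig,
             snp_assembly: str = "hg19",
             enhancer_assembly: str = "hg19") -> list[tuple[Snp, str]]:
    """Pair each SNP with every extended enhancer containing it (0-based
    position in the half-open extended interval). Both inputs must share one
    declared assembly; no coordinate lifting is performed."""
    if snp_assembly != enhancer_assembly:
        raise ValidationError(
            f"assembly mismatch: SNPs on {snp_assembly!r}, enhancers on "
            f"{enhancer_assembly!r}; convert coordinates upstream")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for e in enhancers:
        ext = extend_enhancer(e, cfg)
        by_chrom.setdefault(ext.chrom, []).append((ext.start, ext.end, e.id))
    pairs: list[tuple[Snp, str]] = []
    for snp in snps:
        for start, end, eid in by_chrom.get(snp.chrom, ()):
            if start <= snp.pos0 < end:
                pairs.append((snp, eid))
    return pairs


def classify_snp(snp: Snp, enhancer_id: str, region: GenomicInterval, seq: str,
                 pwms: Sequence[Pwm], cfg: PipelineConfig,
                 null_cache: dict | None = None) -> pd.DataFrame:
    """Score one SNP against every PWM and call gain/loss/unchanged.

    ``seq`` must cover ``region`` and carry the reference allele at the SNP
    position. Events classified unchanged are retained (flagged in the
    classification column).
    """
    if len(seq) != len(region):
        raise ValidationError(f"sequence length {len(seq)} != region span {len(region)}")
    offset = snp.pos0 - region.start
    if not (0 <= offset < len(seq)):
        raise ValidationError(f"{snp.rs_id}: position outside the supplied region")
    if seq[offset].upper() != snp.ref:
        raise ValidationError(
            f"{snp.rs_id}: reference allele {snp.ref} does not match sequence "
            f"base {seq[offset].upper()} at {region.chrom}:{snp.pos}")
    if null_cache is None:
        null_cache = {}
    alt_seq = seq[:offset] + snp.alt + seq[offset + 1:]
    rows = []
    for pwm in pwms:
        key = id(pwm)
        if key not in null_cache:
            null_cache[key] = score_null_distribution(pwm, cfg.score_granularity)
        null = null_cache[key]
        ref_best = best_snp_score(pwm, seq, offset)
        alt_best = best_snp_score(pwm, alt_seq, offset)
        if np.isnan(ref_best) or np.isnan(alt_best):
            delta, ref_p, alt_p, cls = 0.0, 1.0, 1.0, "unchanged"
        else:
            delta = alt_best - ref_best
            ref_p = null.sf(ref_best)
            alt_p = null.sf(alt_best)
            ref_sig = ref_p <= cfg.tfbs_p_max
            alt_sig = alt_p <= cfg.tfbs_p_max
            cls = "gain" if (alt_sig and not ref_sig) else \
                  "loss" if (ref_sig and not alt_sig) else "unchanged"
        rows.append((snp.rs_id, pwm.tf_name, enhancer_id, ref_best, alt_best,
                     delta, ref_p, alt_p, cls))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def classify_all(mapped: Iterable[tuple[Snp, str]],
                 sequences: Mapping[str, tuple[GenomicInterval, str]],
                 pwms: Sequence[Pwm], cfg: PipelineConfig) -> pd.DataFrame:
    """Classify every mapped (SNP, enhancer) pair with a sequence available."""
    null_cache: dict = {}
    frames = []
    n_noseq = 0
    for snp, eid in mapped:
        entry = sequences.get(eid)
        if entry is None or entry[0] is None:
            n_noseq += 1
            continue
        region, seq = entry
        frames.append(classify_snp(snp, eid, region, seq, pwms, cfg, null_cache))
    if n_noseq:
        logger.warning("%d mapped SNP-enhancer pairs had no sequence; skipped", n_noseq)
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def snp_cohort_proportions(counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-cohort share of enhancer SNPs, percentages rounded half-up to one
    decimal (21 of 74 -> 28.4)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("no SNP counts supplied")
    df = pd.DataFrame(sorted(counts.items()), columns=["cohort", "n_snps"])
    df["percent"] = [round_half_up(100.0 * n / total, 1) for n in df["n_snps"]]
    return df.sort_values(["n_snps", "cohort"], ascending=[False, True]).reset_index(drop=True)


def summarize_events(events: pd.DataFrame,
                     snp_cohorts: Mapping[str, str] | None = None) -> dict:
    """Distinct-TF gain/loss counts per SNP, per enhancer, and overall, plus
    the per-cohort SNP-proportion table when cohorts are supplied."""
    hit = events[events["classification"].isin(["gain", "loss"])] if not events.empty \
        else events
    def distinct(group_col: str) -> pd.DataFrame:
        if events.empty:
            return pd.DataFrame(columns=[group_col, "n_tfs"])
        base = events[[group_col]].drop_duplicates()
        if hit.empty:
            out = base.assign(n_tfs=0)
        else:
            counts = hit.groupby(group_col)["tf_name"].nunique().rename("n_tfs").reset_index()
            out = base.merge(counts, on=group_col, how="left").fillna({"n_tfs": 0})
        out["n_tfs"] = out["n_tfs"].astype(int)
        return out.sort_values(group_col).reset_index(drop=True)

    summary = {
        "per_snp": distinct("rs_id"),
        "per_enhancer": distinct("enhancer_id"),
        "n_affected_tfs": 0 if hit.empty else int(hit["tf_name"].nunique()),
        "n_snps_with_effect": 0 if hit.empty else int(hit["rs_id"].nunique()),
    }
    if snp_cohorts is not None and not events.empty:
        counts: dict[str, int] = {}
        for rs in events["rs_id"].unique():
            cohort = snp_cohorts.get(rs)
            if cohort:
                counts[cohort] = counts.get(cohort, 0) + 1
        if counts:
            summary["cohort_proportions"] = snp_cohort_proportions(counts)
    return summary
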