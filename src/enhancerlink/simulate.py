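"""Synthetic multi-cohort tumor/normal data with known ground truth.

The generator emulates the structure of the real inputs — paired
tumor/normal RPKM-scale expression over 13 cancer cohorts, enhancer BED
coordinates, a TSS table, eQTL-style SNPs, JASPAR motifs and GMT gene sets —
with planted differential expression, planted enhancer-gene coexpression,
one enriched gene set and motif-disrupting SNPs, so every downstream stage
can be tested without downloads.

Noise model: expression values are log-normal (continuous, non-negative,
RPKM-like); differential features have their tumor mean scaled by
2^(+/-log2FC); linked enhancer-gene pairs share a latent Gaussian factor
whose Pearson correlation is chosen by the sine transform so the rank
(Spearman) correlation of the generated values equals the requested rho;
random dropout sets individual values to zero. Dropout is not applied to
features of planted linked pairs — zeroing them would break the generator's
contract that those pairs carry Spearman correlation ~ rho.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as elio
from .config import PipelineConfig
from .errors import ValidationError
from .intervals import Enhancer, GeneAnnotation, GenomicInterval, extend_enhancer
from .linking import candidate_pairs
from .records import BASES, BASE_INDEX, Pwm
from .tfbs import score_null_distribution

#: the 13 tumor types whose cohort structure the generator mirrors
DEFAULT_COHORTS = ["BLCA", "BRCA", "COAD", "ESCA", "HNSC", "KICH", "KIRC",
                   "KIRP", "LIHC", "LUAD", "LUSC", "STAD", "THCA"]


@dataclass
class TruthSpec:
    """Planted-effect parameters; the defaults define the study conditions."""

    log2fc: float = 2.0          # planted |log2 fold change| of DE features
    frac_de: float = 0.1         # fraction of features planted DE
    rho: float = 0.6             # planted Spearman correlation of linked pairs
    meanlog: float = 1.0         # baseline log-normal location (natural log)
    sdlog: float = 1.0           # baseline log-normal scale (natural log)
    dropout: float = 0.2         # per-cell probability of a zero value
    n_linked_pairs: int | None = None  # default: 5% of enhancers

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValidationError("rho must lie in (-1, 1)")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValidationError("frac_de must lie in [0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must lie in [0, 1)")
        if self.sdlog <= 0:
            raise ValidationError("sdlog must be > 0")


@dataclass
class SimulationTruth:
    """Ground truth of one generated dataset."""

    de_enhancers: dict = field(default_factory=dict)  # cohort -> {id: signed log2fc}
    de_genes: dict = field(default_factory=dict)
    linked_pairs: list = field(default_factory=list)  # (enhancer_id, gene_id, rho)
    enriched_set_name: str | None = None
    disruptive_snps: list = field(default_factory=list)  # (rs_id, tf, "gain"|"loss")
    neutral_snp_ids: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        data = {
            "de_enhancers": self.de_enhancers,
            "de_genes": self.de_genes,
            "linked_pairs": [list(t) for t in self.linked_pairs],
            "enriched_set_name": self.enriched_set_name,
            "disruptive_snps": [list(t) for t in self.disruptive_snps],
            "neutral_snp_ids": self.neutral_snp_ids,
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            de_enhancers=d["de_enhancers"],
            de_genes=d["de_genes"],
            linked_pairs=[tuple(t) for t in d["linked_pairs"]],
            enriched_set_name=d["enriched_set_name"],
            disruptive_snps=[tuple(t) for t in d["disruptive_snps"]],
            neutral_snp_ids=d["neutral_snp_ids"],
        )


# ---------------------------------------------------------------------------
# genome layout

def generate_layout(n_genes: int, n_enhancers: int, n_chroms: int = 2,
                    chrom_length: int = 20_000_000, seed: int = 0,
                    enhancer_width: int = 1000, proximity_fraction: float = 0.8,
                    link_window: int = 100_000) -> tuple[list[GeneAnnotation], list[Enhancer]]:
    """Place enhancers and gene TSSs on synthetic chromosomes.

    Enhancers are laid out in non-overlapping slots; a ``proximity_fraction``
    of them get one gene whose promoter is guaranteed to fall inside their
    +/-link_window region, so distance-eligible pairs exist by construction.
    Deterministic for a fixed seed.
    """
    if n_genes < 1 or n_enhancers < 1 or n_chroms < 1:
        raise ValidationError("counts must be >= 1")
    if not (0.0 <= proximity_fraction <= 1.0):
        raise ValidationError("proximity_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    per_chrom = [n_enhancers // n_chroms + (1 if i < n_enhancers % n_chroms else 0)
                 for i in range(n_chroms)]
    enhancers: list[Enhancer] = []
    idx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        slot = chrom_length // k
        if slot < 2 * enhancer_width:
            raise ValidationError(
                f"chrom_length {chrom_length} too small for {k} enhancers of "
                f"width {enhancer_width} on {chrom}")
        for j in range(k):
            start = slot * j + int(rng.integers(0, slot - enhancer_width))
            idx += 1
            enhancers.append(Enhancer(f"e{idx:05d}",
                                      GenomicInterval(chrom, start, start + enhancer_width)))
    n_prox = min(n_genes, math.ceil(proximity_fraction * n_enhancers))
    margin = 5000  # keeps the whole promoter inside the window after clamping
    if link_window <= margin:
        raise ValidationError("link_window must exceed the placement margin (5 kb)")
    genes: list[GeneAnnotation] = []
    for i in range(n_genes):
        if i < n_prox:
            e = enhancers[i % n_enhancers]
            delta = int(rng.integers(-(link_window - margin), link_window - margin + 1))
            tss = e.center + delta
            if tss < margin:
                tss = e.center + abs(delta)
            chrom = e.interval.chrom
        else:
            c = int(rng.integers(0, n_chroms))
            chrom = chroms[c]
            tss = int(rng.integers(margin, chrom_length))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i + 1:05d}"
        genes.append(GeneAnnotation(gid, f"GENE{i + 1}", chrom, tss, strand))
    return genes, enhancers


def make_sample_sheet(cohorts: list[str] | None = None, n_tumor: int = 50,
                      n_normal: int = 50) -> pd.DataFrame:
    """Paired tumor/normal sample sheet over the configured cohorts."""
    cohorts = DEFAULT_COHORTS if cohorts is None else list(cohorts)
    if n_tumor < 2 or n_normal < 2:
        raise ValidationError("need >= 2 tumor and >= 2 normal samples per cohort")
    rows = []
    for cohort in cohorts:
        rows += [(f"{cohort}_T{i + 1:03d}", cohort, "tumor") for i in range(n_tumor)]
        rows += [(f"{cohort}_N{i + 1:03d}", cohort, "normal") for i in range(n_normal)]
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "condition"])


# ---------------------------------------------------------------------------
# expression

def _pick_de(rng: np.random.Generator, ids: list[str], forced: list[str],
             n_de: int, log2fc: float) -> dict[str, float]:
    if n_de == 0:
        return {}
    chosen = list(forced[:n_de])
    pool = [i for i in ids if i not in set(chosen)]
    extra = n_de - len(chosen)
    if extra > 0:
        chosen += [pool[j] for j in rng.permutation(len(pool))[:extra]]
    signs = rng.choice([1.0, -1.0], size=len(chosen))
    return {fid: float(s * log2fc) for fid, s in zip(chosen, signs)}


def generate_expression(genes: list[GeneAnnotation], enhancers: list[Enhancer],
                        sheet: pd.DataFrame, spec: TruthSpec, seed: int = 0,
                        cfg: PipelineConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate enhancer and gene expression matrices plus ground truth.

    Non-DE features are i.i.d. log-normal in tumor and normal; DE features
    have the tumor mean scaled by 2^(+/-log2fc); planted pairs share a latent
    factor targeting Spearman rho; dropout zeros individual cells except on
    linked-pair features (see module docstring). Fixed seed, fixed output.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    samples = sheet["sample_id"].tolist()
    tumor_mask = (sheet["condition"] == "tumor").to_numpy()
    eids = [e.id for e in enhancers]
    gids = [g.id for g in genes]

    eligible = candidate_pairs(enhancers, gids, genes, cfg)
    n_linked = spec.n_linked_pairs
    if n_linked is None:
        n_linked = max(1, round(0.05 * len(enhancers)))
    pairs: list[tuple[str, str]] = []
    used_e: set[str] = set()
    used_g: set[str] = set()
    for j in rng.permutation(len(eligible)):
        if len(pairs) >= n_linked:
            break
        row = eligible.iloc[int(j)]
        if row.enhancer_id in used_e or row.gene_id in used_g:
            continue
        pairs.append((row.enhancer_id, row.gene_id))
        used_e.add(row.enhancer_id)
        used_g.add(row.gene_id)
    pairs.sort()

    z_e = rng.standard_normal((len(eids), len(samples)))
    z_g = rng.standard_normal((len(gids), len(samples)))
    rho_pearson = 2.0 * math.sin(math.pi * spec.rho / 6.0)  # Spearman -> latent Pearson
    e_index = {e: i for i, e in enumerate(eids)}
    g_index = {g: i for i, g in enumerate(gids)}
    a = math.sqrt(abs(rho_pearson))
    b = math.sqrt(1.0 - abs(rho_pearson))
    sign = 1.0 if rho_pearson >= 0 else -1.0
    for eid, gid in pairs:
        u = rng.standard_normal(len(samples))
        z_e[e_index[eid]] = a * u + b * rng.standard_normal(len(samples))
        z_g[g_index[gid]] = sign * a * u + b * rng.standard_normal(len(samples))

    n_de_e = round(spec.frac_de * len(eids))
    n_de_g = round(spec.frac_de * len(gids))
    de_e = _pick_de(rng, eids, [p[0] for p in pairs], n_de_e, spec.log2fc)
    de_g = _pick_de(rng, gids, [p[1] for p in pairs], n_de_g, spec.log2fc)

    def build(ids: list[str], z: np.ndarray, de: dict[str, float],
              exempt: set[str]) -> pd.DataFrame:
        vals = np.exp(spec.meanlog + spec.sdlog * z)
        for fid, lfc in de.items():
            vals[ids.index(fid), tumor_mask] *= 2.0 ** lfc
        if spec.dropout > 0:
            mask = rng.random(vals.shape) < spec.dropout
            keep = np.array([fid in exempt for fid in ids])
            mask[keep] = False
            vals[mask] = 0.0
        return pd.DataFrame(vals, index=ids, columns=samples)

    expr_e = build(eids, z_e, de_e, {p[0] for p in pairs})
    expr_g = build(gids, z_g, de_g, {p[1] for p in pairs})

    cohorts = sorted(sheet["tissue"].unique())
    truth = SimulationTruth(
        de_enhancers={c: dict(de_e) for c in cohorts},
        de_genes={c: dict(de_g) for c in cohorts},
        linked_pairs=[(e, g, spec.rho) for e, g in pairs],
    )
    return expr_e, expr_g, truth


# ---------------------------------------------------------------------------
# motifs, SNPs and sequences

def generate_pwms(n_tfs: int = 8, length_range: tuple[int, int] = (8, 9),
                  seed: int = 0, dominant: float = 0.9,
                  background: np.ndarray | None = None) -> list[Pwm]:
    """Random high-information motifs (one dominant base per column).

    Lengths default to 8-9: a single-base change can only flip a binding
    call at p <= 1e-4 when the consensus sits near that significance
    boundary, which against a uniform background bounds the usable motif
    information to roughly that of a compact 8-9 bp core motif.
    """
    if not (0.25 < dominant < 1.0):
        raise ValidationError("dominant base probability must lie in (0.25, 1)")
    rng = np.random.default_rng(seed)
    bg = elio.UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    pwms = []
    for t in range(n_tfs):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        cons = rng.integers(0, 4, size=L)
        probs = np.full((L, 4), (1.0 - dominant) / 3.0)
        probs[np.arange(L), cons] = dominant
        pwms.append(Pwm(f"TF{t + 1:02d}", probs, bg))
    return pwms


def _check_discriminative(pwm: Pwm, cfg: PipelineConfig, cache: dict) -> tuple[int, str, str]:
    """Verify the consensus hits and its worst-position mutation misses at
    tfbs_p_max; returns (position, consensus base, disrupting base)."""
    key = pwm.tf_name
    if key in cache:
        return cache[key]
    null = score_null_distribution(pwm, cfg.score_granularity)
    lom = pwm.log_odds
    j = int(np.argmax(pwm.information_content))
    cons_idx = pwm.probs.argmax(axis=1)
    worst_idx = int(pwm.probs[j].argmin())
    cons_score = float(lom[np.arange(len(pwm)), cons_idx].sum())
    mut_score = cons_score - float(lom[j, cons_idx[j]]) + float(lom[j, worst_idx])
    if null.sf(cons_score) > cfg.tfbs_p_max:
        raise ValidationError(f"{pwm.tf_name}: consensus not significant at tfbs_p_max; "
                              "motif too weak for disruptive-SNP construction")
    if null.sf(mut_score) <= cfg.tfbs_p_max:
        raise ValidationError(f"{pwm.tf_name}: single mismatch stays significant; "
                              "motif too strong for disruptive-SNP construction")
    out = (j, BASES[cons_idx[j]], BASES[worst_idx])
    cache[key] = out
    return out


def generate_snps_and_sequences(enhancers: list[Enhancer], pwms: list[Pwm],
                                n_disruptive: int = 20, n_neutral: int = 20,
                                seed: int = 0, cfg: PipelineConfig | None = None):
    """Background sequences for extended enhancers plus planted SNPs.

    Loss SNPs embed a motif consensus and mutate its most informative
    position to the least favoured base; gain SNPs embed the 1-mismatch
    motif (the reference carries the disrupting base) so the alternate
    allele restores the consensus. Neutral SNPs sit at least one motif
    length away from any embedded motif.

    Returns (sequences, snps, disruptive_truth, neutral_ids) where sequences
    maps enhancer id -> (extended region, sequence).
    """
    cfg = cfg or PipelineConfig()
    if not enhancers or not pwms:
        raise ValidationError("need >= 1 enhancer and >= 1 PWM")
    rng = np.random.default_rng(seed)
    bg = pwms[0].background
    max_l = max(len(p) for p in pwms)
    regions = {e.id: extend_enhancer(e, cfg) for e in enhancers}
    min_len = min(len(r) for r in regions.values())
    if max_l > min_len:
        raise ValidationError("motif longer than the extended enhancer window")

    seqs = {eid: list(rng.choice(list(BASES), size=len(r), p=bg))
            for eid, r in regions.items()}
    occupied: dict[str, list[tuple[int, int]]] = {eid: [] for eid in regions}

    def free_offset(eid: str, span: int) -> int:
        length = len(seqs[eid])
        for _ in range(200):
            off = int(rng.integers(0, length - span + 1))
            if all(off + span + max_l <= s or off >= e + max_l
                   for s, e in occupied[eid]):
                return off
        raise ValidationError(f"could not place a motif/SNP in {eid}; region too crowded")

    disc_cache: dict = {}
    snps = []
    disruptive: list[tuple[str, str, str]] = []
    neutral_ids: list[str] = []
    order = list(regions)
    for i in range(n_disruptive):
        eid = order[i % len(order)]
        pwm = pwms[i % len(pwms)]
        expected = "loss" if i % 2 == 0 else "gain"
        j, cons_base, worst_base = _check_discriminative(pwm, cfg, disc_cache)
        off = free_offset(eid, len(pwm))
        embedded = list(pwm.consensus)
        if expected == "gain":
            embedded[j] = worst_base
        seqs[eid][off:off + len(pwm)] = embedded
        occupied[eid].append((off, off + len(pwm)))
        snp_off = off + j
        ref = seqs[eid][snp_off]
        alt = worst_base if expected == "loss" else cons_base
        region = regions[eid]
        rs = f"rs{100001 + i}"
        from .records import Snp
        snps.append(Snp(rs, region.chrom, region.start + snp_off + 1, ref, alt))
        disruptive.append((rs, pwm.tf_name, expected))
    for i in range(n_neutral):
        eid = order[(n_disruptive + i) % len(order)]
        off = free_offset(eid, 1)
        occupied[eid].append((off, off + 1))
        ref = seqs[eid][off]
        alt = rng.choice([b for b in BASES if b != ref])
        region = regions[eid]
        rs = f"rs{200001 + i}"
        from .records import Snp
        snps.append(Snp(rs, region.chrom, region.start + off + 1, str(ref), str(alt)))
        neutral_ids.append(rs)
    sequences = {eid: (regions[eid], "".join(seqs[eid])) for eid in regions}
    return sequences, snps, disruptive, neutral_ids


# ---------------------------------------------------------------------------
# gene sets

def generate_gene_sets(all_gene_ids: list[str], special_genes: list[str],
                       n_sets: int = 20, set_size: int = 50,
                       enriched_overlap: float = 0.5, seed: int = 0):
    """Random gene sets plus one set enriched for ``special_genes``.

    Returns (gene_sets, enriched_set_name).
    """
    from .records import GeneSet

    rng = np.random.default_rng(seed)
    pool = list(all_gene_ids)
    if set_size > len(pool):
        raise ValidationError("set_size exceeds the number of genes")
    enriched_idx = int(rng.integers(0, n_sets))
    special = [g for g in special_genes if g in set(pool)]
    sets = []
    enriched_name = None
    for s in range(n_sets):
        name = f"pathway_{s + 1:02d}"
        if s == enriched_idx and special:
            n_special = min(len(special), max(1, round(enriched_overlap * set_size)))
            members = list(np.array(special)[rng.permutation(len(special))[:n_special]])
            rest = [g for g in pool if g not in set(members)]
            fill = set_size - len(members)
            members += [rest[j] for j in rng.permutation(len(rest))[:fill]]
            enriched_name = name
        else:
            members = [pool[j] for j in rng.permutation(len(pool))[:set_size]]
        sets.append(GeneSet(name, frozenset(members), "synthetic gene set"))
    return sets, enriched_name


# ---------------------------------------------------------------------------
# full dataset

def generate_dataset(out_dir: str | Path | None = None, seed: int = 0,
                     n_genes: int = 400, n_enhancers: int = 200, n_chroms: int = 2,
                     chrom_length: int = 20_000_000, cohorts: list[str] | None = None,
                     n_tumor: int = 50, n_normal: int = 50,
                     truth_spec: TruthSpec | None = None,
                     n_disruptive: int = 20, n_neutral: int = 20, n_tfs: int = 8,
                     cfg: PipelineConfig | None = None) -> dict:
    """Generate a complete synthetic study; optionally write it to disk.

    Returns a dict with all in-memory objects (and file paths when
    ``out_dir`` is given). Child seeds are spawned deterministically from
    ``seed``.
    """
    cfg = cfg or PipelineConfig()
    spec = truth_spec or TruthSpec()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]

    genes, enhancers = generate_layout(n_genes, n_enhancers, n_chroms, chrom_length,
                                       seed=seeds[0], link_window=cfg.link_window)
    sheet = make_sample_sheet(cohorts, n_tumor, n_normal)
    expr_e, expr_g, truth = generate_expression(genes, enhancers, sheet, spec,
                                                seed=seeds[1], cfg=cfg)
    pwms = generate_pwms(n_tfs, seed=seeds[2])
    sequences, snps, disruptive, neutral_ids = generate_snps_and_sequences(
        enhancers, pwms, n_disruptive, n_neutral, seed=seeds[3], cfg=cfg)
    truth.disruptive_snps = disruptive
    truth.neutral_snp_ids = neutral_ids

    linked_genes = [g for _, g, _ in truth.linked_pairs]
    set_size = min(50, max(5, n_genes // 4))
    gene_sets, enriched_name = generate_gene_sets([g.id for g in genes], linked_genes,
                                                  set_size=set_size, seed=seeds[4])
    truth.enriched_set_name = enriched_name

    rng = np.random.default_rng(seeds[4] + 1)
    cohort_list = sorted(sheet["tissue"].unique())
    snp_cohorts = {s.rs_id: str(rng.choice(cohort_list)) for s in snps}

    out = {
        "genes": genes, "enhancers": enhancers, "sheet": sheet,
        "enhancer_expression": expr_e, "gene_expression": expr_g,
        "pwms": pwms, "sequences": sequences, "snps": snps,
        "snp_cohorts": snp_cohorts, "gene_sets": gene_sets, "truth": truth,
        "config": cfg,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "enhancer_bed": out_dir / "enhancers.bed",
            "gene_table": out_dir / "genes.tsv",
            "sample_sheet": out_dir / "samples.tsv",
            "enhancer_expression": out_dir / "enhancer_expression.tsv",
            "gene_expression": out_dir / "gene_expression.tsv",
            "snp_table": out_dir / "snps.tsv",
            "pfm": out_dir / "motifs.pfm",
            "gmt": out_dir / "gene_sets.gmt",
            "sequences_fasta": out_dir / "enhancer_sequences.fa",
            "truth": out_dir / "truth.json",
        }
        elio.write_enhancer_bed(enhancers, paths["enhancer_bed"])
        elio.write_gene_table(genes, paths["gene_table"])
        elio.write_sample_sheet(sheet, paths["sample_sheet"])
        elio.write_expression_tsv(expr_e, paths["enhancer_expression"])
        elio.write_expression_tsv(expr_g, paths["gene_expression"])
        elio.write_snp_table(snps, paths["snp_table"], cohorts=snp_cohorts)
        elio.write_pfm(pwms, paths["pfm"])
        elio.write_gmt(gene_sets, paths["gmt"])
        elio.write_sequences_fasta(sequences, paths["sequences_fasta"])
        truth.to_json(paths["truth"])
        out["paths"] = {k: str(v) for k, v in paths.items()}
    return out
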