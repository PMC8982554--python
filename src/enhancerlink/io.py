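"""Readers and writers for the external formats the pipeline touches.

Tabular inputs are TSV with a header row; expression matrices put feature ids
in the first column and sample ids in the header. Enhancers come in as BED
(0-based half-open), SNP tables are 1-based, motif models are JASPAR-style
PFMs, gene sets are GMT. Readers validate invariants and raise
:class:`ParseError` / :class:`ValidationError` rather than silently coercing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .intervals import Enhancer, GeneAnnotation, GenomicInterval
from .records import Pwm, Snp

logger = logging.getLogger(__name__)

CONDITIONS = ("tumor", "normal")


# ---------------------------------------------------------------------------
# enhancers (BED)

def read_enhancer_bed(path: str | Path) -> list[Enhancer]:
    """Parse a BED file of enhancer regions.

    The id is taken from column 4 when present, otherwise synthesized as
    ``chrom:start-end``. Malformed lines raise :class:`ParseError` naming the
    line number.
    """
    enhancers: list[Enhancer] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            eid = cols[3] if len(cols) >= 4 and cols[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            if eid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate enhancer id {eid!r}")
            seen.add(eid)
            enhancers.append(Enhancer(eid, interval))
    return enhancers


def write_enhancer_bed(enhancers: Iterable[Enhancer], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in enhancers:
            iv = e.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.id}\n")


# ---------------------------------------------------------------------------
# expression matrices and sample sheets

def validate_expression(df: pd.DataFrame, name: str = "expression matrix") -> pd.DataFrame:
    if df.empty:
        raise ValidationError(f"{name} is empty")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"{name}: duplicate feature ids {dups}")
    if df.columns.duplicated().any():
        raise ValidationError(f"{name}: duplicate sample ids")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name}: non-numeric cells") from exc
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name}: values must be finite")
    if (arr < 0).any():
        raise ValidationError(f"{name}: expression values must be >= 0")
    return values


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples expression matrix (RPKM-scale, TSV)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty expression file") from exc
    df.index.name = None
    return validate_expression(df, name=str(path))


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "tissue", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("sample sheet: duplicate sample_id")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"sample sheet: conditions must be tumor/normal, got {sorted(bad)}")
    counts = sheet.groupby(["tissue", "condition"]).size().unstack(fill_value=0)
    for cond in CONDITIONS:
        if cond not in counts.columns or (counts[cond] < 2).any():
            raise ValidationError("sample sheet: every tissue needs >= 2 tumor and >= 2 normal samples")
    return sheet.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotations (pre-collapsed one-TSS-per-gene table)

def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "symbol": str, "chrom": str, "strand": str})
    required = {"id", "symbol", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: gene table missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids (collapse to one TSS per gene)")
    genes = []
    for row in df.itertuples(index=False):
        try:
            genes.append(GeneAnnotation(row.id, row.symbol, row.chrom, int(row.tss), row.strand))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: gene {row.id}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(g.id, g.symbol, g.chrom, g.tss, g.strand) for g in genes],
        columns=["id", "symbol", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP tables

def read_snp_table(path: str | Path) -> tuple[list[Snp], dict[str, str] | None]:
    """Read a SNP TSV (rs_id, chrom, pos, ref, alt[, cohort]).

    Positions are 1-based. Returns the SNPs plus an optional rs_id -> cohort
    map when the table carries a ``cohort`` column (the cancer type the eQTL
    record came from).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rs_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: SNP table missing columns {sorted(missing)}")
    if df["rs_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate rs_id")
    snps = []
    for row in df.itertuples(index=False):
        try:
            snps.append(Snp(row.rs_id, row.chrom, int(row.pos), row.ref, row.alt))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: SNP {row.rs_id}: {exc}") from exc
    cohorts = dict(zip(df["rs_id"], df["cohort"])) if "cohort" in df.columns else None
    return snps, cohorts


def write_snp_table(snps: Iterable[Snp], path: str | Path,
                    cohorts: Mapping[str, str] | None = None) -> None:
    rows = []
    for s in snps:
        row = {"rs_id": s.rs_id, "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
        if cohorts is not None:
            row["cohort"] = cohorts.get(s.rs_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# motif models (JASPAR-style PFM)

UNIFORM_BG = np.full(4, 0.25)


def read_pfm(path: str | Path, pseudocount: float = 0.8,
             background: np.ndarray | None = None) -> list[Pwm]:
    """Parse a JASPAR-style PFM file into probability matrices.

    Each record is a ``>name`` header followed by 4 count rows (A, C, G, T;
    an optional leading base letter and brackets are tolerated). Counts are
    converted to probabilities with the pseudocount distributed according to
    the background composition.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    pwms: list[Pwm] = []
    name: str | None = None
    rows: list[list[float]] = []
    seen: set[str] = set()

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise ParseError(f"{path}:{lineno}: motif {name!r} needs exactly 4 count rows")
        counts = np.array(rows, dtype=float).T  # L x 4
        if counts.shape[0] < 1:
            raise ParseError(f"{path}:{lineno}: motif {name!r} has zero length")
        if np.any(counts < 0):
            raise ValidationError(f"{path}: motif {name!r} has negative counts")
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount * bg) / (totals + pseudocount)
        if name in seen:
            raise ValidationError(f"{path}: duplicate motif name {name!r}")
        seen.add(name)
        pwms.append(Pwm(name, probs, bg))
        name, rows = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                tokens = line[1:].split()
                if not tokens:
                    raise ParseError(f"{path}:{lineno}: empty motif header")
                # JASPAR headers are "ID NAME"; prefer the TF name when given
                name = tokens[1] if len(tokens) > 1 else tokens[0]
            else:
                if name is None:
                    raise ParseError(f"{path}:{lineno}: counts before any '>' header")
                body = line
                if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                try:
                    rows.append([float(x) for x in body.split()])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric count row") from exc
                if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                    raise ParseError(f"{path}:{lineno}: ragged count rows for motif {name!r}")
        flush(lineno)
    if not pwms:
        raise ValidationError(f"{path}: no motifs found")
    return pwms


def write_pfm(pwms: Iterable[Pwm], path: str | Path, scale: float = 100.0) -> None:
    """Write motifs as JASPAR-style count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name}\t{pwm.tf_name}\n")
            counts = pwm.probs.T * scale  # 4 x L
            for base, row in zip("ACGT", counts):
                fh.write(base + "  [ " + " ".join(f"{v:.2f}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path):
    from .records import GeneSet

    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >= 1 member")
            name, desc, members = cols[0], cols[1], [m for m in cols[2:] if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, frozenset(members), desc))
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# enhancer sequences (FASTA keyed by enhancer id)

def read_sequences_fasta(path: str | Path) -> dict[str, tuple[GenomicInterval | None, str]]:
    """Read enhancer sequences; headers are ``>enh_id chrom:start-end`` where
    the region is the (extended) interval the sequence covers."""
    out: dict[str, tuple[GenomicInterval | None, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        region = None
        if rec.description and " " in rec.description:
            loc = rec.description.split()[1]
            if ":" in loc and "-" in loc:
                chrom, span = loc.rsplit(":", 1)
                start_s, end_s = span.split("-")
                region = GenomicInterval(chrom, int(start_s), int(end_s))
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = (region, str(rec.seq).upper())
    if not out:
        raise ValidationError(f"{path}: no sequences found")
    return out


def write_sequences_fasta(seqs: Mapping[str, tuple[GenomicInterval, str]], path: str | Path) -> None:
    records = []
    for eid, (region, seq) in seqs.items():
        rec = SeqRecord(Seq(seq), id=eid,
                        description=f"{region.chrom}:{region.start}-{region.end}")
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# generic record output

def write_records_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis record table with a stable, documented column order."""
    df.to_csv(path, sep="\t", index=False)
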