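"""Coordinate-bearing record types and genomic window arithmetic.

All intervals are BED-style: 0-based, half-open [start, end). SNP input
positions follow the VCF convention (1-based) and are converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig
from .errors import ValidationError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Abutting intervals ([100,200) vs [200,300)) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Enhancer:
    """An (unstranded) enhancer region with a stable identifier."""

    id: str
    interval: GenomicInterval

    @property
    def center(self) -> int:
        """Midpoint of the region, floor for even lengths."""
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene with a single pre-collapsed TSS; strand is mandatory because
    promoter geometry is strand-dependent."""

    id: str
    symbol: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValidationError(f"gene {self.id}: tss must be >= 0")


def promoter_region(gene: GeneAnnotation, cfg: PipelineConfig) -> GenomicInterval:
    """Strand-aware promoter window: upstream bp before the TSS, downstream
    bp after it (0.5 kb / 1 kb by default), clamped at position 0."""
    up, down = cfg.promoter_upstream, cfg.promoter_downstream
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def enhancer_window(e: Enhancer, cfg: PipelineConfig) -> GenomicInterval:
    """Symmetric +/-link_window bp region around the enhancer center used to
    nominate candidate target genes."""
    if cfg.link_window <= 0:
        raise ValidationError("link_window must be > 0 for a non-degenerate window")
    c = e.center
    return GenomicInterval(e.interval.chrom, max(0, c - cfg.link_window), c + cfg.link_window)


def extend_enhancer(e: Enhancer, cfg: PipelineConfig) -> GenomicInterval:
    """Enhancer boundary extended by snp_flank bp on each side (SNP mapping)."""
    iv = e.interval
    return GenomicInterval(iv.chrom, max(0, iv.start - cfg.snp_flank), iv.end + cfg.snp_flank)
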