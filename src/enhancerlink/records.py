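"""Non-coordinate domain records: SNPs, motif models, gene sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Snp:
    """A biallelic single-nucleotide variant; ``pos`` is 1-based (VCF style)."""

    rs_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.rs_id}: pos is 1-based, must be >= 1")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if allele not in BASE_INDEX:
                raise ValidationError(f"{self.rs_id}: {name} allele must be one of ACGT")
        if self.ref == self.alt:
            raise ValidationError(f"{self.rs_id}: ref and alt alleles must differ")

    @property
    def pos0(self) -> int:
        """0-based position, for interval arithmetic."""
        return self.pos - 1


@dataclass(frozen=True)
class Pwm:
    """A position probability matrix (L x 4, columns ordered A,C,G,T) with a
    background base composition. Rows must each sum to 1."""

    tf_name: str
    probs: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValidationError(f"{self.tf_name}: probs must be an L x 4 matrix, L >= 1")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError(f"{self.tf_name}: each PWM row must sum to 1")
        if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValidationError(f"{self.tf_name}: background must be 4 positive probs summing to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 matrix of log2(p_ib / bg_b); zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @property
    def information_content(self) -> np.ndarray:
        """Per-position Kullback-Leibler information against background, bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.probs > 0, self.probs * (np.log2(self.probs) - np.log2(self.background)), 0.0)
        return terms.sum(axis=1)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
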