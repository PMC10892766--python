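"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (the VCF/GFF convention);
``length = end - start + 1``. Conversion to BED's 0-based half-open
system happens only at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class SvType(str, enum.Enum):
    """Structural-variant call type consumed by the pipeline."""

    DEL = "DEL"
    DUP = "DUP"


class CnvrType(str, enum.Enum):
    """CNVR class: only deletions, only duplications, or both overlapping."""

    LOSS = "loss"
    GAIN = "gain"
    MIXED = "mixed"


@dataclass(frozen=True)
class CnvCall:
    """One filtered DEL/DUP call for one sample on one chromosome."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive (VCF POS)
    end: int    # 1-based inclusive (VCF INFO/END)
    svtype: SvType
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"CnvCall end < start ({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Cnvr:
    """A copy-number-variation region: overlapping calls merged across samples."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    cnvr_type: CnvrType
    supporting_calls: list[CnvCall] = field(default_factory=list)
    carriers: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class GeneModel:
    """A gene feature from GFF3, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"GeneModel end < start for {self.gene_id}")


@dataclass
class GenotypeMatrix:
    """Samples x CNVRs coding matrix with entries in {-1, 0, +1}.

    +1 codes a gain carrier, -1 a loss carrier, 0 the normal (2n) state.
    ``frequencies[j]`` is the carrier frequency of column j: the fraction
    of samples with a nonzero code.
    """

    sample_ids: list[str]
    cnvr_ids: list[str]
    codes: np.ndarray  # shape (n_samples, n_cnvr), int8
    frequencies: np.ndarray  # shape (n_cnvr,)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.sample_ids), len(self.cnvr_ids)):
            raise ValueError("GenotypeMatrix dimensions inconsistent")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (len(self.cnvr_ids),):
            raise ValueError("frequency vector length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cnvr(self) -> int:
        return len(self.cnvr_ids)

    def column(self, cnvr_id: str) -> np.ndarray:
        return self.codes[:, self.cnvr_ids.index(cnvr_id)]


@dataclass
class GrmMatrix:
    """CNV-derived genomic relationship matrix (symmetric, PSD up to tolerance)."""

    sample_ids: list[str]
    values: np.ndarray  # (n, n)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRM contains non-finite entries")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)
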