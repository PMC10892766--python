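"""Proximal-gene annotation of significant CNVRs.

A gene is proximal to a CNVR when it intersects the window formed by
extending the region ``flank`` bp up- and downstream (default 50 kb each
side, i.e. a 100 kb window plus the region itself). Intervals are closed
and 1-based; intersection means sharing at least one base, so a gene
ending exactly at ``start - flank`` is included. Strand is ignored — the
window is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Cnvr, GeneModel

DEFAULT_FLANK = 50_000

#: How a proximal gene relates to the region itself.
INSIDE = "inside"            # gene entirely within the CNVR
OVERLAPS_CNVR = "overlaps_cnvr"  # intersects the CNVR but extends beyond it
FLANK_ONLY = "flank_only"    # intersects only the flanking window


@dataclass
class AnnotatedCnvr:
    """A CNVR with its flanking window and the genes intersecting it."""

    cnvr_id: str
    window_start: int
    window_end: int
    genes: list[tuple[GeneModel, str]]  # (gene, overlap class), sorted by start

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g, _ in self.genes]


class GeneIndex:
    """Per-chromosome sorted gene arrays for binary-search window queries."""

    def __init__(self, genes: list[GeneModel]) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in per_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
            starts = np.array([g.start for g in gs], dtype=np.int64)
            ends = np.array([g.end for g in gs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, gs)

    def query(self, chrom: str, lo: int, hi: int) -> list[GeneModel]:
        """Genes on ``chrom`` intersecting the closed interval [lo, hi]."""
        if chrom not in self._by_chrom:
            return []
        starts, ends, gs = self._by_chrom[chrom]
        # candidates: start <= hi (prefix by binary search), then end >= lo
        k = int(np.searchsorted(starts, hi, side="right"))
        hit = np.nonzero(ends[:k] >= lo)[0]
        return [gs[i] for i in hit]


def _overlap_class(gene: GeneModel, cnvr: Cnvr) -> str:
    if gene.start >= cnvr.start and gene.end <= cnvr.end:
        return INSIDE
    if gene.start <= cnvr.end and gene.end >= cnvr.start:
        return OVERLAPS_CNVR
    return FLANK_ONLY


def proximal_genes(
    cnvr: Cnvr,
    genes: list[GeneModel] | GeneIndex,
    flank: int = DEFAULT_FLANK,
) -> AnnotatedCnvr:
    """Genes intersecting the CNVR's flanking window, classified and sorted.

    ``genes`` may be a plain list or a prebuilt :class:`GeneIndex` (reuse
    the index when annotating many regions).
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    lo = max(1, cnvr.start - flank)
    hi = cnvr.end + flank
    hits = index.query(cnvr.chrom, lo, hi)
    hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return AnnotatedCnvr(
        cnvr_id=cnvr.cnvr_id,
        window_start=lo,
        window_end=hi,
        genes=[(g, _overlap_class(g, cnvr)) for g in hits],
    )


def annotate_cnvrs(
    cnvrs: list[Cnvr],
    genes: list[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> dict[str, AnnotatedCnvr]:
    """Annotate many regions against one shared gene index."""
    index = GeneIndex(genes)
    return {c.cnvr_id: proximal_genes(c, index, flank=flank) for c in cnvrs}
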