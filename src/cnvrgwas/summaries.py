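"""CNVR landscape summaries: per-chromosome statistics, type distribution,
size-bin distribution, and plot-ready genome tracks.

Percentages and mean sizes are rounded half-up to one decimal, matching
the conventional presentation of such tables.
"""

from __future__ import annotations

import logging
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .types import Cnvr, CnvrType

logger = logging.getLogger(__name__)

#: Size-bin edges in bp: 0.05-1 kb, 1-5 kb, 5-10 kb, 10-50 kb, >50 kb.
DEFAULT_SIZE_EDGES = (50, 1_000, 5_000, 10_000, 50_000)

SUMMARY_COLUMNS = [
    "chrom", "chrom_length", "cnvr_count", "cnvr_total_length",
    "coverage_pct", "max_size", "mean_size", "min_size",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (5 rounds up), unlike banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def per_chromosome_summary(
    cnvrs: list[Cnvr], chroms: pd.DataFrame
) -> pd.DataFrame:
    """One summary row per chromosome plus an 'overall' row.

    Chromosomes without CNVRs get a zero-filled row. The overall row sums
    counts and lengths, its mean is total length / total count, and its
    coverage uses the summed chromosome lengths.
    """
    known = dict(zip(chroms["chrom"], chroms["length"]))
    for r in cnvrs:
        if r.chrom not in known:
            raise ValueError(f"CNVR {r.cnvr_id} on unknown chromosome {r.chrom!r}")
    lengths_by_chrom: dict[str, list[int]] = {c: [] for c in known}
    for r in cnvrs:
        lengths_by_chrom[r.chrom].append(r.length)

    rows = []
    for chrom, chrom_len in known.items():
        sizes = lengths_by_chrom[chrom]
        if sizes:
            total = int(np.sum(sizes))
            rows.append({
                "chrom": chrom,
                "chrom_length": int(chrom_len),
                "cnvr_count": len(sizes),
                "cnvr_total_length": total,
                "coverage_pct": round_half_up(100.0 * total / chrom_len),
                "max_size": int(max(sizes)),
                "mean_size": round_half_up(total / len(sizes)),
                "min_size": int(min(sizes)),
            })
        else:
            rows.append({
                "chrom": chrom, "chrom_length": int(chrom_len),
                "cnvr_count": 0, "cnvr_total_length": 0, "coverage_pct": 0.0,
                "max_size": 0, "mean_size": 0.0, "min_size": 0,
            })
    total_len = sum(r["cnvr_total_length"] for r in rows)
    total_count = sum(r["cnvr_count"] for r in rows)
    genome_len = int(chroms["length"].sum())
    all_sizes = [s for v in lengths_by_chrom.values() for s in v]
    rows.append({
        "chrom": "overall",
        "chrom_length": genome_len,
        "cnvr_count": total_count,
        "cnvr_total_length": total_len,
        "coverage_pct": round_half_up(100.0 * total_len / genome_len),
        "max_size": int(max(all_sizes)) if all_sizes else 0,
        "mean_size": round_half_up(total_len / total_count) if total_count else 0.0,
        "min_size": int(min(all_sizes)) if all_sizes else 0,
    })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def type_distribution(cnvrs: list[Cnvr]) -> dict[str, int]:
    """Counts of loss / gain / mixed CNVRs."""
    counts = Counter(r.cnvr_type for r in cnvrs)
    return {t.value: counts.get(t, 0) for t in CnvrType}


def size_distribution(
    cnvrs: list[Cnvr] | list[int],
    edges: tuple[int, ...] = DEFAULT_SIZE_EDGES,
) -> pd.DataFrame:
    """Histogram of CNVR lengths over half-open bins [e_k, e_{k+1}).

    The last bin is unbounded above. Accepts regions or raw lengths.
    Lengths below the first edge land in an 'underflow' row and are
    logged. Percentages are half-up rounded to one decimal.
    """
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("size-bin edges must be strictly increasing")
    lengths = np.array(
        [r.length if isinstance(r, Cnvr) else int(r) for r in cnvrs], dtype=np.int64
    )
    labels = [
        f"[{a},{b})" for a, b in zip(edges, edges[1:])
    ] + [f">={edges[-1]}"]
    counts = np.zeros(len(labels), dtype=np.int64)
    if lengths.size:
        bin_idx = np.searchsorted(edges, lengths, side="right") - 1
        under = bin_idx < 0
        if under.any():
            logger.warning(
                "%d CNVR(s) shorter than the first size edge %d bp",
                int(under.sum()), edges[0],
            )
        for k in range(len(labels)):
            counts[k] = int((bin_idx == k).sum())
    out_labels, out_counts = list(labels), list(counts)
    n_under = int(lengths.size - counts.sum()) if lengths.size else 0
    if n_under:
        out_labels = [f"<{edges[0]}"] + out_labels
        out_counts = [n_under] + out_counts
    total = int(lengths.size)
    pct = [round_half_up(100.0 * c / total) if total else 0.0 for c in out_counts]
    return pd.DataFrame({"bin": out_labels, "count": out_counts, "percent": pct})


def genome_track(cnvrs: list[Cnvr], chroms: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready segments in Mb, one row per CNVR, colored by type.

    Chromosomes without CNVRs simply contribute no rows.
    """
    known = set(chroms["chrom"])
    rows = [
        {
            "chrom": r.chrom,
            "start_mb": r.start / 1e6,
            "end_mb": r.end / 1e6,
            "type": r.cnvr_type.value,
            "cnvr_id": r.cnvr_id,
        }
        for r in cnvrs
        if r.chrom in known
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start_mb", "end_mb", "type", "cnvr_id"]
    )
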