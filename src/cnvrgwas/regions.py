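"""CNVR construction: size filtering, cross-sample merging, classification,
and the three-state coded genotype matrix with its carrier-frequency filter.

A CNVR is a connected component of the interval-overlap graph of the
filtered calls on one chromosome (overlap = sharing at least one base;
book-ended intervals are *not* merged). The region spans the min start to
the max end of its component, is typed loss / gain / mixed by the call
types it contains, and its carriers are the distinct samples supporting
it.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .types import CnvCall, Cnvr, CnvrType, GenotypeMatrix, SvType

logger = logging.getLogger(__name__)

DEFAULT_MIN_BP = 50
DEFAULT_MAX_BP = 5_000_000
DEFAULT_MIN_FREQ = 0.005

_TYPE_PREFIX = {CnvrType.LOSS: "DEL", CnvrType.GAIN: "DUP", CnvrType.MIXED: "MIX"}


def filter_calls_by_size(
    calls: list[CnvCall],
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
) -> list[CnvCall]:
    """Keep calls whose length lies in [min_bp, max_bp], bounds inclusive."""
    if min_bp > max_bp:
        raise ValueError(f"min_bp ({min_bp}) > max_bp ({max_bp})")
    return [c for c in calls if min_bp <= c.length <= max_bp]


def classify_cnvr(supporting_calls: list[CnvCall]) -> CnvrType:
    """loss if all calls are DEL, gain if all DUP, mixed otherwise."""
    if not supporting_calls:
        raise ValueError("cannot classify a CNVR with no supporting calls")
    types = {c.svtype for c in supporting_calls}
    if types == {SvType.DEL}:
        return CnvrType.LOSS
    if types == {SvType.DUP}:
        return CnvrType.GAIN
    return CnvrType.MIXED


def merge_to_cnvrs(calls: list[CnvCall]) -> list[Cnvr]:
    """Merge overlapping calls across samples into typed CNVRs.

    Per chromosome the calls are sorted by start and swept once: a call
    whose start is <= the running end of the open component overlaps it
    and extends it; otherwise the component is closed as one CNVR. Output
    is sorted by (chrom, start) with ids DEL/DUP/MIX + zero-padded index
    assigned in sort order, so the result is independent of input order.
    """
    by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)

    merged: list[tuple[str, int, int, list[CnvCall]]] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(
            by_chrom[chrom], key=lambda c: (c.start, c.end, c.sample_id, c.svtype.value)
        )
        cur_start, cur_end = chrom_calls[0].start, chrom_calls[0].end
        cur_members = [chrom_calls[0]]
        for call in chrom_calls[1:]:
            if call.start <= cur_end:  # shares >=1 bp
                cur_end = max(cur_end, call.end)
                cur_members.append(call)
            else:
                merged.append((chrom, cur_start, cur_end, cur_members))
                cur_start, cur_end, cur_members = call.start, call.end, [call]
        merged.append((chrom, cur_start, cur_end, cur_members))

    cnvrs: list[Cnvr] = []
    for idx, (chrom, start, end, members) in enumerate(merged, start=1):
        ctype = classify_cnvr(members)
        cnvrs.append(
            Cnvr(
                cnvr_id=f"{_TYPE_PREFIX[ctype]}{idx:08d}",
                chrom=chrom,
                start=start,
                end=end,
                cnvr_type=ctype,
                supporting_calls=members,
                carriers=frozenset(c.sample_id for c in members),
            )
        )
    return cnvrs


def filter_cnvrs_by_size(
    cnvrs: list[Cnvr],
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
) -> list[Cnvr]:
    """Size-select merged regions (same inclusive bounds as the call filter)."""
    if min_bp > max_bp:
        raise ValueError(f"min_bp ({min_bp}) > max_bp ({max_bp})")
    return [r for r in cnvrs if min_bp <= r.length <= max_bp]


def build_genotype_matrix(
    cnvrs: list[Cnvr], samples: list[str]
) -> GenotypeMatrix:
    """Code each (sample, CNVR) cell as +1 gain / -1 loss / 0 normal.

    A sample's code in a region is driven by its own supporting calls
    there: all-DEL -> -1, all-DUP -> +1, none -> 0. The rare sample with
    both call types in one region is coded by the type with the larger
    total overlapped length; an exact tie codes -1, since losses dominate
    the landscape. Each conflict is logged.
    """
    sample_index = {s: i for i, s in enumerate(samples)}
    n, m = len(samples), len(cnvrs)
    codes = np.zeros((n, m), dtype=np.int8)
    for j, region in enumerate(cnvrs):
        per_sample: dict[str, dict[SvType, int]] = defaultdict(
            lambda: {SvType.DEL: 0, SvType.DUP: 0}
        )
        for call in region.supporting_calls:
            if call.sample_id not in sample_index:
                raise ValueError(
                    f"call sample {call.sample_id!r} not in the sample list"
                )
            ov = min(call.end, region.end) - max(call.start, region.start) + 1
            per_sample[call.sample_id][call.svtype] += max(ov, 0)
        for sid, lengths in per_sample.items():
            i = sample_index[sid]
            if lengths[SvType.DEL] and lengths[SvType.DUP]:
                logger.info(
                    "sample %s carries both DEL and DUP in %s; coding by "
                    "larger overlap (DEL=%d, DUP=%d)",
                    sid, region.cnvr_id, lengths[SvType.DEL], lengths[SvType.DUP],
                )
                codes[i, j] = 1 if lengths[SvType.DUP] > lengths[SvType.DEL] else -1
            elif lengths[SvType.DUP]:
                codes[i, j] = 1
            else:
                codes[i, j] = -1
    freqs = (codes != 0).sum(axis=0) / n if n else np.zeros(m)
    return GenotypeMatrix(
        sample_ids=list(samples),
        cnvr_ids=[r.cnvr_id for r in cnvrs],
        codes=codes,
        frequencies=freqs,
    )


def frequency_filter(
    gm: GenotypeMatrix, min_freq: float = DEFAULT_MIN_FREQ
) -> GenotypeMatrix:
    """Retain columns whose carrier frequency is strictly above min_freq."""
    if not (0 <= min_freq < 1):
        raise ValueError(f"min_freq must be in [0, 1), got {min_freq}")
    keep = gm.frequencies > min_freq
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        cnvr_ids=[cid for cid, k in zip(gm.cnvr_ids, keep) if k],
        codes=gm.codes[:, keep],
        frequencies=gm.frequencies[keep],
    )
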