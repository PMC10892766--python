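"""Synthetic CNV landscapes, structural-variant VCFs and phenotypes.

The generator emulates the statistical shape of a real laying-hen CNV
survey: a landscape dominated by losses (defaults 94.7% loss / 4.4% gain
/ 0.9% mixed), region sizes concentrated below 1 kb with a long tail
(87.4 / 9.6 / 1.3 / 1.5 / 0.2 % across the 0.05-1 / 1-5 / 5-10 / 10-50 /
>50 kb bins), low carrier frequencies, and phenotypes drawn from the
mixed model y = mu + W g + u + e with u ~ N(0, G sigma2_a) and chosen
heritability. Mixed regions are simulated as genuinely overlapping DEL
and DUP calls, never as an atomic third type, so the merge/classify path
is exercised. All draws are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import merge_to_cnvrs
from .types import CnvCall, Cnvr, GenotypeMatrix, GrmMatrix, SvType

DEFAULT_TYPE_PROPORTIONS = (0.947, 0.044, 0.009)  # loss, gain, mixed
DEFAULT_SIZE_EDGES = (50, 1_000, 5_000, 10_000, 50_000, 650_000)
DEFAULT_SIZE_MASSES = (0.874, 0.096, 0.013, 0.015, 0.002)


@dataclass
class SimulationConfig:
    """Stated world for the generators; defaults mirror the emulated survey."""

    seed: int = 0
    n_samples: int = 834
    n_cnvr: int = 500
    chromosomes: pd.DataFrame | None = None  # default: shipped autosome table
    type_proportions: tuple[float, float, float] = DEFAULT_TYPE_PROPORTIONS
    size_edges: tuple[int, ...] = DEFAULT_SIZE_EDGES
    size_masses: tuple[float, ...] = DEFAULT_SIZE_MASSES
    carrier_freq_beta: tuple[float, float] = (1.0, 15.0)
    carrier_freq_range: tuple[float, float] = (0.001, 0.5)
    jitter: float = 0.0  # +/- fractional span noise on individual calls
    n_causal: int = 0
    causal_variance_fractions: tuple[float, ...] = ()
    h2_polygenic: float = 0.3
    mu: float = 0.0
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if len(self.size_masses) != len(self.size_edges) - 1:
            raise ValueError("need one size mass per bin")
        if abs(sum(self.size_masses) - 1.0) > 1e-9:
            raise ValueError("size-bin masses must sum to 1")
        if self.n_causal != len(self.causal_variance_fractions):
            if self.n_causal and not self.causal_variance_fractions:
                # one default fraction per causal region
                self.causal_variance_fractions = tuple(
                    [0.1] * self.n_causal
                )
            else:
                raise ValueError("n_causal != len(causal_variance_fractions)")
        total = self.h2_polygenic + sum(self.causal_variance_fractions)
        if not 0 <= total < 1:
            raise ValueError("h2 + causal variance fractions must be in [0, 1)")

    def chromosome_table(self) -> pd.DataFrame:
        if self.chromosomes is not None:
            return self.chromosomes
        from .io import default_chromosome_table

        return default_chromosome_table()

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests."""

    sample_ids: list[str]
    regions: list[Cnvr] = field(default_factory=list)
    calls: list[CnvCall] = field(default_factory=list)
    carrier_freqs: dict[str, float] = field(default_factory=dict)
    causal_ids: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)
    h2_polygenic: float = 0.0
    polygenic_values: np.ndarray | None = None


def _draw_sizes(rng: np.random.Generator, n: int,
                edges: tuple[int, ...], masses: tuple[float, ...]) -> np.ndarray:
    """Bin by mass, then log-uniform within the bin (sizes skew small)."""
    bins = rng.choice(len(masses), size=n, p=np.asarray(masses) / sum(masses))
    lo = np.asarray(edges[:-1], dtype=float)[bins]
    hi = np.asarray(edges[1:], dtype=float)[bins]
    u = rng.uniform(size=n)
    sizes = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    return np.clip(sizes.astype(np.int64), edges[0], edges[-1] - 1)


def simulate_cnv_landscape(cfg: SimulationConfig) -> tuple[SimulationTruth, list[Cnvr]]:
    """Place non-overlapping typed regions and their per-carrier calls.

    Regions are rejection-sampled onto chromosomes chosen proportionally
    to length; the returned CNVRs come from merging the simulated calls,
    so ids and classification follow the pipeline's own conventions.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chromosome_table()
    samples = cfg.sample_ids()
    if cfg.n_cnvr == 0:
        return SimulationTruth(sample_ids=samples), []
    if len(chroms) == 0:
        raise ValueError("chromosome table is empty")

    sizes = _draw_sizes(rng, cfg.n_cnvr, cfg.size_edges, cfg.size_masses)
    type_draw = rng.choice(3, size=cfg.n_cnvr, p=cfg.type_proportions)
    chrom_p = chroms["length"] / chroms["length"].sum()

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms["chrom"]}
    placements: list[tuple[str, int, int]] = []
    max_tries = 200 * cfg.n_cnvr
    tries = 0
    for size in sizes:
        placed = False
        while tries < max_tries:
            tries += 1
            row = chroms.iloc[int(rng.choice(len(chroms), p=chrom_p))]
            chrom, clen = str(row["chrom"]), int(row["length"])
            if clen < size + 2:
                continue
            start = int(rng.integers(1, clen - size + 1))
            end = start + int(size) - 1
            # keep a 1 bp gap so book-ended regions never merge
            if all(end + 1 < s or e + 1 < start for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                placements.append((chrom, start, end))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place all regions without overlap; "
                "use fewer or smaller regions"
            )

    a, b = cfg.carrier_freq_beta
    flo, fhi = cfg.carrier_freq_range
    freqs = flo + (fhi - flo) * rng.beta(a, b, size=cfg.n_cnvr)

    calls: list[CnvCall] = []
    truth_freqs: dict[str, float] = {}
    region_keys: list[tuple[str, int, int]] = []
    for k, (chrom, start, end) in enumerate(placements):
        kind = int(type_draw[k])  # 0 loss, 1 gain, 2 mixed
        min_carriers = 2 if kind == 2 else 1
        n_car = max(min_carriers, int(rng.binomial(cfg.n_samples, freqs[k])))
        n_car = min(n_car, cfg.n_samples)
        carriers = rng.choice(cfg.n_samples, size=n_car, replace=False)
        if kind == 2:
            n_dup = max(1, int(rng.integers(1, n_car)))
            dup_set = set(carriers[:n_dup].tolist())
        elif kind == 1:
            dup_set = set(carriers.tolist())
        else:
            dup_set = set()
        for ci in carriers:
            s, e = start, end
            if cfg.jitter > 0:
                span = end - start + 1
                ds = int(rng.integers(0, max(1, int(cfg.jitter * span)) + 1))
                de = int(rng.integers(0, max(1, int(cfg.jitter * span)) + 1))
                s, e = start + ds, end - de
                if e < s:
                    s, e = start, end
            calls.append(CnvCall(
                sample_id=samples[int(ci)],
                chrom=chrom, start=s, end=e,
                svtype=SvType.DUP if int(ci) in dup_set else SvType.DEL,
            ))
        region_keys.append((chrom, start, end))
        truth_freqs[f"{chrom}:{start}-{end}"] = n_car / cfg.n_samples

    regions = merge_to_cnvrs(calls)
    truth = SimulationTruth(
        sample_ids=samples,
        regions=regions,
        calls=calls,
        carrier_freqs=truth_freqs,
    )
    return truth, regions


def simulate_cnv_vcf(truth: SimulationTruth, cfg: SimulationConfig,
                     path: str | Path) -> None:
    """Emit the simulated calls as a minimal DELLY-style multi-sample VCF.

    Calls sharing (chrom, start, end, svtype) become one record with
    per-sample GT (0/1 for carriers); FILTER is PASS throughout.
    """
    samples = truth.sample_ids
    grouped: dict[tuple[str, int, int, str], set[str]] = {}
    for c in truth.calls:
        grouped.setdefault((c.chrom, c.start, c.end, c.svtype.value), set()).add(
            c.sample_id
        )
    chroms = cfg.chromosome_table()
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FILTER=<ID=PASS,Description="All filters passed">',
    ]
    for _, row in chroms.iterrows():
        lines.append(f"##contig=<ID={row['chrom']},length={int(row['length'])}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )

    def _key(item):
        (chrom, start, end, svtype), _ = item
        return ((0, int(chrom)) if chrom.isdigit() else (1, chrom),
                start, end, svtype)

    for i, ((chrom, start, end, svtype), carriers) in enumerate(
        sorted(grouped.items(), key=_key), start=1
    ):
        gts = "\t".join("0/1" if s in carriers else "0/0" for s in samples)
        lines.append(
            f"{chrom}\t{start}\tSV{i:07d}\tN\t<{svtype}>\t.\tPASS\t"
            f"SVTYPE={svtype};END={end}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_phenotypes(
    gm: GenotypeMatrix,
    grm: GrmMatrix,
    cfg: SimulationConfig,
    causal_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw one trait from y = mu + W g + u + e on the given genotypes.

    Causal effect sizes are back-computed so each causal CNVR explains
    its configured variance fraction given its empirical code variance;
    the polygenic term u has covariance sigma2_a G with
    sigma2_a = h2_polygenic, and the residual absorbs the rest so the
    total modeled variance is 1.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if gm.sample_ids != grm.sample_ids:
        raise ValueError("genotype and GRM sample orders differ")
    n = gm.n_samples
    if causal_ids is None:
        variances = gm.codes.astype(float).var(axis=0)
        eligible = [i for i in range(gm.n_cnvr) if variances[i] > 0]
        if cfg.n_causal > len(eligible):
            raise ValueError("not enough variable CNVRs to host causal effects")
        picked = rng.choice(len(eligible), size=cfg.n_causal, replace=False)
        causal_ids = [gm.cnvr_ids[eligible[int(i)]] for i in picked]
    effects: dict[str, float] = {}
    genetic = np.zeros(n)
    for cid, vf in zip(causal_ids, cfg.causal_variance_fractions):
        w = gm.column(cid).astype(float)
        v = w.var()
        if v == 0:
            raise ValueError(f"causal CNVR {cid} has zero code variance")
        beta = float(rng.choice([-1.0, 1.0])) * np.sqrt(vf / v)
        effects[cid] = beta
        genetic += beta * w

    sigma2_a = cfg.h2_polygenic
    sigma2_e = 1.0 - sigma2_a - sum(cfg.causal_variance_fractions)
    if sigma2_a > 0:
        d, u_mat = np.linalg.eigh(grm.values)
        d = np.clip(d, 0.0, None)
        poly = u_mat @ (np.sqrt(d * sigma2_a) * rng.standard_normal(n))
    else:
        poly = np.zeros(n)
    e = rng.standard_normal(n) * np.sqrt(sigma2_e)
    y = cfg.mu + genetic + poly + e
    phen = pd.DataFrame({cfg.trait_name: y},
                        index=pd.Index(gm.sample_ids, name="sample_id"))
    truth = SimulationTruth(
        sample_ids=list(gm.sample_ids),
        causal_ids=list(causal_ids),
        effects=effects,
        h2_polygenic=sigma2_a,
        polygenic_values=poly,
    )
    return phen, truth
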