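"""End-to-end orchestration: VCF -> CNVRs -> genotypes -> GRM -> GWAS ->
annotation -> summaries, with a machine-readable run manifest.

Stages run in a fixed order and every stage's row counts are recorded in
the manifest, so a rerun with identical inputs and configuration is
bit-identical and auditable. The defaults are the analysis constants of
the emulated survey (50 bp - 5 Mb size window, 0.5% carrier-frequency
floor, Bonferroni 0.05/N, 50 kb annotation flank).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import DEFAULT_FLANK, annotate_cnvrs
from .grm import DEFAULT_RIDGE, add_ridge, compute_grm
from .io import (
    cnvr_table,
    read_chromosome_table,
    read_cnv_vcf,
    read_gff,
    read_phenotypes,
    vcf_samples,
    write_cnvr_bed,
    write_grm,
)
from .mlm import GwasRun, association_table, manhattan_qq_data, run_gwas
from .regions import (
    DEFAULT_MAX_BP,
    DEFAULT_MIN_BP,
    DEFAULT_MIN_FREQ,
    build_genotype_matrix,
    filter_calls_by_size,
    filter_cnvrs_by_size,
    frequency_filter,
    merge_to_cnvrs,
)
from .summaries import (
    genome_track,
    per_chromosome_summary,
    size_distribution,
    type_distribution,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, filters and model settings for one run."""

    vcf: str
    phenotypes: str
    chromosomes: str
    out_dir: str
    gff: str | None = None
    traits: list[str] | None = None  # default: every phenotype column
    min_bp: int = DEFAULT_MIN_BP
    max_bp: int = DEFAULT_MAX_BP
    min_freq: float = DEFAULT_MIN_FREQ
    alpha: float = 0.05
    multiple_testing: str = "bonferroni"
    ridge: float = DEFAULT_RIDGE
    flank: int = DEFAULT_FLANK
    require_pass: bool = True
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    cnvrs: list
    genotype_matrix: object
    grm: object
    runs: dict[str, GwasRun]
    annotations: dict
    manifest: dict
    out_dir: Path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write all artifacts to cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | dict] = {}

    def stage(name: str):
        def _raise(exc: Exception):
            raise PipelineError(name, str(exc)) from exc
        return _raise

    for name, p in (("read_vcf", cfg.vcf), ("read_phenotypes", cfg.phenotypes),
                    ("read_chromosomes", cfg.chromosomes)):
        if not Path(p).exists():
            raise PipelineError(name, f"input file not found: {p}")
    if cfg.gff is not None and not Path(cfg.gff).exists():
        raise PipelineError("annotate", f"GFF file not found: {cfg.gff}")

    try:
        chroms = read_chromosome_table(cfg.chromosomes)
        samples = vcf_samples(cfg.vcf)
        calls = read_cnv_vcf(cfg.vcf, require_pass=cfg.require_pass)
    except PipelineError:
        raise
    except Exception as e:
        stage("read")(e)
    counts["samples"] = len(samples)
    counts["calls_read"] = len(calls)

    try:
        calls = filter_calls_by_size(calls, cfg.min_bp, cfg.max_bp)
        counts["calls_after_size_filter"] = len(calls)
        cnvrs = merge_to_cnvrs(calls)
        cnvrs = filter_cnvrs_by_size(cnvrs, cfg.min_bp, cfg.max_bp)
        counts["cnvrs"] = len(cnvrs)
    except Exception as e:
        stage("merge")(e)

    try:
        gm = build_genotype_matrix(cnvrs, samples)
        gm = frequency_filter(gm, cfg.min_freq)
        counts["cnvrs_after_frequency_filter"] = gm.n_cnvr
    except Exception as e:
        stage("genotype")(e)
    tested_ids = set(gm.cnvr_ids)
    tested_cnvrs = [c for c in cnvrs if c.cnvr_id in tested_ids]

    try:
        grm = add_ridge(compute_grm(gm), cfg.ridge)
    except Exception as e:
        stage("grm")(e)

    try:
        phen = read_phenotypes(cfg.phenotypes)
    except Exception as e:
        stage("phenotypes")(e)
    traits = cfg.traits if cfg.traits is not None else list(phen.columns)

    runs: dict[str, GwasRun] = {}
    per_trait: dict[str, dict] = {}
    significant = {}
    for trait in traits:
        try:
            run = run_gwas(gm, phen, trait, grm, alpha=cfg.alpha,
                           method=cfg.multiple_testing)
        except Exception as e:
            stage(f"gwas:{trait}")(e)
        runs[trait] = run
        hits = [r.cnvr_id for r in run.results if r.significant]
        significant[trait] = hits
        per_trait[trait] = {
            "n_used": run.n_used,
            "h2": run.variance_components.h2,
            "sigma2_a": run.variance_components.sigma2_a,
            "sigma2_e": run.variance_components.sigma2_e,
            "threshold": run.threshold,
            "n_significant": len(hits),
        }

    annotations: dict = {}
    if cfg.gff is not None:
        try:
            genes = read_gff(cfg.gff)
            hit_ids = {cid for ids in significant.values() for cid in ids}
            hit_regions = [c for c in cnvrs if c.cnvr_id in hit_ids]
            annotations = annotate_cnvrs(hit_regions, genes, flank=cfg.flank)
        except PipelineError:
            raise
        except Exception as e:
            stage("annotate")(e)
        counts["genes"] = len(genes)

    # ---- artifacts -------------------------------------------------------
    try:
        cnvr_table(cnvrs, n_samples=len(samples)).to_csv(
            out / "cnvrs.tsv", sep="\t", index=False)
        write_cnvr_bed(cnvrs, out / "cnvrs.bed")
        per_chromosome_summary(cnvrs, chroms).to_csv(
            out / "chromosome_summary.tsv", sep="\t", index=False)
        tdist = type_distribution(cnvrs)
        with open(out / "type_distribution.tsv", "w") as fh:
            fh.write("type\tcount\n")
            for k, v in tdist.items():
                fh.write(f"{k}\t{v}\n")
        size_distribution(cnvrs).to_csv(
            out / "size_distribution.tsv", sep="\t", index=False)
        write_grm(grm, out / "grm.tsv")
        track = genome_track(cnvrs, chroms)
        for trait, run in runs.items():
            proximal = {
                cid: annotations[cid].gene_ids
                for cid in significant[trait] if cid in annotations
            }
            association_table(run, cnvrs, proximal).to_csv(
                out / f"assoc_{trait}.tsv", sep="\t", index=False)
            mh, qq, lam = manhattan_qq_data(run.results, tested_cnvrs)
            mh.to_csv(out / f"manhattan_{trait}.tsv", sep="\t", index=False)
            qq.to_csv(out / f"qq_{trait}.tsv", sep="\t", index=False)
            per_trait[trait]["lambda_gc"] = lam
            if cfg.make_plots:
                from . import plots

                plots.plot_manhattan(mh, run.threshold,
                                     out / f"manhattan_{trait}.png")
                plots.plot_qq(qq, lam, out / f"qq_{trait}.png")
        if cfg.make_plots:
            from . import plots

            plots.plot_genome_track(track, chroms, out / "genome_track.png")
        if annotations:
            with open(out / "annotated_hits.tsv", "w") as fh:
                fh.write("cnvr_id\ttrait\tgene_id\tgene_start\tgene_end\t"
                         "overlap_class\n")
                for trait, ids in significant.items():
                    for cid in ids:
                        ann = annotations.get(cid)
                        if ann is None:
                            continue
                        for gene, klass in ann.genes:
                            fh.write(f"{cid}\t{trait}\t{gene.gene_id}\t"
                                     f"{gene.start}\t{gene.end}\t{klass}\n")
    except PipelineError:
        raise
    except Exception as e:
        stage("write")(e)

    manifest = {
        "package": "cnvrgwas",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": counts,
        "type_distribution": tdist,
        "traits": per_trait,
        "significant": significant,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    logger.info("pipeline finished: %s", json.dumps(counts, default=int))
    return PipelineResult(
        cnvrs=cnvrs, genotype_matrix=gm, grm=grm, runs=runs,
        annotations=annotations, manifest=manifest, out_dir=out,
    )
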