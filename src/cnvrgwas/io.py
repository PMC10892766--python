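"""Readers and writers for the standard formats the pipeline touches.

Structural-variant VCF in (DELLY-style dialect: SVTYPE and END in INFO,
GT in FORMAT), plus chromosome tables, phenotype TSVs, GFF3 gene models,
and BED/TSV outputs for CNVRs and the relationship matrix.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import CnvCall, Cnvr, CnvrType, GeneModel, GrmMatrix, SvType

logger = logging.getLogger(__name__)

_SV_TYPES = {t.value for t in SvType}


def read_cnv_vcf(path: str | Path, require_pass: bool = True) -> list[CnvCall]:
    """Read DEL/DUP calls from a structural-variant VCF, one call per carrier.

    A sample is a carrier of a record when its genotype contains at least
    one copy of allele 1; ``./.`` and ``0/0`` are non-carriers. Records
    whose SVTYPE is outside {DEL, DUP} (inversions, breakends, ...) are
    skipped with a logged count. With ``require_pass`` (the default), only
    records whose FILTER matches "pass" case-insensitively are retained —
    cyvcf2 reports a PASS/'.' FILTER as None.

    Raises
    ------
    ValueError
        If a retained DEL/DUP record lacks the END INFO key, or a
        genotype cannot be interpreted.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    calls: list[CnvCall] = []
    n_skipped_type = 0
    n_filtered = 0
    for var in vcf:
        svtype = var.INFO.get("SVTYPE")
        if svtype is None:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} has no SVTYPE INFO field"
            )
        if svtype not in _SV_TYPES:
            n_skipped_type += 1
            continue
        filter_status = var.FILTER if var.FILTER is not None else "PASS"
        if require_pass and "pass" not in filter_status.lower():
            n_filtered += 1
            continue
        end = var.INFO.get("END")
        if end is None:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} ({svtype}) has no END INFO field"
            )
        gts = var.genotypes  # [[a0, a1, phased], ...]
        for i, sample in enumerate(samples):
            alleles = gts[i][:-1]
            if any(a not in (-1, 0, 1) for a in alleles):
                raise ValueError(
                    f"unparseable genotype {gts[i]} for sample {sample} at "
                    f"{var.CHROM}:{var.POS}"
                )
            if 1 in alleles:
                calls.append(
                    CnvCall(
                        sample_id=sample,
                        chrom=var.CHROM,
                        start=var.POS,
                        end=int(end),
                        svtype=SvType(svtype),
                        filter_status=filter_status,
                    )
                )
    if n_skipped_type:
        logger.info("skipped %d records with non-DEL/DUP SVTYPE", n_skipped_type)
    if n_filtered:
        logger.info("dropped %d records failing the PASS filter", n_filtered)
    return calls


def vcf_samples(path: str | Path) -> list[str]:
    """Sample ids from a VCF header, in file order."""
    return list(VCF(str(path)).samples)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV (header row, first column sample_id).

    Missing cells (empty or NA) become NaN, never zeros. Returns a
    DataFrame indexed by sample_id with one float column per trait.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    sample_col = df.columns[0]
    if df[sample_col].duplicated().any():
        dups = df[sample_col][df[sample_col].duplicated()].tolist()
        raise ValueError(f"duplicate sample_id(s) in phenotype file: {dups[:5]}")
    df = df.set_index(sample_col)
    df.index.name = "sample_id"
    df = df.apply(pd.to_numeric, errors="coerce")
    for trait in df.columns:
        if df[trait].isna().all():
            logger.warning("trait %r has no non-missing values", trait)
    return df


def read_chromosome_table(path: str | Path) -> pd.DataFrame:
    """Read a chromosome-length TSV with columns ``chrom`` and ``length``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "length"}.issubset(df.columns):
        raise ValueError("chromosome table needs columns 'chrom' and 'length'")
    df = df[["chrom", "length"]].copy()
    df["length"] = df["length"].astype(np.int64)
    if (df["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    if df["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome names")
    return df.reset_index(drop=True)


def default_chromosome_table() -> pd.DataFrame:
    """The 38 chicken autosome lengths shipped with the package."""
    with resources.as_file(
        resources.files("cnvrgwas.data") / "chicken_autosomes.tsv"
    ) as p:
        return read_chromosome_table(p)


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Only rows of feature type ``gene`` are returned; coordinates stay
    1-based inclusive as in GFF. The gene identifier is taken from the
    ``ID`` or ``gene_id`` attribute.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            attr_map = {}
            for item in attrs.strip(";").split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if gene_id is None:
                raise ValueError(
                    f"{path}: line {lineno}: gene feature without ID/gene_id"
                )
            if strand not in ("+", "-", "."):
                strand = "."
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return genes


def write_cnvr_bed(cnvrs: list[Cnvr], path: str | Path) -> None:
    """Write CNVRs as BED6+2 (0-based half-open): name=id, extra cols type, n_carriers.

    Input must be sorted by (chrom, start); chromStart = start - 1,
    chromEnd = end.
    """
    keys = [(c.chrom, c.start) for c in cnvrs]
    if keys != sorted(keys):
        raise ValueError("CNVRs must be sorted by (chrom, start) before BED export")
    with open(path, "w") as fh:
        for c in cnvrs:
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.cnvr_id}\t0\t.\t"
                f"{c.cnvr_type.value}\t{c.n_carriers}\n"
            )


def read_cnvr_bed(path: str | Path) -> list[Cnvr]:
    """Read CNVRs back from :func:`write_cnvr_bed` output (1-based inclusive again).

    Supporting calls are not representable in BED; regions come back with
    empty call lists and anonymous carrier placeholders sized to the
    n_carriers column.
    """
    cnvrs: list[Cnvr] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, bed_start, bed_end, name, _, _, ctype, n_car = (
                line.rstrip("\n").split("\t")
            )
            cnvrs.append(
                Cnvr(
                    cnvr_id=name,
                    chrom=chrom,
                    start=int(bed_start) + 1,
                    end=int(bed_end),
                    cnvr_type=CnvrType(ctype),
                    supporting_calls=[],
                    carriers=frozenset(f"_carrier{i}" for i in range(int(n_car))),
                )
            )
    return cnvrs


def cnvr_table(cnvrs: list[Cnvr], n_samples: int | None = None) -> pd.DataFrame:
    """Tabulate CNVRs: id, chrom, start, end, type, n_carriers (+frequency)."""
    rows = [
        {
            "cnvr_id": c.cnvr_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "length": c.length,
            "type": c.cnvr_type.value,
            "n_carriers": c.n_carriers,
        }
        for c in cnvrs
    ]
    df = pd.DataFrame(
        rows,
        columns=["cnvr_id", "chrom", "start", "end", "length", "type", "n_carriers"],
    )
    if n_samples:
        df["frequency"] = df["n_carriers"] / n_samples
    return df


def write_grm(grm: GrmMatrix, path: str | Path) -> None:
    """Write a GRM as a TSV matrix with sample ids as header row and first column."""
    df = pd.DataFrame(grm.values, index=grm.sample_ids, columns=grm.sample_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_grm(path: str | Path) -> GrmMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GrmMatrix(sample_ids=[str(s) for s in df.index], values=df.to_numpy())
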