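"""Shared fixtures: tiny hand-written input files and small simulated data."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cnvrgwas.types import CnvCall, SvType

DATA_DIR = Path(__file__).parent / "data"

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=LowQual,Description="Low quality">
##contig=<ID=1,length=1000000>
##contig=<ID=2,length=500000>
"""


def make_vcf(path: Path, records: list[str], samples: list[str]) -> Path:
    """Write a minimal SV VCF from pre-formatted record lines."""
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    header += "\t".join(samples) + "\n"
    path.write_text(header + "".join(r + "\n" for r in records))
    return path


@pytest.fixture
def two_sample_del_vcf(tmp_path):
    """One PASS DEL record; sample A is a het carrier, sample B is 0/0."""
    return make_vcf(
        tmp_path / "two.vcf",
        ["1\t100\tSV1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\tGT\t0/1\t0/0"],
        ["A", "B"],
    )


@pytest.fixture
def four_sample_vcf(tmp_path):
    """3 records x 4 samples with carriers enumerated by hand.

    rec1 DEL 1:100-250   carriers: A (0/1), C (1/1)
    rec2 DUP 1:300-600   carriers: B (0/1)
    rec3 DEL 2:50-149    carriers: A (0/1), B (0/1), D (1/1)
    plus one INV record (skipped) and one LowQual DEL (filtered).
    """
    recs = [
        "1\t100\tSV1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=250\tGT\t0/1\t0/0\t1/1\t0/0",
        "1\t300\tSV2\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=600\tGT\t0/0\t0/1\t0/0\t./.",
        "1\t700\tSV3\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=900\tGT\t0/1\t0/0\t0/0\t0/0",
        "1\t800\tSV4\tN\t<DEL>\t.\tLowQual\tSVTYPE=DEL;END=900\tGT\t0/1\t0/1\t0/1\t0/1",
        "2\t50\tSV5\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=149\tGT\t0/1\t0/1\t0/0\t1/1",
    ]
    return make_vcf(tmp_path / "four.vcf", recs, ["A", "B", "C", "D"])


@pytest.fixture
def phenotype_file(tmp_path):
    p = tmp_path / "phen.tsv"
    p.write_text(
        "sample_id\tegg_weight\tbody_weight\n"
        "A\t52.1\t1.91\n"
        "B\tNA\t2.05\n"
        "C\t49.8\t1.77\n"
    )
    return p


@pytest.fixture
def gff_file(tmp_path):
    """2 gene rows, 5 exon rows, one strandless gene."""
    rows = [
        "##gff-version 3",
        "1\ttest\tgene\t1000\t5000\t.\t+\t.\tID=geneA;Name=A",
        "1\ttest\texon\t1000\t1500\t.\t+\t.\tParent=geneA",
        "1\ttest\texon\t2000\t2500\t.\t+\t.\tParent=geneA",
        "1\ttest\texon\t4000\t5000\t.\t+\t.\tParent=geneA",
        "2\ttest\tgene\t700\t900\t.\t.\t.\tID=geneB",
        "2\ttest\texon\t700\t800\t.\t.\t.\tParent=geneB",
        "2\ttest\texon\t850\t900\t.\t.\t.\tParent=geneB",
    ]
    p = tmp_path / "genes.gff3"
    p.write_text("\n".join(rows) + "\n")
    return p


@pytest.fixture
def published_summary():
    """The printed per-chromosome CNVR summary used as a recomputation fixture."""
    return pd.read_csv(
        DATA_DIR / "published_cnvr_chromosome_summary.tsv",
        sep="\t", dtype={"chrom": str},
    )


def random_calls(rng: np.random.Generator, n: int, chrom_len: int = 10_000,
                 n_samples: int = 6, chroms=("1", "2")) -> list[CnvCall]:
    """Small random call sets for merge/property tests (per-base oracle scale)."""
    calls = []
    for _ in range(n):
        start = int(rng.integers(1, chrom_len - 100))
        length = int(rng.integers(1, 300))
        calls.append(CnvCall(
            sample_id=f"S{int(rng.integers(n_samples))}",
            chrom=str(rng.choice(chroms)),
            start=start,
            end=min(start + length - 1, chrom_len),
            svtype=SvType.DEL if rng.random() < 0.9 else SvType.DUP,
        ))
    return calls
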