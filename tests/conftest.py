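"""Shared fixtures: a small simulated dataset and tiny genotype files."""

from __future__ import annotations

import numpy as np
import pytest

import jacquard as jq


@pytest.fixture(scope="session")
def small_sim():
    """One small pedigree realization shared by read-only tests."""
    cfg = jq.SimConfig(L=2000, seed=3)
    ped, freqs, genomes, g, gold = jq.simulate_dataset(cfg)
    return {
        "config": cfg,
        "pedigree": ped,
        "true_freqs": freqs,
        "genomes": genomes,
        "genotypes": g,
        "gold": gold,
    }


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return path


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples x 2 bi-allelic variants; dosages [[0,1],[1,2],[2,0]]."""
    records = [
        "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
        "1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0",
    ]
    return write_vcf(tmp_path / "tiny.vcf", records)


@pytest.fixture
def tiny_dosage_tsv(tmp_path):
    """TSV dosage matrix equivalent to tiny_vcf."""
    text = (
        "sample_id\tv1\tv2\n"
        "S1\t0\t1\n"
        "S2\t1\t2\n"
        "S3\t2\t0\n"
    )
    path = tmp_path / "tiny.tsv"
    path.write_text(text)
    return path


def random_simplex(rng, k=9):
    x = rng.dirichlet(np.ones(k))
    return x
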