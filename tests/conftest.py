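import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from colocus import data_io, synthetic
from colocus.core import ColocResult


def make_result(pp, *, Q=100, region="", disease="", probe="", gene="", cell_state="",
                classification=None, gwas_min_p=None, eqtl_min_p=None) -> ColocResult:
    """Build a ColocResult straight from a posterior vector (test helper)."""
    pp = np.asarray(pp, dtype=float)
    pp = pp / pp.sum()
    return ColocResult(
        Q=Q, pp0=pp[0], pp1=pp[1], pp2=pp[2], pp3=pp[3], pp4=pp[4],
        sum_log_abf1=0.0, sum_log_abf2=0.0,
        gwas_min_p=gwas_min_p, eqtl_min_p=eqtl_min_p, classification=classification,
        region=region, disease=disease, probe=probe, gene=gene, cell_state=cell_state,
    )


@pytest.fixture(scope="session")
def small_panel():
    return synthetic.simulate_haplotype_panel(Q=50, n_hap=600, rho=0.8, seed=7)


@pytest.fixture
def gwas_file(tmp_path):
    path = tmp_path / "gwas.tsv"
    path.write_text(
        "snp\tchrom\tpos\ta1\ta2\tmaf\tp\n"
        "rs1\tchr15\t1000\tA\tG\t0.30\t0.01\n"
        "rs2\tchr15\t2000\tC\tT\t0.10\t0.5\n"
        "rs3\tchr15\t3000\tG\tA\t0.45\t1.0\n"
    )
    return path


@pytest.fixture
def vcf_file(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "chr1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n"
        "chr1\t200\tv2\tA\tC\t.\t.\t.\tGT\t1/1\t0/1\n"
        "chr1\t300\tv3\tT\tG\t.\t.\t.\tGT\t./.\t0/1\n"
    )
    return path
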