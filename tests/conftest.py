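import numpy as np
import pytest

from snptag import GenotypeMatrix, MISSING, SimSpec, simulate_hwe


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 samples x 2 SNPs with one missing call."""
    calls = np.array([[0, 1], [1, 2], [2, MISSING]], dtype=np.int8)
    return GenotypeMatrix(["s1", "s2", "s3"], ["rs1", "rs2"], calls)


@pytest.fixture
def hwe_population() -> GenotypeMatrix:
    """2000 individuals at 6 independent HWE SNPs, alt freq 0.3-0.5."""
    freqs = (0.3, 0.35, 0.4, 0.45, 0.5, 0.42)
    return simulate_hwe(SimSpec(freqs, 2000, seed=11))


@pytest.fixture
def vcf_path(tmp_path):
    """Small plain-text VCF with multi-allelic, indel, chrX and missing calls."""
    text = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=7>
##contig=<ID=X>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t50\tPASS\t.\tGT\t0/0\t0|1\t1/1
1\t200\trs2\tC\tT\t50\tPASS\t.\tGT\t1/0\t./.\t0/0
1\t300\trs3\tG\tA,T\t50\tPASS\t.\tGT\t0/0\t0/1\t0/2
1\t400\trs4\tGT\tG\t50\tPASS\t.\tGT\t0/0\t0/1\t1/1
7\t500\trs5\tT\tC\t50\tPASS\t.\tGT\t1/1\t1|1\t0/1
X\t600\trs6\tA\tC\t50\tPASS\t.\tGT\t0/0\t0/1\t1/1
"""
    p = tmp_path / "tiny.vcf"
    p.write_text(text)
    return p
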