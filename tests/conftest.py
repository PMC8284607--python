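import numpy as np
import pytest

from mutacc.genome_io import Genome
from mutacc.simulate import pombe_like_genome


@pytest.fixture(scope="session")
def at_rich_genome() -> Genome:
    """100 kb AT-rich random genome shared by sampling-based tests."""
    return pombe_like_genome(length=100_000, seed=7)


@pytest.fixture(scope="session")
def uniform_genome() -> Genome:
    """200 kb uniform-composition random genome."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=200_000))
    return Genome({"u1": seq})


@pytest.fixture()
def tiny_genome() -> Genome:
    return Genome({"c1": "ATCTA", "c2": "GGGGG"})


def write_vcf(path, rows, contigs=(("c1", 1000),)):
    """Write a minimal VCF v4.2 text file; rows are (chrom, pos, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")
    return path
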