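import numpy as np
import pytest

from sumstatsim import CausalModel, HaplotypePanel


def make_panel(columns, ids=None, positions=None, chrom="1"):
    """Panel from an (H, n) 0/1 array-like."""
    al = np.asarray(columns, dtype=np.int8)
    n = al.shape[1]
    ids = np.array(ids if ids is not None
                   else [f"snp{j}" for j in range(n)], dtype=object)
    positions = np.array(positions if positions is not None
                         else (np.arange(n) + 1) * 100)
    labels = np.array([("A", "G")] * n, dtype=object)
    return HaplotypePanel(al, ids, positions, labels, chrom=chrom)


@pytest.fixture
def tiny_panel():
    """Four haplotypes {00, 00, 11, 11} over two SNPs (perfect LD)."""
    return make_panel([[0, 0], [0, 0], [1, 1], [1, 1]])


@pytest.fixture
def maf_half_panel():
    """Single SNP with exact allele frequency 0.5 in 600 haplotypes."""
    col = np.zeros((600, 1), dtype=np.int8)
    col[:300, 0] = 1
    return make_panel(col, ids=["x"])


@pytest.fixture
def or12_model():
    """Single causal SNP 'x', odds ratio 1.2, 1000 cases / 1000 controls."""
    return CausalModel(["x"], [np.log(1.2)], n0=1000, n1=1000)


@pytest.fixture
def random_panel():
    """120 haplotypes x 5 SNPs of unstructured binary noise (polymorphic)."""
    rng = np.random.default_rng(42)
    while True:
        al = (rng.random((120, 5)) < rng.uniform(0.15, 0.5, 5)).astype(np.int8)
        f = al.mean(axis=0)
        if ((f > 0) & (f < 1)).all():
            return make_panel(al)
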