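import numpy as np
import pytest

from chromacell.genome import BinGrid, GeneModel


@pytest.fixture
def small_grid():
    return BinGrid({"chr1": 4_000_000}, 40_000)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("G1", "chr1", "+", 100_000, ((100_000, 100_300), (101_000, 101_400))),
        GeneModel("G2", "chr1", "-", 500_000, ((499_000, 499_200), (499_600, 500_000))),
        GeneModel("G3", "chr1", "+", 2_000_000, ((2_000_000, 2_000_500),)),
    ]


def random_toy_genome(rng, chrom_len=1_000_000, resolution=10_000, n_genes=6):
    """Small random genome for oracle-equality tests."""
    grid = BinGrid({"chr1": chrom_len}, resolution)
    genes = []
    tss_used = set()
    for k in range(n_genes):
        while True:
            tss = int(rng.integers(10_000, chrom_len - 20_000))
            if tss not in tss_used:
                tss_used.add(tss)
                break
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        exons = []
        cursor = tss if strand == "+" else tss - 8000
        for _ in range(n_ex):
            a = cursor + int(rng.integers(0, 1500))
            b = a + int(rng.integers(100, 600))
            exons.append((a, b))
            cursor = b + 200
        exons = [
            (max(0, a), min(chrom_len, b)) for a, b in exons if max(0, a) < min(chrom_len, b)
        ]
        genes.append(GeneModel(f"G{k + 1}", "chr1", strand, tss, tuple(exons)))
    return grid, genes


@pytest.fixture
def rng():
    return np.random.default_rng(0)
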