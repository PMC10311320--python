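import numpy as np
import pytest

from hogimine.bitsupport import StratifiedCounts, StratumMasks
from hogimine.data_io import (
    CovariateStrata,
    Dataset,
    GeneMap,
    GenotypeMatrix,
    InteractionSet,
    PhenotypeLabels,
)


def masks_from_margins(n, n1):
    """StratumMasks with prescribed per-stratum sizes and case counts."""
    y = []
    c = []
    for j, (nj, n1j) in enumerate(zip(n, n1)):
        y.extend([1] * n1j + [0] * (nj - n1j))
        c.extend([j] * nj)
    return StratumMasks(np.asarray(y), np.asarray(c))


def counts_from(x, a, masks):
    return StratifiedCounts(tuple(x), tuple(a), masks)


def random_margins(rng, n_max, C_max, min_per_stratum=2):
    """Random non-degenerate-ish margins (x, n, n1) for property tests."""
    C = int(rng.integers(1, C_max + 1))
    n = [int(rng.integers(min_per_stratum, n_max + 1)) for _ in range(C)]
    n1 = [int(rng.integers(0, nj + 1)) for nj in n]
    x = [int(rng.integers(0, nj + 1)) for nj in n]
    return x, n, n1


def build_dataset(values, y, c=None, gene_sizes=None, mode="additive"):
    """Assemble a Dataset from arrays; genes partition rows consecutively."""
    values = np.asarray(values, dtype=np.int8)
    L = values.shape[0]
    if c is None:
        c = np.zeros(len(y), dtype=int)
    if gene_sizes is None:
        gene_sizes = [L]
    genes = {}
    start = 0
    for i, sz in enumerate(gene_sizes):
        genes[f"g{i}"] = list(range(start, start + sz))
        start += sz
    assert start == L
    return Dataset(
        genotypes=GenotypeMatrix(values, [f"m{i}" for i in range(L)]),
        labels=PhenotypeLabels(np.asarray(y)),
        covariates=CovariateStrata(np.asarray(c)),
        genemap=GeneMap(genes),
        mode=mode,
    )


def random_tiny_dataset(rng, mode="additive", n_max=50, max_genes=4, max_snps=4):
    """A small random instance for miner/oracle equivalence checks."""
    n = int(rng.integers(12, n_max + 1))
    n_genes = int(rng.integers(1, max_genes + 1))
    gene_sizes = [int(rng.integers(1, max_snps + 1)) for _ in range(n_genes)]
    L = sum(gene_sizes)
    top = 2 if mode == "additive" else 1
    maf = rng.uniform(0.1, 0.5, size=L)
    values = rng.binomial(top, maf[:, None], size=(L, n)).astype(np.int8)
    y = rng.integers(0, 2, size=n)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    C = int(rng.integers(1, 3))
    c = rng.integers(0, C, size=n)
    for j in range(C):  # keep every class inhabited
        if not (c == j).any():
            c[j] = j
    ds = build_dataset(values, y, c, gene_sizes, mode=mode)
    gene_ids = list(ds.genemap.genes)
    inters = []
    for k in (1, 2, 3):
        if len(gene_ids) >= k:
            pick = rng.choice(len(gene_ids), size=k, replace=False)
            inters.append(tuple(sorted(gene_ids[i] for i in pick)))
    interactions = InteractionSet(sorted(set(inters)))
    return ds, interactions


@pytest.fixture
def tiny_dataset():
    """A fixed 3-gene dataset small enough to reason about by hand."""
    rng = np.random.default_rng(7)
    values = rng.integers(0, 3, size=(8, 20)).astype(np.int8)
    y = rng.integers(0, 2, size=20)
    c = rng.integers(0, 2, size=20)
    return build_dataset(values, y, c, gene_sizes=[3, 3, 2], mode="additive")
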