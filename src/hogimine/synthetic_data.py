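"""Synthetic GWAS datasets with a planted meta-marker of tunable strength.

The generator emulates the simulation design used to study power of
network-guided meta-marker miners:

* a gene network drawn from the Erdos-Renyi G(n, m) model (default 75
  genes, 100 edges);
* a per-gene SNP count drawn uniformly from [3, 10]; genotypes i.i.d.
  per marker with a minor-allele frequency drawn uniformly from
  [0.1, 0.4] -- Bernoulli(maf) in binary mode, Binomial(2, maf) in
  additive mode (no linkage disequilibrium, no population structure);
* a planted *meta-marker*: a random connected subgraph of k* genes, one
  random genomic interval per planted gene (lengths U[1, 3]), one
  encoding; its OR-aggregated value z_i over samples is the causal
  signal;
* labels: carriers (z_i = 1) are cases with probability 0.5 + rho/2,
  non-carriers with probability 0.5 - rho/2.  rho = 0 gives labels
  independent of genotypes; the association strength grows
  monotonically with rho;
* a categorical covariate drawn uniformly over C classes, independent of
  everything (a --confounded variant shifts both the label odds and one
  marker's frequency per class, for demonstrating CMH-vs-chi2).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .bitsupport import DOMINANT, RECESSIVE
from .data_io import (
    ADDITIVE,
    BINARY,
    CovariateStrata,
    Dataset,
    GeneMap,
    GenotypeMatrix,
    InteractionSet,
    PhenotypeLabels,
    write_genemap,
    write_genotypes,
    write_int_lines,
)
from .network_priors import GeneGraph

__all__ = ["SimConfig", "GroundTruth", "SimulatedData", "simulate", "count_true_positives"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated screen (defaults = headline design)."""

    n_genes: int = 75
    n_edges: int = 100
    n_samples: int = 3000
    snps_per_gene: tuple[int, int] = (3, 10)
    mode: str = BINARY
    maf_range: tuple[float, float] = (0.1, 0.4)
    k_star: int = 3
    planted_interval_len: tuple[int, int] = (1, 3)
    planted_encoding: str = DOMINANT
    rho: float = 0.0
    n_covariate_classes: int = 2
    confounded: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.k_star > self.n_genes:
            raise ValueError("planted subgraph larger than the gene set")
        if self.mode not in (BINARY, ADDITIVE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.planted_encoding not in (DOMINANT, RECESSIVE):
            raise ValueError(f"unknown encoding {self.planted_encoding!r}")


@dataclass
class GroundTruth:
    """What was planted: genes, gene-local intervals, encoding, marker rows."""

    genes: tuple[str, ...]
    intervals: dict[str, tuple[int, int]]
    encoding: str
    marker_rows: tuple[int, ...]
    z: np.ndarray  # planted meta-marker value per sample


@dataclass
class SimulatedData:
    dataset: Dataset
    graph: GeneGraph
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir) -> dict[str, Path]:
        """Write all miner input files plus the ground-truth record."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": out / "genotypes.txt",
            "labels": out / "labels.txt",
            "covariates": out / "covariates.txt",
            "genemap": out / "genemap.txt",
            "edges": out / "edges.txt",
            "truth": out / "truth.tsv",
        }
        write_genotypes(paths["genotypes"], self.dataset.genotypes.values)
        write_int_lines(paths["labels"], self.dataset.labels.y)
        write_int_lines(paths["covariates"], self.dataset.covariates.c)
        write_genemap(
            paths["genemap"], self.dataset.genemap, self.dataset.genotypes.marker_ids
        )
        with open(paths["edges"], "w") as fh:
            for u, v in self.graph.edges():
                fh.write(f"{u} {v}\n")
        mids = self.dataset.genotypes.marker_ids
        with open(paths["truth"], "w") as fh:
            fh.write("gene\tfirst_marker\tlast_marker\tencoding\n")
            for g in self.truth.genes:
                s, e = self.truth.intervals[g]
                rows = self.dataset.genemap[g]
                fh.write(
                    f"{g}\t{mids[rows[s]]}\t{mids[rows[e - 1]]}\t"
                    f"{'d' if self.truth.encoding == DOMINANT else 'r'}\n"
                )
        return paths


def _planted_subgraph(g: nx.Graph, k: int, rng: np.random.Generator) -> list[int]:
    """Uniform-random BFS growth of a connected k-node subgraph."""
    candidates = [c for c in nx.connected_components(g) if len(c) >= k]
    if not candidates:
        raise ValueError(f"no connected component with >= {k} nodes to plant in")
    comp = sorted(candidates[rng.integers(len(candidates))])
    start = comp[rng.integers(len(comp))]
    chosen = [start]
    boundary = sorted(set(g.neighbors(start)))
    while len(chosen) < k:
        nxt = boundary[rng.integers(len(boundary))]
        chosen.append(nxt)
        boundary = sorted(
            (set(boundary) | set(g.neighbors(nxt))) - set(chosen)
        )
    return chosen


def simulate(config: SimConfig) -> SimulatedData:
    """Generate one replicate of the simulation design."""
    rng = np.random.default_rng(config.seed)

    graph_nx = nx.gnm_random_graph(
        config.n_genes, config.n_edges, seed=int(rng.integers(2**31))
    )
    gene_names = [f"g{i}" for i in range(config.n_genes)]

    lo, hi = config.snps_per_gene
    snp_counts = rng.integers(lo, hi + 1, size=config.n_genes)
    L = int(snp_counts.sum())
    n = config.n_samples

    genes: dict[str, list[int]] = {}
    start = 0
    for i, name in enumerate(gene_names):
        genes[name] = list(range(start, start + int(snp_counts[i])))
        start += int(snp_counts[i])
    genemap = GeneMap(genes)

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=L)
    n_alleles = 1 if config.mode == BINARY else 2
    values = rng.binomial(n_alleles, maf[:, None], size=(L, n)).astype(np.int8)

    # plant the causal meta-marker
    planted_nodes = _planted_subgraph(graph_nx, config.k_star, rng)
    planted_genes = tuple(gene_names[i] for i in planted_nodes)
    intervals: dict[str, tuple[int, int]] = {}
    marker_rows: list[int] = []
    len_lo, len_hi = config.planted_interval_len
    for gname in planted_genes:
        rows = genes[gname]
        ln = min(int(rng.integers(len_lo, len_hi + 1)), len(rows))
        s = int(rng.integers(0, len(rows) - ln + 1))
        intervals[gname] = (s, s + ln)
        marker_rows.extend(rows[s : s + ln])

    thresh = 2 if (config.mode == ADDITIVE and config.planted_encoding == RECESSIVE) else 1
    z = (values[marker_rows, :] >= thresh).any(axis=0)

    # labels: symmetric shift around 0.5 -- carriers up, non-carriers down by
    # rho/2.  Feasible for every rho < 1 regardless of the carrier frequency
    # of the planted meta-marker, exactly null at rho = 0, and monotone in rho.
    prob = np.where(z, 0.5 + config.rho / 2.0, 0.5 - config.rho / 2.0)
    y = (rng.random(n) < prob).astype(np.int8)

    c = rng.integers(0, config.n_covariate_classes, size=n)
    if config.confounded:
        # covariate shifts both the label odds and one random marker's maf
        shift = (c == 0) & (rng.random(n) < 0.15)
        y = np.where(shift, 1, y).astype(np.int8)
        row = int(rng.integers(L))
        extra = (c == 0) & (rng.random(n) < 0.3)
        values[row] = np.where(extra, n_alleles, values[row])

    dataset = Dataset(
        genotypes=GenotypeMatrix(values, [f"m{i}" for i in range(L)]),
        labels=PhenotypeLabels(y),
        covariates=CovariateStrata(c, C=config.n_covariate_classes),
        genemap=genemap,
        mode=config.mode,
    )
    graph = GeneGraph.from_edges(
        [(gene_names[u], gene_names[v]) for u, v in graph_nx.edges()],
        extra_nodes=gene_names,
    )
    truth = GroundTruth(
        genes=planted_genes,
        intervals=intervals,
        encoding=config.planted_encoding,
        marker_rows=tuple(marker_rows),
        z=z.astype(np.int8),
    )
    return SimulatedData(dataset=dataset, graph=graph, truth=truth, config=config)


def count_true_positives(mining_result, truth: GroundTruth, genemap: GeneMap) -> int:
    """Significant patterns whose marker set overlaps the planted markers."""
    planted = set(truth.marker_rows)
    tp = 0
    for pat in mining_result.significant:
        rows = set()
        for g, (s, e) in zip(pat.genes, pat.intervals):
            rows.update(genemap[g][s:e])
        if rows & planted:
            tp += 1
    return tp
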