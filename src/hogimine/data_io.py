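"""Reading, validating and writing the miner's plain-text file formats.

Formats (all whitespace/TAB separated, diff-able):

* genotypes: one row per marker, column i = sample i, values 0/1/2
  (additive mode) or 0/1 (binary mode); row order is genomic order.
  Marker identity is the row index; the canonical label of row i is "m<i>".
* labels / covariates: one integer per line, sample i on line i.
  Covariate classes are re-indexed densely to 0..C-1 on read.
* gene map: ``gene_id<TAB>marker_id,marker_id,...`` with marker ids in
  genomic order within the gene; markers may belong to several genes.
* interactions: one gene interaction per line, gene ids whitespace
  separated; duplicate sets are dropped, file order is kept for reporting.

Missing genotypes are not supported: matrices are assumed complete and
imputation is left to preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .bitsupport import StratumMasks

__all__ = [
    "DataError",
    "GenotypeMatrix",
    "PhenotypeLabels",
    "CovariateStrata",
    "GeneMap",
    "InteractionSet",
    "Dataset",
    "read_dataset",
    "read_interactions",
    "write_results",
]

BINARY = "binary"
ADDITIVE = "additive"


class DataError(ValueError):
    """Malformed or mutually inconsistent input files."""


@dataclass
class GenotypeMatrix:
    """L x n integer matrix of marker values, rows in genomic order."""

    values: np.ndarray
    marker_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise DataError("genotype matrix must be 2-D with L >= 1, n >= 1")
        if len(self.marker_ids) != self.values.shape[0]:
            raise DataError("marker id count does not match row count")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise DataError("marker ids are not unique")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeLabels:
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        if not np.isin(self.y, (0, 1)).all():
            raise DataError("labels must be 0/1")
        if len(np.unique(self.y)) < 2:
            warnings.warn("phenotype has a single class; no association is testable")


@dataclass
class CovariateStrata:
    c: np.ndarray
    C: int = 0

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.int64)
        if self.C == 0:
            self.C = int(self.c.max()) + 1 if self.c.size else 1
        counts = np.bincount(self.c, minlength=self.C)
        if (counts == 0).any():
            raise DataError("every covariate class 0..C-1 must be non-empty")


@dataclass
class GeneMap:
    """Ordered mapping gene_id -> marker row indices (genomic order)."""

    genes: dict[str, list[int]]

    def validate(self, L: int) -> None:
        for gene, rows in self.genes.items():
            if not rows:
                raise DataError(f"gene {gene!r} maps to no markers")
            if any(r < 0 or r >= L for r in rows):
                raise DataError(f"gene {gene!r} references a marker index >= L={L}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __getitem__(self, gene: str) -> list[int]:
        return self.genes[gene]


@dataclass
class InteractionSet:
    """Deduplicated family of gene-id sets, file order preserved."""

    sets: list[tuple[str, ...]]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


@dataclass
class Dataset:
    """All inputs assembled, with per-stratum masks precomputed."""

    genotypes: GenotypeMatrix
    labels: PhenotypeLabels
    covariates: CovariateStrata
    genemap: GeneMap
    mode: str
    masks: StratumMasks = field(init=False)

    def __post_init__(self):
        n = self.genotypes.n_samples
        if self.labels.y.size != n:
            raise DataError(
                f"labels length {self.labels.y.size} does not match {n} samples"
            )
        if self.covariates.c.size != n:
            raise DataError(
                f"covariates length {self.covariates.c.size} does not match {n} samples"
            )
        if self.mode not in (BINARY, ADDITIVE):
            raise DataError(f"mode must be 'binary' or 'additive', got {self.mode!r}")
        alphabet = (0, 1) if self.mode == BINARY else (0, 1, 2)
        if not np.isin(self.genotypes.values, alphabet).all():
            bad = sorted(
                set(np.unique(self.genotypes.values)) - set(alphabet)
            )
            raise DataError(f"value {bad[0]} not allowed in {self.mode} mode")
        self.genemap.validate(self.genotypes.L)
        self.masks = StratumMasks(self.labels.y, self.covariates.c)

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    @property
    def n_cases(self) -> int:
        return int(self.labels.y.sum())


def _read_int_lines(path, what: str) -> np.ndarray:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.strip()
            if not tok:
                continue
            try:
                out.append(int(tok))
            except ValueError:
                raise DataError(
                    f"{path}: line {lineno}: non-integer {what} token {tok!r}"
                ) from None
    return np.asarray(out, dtype=np.int64)


def _read_genotype_matrix(path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            try:
                row = [int(t) for t in toks]
            except ValueError:
                raise DataError(
                    f"{path}: line {lineno}: non-integer genotype token"
                ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise DataError(
                    f"{path}: line {lineno}: expected {width} columns, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise DataError(f"{path}: empty genotype matrix")
    return np.asarray(rows, dtype=np.int8)


def read_genemap(path, marker_index: dict[str, int]) -> GeneMap:
    genes: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                gene, markers = line.rstrip("\n").split("\t")
            except ValueError:
                raise DataError(
                    f"{path}: line {lineno}: expected 'gene<TAB>marker,marker,...'"
                ) from None
            rows = []
            for mid in markers.split(","):
                mid = mid.strip()
                if mid not in marker_index:
                    raise DataError(
                        f"{path}: line {lineno}: unknown marker id {mid!r}"
                    )
                rows.append(marker_index[mid])
            if gene in genes:
                raise DataError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            genes[gene] = rows
    return GeneMap(genes)


def read_dataset(
    genotype_path,
    labels_path,
    genemap_path,
    covariates_path=None,
    mode: str = ADDITIVE,
) -> Dataset:
    """Read and cross-validate all dataset files.

    In binary mode any genotype value 2 is rejected.  An absent covariate
    file yields a single stratum (C = 1).
    """
    values = _read_genotype_matrix(genotype_path)
    marker_ids = [f"m{i}" for i in range(values.shape[0])]
    genotypes = GenotypeMatrix(values, marker_ids)
    n = genotypes.n_samples

    y = _read_int_lines(labels_path, "label")
    if y.size != n:
        raise DataError(
            f"length mismatch: {labels_path} has {y.size} labels but "
            f"{genotype_path} has {n} samples"
        )
    if not np.isin(y, (0, 1)).all():
        raise DataError(f"{labels_path}: labels must be 0/1")

    if covariates_path is not None:
        c_raw = _read_int_lines(covariates_path, "covariate")
        if c_raw.size != n:
            raise DataError(
                f"length mismatch: {covariates_path} has {c_raw.size} values but "
                f"{genotype_path} has {n} samples"
            )
        # dense re-indexing to 0..C-1 in order of first appearance of sorted values
        uniq = np.unique(c_raw)
        remap = {v: i for i, v in enumerate(uniq.tolist())}
        c = np.asarray([remap[v] for v in c_raw.tolist()], dtype=np.int64)
    else:
        c = np.zeros(n, dtype=np.int64)

    marker_index = {mid: i for i, mid in enumerate(marker_ids)}
    genemap = read_genemap(genemap_path, marker_index)

    return Dataset(
        genotypes=genotypes,
        labels=PhenotypeLabels(y),
        covariates=CovariateStrata(c),
        genemap=genemap,
        mode=mode,
    )


def read_interactions(path, genemap: GeneMap) -> InteractionSet:
    """Read gene interactions (one gene set per line), deduplicated."""
    sets: list[tuple[str, ...]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            genes = line.split()
            if not genes:
                continue
            for g in genes:
                if g not in genemap:
                    raise DataError(
                        f"{path}: line {lineno}: gene id {g!r} not in gene map"
                    )
            key = tuple(sorted(set(genes)))
            if key not in seen:
                seen.add(key)
                sets.append(key)
    return InteractionSet(sets)


# ---------------------------------------------------------------------------
# writers


def write_genotypes(path, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for row in np.asarray(values):
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def write_int_lines(path, values: Sequence[int]) -> None:
    with open(path, "w") as fh:
        for v in values:
            fh.write(f"{int(v)}\n")


def write_genemap(path, genemap: GeneMap, marker_ids: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for gene, rows in genemap.genes.items():
            fh.write(gene + "\t" + ",".join(marker_ids[r] for r in rows) + "\n")


def write_interactions(path, interactions: InteractionSet) -> None:
    with open(path, "w") as fh:
        for genes in interactions:
            fh.write(" ".join(genes) + "\n")


def write_results(result, out_prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.sig.tsv`` (significant closed patterns, ascending p,
    ties broken by canonical key) and ``<prefix>.summary.txt``."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sig_path = prefix.with_name(prefix.name + ".sig.tsv")
    sum_path = prefix.with_name(prefix.name + ".summary.txt")

    with open(sig_path, "w") as fh:
        fh.write(
            "p_value\tmin_p\tsupport_count\tgenes\tencodings\tintervals\n"
        )
        for pat in sorted(result.significant, key=lambda s: (s.p, s.key)):
            enc = ",".join("d" if e == "dominant" else "r" for e in pat.encodings)
            ivals = ",".join(
                f"{first}..{last}" for first, last in pat.interval_marker_ids
            )
            fh.write(
                f"{pat.p:.6g}\t{pat.p_min:.6g}\t{pat.support_count}\t"
                f"{';'.join(pat.genes)}\t{enc}\t{ivals}\n"
            )

    with open(sum_path, "w") as fh:
        fh.write(f"alpha\t{result.alpha:g}\n")
        fh.write(f"method\t{result.method}\n")
        fh.write(f"delta_final\t{result.delta_final:.6g}\n")
        fh.write(f"n_processed\t{result.n_processed}\n")
        fh.write(f"n_testable\t{result.n_testable}\n")
        fh.write(f"n_pruned\t{result.n_pruned}\n")
        fh.write(f"n_significant\t{len(result.significant)}\n")
    return sig_path, sum_path
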