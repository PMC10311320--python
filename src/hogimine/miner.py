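"""Breadth-first enumeration of meta-marker patterns with envelope pruning.

A *pattern* over one gene interaction (g_1, ..., g_k) is a choice of one
contiguous genomic interval per gene plus one dominant/recessive encoding
per gene; its support is the OR, over all markers it spans, of the
binarized marker columns.  The search runs per interaction, level by level
on the total interval length:

* level k holds all patterns with a single marker per gene (every position
  combination, and in additive mode every one of the 2^k encoding
  assignments; encodings are fixed here and inherited by all children);
* a child extends exactly one gene's interval by one position to the
  right.  The canonical-generation rule -- gene i may be extended only
  while every gene with a smaller index still has interval length 1 --
  gives each pattern exactly one producing parent, so no cross-level
  deduplication is needed;
* a child's support is the parent support OR the single new binarized
  column.

Every generated pattern is tested (CMH p-value, minimum attainable
p-value) and fed to the shared FWER state; if its descendant envelope
exceeds the current threshold delta, its whole subtree is pruned.  Because
the envelope is monotone along descent and delta never increases, a
pruning decision taken now remains valid for the rest of the run, and (in
Westfall-Young mode) for all label permutations at once, since stratified
permutation preserves every pattern's margins.

Only *closed* patterns -- no interval-shrink sub-pattern with identical
support -- are reported, to avoid redundant output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

from .bitsupport import (
    DOMINANT,
    RECESSIVE,
    SampleBitset,
    StratifiedCounts,
    binarize_marker,
)
from .cmh_stats import chi2_sf, cmh_statistic_margins, corner_statistic_margins, envelope_pvalue_margins
from .data_io import ADDITIVE, BINARY, Dataset, InteractionSet
from .fwer_control import TaroneState, WYState

__all__ = [
    "MinerConfig",
    "Pattern",
    "SignificantPattern",
    "MiningResult",
    "initial_patterns",
    "generate_children",
    "pattern_support",
    "evaluate_pattern",
    "is_closed",
    "mine",
]


@dataclass(frozen=True)
class MinerConfig:
    """Search and correction settings.

    max_interval_len caps the per-gene interval length (the l' cap that
    keeps the pattern count manageable for large genes); prune=False is a
    debug mode that enumerates the complete pattern class.
    """

    alpha: float = 0.05
    mode: str = ADDITIVE
    fwer: str = "tarone"  # or "wy"
    n_permutations: int = 10_000
    seed: int = 0
    max_interval_len: Optional[int] = None
    grid_ratio: float = 0.9
    prune: bool = True
    envelope_method: str = "tight"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode not in (BINARY, ADDITIVE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fwer not in ("tarone", "wy"):
            raise ValueError(f"unknown FWER method {self.fwer!r}")
        if self.max_interval_len is not None and self.max_interval_len < 1:
            raise ValueError("max_interval_len must be >= 1")


@dataclass(frozen=True)
class Pattern:
    """One meta-marker: per-gene half-open gene-local intervals + encodings."""

    genes: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...]
    encodings: tuple[str, ...]

    @property
    def key(self):
        return (self.genes, self.intervals, self.encodings)

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class SignificantPattern:
    genes: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...]
    encodings: tuple[str, ...]
    p: float
    p_min: float
    support_count: int
    interval_marker_ids: tuple[tuple[str, str], ...]

    @property
    def key(self):
        return (self.genes, self.intervals, self.encodings)


@dataclass
class MiningResult:
    significant: list[SignificantPattern]
    delta_final: float
    alpha: float
    method: str
    n_processed: int = 0
    n_testable: int = 0
    n_pruned: int = 0
    n_closed_filtered: int = 0
    best_p: float = 1.0  # smallest CMH p-value among all processed patterns


def _encoding_choices(k: int, mode: str) -> list[tuple[str, ...]]:
    if mode == BINARY:
        return [(DOMINANT,) * k]
    return list(product((DOMINANT, RECESSIVE), repeat=k))


def initial_patterns(
    genes: Sequence[str], gene_sizes: Sequence[int], mode: str
) -> list[Pattern]:
    """All patterns with one marker per gene: every position combination
    crossed (in additive mode) with every per-gene encoding assignment."""
    genes = tuple(genes)
    k = len(genes)
    out = []
    for H in _encoding_choices(k, mode):
        for pos in product(*(range(sz) for sz in gene_sizes)):
            out.append(
                Pattern(genes, tuple((t, t + 1) for t in pos), H)
            )
    return out


def generate_children(
    pattern: Pattern,
    gene_sizes: Sequence[int],
    max_interval_len: Optional[int] = None,
) -> list[tuple[Pattern, int, int]]:
    """Canonical children of a pattern: each extends exactly one gene's
    interval one position rightward; gene i is extendable only while every
    gene with smaller index has interval length 1.  Returns
    (child, gene_index, appended_gene_local_position) triples."""
    out = []
    for i, (s, e) in enumerate(pattern.intervals):
        extendable = e < gene_sizes[i] and (
            max_interval_len is None or e - s < max_interval_len
        )
        if extendable:
            child_intervals = (
                pattern.intervals[:i] + ((s, e + 1),) + pattern.intervals[i + 1 :]
            )
            out.append(
                (Pattern(pattern.genes, child_intervals, pattern.encodings), i, e)
            )
        if e - s > 1:
            # once gene i has length > 1, no later gene may grow
            break
    return out


class _ColumnCache:
    """Binarized marker columns as raw bit integers, built on demand."""

    __slots__ = ("dataset", "_cols")

    def __init__(self, dataset: Dataset):
        self.dataset = dataset
        self._cols: dict[tuple[int, str], int] = {}

    def get(self, row: int, encoding: str) -> int:
        key = (row, encoding)
        v = self._cols.get(key)
        if v is None:
            v = binarize_marker(self.dataset.genotypes.values[row], encoding).value
            self._cols[key] = v
        return v


def pattern_support(
    pattern: Pattern, dataset: Dataset, cache: Optional[_ColumnCache] = None
) -> SampleBitset:
    """Recompute a pattern's support from scratch (OR of binarized columns)."""
    if cache is None:
        cache = _ColumnCache(dataset)
    val = 0
    for g, (s, e), h in zip(pattern.genes, pattern.intervals, pattern.encodings):
        rows = dataset.genemap[g]
        for t in range(s, e):
            val |= cache.get(rows[t], h)
    return SampleBitset(dataset.n_samples, val)


def evaluate_pattern(
    pattern: Pattern,
    dataset: Dataset,
    cache: Optional[_ColumnCache] = None,
    envelope_method: str = "tight",
):
    """Test a single pattern: returns (TestResult, support).

    The miner decides from the TestResult against the current threshold
    delta: testable iff p_min <= delta, prunable iff p_env > delta (an
    untestable pattern can still be worth expanding when its envelope is
    small, e.g. an empty support whose descendants may gain carriers).
    """
    from .bitsupport import stratified_counts
    from .cmh_stats import test_pattern_counts

    support = pattern_support(pattern, dataset, cache)
    counts = stratified_counts(support, dataset.masks)
    return test_pattern_counts(counts, envelope_method=envelope_method), support


def is_closed(
    pattern: Pattern, dataset: Dataset, cache: Optional[_ColumnCache] = None
) -> bool:
    """True iff every immediate interval-shrink sub-pattern (drop one marker
    from either end of any interval of length >= 2) loses support."""
    if cache is None:
        cache = _ColumnCache(dataset)
    full = pattern_support(pattern, dataset, cache).popcount()
    for i, (s, e) in enumerate(pattern.intervals):
        if e - s < 2:
            continue
        for shrunk in ((s + 1, e), (s, e - 1)):
            sub = Pattern(
                pattern.genes,
                pattern.intervals[:i] + (shrunk,) + pattern.intervals[i + 1 :],
                pattern.encodings,
            )
            if pattern_support(sub, dataset, cache).popcount() == full:
                return False
    return True


def _make_state(config: MinerConfig, dataset: Dataset):
    if config.fwer == "tarone":
        return TaroneState(config.alpha, config.grid_ratio)
    return WYState(
        config.alpha,
        dataset.masks,
        config.n_permutations,
        config.seed,
        config.grid_ratio,
    )


def mine(
    dataset: Dataset, interactions: InteractionSet, config: MinerConfig
) -> MiningResult:
    """Run the full search over all interactions with a shared FWER state.

    Deterministic given the inputs and (in Westfall-Young mode) the seed.
    """
    masks = dataset.masks
    cache = _ColumnCache(dataset)
    state = _make_state(config, dataset)
    wy = config.fwer == "wy"
    result = MiningResult(
        significant=[],
        delta_final=config.alpha,
        alpha=config.alpha,
        method=config.fwer,
    )

    mem_vals = [m.value for m in masks.members]
    case_vals = [m.value for m in masks.cases]
    C = masks.C
    n = masks.n
    env_cache: dict[tuple, float] = {}
    pmin_cache: dict[tuple, float] = {}

    def process(pattern: Pattern, support_val: int) -> bool:
        """Test one pattern, update the FWER state; returns prunable."""
        result.n_processed += 1
        if C == 1:
            x = (support_val.bit_count(),)
            a = ((support_val & case_vals[0]).bit_count(),)
        else:
            x = tuple((support_val & mv).bit_count() for mv in mem_vals)
            a = tuple((support_val & cv).bit_count() for cv in case_vals)
        t = cmh_statistic_margins(x, a, masks)
        p = chi2_sf(t)
        if p < result.best_p:
            result.best_p = p
        p_min = pmin_cache.get(x)
        if p_min is None:
            p_min = chi2_sf(corner_statistic_margins(x, masks))
            pmin_cache[x] = p_min
        if wy:
            if p_min <= state.delta:
                state.update(
                    pattern.key,
                    SampleBitset(n, support_val),
                    StratifiedCounts(x, a, masks),
                    p_min,
                    p,
                    payload=support_val.bit_count(),
                )
        else:
            state.update(pattern.key, p_min, p, payload=support_val.bit_count())
        if not config.prune:
            return False
        p_env = env_cache.get(x)
        if p_env is None:
            p_env = envelope_pvalue_margins(x, masks, config.envelope_method)
            env_cache[x] = p_env
        if p_env > state.delta:
            result.n_pruned += 1
            return True
        return False

    for inter in interactions:
        genes = tuple(sorted(inter))
        missing = [g for g in genes if g not in dataset.genemap or not dataset.genemap[g]]
        if missing:
            warnings.warn(
                f"skipping interaction {genes}: no markers mapped for {missing}"
            )
            continue
        rows_per_gene = [dataset.genemap[g] for g in genes]
        sizes = [len(r) for r in rows_per_gene]

        frontier: list[tuple[Pattern, int]] = []
        for pat in initial_patterns(genes, sizes, config.mode):
            val = 0
            for i, ((s, _), h) in enumerate(zip(pat.intervals, pat.encodings)):
                val |= cache.get(rows_per_gene[i][s], h)
            if not process(pat, val):
                frontier.append((pat, val))

        while frontier:
            next_frontier: list[tuple[Pattern, int]] = []
            for parent, pval in frontier:
                for child, gi, pos in generate_children(
                    parent, sizes, config.max_interval_len
                ):
                    cval = pval | cache.get(rows_per_gene[gi][pos], child.encodings[gi])
                    if not process(child, cval):
                        next_frontier.append((child, cval))
            frontier = next_frontier

    delta_final, ledger = state.finalize()
    result.delta_final = delta_final
    result.n_testable = state.n_testable

    marker_ids = dataset.genotypes.marker_ids
    for key, p_min, p, support_count in ledger:
        genes_k, intervals_k, encodings_k = key
        pat = Pattern(genes_k, intervals_k, encodings_k)
        if not is_closed(pat, dataset, cache):
            result.n_closed_filtered += 1
            continue
        ival_ids = tuple(
            (marker_ids[dataset.genemap[g][s]], marker_ids[dataset.genemap[g][e - 1]])
            for g, (s, e) in zip(genes_k, intervals_k)
        )
        result.significant.append(
            SignificantPattern(
                genes=genes_k,
                intervals=intervals_k,
                encodings=encodings_k,
                p=p,
                p_min=p_min,
                support_count=support_count,
                interval_marker_ids=ival_ids,
            )
        )
    result.significant.sort(key=lambda s: (s.p, s.key))
    return result


def count_patterns(
    dataset: Dataset, interactions: InteractionSet, config: MinerConfig
) -> int:
    """Number of patterns the search space contains (pruning disabled)."""
    cfg = MinerConfig(
        alpha=config.alpha,
        mode=config.mode,
        fwer="tarone",
        seed=config.seed,
        max_interval_len=config.max_interval_len,
        grid_ratio=config.grid_ratio,
        prune=False,
    )
    return mine(dataset, interactions, cfg).n_processed
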