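"""Family-wise error rate control: Tarone's testability threshold and the
Westfall-Young permutation procedure.

Both maintain an evolving significance threshold delta on a geometric grid
delta_i = alpha * gamma**i.  Tarone's method keeps the upper bound
delta * |T(delta)| <= alpha, where T(delta) is the set of processed patterns
whose minimum attainable p-value is at most delta; lowering delta drops
entries that are no longer testable, and they can never re-enter because
delta is non-increasing.  The Westfall-Young variant estimates the FWER at
threshold delta as the fraction of K label permutations whose minimum
p-value (over all processed patterns) is at most delta, and keeps that
estimate at or below alpha.

Permutations are drawn independently *within* each covariate stratum, so
every permutation preserves the CMH margins (n_j, n1_j) and every pattern's
x_j.  Consequently the minimum attainable p-value and the envelope of a
pattern are identical across all permutations, and a single pruning
decision is valid simultaneously for the observed labels and all K
permuted label vectors.
"""

from __future__ import annotations

import heapq
from typing import Optional

import numpy as np
from scipy.special import erfc

from .bitsupport import SampleBitset, StratifiedCounts, StratumMasks

__all__ = ["TaroneState", "WYState", "make_permutations", "PermutationSet"]


class PermutationSet:
    """K stratified label permutations, as packed case masks.

    ``per_stratum[s][j]`` is permutation j's case mask within stratum s;
    ``combined[j]`` is the union over strata (what the CMH total needs,
    since the statistic depends on the a_j only through their sum);
    ``combined_words`` stacks those as a (K, n_words) uint64 array for
    vectorised counting.
    """

    __slots__ = ("K", "per_stratum", "combined", "combined_words")

    def __init__(self, K: int, per_stratum, combined):
        self.K = K
        self.per_stratum = per_stratum
        self.combined = combined
        self.combined_words = np.stack([m.words for m in combined])


def make_permutations(masks: StratumMasks, K: int, seed: int) -> PermutationSet:
    """Draw K label permutations, uniform within each covariate stratum.

    Each permutation reassigns the n1_j case labels uniformly among the
    members of stratum j, independently across strata and permutations.
    Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("permutation count K must be >= 1")
    rng = np.random.default_rng(seed)
    n = masks.n
    per_stratum: list[list[SampleBitset]] = []
    combined_ind = np.zeros((K, n), dtype=bool)
    for s in range(masks.C):
        member_idx = np.flatnonzero(masks.members[s].to_indicators())
        n1 = masks.n1_per[s]
        stratum_masks = []
        for j in range(K):
            chosen = rng.choice(member_idx, size=n1, replace=False)
            ind = np.zeros(n, dtype=bool)
            ind[chosen] = True
            stratum_masks.append(SampleBitset.from_indicators(ind))
            combined_ind[j, chosen] = True
        per_stratum.append(stratum_masks)
    combined = [SampleBitset.from_indicators(row) for row in combined_ind]
    return PermutationSet(K, per_stratum, combined)


class TaroneState:
    """Evolving Tarone threshold with a testable-pattern ledger.

    Invariant after every update: delta * |ledger| <= alpha, where the
    ledger holds exactly the patterns (deduplicated by canonical key) with
    minimum attainable p-value <= delta.  delta moves down a geometric grid
    alpha * gamma**i and never increases.
    """

    def __init__(self, alpha: float, grid_ratio: float = 0.9):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < grid_ratio < 1.0:
            raise ValueError("grid ratio must be in (0, 1)")
        self.alpha = alpha
        self.grid_ratio = grid_ratio
        self.grid_index = 0
        self.delta = alpha
        self._heap: list[tuple[float, int]] = []  # (-p_min, entry id)
        self._entries: dict[int, tuple] = {}  # id -> (key, p_min, p, payload)
        self._keys: set = set()
        self._next_id = 0
        self.m_processed = 0
        self.m_pruned = 0

    @property
    def n_testable(self) -> int:
        return len(self._entries)

    @property
    def delta_bonferroni(self) -> float:
        """Plain Bonferroni threshold over all processed patterns (diagnostic)."""
        return self.alpha / self.m_processed if self.m_processed else self.alpha

    def fwer_bound(self) -> float:
        return self.delta * self.n_testable

    def update(self, pattern_key, p_min: float, p: float, payload=None) -> None:
        """Insert a processed pattern (if testable) and restore the invariant."""
        if p_min <= self.delta and pattern_key not in self._keys:
            eid = self._next_id
            self._next_id += 1
            self._entries[eid] = (pattern_key, p_min, p, payload)
            self._keys.add(pattern_key)
            heapq.heappush(self._heap, (-p_min, eid))
            while self.delta * len(self._entries) > self.alpha:
                self.grid_index += 1
                self.delta = self.alpha * self.grid_ratio**self.grid_index
                while self._heap and -self._heap[0][0] > self.delta:
                    _, drop = heapq.heappop(self._heap)
                    self._keys.discard(self._entries.pop(drop)[0])

    def finalize(self) -> tuple[float, list]:
        """Final threshold and the significant ledger entries (p <= delta)."""
        sig = [
            (key, p_min, p, payload)
            for key, p_min, p, payload in self._entries.values()
            if p <= self.delta
        ]
        return self.delta, sig


class WYState:
    """Westfall-Young permutation FWER state.

    Tracks, for each of K permutations, the running minimum p-value over
    all processed patterns, and keeps the estimated
    FWER(delta) = #{j : minp_j <= delta} / K at or below alpha by lowering
    delta on the geometric grid.  A candidate ledger retains patterns whose
    observed p was <= delta at insertion; it is re-filtered at finalize.
    """

    def __init__(
        self,
        alpha: float,
        masks: StratumMasks,
        K: int,
        seed: int,
        grid_ratio: float = 0.9,
        permutations: Optional[PermutationSet] = None,
    ):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < grid_ratio < 1.0:
            raise ValueError("grid ratio must be in (0, 1)")
        self.alpha = alpha
        self.grid_ratio = grid_ratio
        self.grid_index = 0
        self.delta = alpha
        self.masks = masks
        self.permutations = (
            permutations
            if permutations is not None
            else make_permutations(masks, K, seed)
        )
        self.K = self.permutations.K
        self.min_p = np.ones(self.K)
        self._candidates: dict = {}  # key -> (p_min, p, payload)
        self.m_processed = 0
        self.m_pruned = 0

    @property
    def n_testable(self) -> int:
        return len(self._candidates)

    def fwer_estimate(self, delta: Optional[float] = None) -> float:
        d = self.delta if delta is None else delta
        return float(np.count_nonzero(self.min_p <= d)) / self.K

    def permutation_pvalues(self, support: SampleBitset, counts: StratifiedCounts) -> np.ndarray:
        """p-values of a pattern under all K permuted label vectors.

        The margins (n_j, n1_j, x_j) are permutation-invariant, so only the
        total case-carrier count changes; it is a popcount of the support
        against each permutation's combined case mask.
        """
        masks = counts.masks
        expect = 0.0
        den = 0.0
        for j in range(masks.C):
            xj = counts.x[j]
            expect += xj * masks.ratio[j]
            den += xj * (masks.n_per[j] - xj) * masks.var_coef[j]
        if den <= 0.0:
            return np.ones(self.K)
        words = support.words
        totals = np.bitwise_count(
            self.permutations.combined_words & words[None, :]
        ).sum(axis=1)
        t = (totals - expect) ** 2 / den
        return erfc(np.sqrt(0.5 * t))

    def update(
        self,
        pattern_key,
        support: SampleBitset,
        counts: StratifiedCounts,
        p_min: float,
        p: float,
        payload=None,
    ) -> None:
        """Fold one pattern's permutation p-values into the minima, record it
        as a candidate if currently significant, and restore the invariant."""
        perm_p = self.permutation_pvalues(support, counts)
        np.minimum(self.min_p, perm_p, out=self.min_p)
        if p <= self.delta and pattern_key not in self._candidates:
            self._candidates[pattern_key] = (p_min, p, payload)
        while self.fwer_estimate() > self.alpha and self.delta > 1e-300:
            # the floor only matters if > alpha*K permutation minima underflow
            self.grid_index += 1
            self.delta = self.alpha * self.grid_ratio**self.grid_index

    def finalize(self) -> tuple[float, list]:
        sig = [
            (key, p_min, p, payload)
            for key, (p_min, p, payload) in self._candidates.items()
            if p <= self.delta
        ]
        return self.delta, sig
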