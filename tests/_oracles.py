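"""Independent reference implementations used only to check the package.

Everything here is written for clarity, not speed: naive per-sample loops,
exhaustive enumeration, textbook formulas evaluated with scipy, and a
no-pruning exhaustive miner.  None of it shares code with the package's
hot paths.
"""

from __future__ import annotations

from itertools import combinations, product

import networkx as nx
import numpy as np
from scipy.stats import chi2


# ---------------------------------------------------------------------------
# CMH test


def naive_cmh(x, a, n, n1, stat_only=False):
    """Textbook CMH chi-square (1 df), no continuity correction."""
    num = 0.0
    den = 0.0
    for xj, aj, nj, n1j in zip(x, a, n, n1):
        if nj <= 1 or xj in (0, nj) or n1j in (0, nj):
            continue
        num += aj - xj * n1j / nj
        den += xj * (nj - xj) * n1j * (nj - n1j) / (nj**2 * (nj - 1))
    if den <= 0:
        return 0.0, 1.0
    t = num**2 / den
    return (t, None) if stat_only else (t, float(chi2.sf(t, 1)))


def a_ranges(x, n, n1):
    """Feasible per-stratum range of a_j given the margins."""
    return [
        (max(0, xj - (nj - n1j)), min(xj, n1j))
        for xj, nj, n1j in zip(x, n, n1)
    ]


def enumerate_min_p(x, n, n1):
    """Minimum p over exhaustive enumeration of every achievable a-vector
    (p is decreasing in the statistic, so min p = sf(max T))."""
    best_t = 0.0
    for a in product(*(range(lo, hi + 1) for lo, hi in a_ranges(x, n, n1))):
        t, _ = naive_cmh(x, a, n, n1, stat_only=True)
        best_t = max(best_t, t)
    return float(chi2.sf(best_t, 1)) if best_t > 0 else 1.0


def box_min_p(x, n, n1):
    """min over the full descendant box {x' : x <= x' <= n} of the
    enumeration-based minimum attainable p-value."""
    best_t = 0.0
    for xp in product(*(range(xj, nj + 1) for xj, nj in zip(x, n))):
        for a in product(*(range(lo, hi + 1) for lo, hi in a_ranges(xp, n, n1))):
            t, _ = naive_cmh(xp, a, n, n1, stat_only=True)
            best_t = max(best_t, t)
    return float(chi2.sf(best_t, 1)) if best_t > 0 else 1.0


# ---------------------------------------------------------------------------
# supports and counting


def naive_stratified_counts(support, strata, labels):
    """Per-sample loop over the 2x2xC table."""
    C = int(max(strata)) + 1
    x = [0] * C
    a = [0] * C
    n = [0] * C
    n1 = [0] * C
    for s, c, y in zip(support, strata, labels):
        n[c] += 1
        n1[c] += int(y)
        if s:
            x[c] += 1
            a[c] += int(y)
    return x, a, n, n1


def naive_binarize(row, encoding):
    if encoding == "dominant":
        return [1 if v >= 1 else 0 for v in row]
    return [1 if v == 2 else 0 for v in row]


# ---------------------------------------------------------------------------
# exhaustive no-pruning miner


def all_patterns(dataset, interactions, mode, max_interval_len=None):
    """Every pattern of every interaction, deduplicated by canonical key.

    Yields (key, support_bool_array) with key = (genes, intervals, encodings).
    """
    seen = set()
    values = dataset.genotypes.values
    for inter in interactions:
        genes = tuple(sorted(inter))
        per_gene_rows = [dataset.genemap[g] for g in genes]
        k = len(genes)
        enc_choices = (
            [("dominant",) * k]
            if mode == "binary"
            else list(product(("dominant", "recessive"), repeat=k))
        )
        interval_choices = []
        for rows in per_gene_rows:
            ivals = [
                (s, e)
                for s in range(len(rows))
                for e in range(s + 1, len(rows) + 1)
                if max_interval_len is None or e - s <= max_interval_len
            ]
            interval_choices.append(ivals)
        for H in enc_choices:
            for ivals in product(*interval_choices):
                key = (genes, tuple(ivals), H)
                if key in seen:
                    continue
                seen.add(key)
                sup = np.zeros(dataset.n_samples, dtype=bool)
                for rows, (s, e), h in zip(per_gene_rows, ivals, H):
                    for t in range(s, e):
                        sup |= np.asarray(naive_binarize(values[rows[t]], h), bool)
                yield key, sup


def pattern_stats(dataset, sup):
    x, a, n, n1 = naive_stratified_counts(
        sup, dataset.covariates.c, dataset.labels.y
    )
    _, p = naive_cmh(x, a, n, n1)
    p_min = min(
        1.0,
        *(
            naive_cmh(x, corner, n, n1)[1]
            for corner in (
                [hi for _, hi in a_ranges(x, n, n1)],
                [lo for lo, _ in a_ranges(x, n, n1)],
            )
        ),
    )
    return x, a, p, p_min


def tarone_delta(p_mins, alpha, grid_ratio):
    """Largest grid value alpha * gamma**i with delta * #{p_min <= delta} <= alpha."""
    p_mins = np.asarray(sorted(p_mins))
    delta = alpha
    i = 0
    while delta * np.count_nonzero(p_mins <= delta) > alpha:
        i += 1
        delta = alpha * grid_ratio**i
    return delta


def wy_delta(min_p_per_perm, alpha, grid_ratio):
    minp = np.asarray(min_p_per_perm)
    K = minp.size
    delta = alpha
    i = 0
    while np.count_nonzero(minp <= delta) / K > alpha and delta > 1e-300:
        i += 1
        delta = alpha * grid_ratio**i
    return delta


def naive_is_closed(dataset, key, mode):
    genes, intervals, H = key
    per_gene_rows = [dataset.genemap[g] for g in genes]

    def support_of(ivals):
        sup = np.zeros(dataset.n_samples, dtype=bool)
        for rows, (s, e), h in zip(per_gene_rows, ivals, H):
            for t in range(s, e):
                sup |= np.asarray(
                    naive_binarize(dataset.genotypes.values[rows[t]], h), bool
                )
        return sup

    full = support_of(intervals).sum()
    for i, (s, e) in enumerate(intervals):
        if e - s < 2:
            continue
        for shrunk in ((s + 1, e), (s, e - 1)):
            ivals = intervals[:i] + (shrunk,) + intervals[i + 1 :]
            if support_of(ivals).sum() == full:
                return False
    return True


def oracle_mine(dataset, interactions, mode, alpha, grid_ratio, fwer="tarone",
                permutations=None, max_interval_len=None):
    """Exhaustive no-pruning miner: exact significant set and final delta.

    ``permutations`` is the PermutationSet shared with the miner under test
    (the permuted labels are an input to the procedure, not part of it).
    """
    records = []
    for key, sup in all_patterns(dataset, interactions, mode, max_interval_len):
        x, a, p, p_min = pattern_stats(dataset, sup)
        records.append((key, sup, p, p_min))

    if fwer == "tarone":
        delta = tarone_delta([r[3] for r in records], alpha, grid_ratio)
    else:
        K = permutations.K
        C = int(max(dataset.covariates.c)) + 1
        perm_ind = [
            [permutations.per_stratum[s][j].to_indicators().astype(bool) for j in range(K)]
            for s in range(C)
        ]
        minp = np.ones(K)
        for key, sup, p, p_min in records:
            x, a, n, n1 = naive_stratified_counts(
                sup, dataset.covariates.c, dataset.labels.y
            )
            for j in range(K):
                perm_a = [int((sup & perm_ind[s][j]).sum()) for s in range(C)]
                _, pj = naive_cmh(x, perm_a, n, n1)
                minp[j] = min(minp[j], pj)
        delta = wy_delta(minp, alpha, grid_ratio)

    significant = sorted(
        key
        for key, sup, p, p_min in records
        if p <= delta and naive_is_closed(dataset, key, mode)
    )
    return delta, significant


# ---------------------------------------------------------------------------
# subgraph enumeration


def brute_force_connected_subgraphs(nodes, edges, k_max):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    out = []
    for k in range(1, k_max + 1):
        for subset in combinations(sorted(g.nodes), k):
            if nx.is_connected(g.subgraph(subset)):
                out.append(tuple(sorted(subset)))
    out.sort(key=lambda t: (len(t), t))
    return out
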