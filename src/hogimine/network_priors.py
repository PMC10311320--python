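"""Deriving gene-interaction sets from biological networks.

Two sources of prior knowledge are supported: an undirected gene/protein
interaction network, from which all connected subgraphs up to a chosen
size are enumerated, and protein-complex membership lists, which become
interactions directly (small complexes only -- large ones blow up the
pattern space and dilute statistical power).

Connected subgraphs are enumerated with the ESU scheme (exclusive
neighbourhood extension): each subgraph is grown only from its
minimum-labelled vertex, through neighbours strictly greater than that
root and not adjacent to earlier-added vertices, which yields every
connected vertex set exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_io import DataError, GeneMap, InteractionSet

__all__ = [
    "GeneGraph",
    "read_edge_list",
    "read_complexes",
    "connected_subgraphs",
    "complexes_to_interactions",
]


@dataclass
class GeneGraph:
    """Undirected graph over gene ids; no self-loops."""

    nodes: list[str]
    adjacency: dict[str, set[str]]

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "GeneGraph":
        adj: dict[str, set[str]] = {}
        for u, v in edges:
            if u == v:
                continue  # ignore self-loops
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        for node in extra_nodes:
            adj.setdefault(node, set())
        return cls(nodes=sorted(adj), adjacency=adj)

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for u in self.nodes:
            for v in self.adjacency[u]:
                if u < v:
                    out.append((u, v))
        return sorted(out)


def read_edge_list(path) -> GeneGraph:
    """Read an undirected edge list: two whitespace-separated gene ids per line."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 2:
                raise DataError(
                    f"{path}: line {lineno}: expected two gene ids, got {len(toks)}"
                )
            edges.append((toks[0], toks[1]))
    return GeneGraph.from_edges(edges)


def read_complexes(path) -> list[list[str]]:
    """One complex per line, member gene ids whitespace separated."""
    out = []
    with open(path) as fh:
        for line in fh:
            genes = line.split()
            if genes:
                out.append(genes)
    return out


def connected_subgraphs(graph: GeneGraph, k_max: int) -> InteractionSet:
    """All node sets of size 1..k_max that induce a connected subgraph,
    each exactly once, in sorted canonical order (by size, then node ids)."""
    if k_max < 1:
        raise DataError("k_max must be >= 1")
    found: list[tuple[str, ...]] = []

    def extend(subgraph: list[str], extension: set[str], root: str) -> None:
        if 1 <= len(subgraph) <= k_max:
            found.append(tuple(sorted(subgraph)))
        if len(subgraph) >= k_max:
            return
        ext = sorted(extension)
        for i, w in enumerate(ext):
            # exclusive neighbourhood: neighbours of w beyond the root that
            # are not already reachable from the current subgraph
            new_ext = {u for u in set(ext[i + 1 :])}
            for u in graph.adjacency[w]:
                if u > root and u not in subgraph and all(
                    u not in graph.adjacency[s] for s in subgraph
                ):
                    new_ext.add(u)
            new_ext.discard(w)
            extend(subgraph + [w], new_ext, root)

    for root in graph.nodes:
        extend([root], {u for u in graph.adjacency[root] if u > root}, root)

    found.sort(key=lambda t: (len(t), t))
    return InteractionSet(found)


def complexes_to_interactions(
    complex_lists: Sequence[Sequence[str]], genemap: GeneMap, max_size: int = 5
) -> InteractionSet:
    """Turn protein complexes into interactions; complexes larger than
    ``max_size`` or containing unmapped genes are skipped with a warning."""
    sets: list[tuple[str, ...]] = []
    seen = set()
    for i, members in enumerate(complex_lists):
        genes = tuple(sorted(set(members)))
        if len(genes) > max_size:
            warnings.warn(
                f"complex {i} has {len(genes)} genes (> {max_size}); skipped"
            )
            continue
        unmapped = [g for g in genes if g not in genemap]
        if unmapped:
            warnings.warn(f"complex {i} has unmapped genes {unmapped}; skipped")
            continue
        if genes and genes not in seen:
            seen.add(genes)
            sets.append(genes)
    return InteractionSet(sets)
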