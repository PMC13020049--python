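"""Undirected weighted gene–gene interaction network.

The network is the substrate of all propagation: nodes are gene identifiers
(opaque, case-sensitive strings), edges carry confidence weights in (0, 1].
Internally the edge list is held as a symmetric ``scipy.sparse`` adjacency
matrix over a lexicographically sorted node vector, which makes the
propagation solver a plain sparse mat-vec loop and keeps node order (and
therefore every downstream vector) deterministic.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp

from .exceptions import InputError

__all__ = ["InteractionNetwork"]


class InteractionNetwork:
    """Undirected weighted graph over gene identifiers.

    Construction removes self-loops and collapses duplicate unordered pairs,
    keeping the maximum weight, so the class invariants (no self-loops, no
    duplicate pairs, positive finite weights) hold for every instance.

    Parameters
    ----------
    nodes : sequence of str
        Sorted node identifiers.
    adjacency : scipy.sparse matrix
        Symmetric weighted adjacency aligned with ``nodes``.
    """

    def __init__(self, nodes: tuple[str, ...], adjacency: sp.csr_matrix):
        self.nodes = tuple(nodes)
        self._index = {g: i for i, g in enumerate(self.nodes)}
        self.adjacency = sp.csr_matrix(adjacency)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "InteractionNetwork":
        """Build a network from (gene_a, gene_b, weight) triples.

        Self-loops are dropped; duplicate unordered pairs keep the maximum
        weight; the node set is exactly the endpoints of surviving edges.
        """
        best: dict[tuple[str, str], float] = {}
        for a, b, w in edges:
            w = float(w)
            if not np.isfinite(w) or w <= 0:
                raise InputError(f"edge ({a!r}, {b!r}) has non-positive or non-finite weight {w}")
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            prev = best.get(key)
            if prev is None or w > prev:
                best[key] = w
        if not best:
            raise InputError("no edges remain after removing self-loops")
        nodes = tuple(sorted({g for pair in best for g in pair}))
        index = {g: i for i, g in enumerate(nodes)}
        rows, cols, vals = [], [], []
        for (a, b), w in best.items():
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        adj = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
        return cls(nodes, adj)

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return len(self.nodes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._index[g] for g in genes], dtype=np.intp)

    def degree(self, weighted: bool = False) -> np.ndarray:
        if weighted:
            return np.asarray(self.adjacency.sum(axis=1)).ravel()
        return np.asarray((self.adjacency != 0).sum(axis=1)).ravel()

    def iter_edges(self) -> Iterator[tuple[str, str, float]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.nodes[i], self.nodes[j], float(w)

    # -- views -------------------------------------------------------------

    def transition_operator(self, weighted: bool = True) -> sp.csr_matrix:
        """Return W·D⁻¹, the transpose of the row-stochastic walk matrix.

        For a symmetric adjacency W with degree matrix D, the personalized-
        PageRank update x ← d·Pᵀx + (1−d)r uses Pᵀ = W·D⁻¹, so propagation
        needs no explicit transpose. Unweighted mode binarizes W first.
        """
        W = self.adjacency if weighted else sp.csr_matrix(
            ((self.adjacency.data != 0).astype(float), self.adjacency.indices,
             self.adjacency.indptr), shape=self.adjacency.shape)
        deg = np.asarray(W.sum(axis=1)).ravel()
        # Nodes exist only as edge endpoints, so deg > 0 always holds.
        inv = sp.diags(1.0 / deg)
        return (W @ inv).tocsr()

    def subgraph(self, genes: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on ``genes`` (edges between kept nodes only)."""
        keep = sorted(g for g in genes if g in self._index)
        idx = self.indices_of(keep)
        sub = self.adjacency[np.ix_(idx, idx)]
        return InteractionNetwork(tuple(keep), sp.csr_matrix(sub))

    def connected_components(self) -> list[list[str]]:
        n_comp, labels = sp.csgraph.connected_components(self.adjacency, directed=False)
        comps: list[list[str]] = [[] for _ in range(n_comp)]
        for gene, lab in zip(self.nodes, labels):
            comps[lab].append(gene)
        return sorted(comps, key=lambda c: (-len(c), c[0]))

    def to_igraph(self):
        """Convert to a python-igraph graph (names and weights preserved)."""
        import igraph as ig

        coo = sp.triu(self.adjacency, k=1).tocoo()
        g = ig.Graph(n=self.n_nodes, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
        g.vs["name"] = list(self.nodes)
        g.es["weight"] = coo.data.tolist()
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
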