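"""Molecular interaction networks and their diffusion normalisation.

An :class:`Interactome` is a simple undirected graph over string gene
identifiers, stored with a fixed lexicographic node order so that every
downstream vector and matrix is bit-reproducible.  The diffusion kernel
uses the symmetrically normalised adjacency

    w_ij = a_ij / sqrt(k_i * k_j)

whose spectral radius is at most 1, which guarantees convergence of the
propagation iteration for any restart parameter ``0 < alpha < 1``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Interactome",
    "read_edge_list",
    "normalize_adjacency",
    "align_scores",
]


class Interactome:
    """A simple undirected gene network with a fixed node order.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v)`` string pairs.  Self-loops are dropped and
        duplicate edges (in either orientation) are collapsed.
    nodes:
        Optional extra nodes to include even if isolated.

    Attributes
    ----------
    nodes : list of str
        Unique identifiers in lexicographic order.
    adjacency : scipy.sparse.csr_matrix
        Symmetric binary adjacency with zero diagonal, rows/columns
        ordered as ``nodes``.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> None:
        node_set = set(nodes)
        edge_set: set[tuple[str, str]] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            node_set.add(u)
            node_set.add(v)
            if u == v:
                continue
            edge_set.add((u, v) if u < v else (v, u))
        self.nodes: list[str] = sorted(node_set)
        self._index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        if edge_set:
            rows = np.fromiter((self._index[u] for u, v in edge_set), dtype=np.int64, count=len(edge_set))
            cols = np.fromiter((self._index[v] for u, v in edge_set), dtype=np.int64, count=len(edge_set))
            data = np.ones(len(edge_set), dtype=np.float64)
            a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
            self.adjacency = (a + a.T).tocsr()
        else:
            self.adjacency = sp.csr_matrix((n, n), dtype=np.float64)
        self._edges = sorted(edge_set)

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Sorted list of edges as (min, max) identifier pairs."""
        return list(self._edges)

    @property
    def degrees(self) -> np.ndarray:
        """Node degrees, ordered as ``nodes``."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def index_of(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self._index[g] for g in genes], dtype=np.int64)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- conversions ------------------------------------------------------

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "Interactome":
        return cls(graph.edges(), nodes=graph.nodes())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self._edges)
        return g

    def subgraph(self, genes: Iterable[str]) -> "Interactome":
        keep = {g for g in genes if g in self._index}
        edges = [(u, v) for u, v in self._edges if u in keep and v in keep]
        return Interactome(edges, nodes=keep)


def read_edge_list(
    path,
    score_column: int | None = None,
    min_score: float | None = None,
) -> Interactome:
    """Read a whitespace/tab separated edge list into an :class:`Interactome`.

    The first two columns are node identifiers; lines starting with ``#``
    are skipped.  When ``score_column`` (0-based) is given together with
    ``min_score``, edges whose score is below the threshold are dropped
    (the retention rule is ``score >= min_score``, matching the common
    STRING confidence cut).

    Raises
    ------
    ValueError
        On malformed lines (fewer than two columns, or a non-numeric
        score), reporting the 1-based line number; or if ``min_score``
        is given without ``score_column``.
    """
    if min_score is not None and score_column is None:
        raise ValueError("min_score requires score_column")
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected at least 2 columns, got {len(fields)}")
            if score_column is not None:
                if score_column >= len(fields):
                    raise ValueError(f"line {lineno}: no score column {score_column}")
                try:
                    score = float(fields[score_column])
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: non-numeric score {fields[score_column]!r}") from exc
                if min_score is not None and score < min_score:
                    continue
            edges.append((fields[0], fields[1]))
    return Interactome(edges)


def read_sif(path) -> Interactome:
    """Read a SIF file (``node<TAB>relation<TAB>node [node ...]``)."""
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                nodes.add(fields[0])
            elif len(fields) >= 3:
                edges.extend((fields[0], t) for t in fields[2:])
            else:
                raise ValueError(f"line {lineno}: SIF lines need 1 or >=3 columns")
    return Interactome(edges, nodes=nodes)


def normalize_adjacency(net: Interactome) -> sp.csr_matrix:
    """Symmetrically normalised adjacency W = D^{-1/2} A D^{-1/2}.

    Rows and columns of degree-0 nodes are identically zero; such nodes
    simply retain ``(1 - alpha) * x0`` at the diffusion steady state.
    """
    k = net.degrees.astype(np.float64)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(k > 0, 1.0 / np.sqrt(np.maximum(k, 1e-300)), 0.0)
    d = sp.diags(inv_sqrt)
    return (d @ net.adjacency @ d).tocsr()


def align_scores(
    scores: Mapping[str, float],
    net: Interactome,
    fill: float = 0.0,
) -> tuple[np.ndarray, list[str]]:
    """Order a gene->value mapping as ``net.nodes``.

    Returns the aligned vector and the sorted list of unmapped genes
    (genes in ``scores`` absent from the network); network genes absent
    from ``scores`` receive ``fill``.

    Raises
    ------
    ValueError
        If no score gene is present in the network.
    """
    mapped = [g for g in scores if g in net]
    if not mapped:
        raise ValueError("no score gene maps onto the network")
    x = np.full(net.n_nodes, float(fill))
    idx = net.index_of(mapped)
    x[idx] = [float(scores[g]) for g in mapped]
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    unmapped = sorted(g for g in scores if g not in net)
    return x, unmapped
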