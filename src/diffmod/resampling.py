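"""Network resampling: significance of connectedness among top-ranked genes.

For a gene list ranked by a non-negative score (dS or Sp restricted to
positive values) the objective

    Omega(n) = sum over unordered interacting pairs (i, j) among the
               top-n genes of score_i * score_j

is non-decreasing in n.  Its significance at each rank is assessed
against k degree-preserving rewirings of the network (double-edge-swap
Markov chain): p_nr(n) is the add-one-corrected fraction of rewired
networks whose Omega(n) reaches the observed one.  A contiguous run of
ranks with small p_nr marks a connected module of top-scoring genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .interactome import Interactome

__all__ = [
    "ResamplingProfile",
    "Module",
    "omega",
    "rewire_degree_preserving",
    "resampling_profile",
    "extract_module",
    "overlap_coefficient",
]


@dataclass(frozen=True)
class ResamplingProfile:
    """Per-rank Omega values and resampling p-values.

    ``ranks[i]`` is the list prefix length n, ``omega[i]`` the observed
    Omega(n) and ``p_nr[i]`` its add-one permutation p-value over ``k``
    degree-preserving rewirings.
    """

    ranks: np.ndarray
    omega: np.ndarray
    p_nr: np.ndarray
    k: int
    seed: int | None
    score_name: str = ""
    ranking: tuple[str, ...] = ()


@dataclass(frozen=True)
class Module:
    """Top-n* induced subnetwork extracted from a resampling profile."""

    genes: tuple[str, ...]
    n_star: int
    edges: tuple[tuple[str, str], ...]
    scores: dict
    first_significant_rank: int = 0

    def __len__(self) -> int:
        return len(self.genes)


def omega(net: Interactome, scores, ranking, n: int) -> float:
    """Omega(n): summed score products over interacting pairs among the
    top-n genes of ``ranking``; each unordered pair counts once."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranking = list(ranking)
    if n > len(ranking):
        raise ValueError(f"n={n} exceeds ranking length {len(ranking)}")
    top = ranking[:n]
    idx = net.index_of(top)
    s = np.array([float(scores[g]) for g in top])
    sub = net.adjacency[np.ix_(idx, idx)]
    return 0.5 * float(s @ (sub @ s))


def _omega_curve(indptr, indices, s, rank_idx, n_nodes) -> np.ndarray:
    """Cumulative Omega over prefixes of ``rank_idx`` for a CSR adjacency."""
    included = np.zeros(n_nodes, dtype=bool)
    out = np.empty(len(rank_idx))
    total = 0.0
    for pos, g in enumerate(rank_idx):
        nbrs = indices[indptr[g]: indptr[g + 1]]
        if nbrs.size:
            inc = nbrs[included[nbrs]]
            if inc.size:
                total += s[g] * s[inc].sum()
        included[g] = True
        out[pos] = total
    return out


@njit(cache=False)
def _swap_kernel(u, v, adj, ei, ej, flips):  # pragma: no cover - jitted
    for t in range(ei.size):
        i, j = ei[t], ej[t]
        if i == j:
            continue
        a, b = u[i], v[i]
        c, d = u[j], v[j]
        if flips[t]:
            c, d = d, c
        # proposed new edges: (a, d) and (c, b)
        if a == d or c == b:
            continue
        if a == c and d == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        u[i] = a
        v[i] = d
        u[j] = c
        v[j] = b


def _rewire_edges(u: np.ndarray, v: np.ndarray, n_nodes: int, n_attempts: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Double-edge-swap chain on an edge array; returns rewired (u, v).

    Swaps producing self-loops or multi-edges are rejected, so the
    degree sequence is conserved exactly.  Swap-rigid graphs (e.g. K4)
    come back unchanged.
    """
    m = u.size
    u = u.astype(np.int64).copy()
    v = v.astype(np.int64).copy()
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    adj[u, v] = True
    adj[v, u] = True
    ei = rng.integers(0, m, size=n_attempts)
    ej = rng.integers(0, m, size=n_attempts)
    flips = rng.integers(0, 2, size=n_attempts).astype(np.bool_)
    _swap_kernel(u, v, adj, ei, ej, flips)
    return u, v


def rewire_degree_preserving(
    net: Interactome, n_swap_factor: float = 10.0, seed=None
) -> Interactome:
    """Degree-preserving randomisation via attempted double edge swaps.

    Performs ``n_swap_factor * |E|`` attempted swaps; the output is a
    simple graph with exactly the input degree sequence.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = np.random.default_rng(seed)
    edges = net.edges
    u = net.index_of([a for a, _ in edges])
    v = net.index_of([b for _, b in edges])
    n_attempts = int(n_swap_factor * net.n_edges)
    ru, rv = _rewire_edges(u, v, net.n_nodes, n_attempts, rng)
    nodes = net.nodes
    return Interactome(((nodes[a], nodes[b]) for a, b in zip(ru.tolist(), rv.tolist())), nodes=nodes)


def resampling_profile(
    net: Interactome,
    scores,
    ranking,
    k: int = 100,
    n_max: int | None = None,
    seed=None,
    n_swap_factor: float = 10.0,
    rewire_scope: str = "global",
    score_name: str = "",
) -> ResamplingProfile:
    """Omega(n) and p_nr(n) for n = 2 .. n_max.

    The ranking is restricted to genes with strictly positive score
    (guaranteeing a non-decreasing Omega); ``k`` rewired networks are
    generated once on the whole network and reused across ranks
    (``rewire_scope="global"``), or regenerated on the induced top-n
    subnetwork at every rank (``rewire_scope="induced"``, much slower).

    p_nr(n) = (1 + #{r : Omega_r(n) >= Omega_real(n)}) / (k + 1).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if rewire_scope not in ("global", "induced"):
        raise ValueError(f"unknown rewire_scope {rewire_scope!r}")
    ranking = [g for g in ranking if float(scores[g]) > 0]
    if not ranking:
        raise ValueError("no gene has a positive score")
    if n_max is None:
        n_max = len(ranking)
    n_max = min(n_max, len(ranking))
    if n_max < 2:
        raise ValueError("need at least 2 positively scored genes")

    rng = np.random.default_rng(seed)
    n_nodes = net.n_nodes
    s = np.zeros(n_nodes)
    all_idx = net.index_of(ranking)
    s[all_idx] = [float(scores[g]) for g in ranking]
    rank_idx = all_idx[:n_max]

    A = net.adjacency.tocsr()
    omega_real = _omega_curve(A.indptr, A.indices, s, rank_idx, n_nodes)

    ranks = np.arange(2, n_max + 1)
    count = np.zeros(len(ranks), dtype=np.int64)

    if rewire_scope == "global":
        edges = net.edges
        u = net.index_of([a for a, _ in edges])
        v = net.index_of([b for _, b in edges])
        n_attempts = int(n_swap_factor * net.n_edges)
        for _ in range(k):
            ru, rv = _rewire_edges(u, v, n_nodes, n_attempts, rng)
            data = np.ones(ru.size)
            Ar = sp.coo_matrix((data, (ru, rv)), shape=(n_nodes, n_nodes))
            Ar = (Ar + Ar.T).tocsr()
            omega_r = _omega_curve(Ar.indptr, Ar.indices, s, rank_idx, n_nodes)
            count += omega_r[1:] >= omega_real[1:]
    else:
        for pos, n in enumerate(ranks):
            sub = net.subgraph(ranking[:n])
            if sub.n_edges < 2:
                # too few induced edges to rewire: every resample is the
                # induced graph itself
                count[pos] += k
                continue
            s_sub = np.array([float(scores[g]) for g in sub.nodes])
            sub_edges = sub.edges
            su = sub.index_of([a for a, _ in sub_edges])
            sv = sub.index_of([b for _, b in sub_edges])
            obs = omega_real[pos + 1]
            for _ in range(k):
                ru, rv = _rewire_edges(su, sv, sub.n_nodes, int(n_swap_factor * sub.n_edges), rng)
                val = float(np.sum(s_sub[ru] * s_sub[rv]))
                count[pos] += val >= obs
    p_nr = (1.0 + count) / (k + 1.0)
    return ResamplingProfile(
        ranks, omega_real[1:], p_nr, k, seed, score_name, tuple(ranking[:n_max])
    )


def extract_module(
    profile: ResamplingProfile,
    ranking=None,
    net: Interactome | None = None,
    threshold: float = 0.05,
    scores=None,
) -> Module:
    """Cut the ranking at the end of the first contiguous run of ranks
    with ``p_nr <= threshold`` and return the induced subnetwork.

    If no rank is significant, an empty module (n* = 0) is returned.
    Both the first significant rank and n* are reported.
    """
    ranking = list(ranking if ranking is not None else profile.ranking)
    sig = profile.p_nr <= threshold
    if not sig.any():
        return Module((), 0, (), {}, 0)
    first = int(np.argmax(sig))
    last = first
    while last + 1 < len(sig) and sig[last + 1]:
        last += 1
    n_star = int(profile.ranks[last])
    genes = tuple(ranking[:n_star])
    edges: tuple[tuple[str, str], ...] = ()
    if net is not None:
        edges = tuple(net.subgraph(genes).edges)
    mod_scores = {}
    if scores is not None:
        mod_scores = {g: float(scores[g]) for g in genes}
    return Module(genes, n_star, edges, mod_scores, int(profile.ranks[first]))


def overlap_coefficient(A, B) -> float:
    """|A ∩ B| / min(|A|, |B|) for two gene sets."""
    A, B = set(A), set(B)
    if not A and not B:
        raise ValueError("both sets are empty")
    if not A or not B:
        return 0.0
    return len(A & B) / min(len(A), len(B))
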