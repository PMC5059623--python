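"""Network smoothing indices: S, the two-group differential dS, and the
permutation-adjusted Sp, plus the helper statistics used to build inputs
(lfcp, top-N binarisation, per-group mutation frequencies).

S_j = x*_j / (x0_j + eps) compares the diffused steady state with the
initial statistic of gene j.  Small eps emphasises the gain of signal
relative to the initial state (network proximity to sources); as eps
grows only the steady state matters and the S ranking converges to the
x* ranking.

dS subtracts the indices of two sample groups computed on the same
network; because the topology is identical on both sides, purely
topological effects (hubs) cancel.  Sp = S * (1 - p) down-weights genes
whose S is reproduced by diffusing random relabellings of the input, the
permutation route to hub mitigation for inferential statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .diffusion import steady_state_solver

__all__ = [
    "SmoothingIndex",
    "DifferentialIndex",
    "SpIndex",
    "smoothing_index",
    "delta_smoothing_index",
    "sp_index",
    "binarize_top",
    "lfcp",
    "mutation_frequency",
    "rank_genes",
]


@dataclass(frozen=True)
class SmoothingIndex:
    S: np.ndarray
    epsilon: float
    alpha: float
    provenance: str = ""
    genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class DifferentialIndex:
    delta_S: np.ndarray
    epsilon: float
    alpha: float
    genes: tuple[str, ...] = ()
    label_cases: str = "u2"
    label_controls: str = "u1"


@dataclass(frozen=True)
class SpIndex:
    Sp: np.ndarray
    p: np.ndarray
    S: np.ndarray
    n_perm: int
    seed: int | None
    epsilon: float
    alpha: float
    genes: tuple[str, ...] = ()


def smoothing_index(
    x_star: np.ndarray,
    x0: np.ndarray,
    epsilon: float,
    alpha: float = 0.7,
    provenance: str = "",
    genes=(),
) -> SmoothingIndex:
    """S_j = x*_j / (x0_j + epsilon), element-wise.

    ``epsilon`` must be positive; it weights the relative importance of
    the initial and final states.
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    x_star = np.asarray(x_star, dtype=np.float64).ravel()
    x0 = np.asarray(x0, dtype=np.float64).ravel()
    if x_star.shape != x0.shape:
        raise ValueError("x_star and x0 must have the same shape")
    S = x_star / (x0 + epsilon)
    return SmoothingIndex(S, float(epsilon), float(alpha), provenance, tuple(genes))


def delta_smoothing_index(
    S_cases: SmoothingIndex, S_controls: SmoothingIndex
) -> DifferentialIndex:
    """dS_j = S_j(cases) - S_j(controls).

    Both indices must come from the same network (gene order), alpha and
    epsilon; a mismatch raises ``ValueError``.
    """
    if S_cases.epsilon != S_controls.epsilon or S_cases.alpha != S_controls.alpha:
        raise ValueError("smoothing indices computed with different (alpha, epsilon)")
    if S_cases.genes != S_controls.genes or S_cases.S.shape != S_controls.S.shape:
        raise ValueError("smoothing indices cover different gene sets")
    return DifferentialIndex(
        S_cases.S - S_controls.S,
        S_cases.epsilon,
        S_cases.alpha,
        S_cases.genes,
        label_cases=S_cases.provenance or "u2",
        label_controls=S_controls.provenance or "u1",
    )


def sp_index(
    u: np.ndarray,
    W,
    alpha: float = 0.7,
    epsilon: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    genes=(),
    exhaustive: bool = False,
) -> SpIndex:
    """Permutation-adjusted smoothing index Sp = S * (1 - p).

    ``p_j`` is the add-one-corrected fraction of permutations of the
    input values (shuffled across network genes) whose smoothing index
    at gene j is at least the observed one:

        p_j = (1 + #{perm : S_j^perm >= S_j}) / (n_perm + 1)

    so ``0 < p_j <= 1`` and the observed ranking counts as one of the
    permutations.  The linear system is factorised once and reused for
    every permutation.  With ``exhaustive=True`` all n! value
    permutations are enumerated instead of sampled (small vectors
    only); ``n_perm`` is then ignored.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    solve = steady_state_solver(W, alpha)
    S_real = smoothing_index(solve(u), u, epsilon, alpha).S
    count = np.zeros(u.size, dtype=np.int64)
    if exhaustive:
        if u.size > 8:
            raise ValueError("exhaustive enumeration is limited to <= 8 genes")
        perms = list(itertools.permutations(range(u.size)))
        n_perm = len(perms)
        for order in perms:
            u_perm = u[list(order)]
            S_perm = smoothing_index(solve(u_perm), u_perm, epsilon, alpha).S
            count += S_perm >= S_real
    else:
        if n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {n_perm}")
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            u_perm = rng.permutation(u)
            S_perm = smoothing_index(solve(u_perm), u_perm, epsilon, alpha).S
            count += S_perm >= S_real
    p = (1.0 + count) / (n_perm + 1.0)
    return SpIndex(S_real * (1.0 - p), p, S_real, n_perm, seed, float(epsilon), float(alpha), tuple(genes))


def rank_genes(scores: np.ndarray, genes) -> list[str]:
    """Order genes by decreasing score; ties broken by ascending gene ID."""
    genes = list(genes)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(genes) != scores.size:
        raise ValueError("genes and scores have different lengths")
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return [genes[i] for i in order]


def binarize_top(u: np.ndarray, genes, N: int = 500) -> np.ndarray:
    """Binary vector with 1 for the N largest values, 0 elsewhere.

    Ties at the cutoff are resolved by ascending gene identifier so the
    output always has exactly N ones.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    genes = list(genes)
    if N > u.size:
        raise ValueError(f"N={N} exceeds gene count {u.size}")
    ranked = rank_genes(u, genes)
    top = set(ranked[:N])
    return np.array([1.0 if g in top else 0.0 for g in genes])


def lfcp(p_values: np.ndarray, fold_changes: np.ndarray) -> np.ndarray:
    """Combined differential-expression statistic -log10(p) * |log2(FC)|."""
    p = np.asarray(p_values, dtype=np.float64).ravel()
    fc = np.asarray(fold_changes, dtype=np.float64).ravel()
    if p.shape != fc.shape:
        raise ValueError("p_values and fold_changes must have the same shape")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(fc <= 0):
        raise ValueError("fold changes must be > 0")
    return -np.log10(p) * np.abs(np.log2(fc))


def mutation_frequency(mut_matrix, group) -> np.ndarray:
    """Per-gene relative mutation frequency within a sample group.

    Parameters
    ----------
    mut_matrix:
        Binary genes-by-samples ``pandas.DataFrame`` (gene index, sample
        columns).
    group:
        Iterable of sample identifiers (must be columns of the matrix).

    Returns the fraction of group samples carrying a 1 for each gene,
    ordered as the matrix index.
    """
    group = list(group)
    if not group:
        raise ValueError("empty sample group")
    sub = mut_matrix[group]
    values = sub.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("mutation matrix must be binary")
    return values.mean(axis=1)
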