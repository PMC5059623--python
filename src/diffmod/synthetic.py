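"""Planted-module simulation benchmark.

The generator plants a connected module of size M inside a synthetic
interactome and redistributes a realistic mutation-frequency landscape
so that the module carries a controlled share of the total signal
(omega).  Within the module a fraction ``m_pct`` of genes receive the
globally highest frequencies ("mountains") and the remaining module
genes ("hills") receive values whose mean approximates ``h``; outside
the module values are assigned at random.  Both the value multiset and
— when working from a binary mutation matrix — the per-patient sums are
exactly conserved, so planted datasets differ from unplanted controls
only in where the signal sits on the network.

Recovery is scored by recall: the fraction of module genes among the
top-M genes of a ranking (by the smoothing index S or by the raw
frequency f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import propagate_closed_form, propagate_iterative
from .indices import mutation_frequency, rank_genes, smoothing_index
from .interactome import Interactome, normalize_adjacency

__all__ = [
    "SimulatedDataset",
    "RecallResult",
    "generate_network",
    "simulate_mutation_matrix",
    "sample_module",
    "permute_signal",
    "assign_module_signal",
    "signal_fraction",
    "recall_at_M",
    "module_density",
    "simulate_dataset",
    "run_benchmark",
]


@dataclass(frozen=True)
class SimulatedDataset:
    """A synthetic network with a planted, signal-enriched module."""

    net: Interactome
    module: tuple[str, ...]
    f_sim: dict
    f_control: dict
    m_pct: float
    h: float
    omega: float
    density: float
    seed: int | None
    mut_matrix: object = None


@dataclass(frozen=True)
class RecallResult:
    recall: float
    H: tuple[str, ...]
    G: tuple[str, ...]
    score_name: str = ""


def generate_network(
    n_nodes: int,
    model: str = "scale_free",
    seed=None,
    m: int = 3,
    p: float | None = None,
    p_triangle: float = 0.9,
) -> Interactome:
    """Synthetic interactome with zero-padded node labels.

    ``scale_free`` uses the Holme–Kim powerlaw-cluster model (heavy
    tailed degrees plus the high clustering typical of protein
    interaction networks; ``m`` edges per new node, triangle closure
    probability ``p_triangle``).  ``erdos_renyi`` is the G(n, p)
    homogeneous control.
    """
    width = max(4, len(str(n_nodes)))
    if model == "scale_free":
        if not 1 <= m < n_nodes:
            raise ValueError(f"need 1 <= m < n_nodes, got m={m}")
        g = nx.powerlaw_cluster_graph(n_nodes, m, p_triangle, seed=_to_int_seed(seed))
    elif model == "erdos_renyi":
        if p is None or not 0 <= p <= 1:
            raise ValueError("erdos_renyi requires edge probability p in [0, 1]")
        g = nx.gnp_random_graph(n_nodes, p, seed=_to_int_seed(seed))
    else:
        raise ValueError(f"unknown model {model!r}")
    mapping = {i: f"g{i:0{width}d}" for i in g.nodes()}
    return Interactome.from_networkx(nx.relabel_nodes(g, mapping))


def _to_int_seed(seed) -> int | None:
    if seed is None:
        return None
    return int(np.random.default_rng(seed).integers(0, 2**31 - 1))


def simulate_mutation_matrix(
    genes,
    n_samples: int = 100,
    seed=None,
    log_mu: float = -5.5,
    log_sigma: float = 2.0,
    max_freq: float = 0.9,
) -> pd.DataFrame:
    """Binary genes-by-samples somatic-mutation matrix.

    Per-gene mutation probabilities follow a clipped lognormal, giving
    the heavy-tailed mountains-and-hills landscape typical of cancer
    cohorts (a handful of frequently mutated genes, a long tail of
    rarely mutated ones); samples are independent Bernoulli draws.
    """
    genes = list(genes)
    rng = np.random.default_rng(seed)
    probs = np.minimum(rng.lognormal(log_mu, log_sigma, size=len(genes)), max_freq)
    data = (rng.random((len(genes), n_samples)) < probs[:, None]).astype(np.int8)
    return pd.DataFrame(data, index=genes, columns=[f"s{j:04d}" for j in range(n_samples)])


def sample_module(net: Interactome, M: int, seed=None, max_interactors: int = 5, max_restarts: int = 100):
    """Seed-and-grow sampling of a connected module of exactly M genes.

    A seed gene is drawn at random; at each step a new seed is drawn
    from the current module and 1..``max_interactors`` of its direct
    non-module interactors (uniform count, capped by availability and
    the remaining size budget) are added.  If growth stalls the draw
    restarts from a fresh seed gene, up to ``max_restarts`` times.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    components = sorted(nx.connected_components(net.to_networkx()), key=len, reverse=True)
    if not components or len(components[0]) < M:
        raise ValueError(f"largest connected component is smaller than M={M}")
    pool = sorted(components[0])
    rng = np.random.default_rng(seed)
    A = net.adjacency
    idx = {g: i for i, g in enumerate(net.nodes)}
    nodes = net.nodes

    def neighbors(g):
        i = idx[g]
        return [nodes[j] for j in A.indices[A.indptr[i]: A.indptr[i + 1]]]

    for _ in range(max_restarts):
        module = {pool[rng.integers(0, len(pool))]}
        while len(module) < M:
            growable = sorted(g for g in module if any(n not in module for n in neighbors(g)))
            if not growable:
                break
            seed_gene = growable[rng.integers(0, len(growable))]
            avail = sorted(n for n in neighbors(seed_gene) if n not in module)
            r = min(int(rng.integers(1, max_interactors + 1)), len(avail), M - len(module))
            chosen = rng.choice(avail, size=r, replace=False)
            module.update(chosen.tolist())
        if len(module) == M:
            return frozenset(module)
    raise RuntimeError(f"could not grow a connected module of size {M} in {max_restarts} restarts")


def permute_signal(mut_matrix: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Randomly permute gene labels (rows) of a binary mutation matrix.

    Per-patient column sums are exactly unchanged and the multiset of
    per-gene row sums is exactly conserved.
    """
    values = mut_matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("mutation matrix must be binary")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(mut_matrix))
    return pd.DataFrame(values[perm], index=mut_matrix.index, columns=mut_matrix.columns)


def signal_fraction(f, module) -> float:
    """omega: the module's share of the total signal,
    sum_{j in module} f_j / sum_j f_j."""
    total = float(sum(f.values() if hasattr(f, "values") else f))
    if total <= 0:
        raise ValueError("total signal must be positive")
    return float(sum(float(f[g]) for g in module)) / total


def assign_module_signal(f, module, m_pct: float, h: float, seed=None):
    """Redistribute the values of ``f`` so the module is signal-enriched.

    The ``ceil(m_pct * M)`` largest values become module mountains; the
    remaining module genes (hills) receive values picked greedily from
    the residual pool so their mean lands as close as possible to ``h``;
    everything else is assigned uniformly at random outside the module.
    The value multiset is exactly conserved.

    Returns ``(f_sim, omega)``.

    Raises
    ------
    ValueError
        If ``m_pct`` is outside [0, 1] or ``h`` is outside the mean
        range achievable from the residual pool (the message reports
        the achievable range).
    """
    if not 0 <= m_pct <= 1:
        raise ValueError(f"m_pct must be in [0, 1], got {m_pct}")
    genes = sorted(f.keys() if hasattr(f, "keys") else f.index)
    values = np.array([float(f[g]) for g in genes])
    module = sorted(module)
    M = len(module)
    if M > len(genes):
        raise ValueError("module larger than gene universe")
    rng = np.random.default_rng(seed)

    n_mountains = math.ceil(m_pct * M)
    n_hills = M - n_mountains
    order = np.argsort(values)[::-1]
    mountain_vals = values[order[:n_mountains]]
    residual = np.sort(values[order[n_mountains:]])  # ascending

    hill_vals = np.empty(0)
    if n_hills > 0:
        lo = residual[:n_hills].mean()
        hi = residual[-n_hills:].mean()
        if not lo <= h <= hi:
            raise ValueError(
                f"hill mean h={h} unachievable; achievable range [{lo:.6g}, {hi:.6g}]"
            )
        pool = residual.tolist()
        picked = []
        acc = 0.0
        for step in range(n_hills):
            target = (h * n_hills - acc) / (n_hills - step)
            pos = int(np.searchsorted(pool, target))
            if pos >= len(pool):
                pos = len(pool) - 1
            elif pos > 0 and abs(pool[pos - 1] - target) <= abs(pool[pos] - target):
                pos -= 1
            picked.append(pool.pop(pos))
            acc += picked[-1]
        hill_vals = np.array(picked)
        rest = np.array(pool)
    else:
        rest = residual.copy()

    module_perm = rng.permutation(M)
    module_vals = np.concatenate([mountain_vals, hill_vals])[module_perm]
    module_set = set(module)
    outside = [g for g in genes if g not in module_set]
    rest = rest[rng.permutation(len(rest))]
    f_sim = {}
    for g, val in zip(module, module_vals):
        f_sim[g] = float(val)
    for g, val in zip(outside, rest):
        f_sim[g] = float(val)
    return f_sim, signal_fraction(f_sim, module)


def recall_at_M(scores, module, score_name: str = "") -> RecallResult:
    """Fraction of module genes among the top-M genes of the ranking."""
    module = sorted(module)
    M = len(module)
    genes = sorted(scores.keys() if hasattr(scores, "keys") else scores.index)
    vals = np.array([float(scores[g]) for g in genes])
    H = tuple(rank_genes(vals, genes)[:M])
    hit = len(set(H) & set(module))
    return RecallResult(hit / M, H, tuple(module), score_name)


def module_density(net: Interactome, module) -> float:
    """Induced edge count over all possible pairs among module genes."""
    module = list(module)
    M = len(module)
    if M < 2:
        return 0.0
    return net.subgraph(module).n_edges / (M * (M - 1) / 2)


def simulate_dataset(
    net: Interactome | None = None,
    n_nodes: int = 2000,
    M: int = 100,
    m_pct: float = 0.1,
    h: float | None = None,
    seed=None,
    n_samples: int = 100,
    network_model: str = "scale_free",
    log_mu: float = -5.5,
    log_sigma: float = 2.0,
) -> SimulatedDataset:
    """Build one planted-module dataset end to end.

    Generates (or reuses) a network, grows a connected module of size M,
    simulates a binary mutation cohort, permutes gene labels (the
    margin-preserving null), and plants the module signal.  ``f_control``
    is the permuted-but-unplanted frequency vector used as the
    no-enrichment control for dS.  When ``h`` is None the hill target is
    the 90th percentile of the frequency landscape — hills clearly above
    background but below the mountains.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))
    if net is None:
        net = generate_network(n_nodes, model=network_model, seed=sub())
    else:
        sub()
    module = sample_module(net, M, seed=sub())
    mat = simulate_mutation_matrix(
        net.nodes, n_samples=n_samples, seed=sub(), log_mu=log_mu, log_sigma=log_sigma
    )
    mat = permute_signal(mat, seed=sub())
    f = dict(zip(net.nodes, mutation_frequency(mat, list(mat.columns))))
    if h is None:
        h = float(np.quantile(np.array(list(f.values())), 0.9))
    f_sim, omega = assign_module_signal(f, module, m_pct, h, seed=sub())
    return SimulatedDataset(
        net,
        tuple(sorted(module)),
        f_sim,
        dict(f),
        m_pct,
        float(h),
        omega,
        module_density(net, module),
        seed,
        mat,
    )


def _smooth(net, f_map, alpha, epsilon):
    from .interactome import align_scores

    x0, _ = align_scores(f_map, net)
    W = normalize_adjacency(net)
    res = propagate_closed_form(W, x0, alpha) if net.n_nodes <= 5000 else propagate_iterative(W, x0, alpha)
    return smoothing_index(res.x_star, x0, epsilon, alpha, genes=tuple(net.nodes))


def run_benchmark(
    configs,
    n_seeds: int = 20,
    seed: int = 0,
    alpha: float = 0.7,
    epsilon: float = 0.25,
    use_delta: bool = False,
    resampling_k: int = 0,
    resampling_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run the planted-module recovery benchmark over a configuration grid.

    ``configs`` is an iterable of dicts with keys accepted by
    :func:`simulate_dataset` (``n_nodes``, ``M``, ``m_pct``, ``h``, ...).
    For each configuration and seed the dataset is built, the smoothing
    index S is computed on the planted frequencies (optionally dS
    against the unplanted control), and recall is measured for the
    network-based and the network-free ranking.  With ``resampling_k``
    > 0 a resampling profile over the positive dS genes also estimates
    the module size (first significant rank and n*).

    Returns a tidy DataFrame with one row per (configuration, seed).
    """
    from .resampling import extract_module, resampling_profile

    rows = []
    master = np.random.default_rng(seed)
    for cfg_id, cfg in enumerate(configs):
        cfg = dict(cfg)
        eps = cfg.pop("epsilon", epsilon)
        for rep in range(n_seeds):
            ds_seed = int(master.integers(0, 2**31 - 1))
            ds = simulate_dataset(seed=ds_seed, **cfg)
            S_sim = _smooth(ds.net, ds.f_sim, alpha, eps)
            genes = list(ds.net.nodes)
            if use_delta or resampling_k:
                S_ctl = _smooth(ds.net, ds.f_control, alpha, eps)
                delta = dict(zip(genes, S_sim.S - S_ctl.S))
            score_map = delta if use_delta else dict(zip(genes, S_sim.S))
            rec_S = recall_at_M(score_map, ds.module, "S").recall
            rec_f = recall_at_M(ds.f_sim, ds.module, "f").recall
            row = {
                "config": cfg_id,
                "seed": ds_seed,
                "M": len(ds.module),
                "m_pct": ds.m_pct,
                "h": ds.h,
                "epsilon": eps,
                "omega": ds.omega,
                "density": ds.density,
                "recall_S": rec_S,
                "recall_f": rec_f,
            }
            if resampling_k:
                ranking = rank_genes(
                    np.array([delta[g] for g in genes]), genes
                )
                prof = resampling_profile(
                    ds.net,
                    delta,
                    ranking,
                    k=resampling_k,
                    n_max=2 * len(ds.module),
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                mod = extract_module(prof, threshold=resampling_threshold, net=ds.net)
                row["n_first_significant"] = mod.first_significant_rank
                row["n_star"] = mod.n_star
            rows.append(row)
    return pd.DataFrame(rows)
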