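"""scikit-learn style estimators over the diffusion/smoothing core.

``NetworkSmoother`` is a transformer: it is fitted on an interaction
network (precomputing the normalised diffusion kernel and its
factorisation) and transforms per-gene statistic vectors — rows are
statistic vectors, columns are genes in the network's node order — into
network smoothing indices.  ``SpScorer`` adds the permutation p-value
adjustment for inferential inputs, and ``ModuleDetector`` runs the
network-resampling significance profile and cuts out the detected
module.  All three follow the fit/transform, ``get_params``/
``set_params`` and trailing-underscore conventions, so they compose
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import diffusion as _diff
from .indices import rank_genes, smoothing_index, sp_index
from .interactome import Interactome, align_scores, normalize_adjacency
from .resampling import extract_module, resampling_profile

__all__ = ["NetworkSmoother", "SpScorer", "ModuleDetector"]


def _as_interactome(network) -> Interactome:
    if isinstance(network, Interactome):
        return network
    try:
        return Interactome.from_networkx(network)
    except AttributeError:
        raise TypeError("network must be an Interactome or a networkx Graph")


class NetworkSmoother(TransformerMixin, BaseEstimator):
    """Transform per-gene statistics into network smoothing indices.

    Parameters
    ----------
    alpha : float, default 0.7
        Propagation parameter: weight of the network term versus the
        restart to the initial statistic.
    epsilon : float, default 0.25
        Smoothing-index offset; small values emphasise the diffusion
        gain over the initial state.
    tol, max_iter :
        Convergence control of the iterative solver.
    solver : {"auto", "closed_form", "iterative"}
        ``auto`` uses the factorised linear solve up to ``dense_cutoff``
        nodes and the sparse iteration above it.
    dense_cutoff : int, default 5000

    Attributes
    ----------
    nodes_ : list of gene identifiers (column order of ``transform``).
    W_ : scipy sparse matrix, the symmetrically normalised adjacency.
    n_features_in_ : number of network genes.
    """

    def __init__(
        self,
        alpha: float = 0.7,
        epsilon: float = 0.25,
        tol: float = 1e-6,
        max_iter: int = 10000,
        solver: str = "auto",
        dense_cutoff: int = 5000,
    ):
        self.alpha = alpha
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter
        self.solver = solver
        self.dense_cutoff = dense_cutoff

    # The "X" fitted on is the network, the object whose structure the
    # transformer learns; score vectors are what it transforms.
    def fit(self, network, y=None):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.solver not in ("auto", "closed_form", "iterative"):
            raise ValueError(f"unknown solver {self.solver!r}")
        net = _as_interactome(network)
        self.interactome_ = net
        self.nodes_ = list(net.nodes)
        self.W_ = normalize_adjacency(net)
        self.n_features_in_ = net.n_nodes
        use_lu = self.solver == "closed_form" or (
            self.solver == "auto" and net.n_nodes <= self.dense_cutoff
        )
        self._solve = _diff.steady_state_solver(self.W_, self.alpha) if use_lu else None
        return self

    def _propagate_one(self, x0: np.ndarray) -> np.ndarray:
        if self._solve is not None:
            return self._solve(x0)
        return _diff.propagate_iterative(
            self.W_, x0, self.alpha, self.tol, self.max_iter
        ).x_star

    def propagate(self, X) -> np.ndarray:
        """Steady-state vectors for one or more rows of initial statistics."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, network has {self.n_features_in_} genes"
            )
        out = np.vstack([self._propagate_one(row) for row in X])
        return out[0] if single else out

    def transform(self, X) -> np.ndarray:
        """Smoothing indices S = x* / (x0 + epsilon), row-wise."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        X2 = np.atleast_2d(X)
        x_star = np.atleast_2d(self.propagate(X2))
        S = np.vstack(
            [
                smoothing_index(xs, x0, self.epsilon, self.alpha).S
                for xs, x0 in zip(x_star, X2)
            ]
        )
        return S[0] if single else S

    def smooth_scores(self, scores) -> pd.DataFrame:
        """Smooth a gene->value mapping; returns a tidy per-gene table.

        Genes absent from the network are reported with S = 0, the
        convention for entities without interaction information.
        """
        check_is_fitted(self, "W_")
        x0, unmapped = align_scores(scores, self.interactome_)
        x_star = self.propagate(x0)
        S = smoothing_index(x_star, x0, self.epsilon, self.alpha).S
        df = pd.DataFrame({"gene": self.nodes_, "x0": x0, "x_star": x_star, "S": S})
        if unmapped:
            extra = pd.DataFrame(
                {
                    "gene": unmapped,
                    "x0": [float(scores[g]) for g in unmapped],
                    "x_star": 0.0,
                    "S": 0.0,
                }
            )
            df = pd.concat([df, extra], ignore_index=True)
        return df.sort_values("gene", ignore_index=True)


class SpScorer(TransformerMixin, BaseEstimator):
    """Permutation-adjusted smoothing index Sp for inferential statistics.

    Fitted on a network like :class:`NetworkSmoother`; ``transform``
    maps each row of input statistics to Sp = S * (1 - p) where p is the
    add-one empirical p-value over ``n_perm`` value permutations.

    Attributes (after ``transform``)
    --------------------------------
    p_values_ : array of the last computed permutation p-values.
    S_ : array of the last computed raw smoothing indices.
    """

    def __init__(
        self,
        alpha: float = 0.7,
        epsilon: float = 1.0,
        n_perm: int = 1000,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.epsilon = epsilon
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, network, y=None):
        net = _as_interactome(network)
        self.interactome_ = net
        self.nodes_ = list(net.nodes)
        self.W_ = normalize_adjacency(net)
        self.n_features_in_ = net.n_nodes
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        X2 = np.atleast_2d(X)
        if X2.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X2.shape[1]} features, network has {self.n_features_in_} genes"
            )
        sps, ps, ss = [], [], []
        for i, row in enumerate(X2):
            seed = None if self.random_state is None else int(self.random_state) + i
            res = sp_index(
                row,
                self.W_,
                alpha=self.alpha,
                epsilon=self.epsilon,
                n_perm=self.n_perm,
                seed=seed,
                genes=self.nodes_,
            )
            sps.append(res.Sp)
            ps.append(res.p)
            ss.append(res.S)
        self.p_values_ = np.vstack(ps)[0] if single else np.vstack(ps)
        self.S_ = np.vstack(ss)[0] if single else np.vstack(ss)
        out = np.vstack(sps)
        return out[0] if single else out

    def score_genes(self, scores) -> pd.DataFrame:
        """Sp table for a gene->value mapping (unmapped genes get 0)."""
        check_is_fitted(self, "W_")
        x0, unmapped = align_scores(scores, self.interactome_)
        sp = self.transform(x0)
        df = pd.DataFrame(
            {"gene": self.nodes_, "u": x0, "S": self.S_, "p": self.p_values_, "Sp": sp}
        )
        if unmapped:
            extra = pd.DataFrame(
                {
                    "gene": unmapped,
                    "u": [float(scores[g]) for g in unmapped],
                    "S": 0.0,
                    "p": 1.0,
                    "Sp": 0.0,
                }
            )
            df = pd.concat([df, extra], ignore_index=True)
        return df.sort_values("gene", ignore_index=True)


class ModuleDetector(BaseEstimator):
    """Detect a significantly connected module among top-ranked genes.

    ``fit(network, scores)`` ranks the positively scored genes, builds
    the Omega(n) resampling profile against ``k`` degree-preserving
    rewirings, and cuts the ranking at the first contiguous run of ranks
    with ``p_nr <= threshold``.

    Attributes
    ----------
    profile_ : pandas.DataFrame with columns (n, omega, p_nr).
    n_star_ : int, rank at which the module was cut (0 when nothing is
        significant).
    first_significant_rank_ : int.
    module_genes_ : tuple of gene identifiers.
    module_edges_ : tuple of induced edges.
    """

    def __init__(
        self,
        k: int = 100,
        n_max: int | None = None,
        threshold: float = 0.05,
        n_swap_factor: float = 10.0,
        rewire_scope: str = "global",
        random_state: int | None = None,
    ):
        self.k = k
        self.n_max = n_max
        self.threshold = threshold
        self.n_swap_factor = n_swap_factor
        self.rewire_scope = rewire_scope
        self.random_state = random_state

    def fit(self, network, scores):
        net = _as_interactome(network)
        if not hasattr(scores, "keys"):
            scores = dict(zip(net.nodes, np.asarray(scores, dtype=np.float64)))
        genes = [g for g in scores if g in net]
        ranking = rank_genes(np.array([float(scores[g]) for g in genes]), genes)
        prof = resampling_profile(
            net,
            scores,
            ranking,
            k=self.k,
            n_max=self.n_max,
            seed=self.random_state,
            n_swap_factor=self.n_swap_factor,
            rewire_scope=self.rewire_scope,
        )
        mod = extract_module(prof, net=net, threshold=self.threshold, scores=scores)
        self.interactome_ = net
        self.profile_ = pd.DataFrame(
            {"n": prof.ranks, "omega": prof.omega, "p_nr": prof.p_nr}
        )
        self.ranking_ = tuple(prof.ranking)
        self.n_star_ = mod.n_star
        self.first_significant_rank_ = mod.first_significant_rank
        self.module_genes_ = mod.genes
        self.module_edges_ = mod.edges
        return self

    def fit_predict(self, network, scores):
        """Fit and return the detected module gene tuple."""
        return self.fit(network, scores).module_genes_
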