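import itertools

import networkx as nx
import numpy as np
import pytest

from diffmod import (
    Interactome,
    extract_module,
    omega,
    overlap_coefficient,
    resampling_profile,
    rewire_degree_preserving,
)
from diffmod.resampling import ResamplingProfile

from conftest import random_interactome


def brute_omega(net, scores, ranking, n):
    top = set(ranking[:n])
    edges = {frozenset(e) for e in net.edges}
    total = 0.0
    for i, j in itertools.combinations(sorted(top), 2):
        if frozenset((i, j)) in edges:
            total += scores[i] * scores[j]
    return total


class TestOmega:
    def test_single_gene_no_pairs(self, triangle):
        assert omega(triangle, {"A": 3, "B": 2, "C": 1}, ["A", "B", "C"], 1) == 0.0

    def test_triangle_all_pairs(self, triangle):
        val = omega(triangle, {"A": 3, "B": 2, "C": 1}, ["A", "B", "C"], 3)
        assert val == pytest.approx(11.0)

    def test_path_top_two(self, path3):
        val = omega(path3, {"A": 3, "B": 2, "C": 1}, ["A", "B", "C"], 2)
        assert val == pytest.approx(6.0)

    def test_invalid_rank(self, path3):
        with pytest.raises(ValueError):
            omega(path3, {"A": 1}, ["A"], 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_instances(self, seed):
        net = random_interactome(40, 0.12, seed=seed)
        rng = np.random.default_rng(seed)
        scores = dict(zip(net.nodes, rng.random(net.n_nodes)))
        ranking = sorted(net.nodes, key=lambda g: -scores[g])
        for n in (2, 7, 25, 40):
            assert omega(net, scores, ranking, n) == pytest.approx(
                brute_omega(net, scores, ranking, n)
            )


class TestRewiring:
    def test_degree_sequence_exact(self):
        for seed in range(5):
            net = random_interactome(40, 0.15, seed=seed)
            rewired = rewire_degree_preserving(net, seed=seed)
            assert dict(zip(rewired.nodes, rewired.degrees)) == dict(
                zip(net.nodes, net.degrees)
            )

    def test_complete_graph_is_rigid(self):
        k4 = Interactome(
            [(a, b) for a, b in itertools.combinations("ABCD", 2)]
        )
        rewired = rewire_degree_preserving(k4, seed=0)
        assert set(rewired.edges) == set(k4.edges)

    def test_six_cycle_explores_other_two_regular_graphs(self):
        cyc = Interactome([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        seen_different = False
        for seed in range(20):
            rewired = rewire_degree_preserving(cyc, seed=seed)
            assert np.all(rewired.degrees == 2)
            # reference set: any 2-regular simple graph on 6 labelled
            # nodes is a disjoint union of cycles covering all nodes
            g = rewired.to_networkx()
            comps = list(nx.connected_components(g))
            assert all(len(c) >= 3 for c in comps)
            if set(rewired.edges) != set(cyc.edges):
                seen_different = True
        assert seen_different

    def test_too_few_edges_rejected(self, k2):
        with pytest.raises(ValueError):
            rewire_degree_preserving(k2)

    def test_seed_reproducible(self):
        net = random_interactome(30, 0.2, seed=1)
        a = rewire_degree_preserving(net, seed=42)
        b = rewire_degree_preserving(net, seed=42)
        assert a.edges == b.edges


class TestResamplingProfile:
    def test_complete_graph_never_significant(self):
        k6 = Interactome([(a, b) for a, b in itertools.combinations("ABCDEF", 2)])
        scores = {g: s for g, s in zip("ABCDEF", [6, 5, 4, 3, 2, 1])}
        prof = resampling_profile(k6, scores, list("ABCDEF"), k=20, seed=0)
        assert np.allclose(prof.p_nr, 1.0)

    def test_omega_curve_non_decreasing_and_matches_pointwise(self):
        net = random_interactome(40, 0.12, seed=2)
        rng = np.random.default_rng(2)
        scores = dict(zip(net.nodes, rng.random(net.n_nodes) + 0.01))
        ranking = sorted(net.nodes, key=lambda g: -scores[g])
        prof = resampling_profile(net, scores, ranking, k=10, seed=3)
        assert np.all(np.diff(prof.omega) >= -1e-12)
        for pos, n in [(0, 2), (10, 12), (30, 32)]:
            assert prof.omega[pos] == pytest.approx(omega(net, scores, ranking, n))

    def test_nonpositive_scores_excluded_and_all_negative_rejected(self):
        net = random_interactome(20, 0.2, seed=4)
        scores = {g: -1.0 for g in net.nodes}
        with pytest.raises(ValueError):
            resampling_profile(net, scores, list(net.nodes), k=5)

    def test_planted_clique_detected_against_independent_null(self):
        # high-signal 5-clique in a sparse background: p_nr(5) should be
        # small, matching an independent Monte-Carlo rewiring estimate
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(60, 0.05, seed=3)
        mapping = {i: f"g{i:02d}" for i in g.nodes()}
        g = nx.relabel_nodes(g, mapping)
        clique = [f"g{i:02d}" for i in range(5)]
        g.add_edges_from(itertools.combinations(clique, 2))
        net = Interactome.from_networkx(g)
        scores = {n: (1.0 if n in clique else 0.0) for n in net.nodes}
        ranking = sorted(net.nodes, key=lambda n: (-scores[n], n))
        prof = resampling_profile(net, scores, ranking, k=99, seed=11)
        p5 = prof.p_nr[list(prof.ranks).index(5)]
        # independent oracle: nx double_edge_swap resamples
        obs = omega(net, scores, ranking, 5)
        hits = 0
        trials = 400
        for s in range(trials):
            r = net.to_networkx()
            try:
                nx.double_edge_swap(r, nswap=4 * net.n_edges, max_tries=10**5, seed=s)
            except nx.NetworkXAlgorithmError:
                pass
            val = sum(
                scores[u] * scores[v]
                for u, v in r.edges()
                if scores[u] > 0 and scores[v] > 0
            )
            hits += val >= obs
        oracle = (1 + hits) / (trials + 1)
        se = 3 * np.sqrt(oracle * (1 - oracle) / 99)
        assert abs(p5 - oracle) <= max(se, 0.05)

    def test_flat_scores_on_vertex_transitive_graph_not_significant(self):
        cyc = Interactome([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        scores = {g: 1.0 for g in cyc.nodes}
        prof = resampling_profile(cyc, scores, list(cyc.nodes), k=199, seed=5)
        assert prof.p_nr.min() > 0.05

    def test_bit_reproducible(self):
        net = random_interactome(30, 0.15, seed=8)
        scores = dict(zip(net.nodes, np.random.default_rng(8).random(30) + 0.01))
        ranking = sorted(net.nodes, key=lambda g: -scores[g])
        a = resampling_profile(net, scores, ranking, k=15, seed=21)
        b = resampling_profile(net, scores, ranking, k=15, seed=21)
        assert np.array_equal(a.omega, b.omega)
        assert np.array_equal(a.p_nr, b.p_nr)

    def test_null_calibration_under_random_scores(self):
        # with scores drawn at random on a fixed graph the per-profile
        # minimum p_nr is a scan statistic: we track the fraction of
        # replicates dipping below 0.05 (no multiplicity correction is
        # claimed, so the rate may exceed 0.05 but not be degenerate)
        net = random_interactome(40, 0.12, seed=12)
        rng = np.random.default_rng(12)
        dips = 0
        n_rep = 10
        for _ in range(n_rep):
            scores = dict(zip(net.nodes, rng.random(net.n_nodes) + 1e-3))
            ranking = sorted(net.nodes, key=lambda g: (-scores[g], g))
            prof = resampling_profile(net, scores, ranking, k=99, seed=int(rng.integers(2**31)))
            dips += prof.p_nr.min() <= 0.05
        assert dips < n_rep  # random scores must not always look modular

    def test_induced_scope_runs(self):
        net = random_interactome(25, 0.2, seed=6)
        scores = dict(zip(net.nodes, np.random.default_rng(6).random(25) + 0.01))
        ranking = sorted(net.nodes, key=lambda g: -scores[g])
        prof = resampling_profile(
            net, scores, ranking, k=10, n_max=15, seed=1, rewire_scope="induced"
        )
        assert np.all((prof.p_nr > 0) & (prof.p_nr <= 1))


class TestExtractModule:
    def make_profile(self, p_values):
        n = len(p_values)
        return ResamplingProfile(
            ranks=np.arange(2, n + 2),
            omega=np.zeros(n),
            p_nr=np.array(p_values),
            k=100,
            seed=0,
            ranking=tuple(f"g{i}" for i in range(n + 1)),
        )

    def test_all_non_significant_gives_empty_module(self):
        mod = extract_module(self.make_profile([1.0] * 10), ranking=[f"g{i}" for i in range(11)])
        assert mod.n_star == 0 and mod.genes == ()

    def test_contiguous_run_cut_at_largest_rank(self):
        p = [1.0] * 5 + [0.01] * 4 + [0.5, 0.01]
        ranking = [f"g{i}" for i in range(15)]
        mod = extract_module(self.make_profile(p), ranking=ranking)
        # ranks 7..10 form the first significant run
        assert mod.first_significant_rank == 7
        assert mod.n_star == 10
        assert mod.genes == tuple(ranking[:10])

    def test_induced_edges_restricted_to_module(self, triangle):
        prof = self.make_profile([0.01, 0.01])
        mod = extract_module(prof, ranking=["A", "B", "C"], net=triangle)
        assert mod.n_star == 3
        assert set(mod.edges) == {("A", "B"), ("A", "C"), ("B", "C")}


class TestOverlapCoefficient:
    def test_identical_sets(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_partial(self):
        assert overlap_coefficient({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), set())
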