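"""Supra-transition construction and random walk with restart on multiplexes."""

import numpy as np
import pytest

from afcerna import (
    MultiplexGraph,
    RWRMParams,
    build_supra_transition,
    layer_weights,
    prioritize_lncrnas,
    rwrm_scores,
)


def random_multiplex(n, n_layers=2, p=0.15, seed=0):
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(n_layers):
        a = (rng.random((n, n)) < p).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        layers.append(a)
    return MultiplexGraph([f"N{i:03d}" for i in range(n)], layers)


def direct_solve(graph, seeds, params):
    """Dense linear-algebra oracle: p = r (I - (1-r) M)^-1 p_RS."""
    n, L = graph.n, graph.L
    M = build_supra_transition(graph, params.delta)
    tau = params.resolve_tau(L)
    idx = {g: i for i, g in enumerate(graph.nodes)}
    p0 = np.zeros(n)
    present = [idx[s] for s in seeds if s in idx]
    p0[present] = 1.0 / len(present)
    p_rs = np.concatenate([(tau[a] / L) * p0 for a in range(L)])
    return params.r * np.linalg.solve(
        np.eye(n * L) - (1 - params.r) * M, p_rs
    )


class TestSupraTransition:
    def test_columns_sum_to_one(self):
        g = random_multiplex(20, seed=3)
        M = build_supra_transition(g, 0.5)
        np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-12)

    def test_single_layer_reduces_to_column_normalized_adjacency(self):
        g = random_multiplex(10, n_layers=1, seed=4)
        M = build_supra_transition(g, 0.7)  # delta degenerates to 0
        a = g.layers[0]
        cols = a.sum(axis=0)
        live = cols > 0
        np.testing.assert_allclose(
            M[:, live], a[:, live] / cols[live], atol=1e-12
        )

    def test_hand_constructed_two_node_two_layer_matrix(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        g = MultiplexGraph(["A", "B"], [a, a.copy()])
        M = build_supra_transition(g, 0.5)
        # pre-normalization column: within-layer 0.5 to the neighbor, 0.5 to
        # the same node in the other layer -> each column is (0.5, 0.5)
        expected = np.array(
            [
                [0.0, 0.5, 0.5, 0.0],
                [0.5, 0.0, 0.0, 0.5],
                [0.5, 0.0, 0.0, 0.5],
                [0.0, 0.5, 0.5, 0.0],
            ]
        )
        np.testing.assert_allclose(M, expected, atol=1e-12)

    def test_isolated_everywhere_node_gets_teleport_column(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        g = MultiplexGraph(["A", "B", "C"], [a])
        with pytest.warns(UserWarning, match="teleport"):
            M = build_supra_transition(g, 0.0)
        np.testing.assert_allclose(M[:, 2], 1.0 / 3.0)


class TestLayerWeights:
    @pytest.mark.parametrize("R,expected", [(1.0, [1.0, 1.0]), (3.0, [0.5, 1.5])])
    def test_known_values(self, R, expected):
        np.testing.assert_allclose(layer_weights(R), expected)

    def test_weights_always_sum_to_two(self, rng):
        for R in rng.uniform(0.01, 50, size=20):
            assert layer_weights(R).sum() == pytest.approx(2.0)

    def test_nonpositive_ratio_raises(self):
        with pytest.raises(ValueError):
            layer_weights(0.0)


class TestRWRMScores:
    def test_restart_only_walk_returns_restart_distribution(self):
        g = random_multiplex(12, seed=5)
        params = RWRMParams(r=1.0, tau=np.array([0.5, 1.5]))
        res = rwrm_scores(g, ["N000", "N001"], params)
        expected = np.zeros((12, 2))
        expected[[0, 1], 0] = 0.5 / 2 / 2
        expected[[0, 1], 1] = 1.5 / 2 / 2
        np.testing.assert_allclose(res.per_layer, expected, atol=1e-9)

    def test_iterative_matches_direct_solve_and_mass_is_one(self):
        for seed, n in [(1, 50), (2, 120), (3, 200)]:
            g = random_multiplex(n, seed=seed)
            params = RWRMParams(delta=0.5, r=0.7)
            seeds = [g.nodes[i] for i in (0, 3, 7)]
            res = rwrm_scores(g, seeds, params)
            direct = direct_solve(g, seeds, params)
            np.testing.assert_allclose(
                res.per_layer.T.ravel(), direct, atol=1e-8
            )
            assert res.per_layer.sum() == pytest.approx(1.0, abs=1e-8)

    def test_missing_seeds_raise(self):
        g = random_multiplex(10)
        with pytest.raises(ValueError, match="seed"):
            rwrm_scores(g, ["ZZZ"], RWRMParams())

    def test_identical_uncoupled_layers_reduce_to_single_layer_rwr(self):
        """With delta = 0 and tau = [1, 1] two identical layers decouple and
        each carries half the restart mass, so the per-node global score
        (summed over layers) equals the single-layer stationary distribution.
        (With delta > 0 the inter-layer jumps make the marginal a lazy walk
        with a larger effective restart, so no such reduction holds.)"""
        g2 = random_multiplex(40, seed=9)
        a = g2.layers[0]
        g_twin = MultiplexGraph(g2.nodes, [a, a.copy()])
        g_single = MultiplexGraph(g2.nodes, [a])
        seeds = [g2.nodes[0], g2.nodes[5]]
        params = RWRMParams(delta=0.0, r=0.7, tau=np.array([1.0, 1.0]))
        twin = rwrm_scores(g_twin, seeds, params)
        single = rwrm_scores(g_single, seeds, RWRMParams(delta=0.0, r=0.7))
        np.testing.assert_allclose(
            twin.global_scores, single.global_scores, atol=1e-8
        )
        np.testing.assert_allclose(
            twin.per_layer[:, 0], twin.per_layer[:, 1], atol=1e-8
        )

    def test_seed_mass_is_nondecreasing_in_restart_probability(self):
        g = random_multiplex(30, seed=11)
        seeds = [g.nodes[0], g.nodes[1]]
        masses = []
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            res = rwrm_scores(g, seeds, RWRMParams(r=r))
            masses.append(res.global_scores[:2].sum())
        assert all(b >= a - 1e-10 for a, b in zip(masses, masses[1:]))


class TestPrioritize:
    def test_full_list_when_top_k_exceeds_candidates(self):
        g = random_multiplex(10, seed=13)
        bio = {n: ("lncRNA" if i < 4 else "mRNA") for i, n in enumerate(g.nodes)}
        res = rwrm_scores(g, [g.nodes[9]], RWRMParams())
        out = prioritize_lncrnas(res, bio, top_k=100)
        assert len(out) == 4

    def test_seeds_are_excluded_and_ties_break_by_id(self):
        a = np.zeros((4, 4))  # all lncRNAs isolated: equal minimal scores
        a[2, 3] = a[3, 2] = 1.0
        g = MultiplexGraph(["L2", "L1", "S1", "S2"], [a])
        bio = {"L1": "lncRNA", "L2": "lncRNA", "S1": "mRNA", "S2": "mRNA"}
        with pytest.warns(UserWarning):
            res = rwrm_scores(g, ["S1"], RWRMParams())
        out = prioritize_lncrnas(res, bio, top_k=2)
        assert [g_ for g_, _ in out] == ["L1", "L2"]
        assert out[0][1] == pytest.approx(out[1][1])

    def test_planted_hub_ranks_first_on_synthetic_multiplex(self, small_dataset):
        from afcerna import aggregate_networks, build_module_cerna

        ds = small_dataset
        bio = ds.biotypes.to_dict()
        nets = []
        for m in sorted({int(k) for k in ds.truth["trait_modules"]}):
            genes = [g for g, v in ds.truth["module_labels"].items() if v == m]
            nets.append(build_module_cerna(genes, bio, ds.mirna_db, module=m))
        agg = aggregate_networks(nets, ds.seed_genes)
        nodes = agg.nodes()
        node_set = set(nodes)
        l1 = [(e.lncrna, e.mrna) for e in agg.edges]
        l2 = [
            (r.gene_a, r.gene_b)
            for r in ds.layer2_edges.itertuples()
            if r.gene_a in node_set and r.gene_b in node_set
        ]
        g = MultiplexGraph.from_edge_lists(nodes, [l1, l2])
        res = rwrm_scores(g, ds.seed_genes, RWRMParams())
        out = prioritize_lncrnas(res, bio, top_k=1)
        assert out[0][0] == ds.truth["hub_lncrna"]
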