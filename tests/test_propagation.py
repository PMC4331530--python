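import numpy as np
import pytest

from dualflow import (
    AnnotatedNetwork,
    ConfigurationError,
    PropagationConfig,
    build_operator,
    build_prior,
    propagate,
    rank_scores,
    score_candidates,
    similarity_matrix,
)

from conftest import random_network


def dense_operator_oracle(net, normalization):
    """Entry-by-entry double loop over the edge set; no sparse algebra."""
    n = net.n_nodes
    k = {g: net.degree(g) for g in net.nodes}
    w = np.zeros((n, n))
    idx = net.node_index
    for e in net.edges():
        a, b = tuple(e)
        for x, y in ((a, b), (b, a)):
            if normalization == "pump":
                w[idx[y], idx[x]] = 1.0 / k[x]  # x sends F(x)/k(x) to y
            elif normalization == "average":
                w[idx[x], idx[y]] = 1.0 / k[x]
            else:
                w[idx[x], idx[y]] = 1.0 / np.sqrt(k[x] * k[y])
    return w


def dense_steady_state(net, y, alpha, normalization):
    w = dense_operator_oracle(net, normalization)
    return alpha * np.linalg.solve(np.eye(net.n_nodes) - (1 - alpha) * w, y)


class TestOperator:
    def test_pump_splits_flow_equally(self, path_graph):
        w = build_operator(path_graph, "pump").toarray()
        idx = path_graph.node_index
        f = np.zeros(3)
        f[idx["b"]] = 1.0
        out = w @ f
        assert out[idx["a"]] == pytest.approx(0.5)
        assert out[idx["c"]] == pytest.approx(0.5)
        assert out[idx["b"]] == 0.0

    def test_single_node_zero_operator(self):
        net = AnnotatedNetwork.from_edges([], nodes=["a"])
        assert build_operator(net, "pump").nnz == 0

    @pytest.mark.parametrize("normalization", ["pump", "average", "symmetric"])
    def test_matches_double_loop_oracle(self, normalization):
        rng = np.random.default_rng(3)
        net = random_network(rng, 5, p=0.6)
        w = build_operator(net, normalization).toarray()
        assert w == pytest.approx(dense_operator_oracle(net, normalization))
        f = rng.normal(size=net.n_nodes)
        assert w @ f == pytest.approx(dense_operator_oracle(net, normalization) @ f)

    def test_unknown_mode_rejected(self, path_graph):
        with pytest.raises(ConfigurationError):
            PropagationConfig(normalization="rowsum")


class TestPropagate:
    def test_alpha_one_returns_prior(self, path_graph):
        y = np.array([1.0, -2.0, 0.5])
        res = propagate(path_graph, y, PropagationConfig(alpha=1.0))
        assert res.flow == pytest.approx(y)

    def test_two_node_hand_solution(self):
        # edge a-b, Y=(1,0), alpha=0.5: f_a = 0.5 f_b + 0.5, f_b = 0.5 f_a
        net = AnnotatedNetwork.from_edges([("a", "b")])
        res = propagate(net, np.array([1.0, 0.0]), PropagationConfig(alpha=0.5))
        assert res.flow == pytest.approx([2 / 3, 1 / 3])

    def test_zero_prior_gives_zero_flow(self, path_graph):
        res = propagate(path_graph, np.zeros(3), PropagationConfig(alpha=0.3))
        assert res.flow == pytest.approx(np.zeros(3), abs=1e-12)

    @pytest.mark.parametrize("normalization", ["pump", "average", "symmetric"])
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9, 1.0])
    def test_iterative_matches_dense_closed_form(self, normalization, alpha):
        rng = np.random.default_rng(17)
        for _ in range(5):
            net = random_network(rng, int(rng.integers(5, 50)), p=0.2)
            y = rng.normal(size=net.n_nodes)
            cfg = PropagationConfig(
                alpha=alpha, solver="iterative", tolerance=1e-13,
                max_iterations=50_000, normalization=normalization,
            )
            res = propagate(net, y, cfg)
            expected = dense_steady_state(net, y, alpha, normalization)
            assert res.flow == pytest.approx(expected, abs=1e-8)
            assert res.residual <= cfg.tolerance

    def test_direct_and_iterative_agree(self):
        rng = np.random.default_rng(23)
        net = random_network(rng, 40, p=0.15)
        y = rng.normal(size=net.n_nodes)
        tol = 1e-10
        it = propagate(net, y, PropagationConfig(solver="iterative", tolerance=tol))
        di = propagate(net, y, PropagationConfig(solver="direct"))
        assert np.abs(it.flow - di.flow).max() < 10 * tol

    def test_pump_mode_conserves_total_flow(self):
        rng = np.random.default_rng(29)
        for _ in range(5):
            net = random_network(rng, 30, p=0.3)  # dense enough to be connected
            assert net.degrees.min() > 0
            y = rng.normal(size=net.n_nodes)
            res = propagate(net, y, PropagationConfig(alpha=0.4, normalization="pump"))
            assert res.flow.sum() == pytest.approx(y.sum(), abs=1e-8)

    def test_linearity_of_steady_state(self):
        rng = np.random.default_rng(31)
        net = random_network(rng, 25, p=0.2)
        y1, y2 = rng.normal(size=(2, net.n_nodes))
        cfg = PropagationConfig(alpha=0.6)
        f1 = propagate(net, y1, cfg).flow
        f2 = propagate(net, y2, cfg).flow
        f12 = propagate(net, y1 + y2, cfg).flow
        assert f12 == pytest.approx(f1 + f2, abs=1e-10)

    def test_automorphism_symmetry(self):
        # u and v are swappable leaves of the same hub; symmetric prior
        net = AnnotatedNetwork.from_edges([("hub", "u"), ("hub", "v"), ("hub", "w")])
        y = np.zeros(4)
        y[net.node_index["hub"]] = 1.0
        res = propagate(net, y, PropagationConfig(alpha=0.5))
        assert res.flow[net.node_index["u"]] == pytest.approx(res.flow[net.node_index["v"]])

    def test_flow_approaches_prior_as_alpha_to_one(self):
        rng = np.random.default_rng(37)
        net = random_network(rng, 20, p=0.3)
        y = rng.normal(size=net.n_nodes)
        errs = [
            np.abs(propagate(net, y, PropagationConfig(alpha=a)).flow - y).max()
            for a in (0.5, 0.9, 0.99, 0.999)
        ]
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] < 1e-2

    def test_solver_never_singular_on_random_graphs(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            net = random_network(rng, int(rng.integers(2, 30)), p=0.3)
            y = rng.normal(size=net.n_nodes)
            res = propagate(net, y, PropagationConfig(alpha=0.1))
            assert np.isfinite(res.flow).all()


class TestPrior:
    def test_normalized_dual_prior_sums_to_zero(self):
        net = AnnotatedNetwork.from_edges([("a", "b"), ("b", "e"), ("e", "a")])
        prior = build_prior(net, "np_de", T_h={"a", "b"}, E_minus={"e"})
        idx = net.node_index
        assert prior.values[idx["a"]] == pytest.approx(0.5)
        assert prior.values[idx["b"]] == pytest.approx(0.5)
        assert prior.values[idx["e"]] == pytest.approx(-1.0)
        assert prior.values.sum() == pytest.approx(0.0)

    def test_np_d_single_gene_is_indicator(self):
        net = AnnotatedNetwork.from_edges([("a", "b")])
        prior = build_prior(net, "np_d", T_h={"a"})
        assert list(prior.values) == [1.0, 0.0]

    def test_unit_mode_literal_plus_minus_one(self):
        net = AnnotatedNetwork.from_edges(
            [("a", "b"), ("b", "e"), ("e", "f"), ("f", "g"), ("g", "a")]
        )
        prior = build_prior(net, "np_de", T_h={"a", "b"}, E_minus={"e", "f", "g"}, prior_mode="unit")
        vals = {g: prior.values[net.node_index[g]] for g in "abefg"}
        assert vals == {"a": 1.0, "b": 1.0, "e": -1.0, "f": -1.0, "g": -1.0}

    def test_empty_required_side_rejected(self):
        net = AnnotatedNetwork.from_edges([("a", "b")])
        with pytest.raises(ConfigurationError):
            build_prior(net, "np_de", T_h={"a"}, E_minus={"ghost"})

    def test_overlap_resolves_positive_with_warning(self):
        net = AnnotatedNetwork.from_edges([("a", "b"), ("b", "c")])
        with pytest.warns(UserWarning, match="positive"):
            prior = build_prior(net, "np_de", T_h={"a"}, E_minus={"a", "b"})
        assert prior.values[net.node_index["a"]] > 0


class TestScoring:
    def test_all_off_network_candidates_share_worst_rank(self, path_graph):
        ranked = rank_scores(["x", "y"], {})
        assert [r for _g, _s, r in ranked] == [2, 2]

    def test_ties_ranked_last_among_group(self):
        ranked = rank_scores(
            ["g1", "g2", "g3", "g4", "g5"],
            {"g1": 9.0, "g2": 5.0, "g3": 5.0, "g4": 5.0, "g5": 1.0},
        )
        ranks = {g: r for g, _s, r in ranked}
        assert ranks == {"g1": 1, "g2": 4, "g3": 4, "g4": 4, "g5": 5}

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            rank_scores([], {})

    def test_np_de_is_weighted_superposition(self, toy):
        net, roles = toy
        ess = set(roles["essentials"])
        train = set(roles["train"])
        cfg = PropagationConfig(alpha=0.5)
        cands = [g for g in net.nodes if g not in train]

        def flows(mode):
            ranked = score_candidates(net, mode, train, ess, cfg, candidates=cands)
            return {g: s for g, s, _r in ranked}

        de, d, e = flows("np_de"), flows("np_d"), flows("np_e")
        for g in cands:
            assert de[g] == pytest.approx(d[g] + e[g], abs=1e-10)


class TestSimilarityMatrix:
    def test_columns_are_indicator_propagations(self, toy):
        net, _ = toy
        cfg = PropagationConfig(alpha=0.4)
        s = similarity_matrix(net, cfg)
        for j in (0, net.n_nodes - 1):
            y = np.zeros(net.n_nodes)
            y[j] = 1.0
            assert s[:, j] == pytest.approx(propagate(net, y, cfg).flow, abs=1e-10)

    def test_alpha_one_is_identity(self, path_graph):
        assert similarity_matrix(path_graph, PropagationConfig(alpha=1.0)) == pytest.approx(np.eye(3))
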