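"""Single-network RWR: normalization, initial states, solvers, ranking."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from gwasprop import (
    ConvergenceError,
    InitMode,
    RandomWalkRestart,
    ValidationError,
    build_initial_state,
    normalize_adjacency,
    rank_genes,
    rwr_closed_form,
    rwr_power_iteration,
)


def dense_rwr_oracle(net: nx.Graph, p0: np.ndarray, alpha: float) -> np.ndarray:
    """Independent dense-matrix evaluation of (1-a)(I - aW)^-1 p0."""
    nodes = sorted(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes)
    deg = A.sum(axis=0)
    W = A / np.where(deg == 0, 1.0, deg)
    W = W + np.diag(deg == 0)  # isolated nodes retain mass
    return (1 - alpha) * np.linalg.solve(np.eye(len(nodes)) - alpha * W, p0)


class TestNormalizeAdjacency:
    def test_two_node_path(self, path2):
        tm = normalize_adjacency(path2)
        assert np.allclose(tm.matrix.toarray(), [[0, 1], [1, 0]])

    def test_triangle_columns_half(self, triangle):
        W = normalize_adjacency(triangle).matrix.toarray()
        assert np.allclose(W, (np.ones((3, 3)) - np.eye(3)) / 2)

    def test_column_sums_match_dense_oracle(self, random_graph_factory):
        net = random_graph_factory(50, seed=3)
        tm = normalize_adjacency(net)
        sums = np.asarray(tm.matrix.sum(axis=0)).ravel()
        assert np.allclose(sums[~tm.isolated], 1.0, atol=1e-12)
        A = nx.to_numpy_array(net, nodelist=sorted(net.nodes))
        assert np.allclose(tm.matrix.toarray(), A / A.sum(axis=0), atol=1e-12)

    def test_weighted_normalization(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=3.0)
        net.add_edge("b", "c", weight=1.0)
        W = normalize_adjacency(net).matrix.toarray()
        # column b: 3/4 to a, 1/4 to c
        assert np.allclose(W[:, 1], [0.75, 0, 0.25])
        Wb = normalize_adjacency(net, binarize=True).matrix.toarray()
        assert np.allclose(Wb[:, 1], [0.5, 0, 0.5])

    def test_isolated_nodes_flagged_with_zero_columns(self):
        net = nx.path_graph(["a", "b"])
        net.add_node("z")
        tm = normalize_adjacency(net)
        assert tm.isolated.tolist() == [False, False, True]
        assert tm.matrix.toarray()[:, 2].sum() == 0

    def test_negative_weight_rejected(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValidationError):
            normalize_adjacency(net)

    def test_self_loop_rejected(self, path2):
        path2.add_edge("a", "a")
        with pytest.raises(ValidationError):
            normalize_adjacency(path2)


class TestInitialState:
    def test_seed_binary_uniform_over_present_seeds(self, triangle):
        tm = normalize_adjacency(triangle)
        p0 = build_initial_state(tm, seeds=["a", "b"])
        assert np.allclose(p0.vector, [0.5, 0.5, 0.0])
        assert p0.mode is InitMode.SEED_BINARY

    def test_equal_scores_give_uniform_state(self, triangle):
        tm = normalize_adjacency(triangle)
        p0 = build_initial_state(tm, scores={"a": 2.0, "b": 2.0, "c": 2.0})
        assert np.allclose(p0.vector, 1 / 3)

    def test_score_normalization_arithmetic(self, triangle):
        tm = normalize_adjacency(triangle)
        p0 = build_initial_state(tm, scores={"a": 2.0, "b": 1.0, "c": 1.0})
        assert np.allclose(p0.vector, [0.5, 0.25, 0.25])

    def test_seeds_absent_from_network_raise(self, triangle):
        tm = normalize_adjacency(triangle)
        with pytest.raises(ValidationError, match="no propagation input"):
            build_initial_state(tm, seeds=["zz"])

    def test_all_zero_scores_raise(self, triangle):
        tm = normalize_adjacency(triangle)
        with pytest.raises(ValidationError, match="no propagation input"):
            build_initial_state(tm, scores={"a": 0.0})

    def test_scored_genes_outside_network_ignored(self, triangle):
        tm = normalize_adjacency(triangle)
        p0 = build_initial_state(tm, scores={"a": 1.0, "not_here": 99.0})
        assert np.allclose(p0.vector, [1.0, 0, 0])


class TestSolvers:
    def test_alpha_zero_returns_p0_exactly(self, triangle):
        tm = normalize_adjacency(triangle)
        p0 = build_initial_state(tm, scores={"a": 3.0, "b": 1.0})
        res = rwr_closed_form(tm, p0, 0.0)
        assert (res.ps == p0.vector).all()
        res_it = rwr_power_iteration(tm, p0, 0.0)
        assert res_it.n_iter == 1
        assert np.allclose(res_it.ps, p0.vector, atol=1e-15)

    def test_two_node_hand_derived_stationary(self, path2):
        # (I - aW)x = (1-a)p0 with W=[[0,1],[1,0]], a=1/2 gives x=(2/3, 1/3)
        tm = normalize_adjacency(path2)
        p0 = build_initial_state(tm, seeds=["a"])
        res = rwr_closed_form(tm, p0, 0.5)
        assert np.allclose(res.ps, [2 / 3, 1 / 3], atol=1e-12)

    def test_complete_graph_uniform_fixed_point(self):
        net = nx.complete_graph([f"v{i}" for i in range(7)])
        tm = normalize_adjacency(net)
        p0 = build_initial_state(tm, scores={f"v{i}": 1.0 for i in range(7)})
        for alpha in (0.2, 0.9):
            assert np.allclose(rwr_closed_form(tm, p0, alpha).ps, 1 / 7, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.85])
    def test_closed_form_matches_dense_oracle(self, random_graph_factory, seed, alpha):
        net = random_graph_factory(40, seed=seed)
        tm = normalize_adjacency(net)
        gen = np.random.default_rng(seed)
        raw = gen.random(40)
        p0 = build_initial_state(tm, scores={g: s for g, s in zip(tm.nodes, raw)})
        expected = dense_rwr_oracle(net, p0.vector, alpha)
        assert np.allclose(rwr_closed_form(tm, p0, alpha).ps, expected, atol=1e-10)

    def test_power_iteration_agrees_with_closed_form(self, random_graph_factory):
        net = random_graph_factory(60, seed=7)
        tm = normalize_adjacency(net)
        p0 = build_initial_state(tm, seeds=["g0000", "g0001"])
        exact = rwr_closed_form(tm, p0, 0.3)
        approx = rwr_power_iteration(tm, p0, 0.3, tol=1e-10)
        assert np.abs(exact.ps - approx.ps).sum() < 1e-9

    def test_halving_tol_never_reduces_iterations(self, random_graph_factory):
        net = random_graph_factory(30, seed=5)
        tm = normalize_adjacency(net)
        p0 = build_initial_state(tm, seeds=["g0000"])
        iters = [
            rwr_power_iteration(tm, p0, 0.6, tol=tol).n_iter
            for tol in (1e-4, 5e-5, 2.5e-5, 1.25e-5)
        ]
        assert iters == sorted(iters)

    def test_nonconvergence_raises_with_residual(self, random_graph_factory):
        net = random_graph_factory(30, seed=5)
        tm = normalize_adjacency(net)
        p0 = build_initial_state(tm, seeds=["g0000"])
        with pytest.raises(ConvergenceError) as err:
            rwr_power_iteration(tm, p0, 0.9, tol=1e-14, max_iter=3)
        assert err.value.residual > 0

    def test_alpha_one_rejected(self, path2):
        tm = normalize_adjacency(path2)
        p0 = build_initial_state(tm, seeds=["a"])
        for bad in (1.0, 1.5, -0.1):
            with pytest.raises(ValidationError):
                rwr_closed_form(tm, p0, bad)

    def test_mass_conserved_across_alpha_grid(self, random_graph_factory):
        net = random_graph_factory(80, seed=11)
        tm = normalize_adjacency(net)
        p0 = build_initial_state(tm, seeds=["g0003"])
        for alpha in np.arange(0.0, 1.0, 0.1):
            assert abs(rwr_closed_form(tm, p0, float(alpha)).ps.sum() - 1.0) < 1e-10

    def test_isolated_node_mass_retained_in_place(self):
        net = nx.path_graph(["a", "b"])
        net.add_node("z")
        tm = normalize_adjacency(net)
        p0 = build_initial_state(tm, scores={"a": 1.0, "z": 1.0})
        res = rwr_closed_form(tm, p0, 0.5)
        assert np.isclose(res.ps[2], 0.5)  # z keeps its initial mass
        assert np.isclose(res.ps.sum(), 1.0)

    def test_continuity_at_alpha_zero(self, random_graph_factory):
        net = random_graph_factory(50, seed=2)
        tm = normalize_adjacency(net)
        p0 = build_initial_state(tm, seeds=["g0000"])
        prev = np.inf
        for alpha in (0.1, 0.01, 0.001, 1e-5):
            dist = np.abs(rwr_closed_form(tm, p0, alpha).ps - p0.vector).sum()
            assert dist < prev
            prev = dist
        assert prev < 1e-4

    def test_near_neighbours_gain_more_than_distant_on_path(self, path5):
        # restart-mass dominance for small alpha: 1 hop beats 3 hops
        tm = normalize_adjacency(path5)
        p0 = build_initial_state(tm, seeds=["n0"])
        res = rwr_closed_form(tm, p0, 0.2)
        scores = res.scores()
        assert scores["n1"] > scores["n3"]


class TestRanking:
    def test_sorted_descending(self):
        from gwasprop.propagation import PropagationResult

        res = PropagationResult(
            ps=np.array([0.5, 0.3, 0.2]), nodes=("A", "B", "C"),
            alpha=0.1, mode=InitMode.SEED_BINARY,
        )
        assert rank_genes(res) == ["A", "B", "C"]
        assert rank_genes(res, exclude={"A"}) == ["B", "C"]

    def test_ties_break_lexicographically(self):
        from gwasprop.propagation import PropagationResult

        res = PropagationResult(
            ps=np.array([0.4, 0.4, 0.2]), nodes=("B", "A", "C"),
            alpha=0.1, mode=InitMode.SEED_BINARY,
        )
        assert rank_genes(res) == ["A", "B", "C"]

    @given(st.integers(0, 2**31 - 1))
    def test_ranking_is_permutation_of_nodes(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 30))
        from gwasprop.propagation import PropagationResult

        nodes = tuple(f"x{i}" for i in range(n))
        res = PropagationResult(
            ps=gen.random(n), nodes=nodes, alpha=0.0, mode=InitMode.PVALUE_SCORE
        )
        assert sorted(rank_genes(res)) == sorted(nodes)


class TestEstimatorInterface:
    def test_fit_propagate_rank_roundtrip(self, path2):
        rwr = RandomWalkRestart(alpha=0.5).fit(path2)
        res = rwr.propagate(seeds=["a"])
        assert np.allclose(res.ps, [2 / 3, 1 / 3])
        assert rwr.rank(seeds=["a"]) == ["a", "b"]

    def test_get_set_params_and_clone(self, path2):
        from sklearn.base import clone

        rwr = RandomWalkRestart(alpha=0.42, solver="power_iteration")
        assert clone(rwr).get_params()["alpha"] == 0.42
        rwr.set_params(alpha=0.1).fit(path2)
        assert rwr.propagate(seeds=["a"]).alpha == 0.1

    def test_transform_propagates_rows(self, random_graph_factory):
        net = random_graph_factory(20, seed=9)
        rwr = RandomWalkRestart(alpha=0.3).fit(net)
        X = np.eye(20)[:3]
        out = rwr.transform(X)
        assert out.shape == (3, 20)
        assert np.allclose(out.sum(axis=1), 1.0)
        expected = dense_rwr_oracle(net, X[0], 0.3)
        assert np.allclose(out[0], expected, atol=1e-10)

    def test_unfitted_estimator_raises(self):
        with pytest.raises(ValidationError, match="not fitted"):
            RandomWalkRestart().propagate(seeds=["a"])

    def test_solver_choices_agree(self, random_graph_factory):
        net = random_graph_factory(50, seed=4)
        seeds = ["g0000"]
        direct = RandomWalkRestart(alpha=0.4, solver="closed_form").fit(net)
        power = RandomWalkRestart(alpha=0.4, solver="power_iteration", tol=1e-12).fit(net)
        assert np.allclose(
            direct.propagate(seeds=seeds).ps, power.propagate(seeds=seeds).ps, atol=1e-10
        )
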