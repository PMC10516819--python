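"""Multi-order model construction, likelihood, complexity and order selection."""
import math

import pytest
from hypothesis import given, settings

from multiorder import (
    END_STATE,
    START_STATE,
    ObservedTopology,
    Path,
    PathCollection,
    ToySpec,
    adjacency_power_sums,
    aic_score,
    build_counts,
    collection_log_likelihood,
    degrees_of_freedom,
    encode_state_sequence,
    fit_model,
    model_from_json,
    model_to_json,
    node_state,
    observed_adjacency,
    path_log_probability,
    possible_transitions,
    select_optimal_order,
    to_transition_model,
    toy_collection,
)
from conftest import collections
from oracles import brute_degrees_of_freedom, brute_log_likelihood, brute_selection


class TestEncodeStateSequence:
    @pytest.mark.parametrize(
        "nodes, K, expected",
        [
            (
                ("A", "C", "D", "E"),
                2,
                [START_STATE, node_state("A"), node_state("A", "C"),
                 node_state("C", "D"), node_state("D", "E"), END_STATE],
            ),
            (
                ("A", "C"),
                3,
                [START_STATE, node_state("A"), node_state("A", "C"), END_STATE],
            ),
            (("A",), 1, [START_STATE, node_state("A"), END_STATE]),
            (("A",), 5, [START_STATE, node_state("A"), END_STATE]),
        ],
    )
    def test_schema(self, nodes, K, expected):
        assert encode_state_sequence(nodes, K) == expected

    @settings(max_examples=50, deadline=None)
    @given(collections())
    def test_length_is_l_plus_two(self, col):
        for p in col.paths:
            for K in (1, 2, 4):
                assert len(encode_state_sequence(p, K)) == p.length + 2


class TestCounts:
    def test_toy_start_counts(self, toy):
        counts = build_counts(toy, 3)
        assert counts.rows[START_STATE][node_state("A")] == 30
        assert counts.rows[START_STATE][node_state("B")] == 20

    def test_toy_short_path_termination(self, toy):
        counts = build_counts(toy, 3)
        assert counts.rows[node_state("A", "C")][END_STATE] == 10

    def test_empty_collection_gives_empty_counts(self):
        assert build_counts(PathCollection(), 2).rows == {}

    def test_invalid_order(self, toy):
        with pytest.raises(ValueError):
            build_counts(toy, 0)

    @settings(max_examples=50, deadline=None)
    @given(collections())
    def test_count_conservation(self, col):
        # total transitions = sum over paths of count * (length + 1)
        counts = build_counts(col, 3)
        assert counts.total_transitions == sum(p.count * (p.length + 1) for p in col.paths)


class TestTransitionModel:
    def test_toy_k2_row(self, toy):
        model = fit_model(toy, 2)
        row = model.probs[node_state("A", "C")]
        assert row[node_state("C", "D")] == pytest.approx(2 / 3)
        assert row[END_STATE] == pytest.approx(1 / 3)

    def test_order3_layer_rows_identical_under_independence(self, toy):
        # equal frequencies: termination independent of start node, so the
        # deepest-layer rows for (A,C,D) and (B,C,D) coincide
        model = fit_model(toy, 3)
        row_a = {k.labels[-1]: v for k, v in model.probs[node_state("A", "C", "D")].items()}
        row_b = {k.labels[-1]: v for k, v in model.probs[node_state("B", "C", "D")].items()}
        assert row_a == row_b == {"E": 0.5, "F": 0.5}

    def test_single_path_rows_are_deterministic(self):
        col = PathCollection([Path(("A", "B", "C"))])
        model = fit_model(col, 2)
        for row in model.probs.values():
            assert list(row.values()) == [1.0]

    def test_structural_mask_holds_possible_unobserved(self, toy, toy_top):
        model = to_transition_model(build_counts(toy, 2), toy_top)
        # (C,D) -> terminal is possible (every tuple may terminate) but unobserved
        assert (node_state("C", "D"), END_STATE) in model.structural_mask
        # observed pairs never appear in the mask
        for src, row in model.probs.items():
            for dst in row:
                assert (src, dst) not in model.structural_mask

    @settings(max_examples=50, deadline=None)
    @given(collections())
    def test_rows_stochastic_and_structural_zeros_absent(self, col):
        for K in (1, 2, 3):
            model = to_transition_model(build_counts(col, K), observed_adjacency(col))
            for src, row in model.probs.items():
                assert abs(sum(row.values()) - 1.0) < 1e-12
                assert all(p > 0 for p in row.values())


class TestLikelihood:
    def test_toy_short_path_probability(self, toy):
        model = fit_model(toy, 2)
        assert path_log_probability(model, ("A", "C")) == pytest.approx(math.log(0.2))

    def test_self_trained_single_path_is_certain(self):
        col = PathCollection([Path(("A", "B", "C"))])
        model = fit_model(col, 2)
        assert path_log_probability(model, ("A", "B", "C")) == 0.0
        assert collection_log_likelihood(model, col) == 0.0

    def test_saturated_model_reproduces_empirical_frequencies(self, toy):
        model = fit_model(toy, 3)
        for p in toy.paths:
            assert path_log_probability(model, p) == pytest.approx(math.log(p.count / 50))

    def test_unseen_node_gives_neg_inf_not_exception(self, toy):
        model = fit_model(toy, 2)
        assert path_log_probability(model, ("Z", "C")) == -math.inf

    def test_toy_collection_likelihoods(self, toy):
        assert collection_log_likelihood(fit_model(toy, 2), toy) == pytest.approx(
            50 * math.log(1 / 5)
        )
        expected_k1 = 10 * (math.log(0.12) + 2 * math.log(0.24) + 2 * math.log(0.16))
        assert collection_log_likelihood(fit_model(toy, 1), toy) == pytest.approx(expected_k1)

    @settings(max_examples=30, deadline=None)
    @given(collections(max_paths=6))
    def test_matches_exact_rational_oracle(self, col):
        for K in (1, 2, 3):
            model = fit_model(col, K)
            assert collection_log_likelihood(model, col) == pytest.approx(
                brute_log_likelihood(col, K), abs=1e-9
            )

    @settings(max_examples=30, deadline=None)
    @given(collections(max_paths=6))
    def test_monotone_in_order_and_lossless_at_l_max(self, col):
        l_max = col.max_length
        lls = [
            collection_log_likelihood(fit_model(col, K), col)
            for K in range(1, l_max + 2)
        ]
        for a, b in zip(lls[:-1], lls[1:]):
            assert b >= a - 1e-9
        # lossless regime: empirical path frequencies reproduced exactly
        model = fit_model(col, l_max)
        m = col.total_paths
        for p in col.paths:
            assert path_log_probability(model, p) == pytest.approx(math.log(p.count / m))


class TestComplexity:
    def test_toy_dof(self, toy_top):
        assert degrees_of_freedom(toy_top, 1) == 10
        assert degrees_of_freedom(toy_top, 2) == 14

    def test_toy_possible_transitions(self, toy_top):
        assert possible_transitions(toy_top, 1) == 17
        assert possible_transitions(toy_top, 2) == 26

    def test_edgeless_topology(self):
        import numpy as np

        top = ObservedTopology(("x", "y", "z"), np.zeros((3, 3), dtype=int))
        assert degrees_of_freedom(top, 4) == 2
        assert possible_transitions(top, 1) == 6

    def test_power_sums_exact_on_dense_graph(self):
        import numpy as np

        n = 12
        top = ObservedTopology(
            tuple(f"n{i}" for i in range(n)), np.ones((n, n), dtype=int)
        )
        sums = adjacency_power_sums(top, 40)
        assert sums[-1] == n ** 41  # would overflow int64 by a wide margin

    @settings(max_examples=30, deadline=None)
    @given(collections(max_paths=6))
    def test_dof_matches_walk_enumeration_oracle(self, col):
        top = observed_adjacency(col)
        edges = {pair for pair, _ in col.transitions()}
        nodes = sorted(col.node_set)
        for K in (1, 2, 3):
            assert degrees_of_freedom(top, K) == brute_degrees_of_freedom(edges, nodes, K)


class TestSelection:
    def test_toy_aic_values(self, toy, toy_top):
        assert aic_score(fit_model(toy, 2), toy, toy_top) == pytest.approx(188.94, abs=0.01)
        assert aic_score(fit_model(toy, 1), toy, toy_top) == pytest.approx(192.79, abs=0.01)

    def test_single_path_aic_is_twice_dof(self):
        col = PathCollection([Path(("A", "B"))])
        top = observed_adjacency(col)
        assert aic_score(fit_model(col, 1), col, top) == 2 * degrees_of_freedom(top, 1)

    def test_equal_frequencies_select_order_two(self, toy):
        assert select_optimal_order(toy).selected == 2

    def test_start_terminal_dependency_selects_order_three(self, order3_instance):
        table = select_optimal_order(order3_instance)
        assert table.selected == 3
        assert table.objective[:3] == pytest.approx([183.6, 181.1, 115.8], abs=0.05)

    def test_repeated_short_path_selects_order_one(self):
        col = PathCollection([Path(("A", "B"), 20)])
        assert select_optimal_order(col, K_max=3).selected == 1

    def test_penalty_strictly_increases_and_likelihood_non_decreasing(self, toy):
        t = select_optimal_order(toy, K_max=3)
        assert t.penalty == sorted(t.penalty) and len(set(t.penalty)) == len(t.penalty)
        assert t.log_likelihood == sorted(t.log_likelihood)

    def test_invalid_arguments(self, toy):
        with pytest.raises(ValueError):
            select_optimal_order(toy, K_max=0)
        with pytest.raises(ValueError):
            select_optimal_order(PathCollection())

    @settings(max_examples=20, deadline=None)
    @given(collections(min_paths=2, max_paths=6))
    def test_matches_brute_force_selection(self, col):
        K_max = min(col.max_length, 4)
        assert select_optimal_order(col, K_max=K_max).selected == brute_selection(col, K_max)


class TestSerialisation:
    def test_json_round_trip_preserves_model(self, toy, tmp_path):
        model = fit_model(toy, 2)
        path = tmp_path / "model.json"
        model_to_json(model, path)
        again = model_from_json(path)
        assert again.max_order == 2
        assert again.nodes == model.nodes
        assert again.probs == model.probs
        assert again.row_totals == model.row_totals

    def test_matrix_market_export(self, toy, tmp_path):
        from scipy.io import mmread

        from multiorder import export_matrix_market

        model = fit_model(toy, 2)
        target = tmp_path / "T.mtx"
        export_matrix_market(model, target)
        mat = mmread(target).tocsr()
        n_states = len(model.state_index)
        assert mat.shape == (n_states, n_states)
        # every non-empty row of the exported matrix sums to 1
        sums = mat.sum(axis=1).A1
        assert all(abs(s - 1) < 1e-12 for s in sums if s > 0)
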