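"""Red-black graph machinery: realization, red-sigma, c-reductions."""

import numpy as np
import pytest

from cppp import (
    BinaryMatrix,
    ConstraintSet,
    admits_directed_pp,
    build_conflict_graph,
    build_red_black,
    detect_red_sigma,
    gain,
    loss,
    realize,
)
from cppp.graphs import (
    ACTIVE,
    FREE,
    INACTIVE,
    apply_c_reduction,
    reconcile,
    validate_c_reduction,
)
from cppp.matrix import build_extended_matrix

from conftest import random_instance


class TestConflictGraph:
    def test_all_four_configurations_give_edge(self):
        M = BinaryMatrix(np.array([[0, 1], [1, 1], [1, 0], [0, 0]]))
        assert list(build_conflict_graph(M).edges()) == [("c1", "c2")]

    @pytest.mark.parametrize("data", [
        [[1, 1], [0, 0], [1, 1]],          # identical columns
        [[1, 1], [1, 0], [0, 0]],          # nested columns
        [[1, 0], [1, 1], [0, 1]],          # sigma: (0,0) absent
    ])
    def test_non_conflicting_pairs(self, data):
        assert build_conflict_graph(BinaryMatrix(data)).number_of_edges() == 0

    def test_vertex_set_is_all_characters(self, sigma):
        assert set(build_conflict_graph(sigma).nodes) == {"c1", "c2"}


class TestBuildRedBlack:
    def test_sigma_has_four_black_edges_one_component(self, sigma):
        G = build_red_black(build_extended_matrix(sigma))
        edges = sorted(G.edges())
        assert edges == [
            ("s1", "c1", "black"), ("s2", "c1", "black"),
            ("s2", "c2", "black"), ("s3", "c2", "black"),
        ]
        assert set(G.component_species("c1")) == {"s1", "s2", "s3"}

    def test_fully_constrained_zero_matrix_is_edgeless(self):
        M = BinaryMatrix([[0, 0], [0, 0]])
        F = ConstraintSet(
            (c, s) for c in ("c1", "c2") for s in ("s1", "s2")
        )
        G = build_red_black(build_extended_matrix(M, F))
        assert G.is_edgeless()

    def test_single_one_entry_single_black_edge(self):
        M = BinaryMatrix([[0, 0], [0, 1]])
        G = build_red_black(build_extended_matrix(M))
        assert sorted(G.edges()) == [("s2", "c2", "black")]

    def test_isolated_vertices_pruned(self):
        M = BinaryMatrix([[1, 0], [0, 0]])
        G = build_red_black(build_extended_matrix(M))
        assert not G.has_species("s2") and not G.has_character("c2")


class TestRealize:
    def test_gain_adds_red_edge_and_completes_pairs(self, sigma):
        Me = build_extended_matrix(sigma)
        G = build_red_black(Me)
        out = realize(G, Me, gain("c1"))
        assert out.ok
        assert out.matrix.pair("s3", "c1") == (1, 1)
        assert out.graph.edge_color("s3", "c1") == "red"
        assert out.graph.status["c1"] == ACTIVE
        # s1 is explained entirely by c1 and gets pruned as isolated
        assert not out.graph.has_species("s1")
        assert reconcile(out.graph, out.matrix) == []

    def test_constrained_species_blocks_gain(self, sigma):
        F = ConstraintSet([("c1", "s3")])
        Me = build_extended_matrix(sigma, F)
        G = build_red_black(Me)
        out = realize(G, Me, gain("c1"), F)
        assert not out.ok and out.reason == "constraint-violation"
        # atomicity: inputs untouched
        assert Me.pair("s3", "c1") == (0, 0) and G.status["c1"] == INACTIVE

    def test_loss_requires_active_status(self, sigma):
        Me = build_extended_matrix(sigma)
        G = build_red_black(Me)
        assert realize(G, Me, loss("c1")).reason == "sign-mismatch"

    def test_loss_requires_red_cover_of_component(self, sigma):
        Me = build_extended_matrix(sigma)
        G = build_red_black(Me)
        st = realize(G, Me, gain("c1"))
        # c1 is red-adjacent to s3 only; s2 is still in its component
        out = realize(st.graph, st.matrix, loss("c1"))
        assert not out.ok and out.reason == "active-not-covering"

    def test_free_character_cannot_be_realized_again(self, sigma):
        Me = build_extended_matrix(sigma)
        G = build_red_black(Me)
        for x in (gain("c1"), gain("c2"), loss("c1")):
            st = realize(G, Me, x)
            assert st.ok
            G, Me = st.graph, st.matrix
        assert G.status["c1"] == FREE
        assert realize(G, Me, gain("c1")).reason == "free-character"
        assert realize(G, Me, loss("c1")).reason == "free-character"

    def test_gain_twice_impossible(self, sigma):
        Me = build_extended_matrix(sigma)
        G = build_red_black(Me)
        st = realize(G, Me, gain("c1"))
        assert not realize(st.graph, st.matrix, gain("c1")).ok

    def test_unknown_character_is_lookup_error(self, sigma):
        Me = build_extended_matrix(sigma)
        G = build_red_black(Me)
        with pytest.raises(KeyError):
            realize(G, Me, gain("zz"))

    def test_reconciliation_invariant_on_random_walks(self):
        """After every successful realization the edge/matrix invariants hold."""
        for trial in range(40):
            M, F = random_instance(trial)
            Me = build_extended_matrix(M, F)
            G = build_red_black(Me)
            rng = np.random.default_rng(trial)
            for _ in range(2 * M.m):
                moves = [gain(c) for c in G.inactive_characters()] + [
                    loss(c) for c in G.active_characters()
                ]
                if not moves:
                    break
                x = moves[int(rng.integers(len(moves)))]
                out = realize(G, Me, x, F)
                if out.ok:
                    G, Me = out.graph, out.matrix
                    assert reconcile(G, Me) == []


class TestRedSigma:
    @staticmethod
    def _graph_with_reds(red_edges, black_edges=()):
        import networkx as nx
        from cppp.graphs import RedBlackGraph

        G = nx.Graph()
        status = {}
        for c, s in red_edges:
            G.add_edge(("S", s), ("C", c), color="red")
            status[c] = ACTIVE
        for c, s in black_edges:
            G.add_edge(("S", s), ("C", c), color="black")
            status.setdefault(c, INACTIVE)
        return RedBlackGraph(G, status)

    def test_crossing_red_sets_detected(self):
        G = self._graph_with_reds([("a", "s1"), ("a", "s2"), ("b", "s2"), ("b", "s3")])
        assert detect_red_sigma(G) == ("s1", "a", "s2", "b", "s3")

    def test_short_red_path_is_not_sigma(self):
        G = self._graph_with_reds([("a", "s1"), ("a", "s2"), ("b", "s2")])
        assert detect_red_sigma(G) is None

    def test_black_edges_are_ignored(self):
        G = self._graph_with_reds(
            [], black_edges=[("a", "s1"), ("a", "s2"), ("b", "s2"), ("b", "s3")]
        )
        assert detect_red_sigma(G) is None

    def test_nested_red_sets_are_not_sigma(self):
        # b's red set inside a's: no crossing, hence no certificate
        G = self._graph_with_reds(
            [("a", "s1"), ("a", "s2"), ("a", "s3"), ("b", "s2"), ("b", "s3")]
        )
        assert detect_red_sigma(G) is None


class TestCReduction:
    def test_sigma_reduction_succeeds_and_completes(self, sigma):
        Me = build_extended_matrix(sigma)
        res = apply_c_reduction(Me, ConstraintSet(), [gain("c1"), gain("c2"), loss("c1")])
        assert res.success and res.edgeless
        assert res.matrix.is_complete()
        assert res.matrix.pair("s3", "c1") == (1, 1)  # c1 persistent for s3
        assert admits_directed_pp(res.matrix)

    def test_empty_sequence_on_nonempty_graph_not_successful(self, sigma):
        res = apply_c_reduction(build_extended_matrix(sigma), ConstraintSet(), [])
        assert not res.success and not res.edgeless

    def test_loss_before_gain_rejected(self, sigma):
        with pytest.raises(ValueError, match="before"):
            apply_c_reduction(
                build_extended_matrix(sigma), ConstraintSet(), [loss("c1")]
            )

    def test_repeated_label_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            validate_c_reduction([gain("c1"), gain("c1")])

    def test_failure_reports_step_index(self, sigma):
        # c1- right after c1+ is impossible: s2 of c1's component is not red
        Me = build_extended_matrix(sigma)
        res = apply_c_reduction(Me, ConstraintSet(), [gain("c1"), loss("c1")])
        assert not res.success
        assert res.failed_at == 1 and res.reason == "active-not-covering"

    def test_constrained_gain_fails_at_first_step(self, sigma):
        F = ConstraintSet([("c1", "s3")])
        Me = build_extended_matrix(sigma, F)
        res = apply_c_reduction(Me, F, [gain("c1"), gain("c2")])
        assert not res.success
        assert res.failed_at == 0 and res.reason == "constraint-violation"
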