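"""Tree construction, verification and Newick round trips."""

import numpy as np
import pytest

from cppp import (
    BinaryMatrix,
    ConstraintSet,
    build_tree,
    from_newick,
    gain,
    loss,
    solve_cppp,
    to_newick,
    verify,
)
from cppp.matrix import build_extended_matrix
from cppp.phylogeny import TreeConstructionError, edge_table

from conftest import random_instance


def _sigma_completion(sigma):
    Me = build_extended_matrix(sigma)
    Me.complete("s3", "c1", persistent=True)
    Me.complete("s1", "c2", persistent=False)
    return Me


class TestBuildTree:
    def test_sigma_chain_with_persistent_character(self, sigma):
        T = build_tree(_sigma_completion(sigma), sigma)
        assert verify(T, sigma) == []
        # chain root -c1+- {s1} -c2+- {s2} -c1-- {s3}
        chain = [T.species_node[s] for s in ("s1", "s2", "s3")]
        assert chain[0].parent is T.root
        assert chain[1].parent is chain[0]
        assert chain[2].parent is chain[1]
        assert chain[0].edge_labels == [gain("c1")]
        assert chain[1].edge_labels == [gain("c2")]
        assert chain[2].edge_labels == [loss("c1")]
        assert list(chain[2].label) == [0, 1]

    def test_identity_matrix_star(self):
        M = BinaryMatrix([[1, 0], [0, 1]])
        Me = build_extended_matrix(M)
        for s, c in Me.incomplete_pairs():
            Me.complete(s, c, persistent=False)
        T = build_tree(Me, M)
        assert len(T.root.children) == 2
        labels = sorted(str(x) for ch in T.root.children for x in ch.edge_labels)
        assert labels == ["c1+", "c2+"]

    def test_all_zero_matrix_single_root(self):
        M = BinaryMatrix([[0]])
        Me = build_extended_matrix(M)
        Me.complete("s1", "c1", persistent=False)
        T = build_tree(Me, M)
        assert len(T.nodes) == 1
        assert T.species_node["s1"] is T.root

    def test_rejects_non_laminar_completion(self):
        M = BinaryMatrix([[1, 1], [1, 0], [0, 1]])
        Me = build_extended_matrix(M)
        for s, c in Me.incomplete_pairs():
            Me.complete(s, c, persistent=False)
        with pytest.raises(TreeConstructionError):
            build_tree(Me, M)

    def test_duplicate_rows_share_one_node(self):
        M = BinaryMatrix([[1, 0], [1, 0], [0, 0]])
        Me = build_extended_matrix(M)
        for s, c in Me.incomplete_pairs():
            Me.complete(s, c, persistent=False)
        T = build_tree(Me, M)
        assert T.species_node["s1"] is T.species_node["s2"]
        assert T.species_node["s3"] is T.root

    def test_edge_table_lists_all_edges(self, sigma):
        T = build_tree(_sigma_completion(sigma), sigma)
        rows = edge_table(T)
        assert len(rows) == len(T.nodes) - 1
        assert {r["gains"] for r in rows} == {"c1", "c2", ""}


class TestVerify:
    def test_two_gain_edges_flagged(self):
        # hand-built tree gaining c1 independently on two sibling edges
        M = BinaryMatrix([[1], [1]])
        from cppp.phylogeny import PersistentPhylogeny, PNode

        root = PNode(0, np.array([0], dtype=np.int8))
        for i, s in enumerate(("s1", "s2")):
            child = PNode(i + 1, np.array([1], dtype=np.int8), parent=root,
                          edge_labels=[gain("c1")], species=[s])
            root.children.append(child)
        T = PersistentPhylogeny(root, M.character_names)
        messages = " ".join(verify(T, M))
        assert "gained on 2 edges" in messages

    def test_constrained_species_below_gain_flagged(self, sigma):
        T = build_tree(_sigma_completion(sigma), sigma)
        F = ConstraintSet([("c1", "s3")])
        messages = " ".join(verify(T, sigma, F))
        assert "constraint (c1, s3) violated" in messages

    def test_loss_without_gain_flagged(self):
        M = BinaryMatrix([[0]])
        from cppp.phylogeny import PersistentPhylogeny, PNode

        root = PNode(0, np.array([1], dtype=np.int8))  # bad root too
        child = PNode(1, np.array([0], dtype=np.int8), parent=root,
                      edge_labels=[loss("c1")], species=["s1"])
        root.children.append(child)
        T = PersistentPhylogeny(root, M.character_names)
        messages = " ".join(verify(T, M))
        assert "lost but never gained" in messages
        assert "root label" in messages

    def test_missing_species_flagged(self, sigma):
        Me = _sigma_completion(sigma)
        T = build_tree(Me, sigma)
        T.species_node.pop("s2")
        assert any("s2" in v for v in verify(T, sigma))


class TestNewick:
    def test_round_trip_preserves_verification(self, sigma):
        res = solve_cppp(sigma)
        text = to_newick(res.tree)
        T2 = from_newick(text, sigma)
        assert verify(T2, sigma) == []
        assert to_newick(T2) == text

    def test_round_trip_on_random_solved_instances(self):
        for trial in range(25):
            M, F = random_instance(trial + 100)
            res = solve_cppp(M, F)
            if res.status != "solution":
                continue
            T2 = from_newick(to_newick(res.tree), M)
            assert verify(T2, M, F) == []

    def test_unknown_character_rejected(self, sigma):
        with pytest.raises(TreeConstructionError, match="unknown character"):
            from_newick("(s1[&gains=zz]);", sigma)


class TestEndToEndInvariants:
    def test_persistence_matches_completion_and_path(self):
        """(1,1) completion == gain-then-loss on the species' root path."""
        for trial in range(40):
            M, F = random_instance(trial + 900)
            res = solve_cppp(M, F)
            if res.status != "solution":
                continue
            T = res.tree
            for s in M.species_names:
                node = T.species_node[s]
                path_labels = [
                    x for anc in node.path_from_root() for x in anc.edge_labels
                ]
                for c in M.character_names:
                    persistent = res.completed.pair(s, c) == (1, 1)
                    crossed = gain(c) in path_labels and loss(c) in path_labels
                    assert persistent == crossed, (trial, s, c)
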