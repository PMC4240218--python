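"""Build and verify persistent phylogenies.

A persistent phylogeny for an n × m binary matrix M is a rooted tree whose
nodes carry length-m 0/1 state vectors, with an all-zero root, every edge
labeled by the signed characters changing across it, at most one gain and one
loss edge per character (the loss strictly below the gain on the same
root-to-leaf path), and every row of M equal to the vector of exactly one
node.  Construction goes through the completed extended matrix: the
2m-column completion admits a directed (all-zero-root) perfect phylogeny,
which is built by the classical sort-columns-and-walk construction; gain
columns become gain edges, loss columns loss edges, and the 2m-state vectors
collapse to m states (present = gained and not yet lost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .matrix import (
    BinaryMatrix,
    ConstraintSet,
    CpppError,
    ExtendedMatrix,
    SignedCharacter,
    admits_directed_pp,
    gain,
    loss,
)

__all__ = [
    "PNode",
    "PersistentPhylogeny",
    "TreeConstructionError",
    "build_tree",
    "verify",
    "to_newick",
    "from_newick",
    "edge_table",
]


class TreeConstructionError(CpppError):
    pass


@dataclass
class PNode:
    id: int
    label: np.ndarray  # length-m 0/1 vector over the matrix's characters
    parent: Optional["PNode"] = None
    edge_labels: List[SignedCharacter] = field(default_factory=list)  # on edge parent->self
    children: List["PNode"] = field(default_factory=list)
    species: List[str] = field(default_factory=list)

    def is_root(self) -> bool:
        return self.parent is None

    def path_from_root(self) -> List["PNode"]:
        path, node = [], self
        while node is not None:
            path.append(node)
            node = node.parent
        return list(reversed(path))


class PersistentPhylogeny:
    """Rooted tree with node state vectors, signed edge labels and species."""

    def __init__(self, root: PNode, character_names: Sequence[str]):
        self.root = root
        self.character_names = tuple(character_names)
        self.nodes: List[PNode] = []
        self.species_node: Dict[str, PNode] = {}
        stack = [root]
        while stack:
            node = stack.pop()
            self.nodes.append(node)
            for s in node.species:
                if s in self.species_node:
                    raise TreeConstructionError(f"species {s} labels two nodes")
                self.species_node[s] = node
            stack.extend(reversed(node.children))

    @property
    def m(self) -> int:
        return len(self.character_names)

    def edges(self) -> List[Tuple[PNode, PNode]]:
        return [(n.parent, n) for n in self.nodes if n.parent is not None]

    def __repr__(self) -> str:
        return (
            f"PersistentPhylogeny({len(self.nodes)} nodes, "
            f"{len(self.species_node)} species)"
        )


def build_tree(completed: ExtendedMatrix, M: BinaryMatrix) -> PersistentPhylogeny:
    """Persistent phylogeny from a completed extended matrix.

    Preconditions: no '?' cells and the 2m-column matrix admits a directed
    perfect phylogeny.  The tree is canonical: columns are grouped by their
    species 1-sets, ordered by decreasing size (gains before losses, then
    name, within a group).
    """
    if not admits_directed_pp(completed):
        raise TreeConstructionError(
            "completed matrix does not admit a directed perfect phylogeny"
        )
    n, m = completed.n, completed.m
    char_names = completed.character_names
    # group signed columns by their species support
    groups: Dict[frozenset, List[SignedCharacter]] = {}
    for c_idx, c in enumerate(char_names):
        for part, sc in ((0, gain(c)), (1, loss(c))):
            support = frozenset(np.nonzero(completed.cells[:, c_idx, part] == 1)[0])
            if support:
                groups.setdefault(support, []).append(sc)
    for labels in groups.values():
        labels.sort(key=lambda x: (x.sign != "+", x.name))
    group_order = sorted(
        groups, key=lambda g: (-len(g), tuple(sorted(groups[g]))), reverse=False
    )
    group_rank = {g: i for i, g in enumerate(group_order)}

    root = PNode(0, np.zeros(m, dtype=np.int8))
    trie: Dict[tuple, PNode] = {(): root}
    next_id = 1
    for s_idx, s_name in enumerate(completed.species_names):
        chain = sorted(
            (g for g in groups if s_idx in g), key=lambda g: group_rank[g]
        )
        # supports containing one species are totally ordered by containment
        for a, b in zip(chain, chain[1:]):
            if not b < a:
                raise TreeConstructionError(
                    f"columns through species {s_name} are not nested"
                )
        path = ()
        for g in chain:
            path = path + (group_rank[g],)
            if path not in trie:
                parent = trie[path[:-1]]
                node = PNode(next_id, _collapse(path, group_order, groups, m, char_names),
                             parent=parent, edge_labels=list(groups[g]))
                next_id += 1
                parent.children.append(node)
                trie[path] = node
        trie[path].species.append(s_name)

    _contract_cancelled(root)
    tree = PersistentPhylogeny(root, char_names)
    # postcondition: every species row of M matches its node's vector
    for s_idx, s_name in enumerate(M.species_names):
        node = tree.species_node.get(s_name)
        if node is None or not np.array_equal(node.label, M.data[s_idx, :]):
            raise TreeConstructionError(
                f"species {s_name} does not match any node vector"
            )
    return tree


def _collapse(path, group_order, groups, m, char_names) -> np.ndarray:
    """m-state vector of the node reached through the given group path."""
    idx = {c: j for j, c in enumerate(char_names)}
    label = np.zeros(m, dtype=np.int8)
    for rank in path:
        for sc in groups[group_order[rank]]:
            label[idx[sc.name]] = 1 if sc.sign == "+" else 0
    return label


def _contract_cancelled(root: PNode) -> None:
    """Drop gain/loss pairs sharing one edge (no net state change) and merge
    away edges left without labels."""
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            names = {}
            for sc in child.edge_labels:
                names.setdefault(sc.name, set()).add(sc.sign)
            cancelled = {c for c, signs in names.items() if signs == {"+", "-"}}
            if cancelled:
                child.edge_labels = [
                    sc for sc in child.edge_labels if sc.name not in cancelled
                ]
            if not child.edge_labels:
                # merge child into node
                node.children.remove(child)
                node.children.extend(child.children)
                for gc in child.children:
                    gc.parent = node
                node.species.extend(child.species)
                stack.append(node)
                break
            stack.append(child)


def verify(
    T: PersistentPhylogeny, M: BinaryMatrix, F: ConstraintSet = ConstraintSet()
) -> List[str]:
    """Check a tree against the model definition and the constraints.

    Returns a list of violation messages (empty list = pass).  Checks: the
    all-zero root; every edge labeled and its labels matching the actual
    state changes; at most one gain and one loss per character with the loss
    below the gain on one path; every species row equal to the vector of its
    (unique) node; and, for each constraint (c, s), no gain of c on the path
    from the root to the node of s.
    """
    out: List[str] = []
    m = len(T.character_names)
    cidx = {c: j for j, c in enumerate(T.character_names)}
    if T.root.label.shape != (m,) or T.root.label.any():
        out.append("root label is not the all-zero vector")
    gains_of: Dict[str, List[PNode]] = {}
    losses_of: Dict[str, List[PNode]] = {}
    for parent, child in T.edges():
        diff_gains = {
            T.character_names[j]
            for j in range(m)
            if parent.label[j] == 0 and child.label[j] == 1
        }
        diff_losses = {
            T.character_names[j]
            for j in range(m)
            if parent.label[j] == 1 and child.label[j] == 0
        }
        declared = set(child.edge_labels)
        expected = {gain(c) for c in diff_gains} | {loss(c) for c in diff_losses}
        if not declared:
            out.append(f"edge to node {child.id} has no character label")
        if declared != expected:
            out.append(
                f"edge to node {child.id}: labels {sorted(map(str, declared))} "
                f"do not match state changes {sorted(map(str, expected))}"
            )
        for c in diff_gains:
            gains_of.setdefault(c, []).append(child)
        for c in diff_losses:
            losses_of.setdefault(c, []).append(child)
    for c in T.character_names:
        gs, ls = gains_of.get(c, []), losses_of.get(c, [])
        if len(gs) > 1:
            out.append(f"character {c} is gained on {len(gs)} edges")
        if len(ls) > 1:
            out.append(f"character {c} is lost on {len(ls)} edges")
        if len(gs) == 1 and len(ls) == 1:
            # the loss edge must lie strictly below the gain edge's child
            anc = ls[0].parent
            ok = False
            while anc is not None:
                if anc is gs[0]:
                    ok = True
                    break
                anc = anc.parent
            if not ok:
                out.append(
                    f"loss of {c} (node {ls[0].id}) is not below its gain "
                    f"(node {gs[0].id})"
                )
        if ls and not gs:
            out.append(f"character {c} is lost but never gained")
    seen = set()
    for s_idx, s in enumerate(M.species_names):
        node = T.species_node.get(s)
        if node is None:
            out.append(f"species {s} labels no node")
            continue
        seen.add(s)
        if not np.array_equal(node.label, M.data[s_idx, :]):
            out.append(f"species {s}: node vector differs from its matrix row")
    for c, s in F:
        node = T.species_node.get(s)
        if node is None:
            continue
        for anc in node.path_from_root():
            if gain(c) in anc.edge_labels:
                out.append(
                    f"constraint ({c}, {s}) violated: {c}+ labels an edge on "
                    f"the path to {s}"
                )
                break
    return out


# ---------------------------------------------------------------------------
# Newick serialization: edge labels ride as node comments, species as names.
# Example: (s1[&gains=c2],s2|s4[&gains=c1,losses=c3])root;


def _newick_node(node: PNode) -> str:
    parts = ""
    if node.children:
        parts = "(" + ",".join(_newick_node(ch) for ch in
                               sorted(node.children, key=lambda x: x.id)) + ")"
    name = "|".join(node.species)
    comment = ""
    gains_ = [sc.name for sc in node.edge_labels if sc.sign == "+"]
    losses_ = [sc.name for sc in node.edge_labels if sc.sign == "-"]
    fields = []
    if gains_:
        fields.append("gains=" + "|".join(gains_))
    if losses_:
        fields.append("losses=" + "|".join(losses_))
    if fields:
        comment = "[&" + ",".join(fields) + "]"
    return f"{parts}{name}{comment}"


def to_newick(T: PersistentPhylogeny) -> str:
    return _newick_node(T.root) + ";"


def from_newick(text: str, M: BinaryMatrix) -> PersistentPhylogeny:
    """Rebuild an annotated tree; node vectors are recomputed from the root
    (all zeroes) by applying the gain/loss annotations along each path."""
    import dendropy

    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,
    )
    cidx = {c: j for j, c in enumerate(M.character_names)}
    next_id = [0]

    def convert(dnode, parent: Optional[PNode]) -> PNode:
        labels: List[SignedCharacter] = []
        # dendropy surfaces [&key=value] hot comments as node annotations
        fieldspecs = [
            (ann.name, str(ann.value)) for ann in dnode.annotations
        ]
        for comment in dnode.comments or []:
            for part in comment.lstrip("&").split(","):
                if "=" in part:
                    fieldspecs.append(tuple(part.split("=", 1)))
        for key, val in fieldspecs:
            names = [v for v in val.split("|") if v]
            if key == "gains":
                labels.extend(gain(c) for c in names)
            elif key == "losses":
                labels.extend(loss(c) for c in names)
        for sc in labels:
            if sc.name not in cidx:
                raise TreeConstructionError(f"unknown character {sc.name!r} in tree")
        if parent is None:
            label = np.zeros(M.m, dtype=np.int8)
        else:
            label = parent.label.copy()
            for sc in labels:
                label[cidx[sc.name]] = 1 if sc.sign == "+" else 0
        raw_name = dnode.label if dnode.label else (
            dnode.taxon.label if dnode.taxon else None
        )
        species = [s for s in (raw_name or "").split("|") if s]
        node = PNode(next_id[0], label, parent=parent, edge_labels=labels,
                     species=species)
        next_id[0] += 1
        if parent is not None:
            parent.children.append(node)
        for dchild in dnode.child_nodes():
            convert(dchild, node)
        return node

    root = convert(dtree.seed_node, None)
    return PersistentPhylogeny(root, M.character_names)


def edge_table(T: PersistentPhylogeny) -> List[dict]:
    """Tabular edge list: parent, child, gains, losses, species at child."""
    rows = []
    for parent, child in sorted(T.edges(), key=lambda e: e[1].id):
        rows.append(
            {
                "parent": parent.id,
                "child": child.id,
                "gains": ",".join(sc.name for sc in child.edge_labels if sc.sign == "+"),
                "losses": ",".join(sc.name for sc in child.edge_labels if sc.sign == "-"),
                "species": ",".join(child.species),
            }
        )
    return rows
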