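"""Conflict graph, red-black graph and the character-realization operator.

The red-black graph is the solver's working state: a bipartite graph on
species and characters where a black edge (s, c) records an unresolved 1-entry
(pair (1,0) with the conjugate pair still incomplete) and a red edge records a
persistence completion (pair (1,1)).  Realizing ``c+`` turns an inactive
character active: species outside c's connected component get the (0,0)
completion, species inside it that are not yet adjacent get a red edge and the
(1,1) completion, and c's black edges are dropped.  Realizing ``c-`` frees an
active character that is red-adjacent to its whole component.  A sequence of
signed characters whose realization empties the graph is a successful
c-reduction, and is exactly the edge-label sequence of a depth-first visit of
a persistent phylogeny.

Constraints make a third case impossible: a constrained pair may never
receive a red edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .matrix import (
    UNKNOWN,
    BinaryMatrix,
    ConstraintSet,
    ExtendedMatrix,
    SignedCharacter,
)

__all__ = [
    "INACTIVE",
    "ACTIVE",
    "FREE",
    "RedBlackGraph",
    "RealizationOutcome",
    "ReductionResult",
    "build_conflict_graph",
    "build_red_black",
    "realize",
    "detect_red_sigma",
    "apply_c_reduction",
    "validate_c_reduction",
    "residual_conflict_graph",
    "reconcile",
]

INACTIVE = "inactive"
ACTIVE = "active"
FREE = "free"


def _snode(name: str) -> Tuple[str, str]:
    return ("S", name)


def _cnode(name: str) -> Tuple[str, str]:
    return ("C", name)


def build_conflict_graph(M: BinaryMatrix) -> nx.Graph:
    """Graph on characters; edge iff the column pair induces all four
    configurations (0,0), (0,1), (1,0), (1,1) over the species."""
    A = M.data.astype(np.int32)
    B = 1 - A
    c11 = (A.T @ A) > 0
    c10 = (A.T @ B) > 0
    c00 = (B.T @ B) > 0
    conflict = c11 & c10 & c10.T & c00
    G = nx.Graph()
    G.add_nodes_from(M.character_names)
    names = M.character_names
    for i, j in zip(*np.nonzero(np.triu(conflict, k=1))):
        G.add_edge(names[i], names[j])
    return G


class RedBlackGraph:
    """Bipartite species/character graph with black/red edges and statuses.

    Nodes are ("S", species_name) / ("C", character_name); isolated vertices
    are pruned eagerly (they correspond to trivially solved sub-instances).
    ``status`` keeps the state of *every* character of the instance, including
    characters no longer present in the graph.
    """

    def __init__(self, graph: nx.Graph, status: dict):
        self.graph = graph
        self.status = status  # character_name -> INACTIVE/ACTIVE/FREE

    # -- queries ----------------------------------------------------------
    def has_species(self, name: str) -> bool:
        return self.graph.has_node(_snode(name))

    def has_character(self, name: str) -> bool:
        return self.graph.has_node(_cnode(name))

    def species_present(self) -> List[str]:
        return sorted(n for k, n in self.graph.nodes if k == "S")

    def characters_present(self) -> List[str]:
        return sorted(n for k, n in self.graph.nodes if k == "C")

    def is_edgeless(self) -> bool:
        return self.graph.number_of_edges() == 0

    def edges(self):
        """Yield (species, character, color) triples."""
        for u, v, color in self.graph.edges(data="color"):
            if u[0] == "S":
                yield u[1], v[1], color
            else:
                yield v[1], u[1], color

    def edge_color(self, s: str, c: str) -> Optional[str]:
        data = self.graph.get_edge_data(_snode(s), _cnode(c))
        return None if data is None else data["color"]

    def component_species(self, c: str) -> List[str]:
        """Species in the connected component C(c); empty if c absent."""
        if not self.has_character(c):
            return []
        comp = nx.node_connected_component(self.graph, _cnode(c))
        return sorted(n for k, n in comp if k == "S")

    def red_neighbors(self, c: str) -> set:
        node = _cnode(c)
        if not self.graph.has_node(node):
            return set()
        return {
            v[1]
            for v in self.graph.neighbors(node)
            if self.graph.edges[node, v]["color"] == "red"
        }

    def black_neighbors(self, c: str) -> set:
        node = _cnode(c)
        if not self.graph.has_node(node):
            return set()
        return {
            v[1]
            for v in self.graph.neighbors(node)
            if self.graph.edges[node, v]["color"] == "black"
        }

    def active_characters(self) -> List[str]:
        return sorted(c for c, st in self.status.items() if st == ACTIVE)

    def inactive_characters(self) -> List[str]:
        return sorted(c for c, st in self.status.items() if st == INACTIVE)

    # -- mutation ---------------------------------------------------------
    def prune_isolated(self) -> None:
        isolated = [n for n in self.graph.nodes if self.graph.degree(n) == 0]
        self.graph.remove_nodes_from(isolated)

    def copy(self) -> "RedBlackGraph":
        return RedBlackGraph(self.graph.copy(), dict(self.status))

    def to_dot(self) -> str:
        """DOT export for debugging: black = solid, red = dashed."""
        lines = ["graph redblack {"]
        for k, n in sorted(self.graph.nodes):
            shape = "box" if k == "C" else "ellipse"
            lines.append(f'  "{k}:{n}" [shape={shape}];')
        for s, c, color in sorted(self.edges()):
            style = "dashed" if color == "red" else "solid"
            lines.append(f'  "S:{s}" -- "C:{c}" [color={color}, style={style}];')
        lines.append("}")
        return "\n".join(lines)


def build_red_black(Me: ExtendedMatrix) -> RedBlackGraph:
    """Red-black graph of an extended matrix (isolated vertices pruned)."""
    G = nx.Graph()
    status = {}
    for c_idx, c in enumerate(Me.character_names):
        G.add_node(_cnode(c))
        col = Me.cells[:, c_idx, :]
        red_any = bool(((col[:, 0] == 1) & (col[:, 1] == 1)).any())
        status[c] = ACTIVE if red_any else INACTIVE
        for s_idx, s in enumerate(Me.species_names):
            plus, minus = col[s_idx]
            if plus == 1 and minus == 1:
                G.add_edge(_snode(s), _cnode(c), color="red")
            elif plus == 1 and minus == 0 and not red_any:
                # black edges exist only while the character is unrealized;
                # an active character's (1,0) cells are settled history
                G.add_edge(_snode(s), _cnode(c), color="black")
    for s in Me.species_names:
        G.add_node(_snode(s))
    rb = RedBlackGraph(G, status)
    rb.prune_isolated()
    return rb


@dataclass
class RealizationOutcome:
    """Result of realizing one signed character.

    ``reason`` is 'none' on success, else one of 'free-character',
    'active-not-covering', 'constraint-violation', 'sign-mismatch'.
    """

    status: str  # 'ok' or 'impossible'
    reason: str = "none"
    graph: Optional[RedBlackGraph] = None
    matrix: Optional[ExtendedMatrix] = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _realize_in_place(
    G: RedBlackGraph, Me: ExtendedMatrix, x: SignedCharacter, F: ConstraintSet
) -> RealizationOutcome:
    c = x.name
    if c not in G.status:
        raise KeyError(f"unknown character {c!r}")
    st = G.status[c]
    if st == FREE:
        return RealizationOutcome("impossible", "free-character")
    if x.sign == "+":
        if st != INACTIVE:
            return RealizationOutcome("impossible", "sign-mismatch")
        comp_species = set(G.component_species(c))
        to_red = sorted(comp_species - G.black_neighbors(c) - G.red_neighbors(c))
        # constraint check before any mutation: a constrained pair must never
        # receive a red edge (the third impossible case)
        for s in to_red:
            if (c, s) in F:
                return RealizationOutcome("impossible", "constraint-violation")
        # defensive literal third case: an existing red edge on a constrained pair
        for s in G.red_neighbors(c):
            if (c, s) in F:
                return RealizationOutcome("impossible", "constraint-violation")
        for s in Me.species_names:
            if s not in comp_species and Me.is_incomplete(s, c):
                Me.complete(s, c, persistent=False)
        for s in to_red:
            Me.complete(s, c, persistent=True)
            G.graph.add_edge(_snode(s), _cnode(c), color="red")
        for s in sorted(G.black_neighbors(c)):
            G.graph.remove_edge(_snode(s), _cnode(c))
        G.status[c] = ACTIVE
        G.prune_isolated()
        return RealizationOutcome("ok", "none", G, Me)
    # x.sign == '-'
    if st != ACTIVE:
        return RealizationOutcome("impossible", "sign-mismatch")
    comp_species = set(G.component_species(c))
    reds = G.red_neighbors(c)
    if reds != comp_species:
        return RealizationOutcome("impossible", "active-not-covering")
    for s in sorted(reds):
        G.graph.remove_edge(_snode(s), _cnode(c))
    G.status[c] = FREE
    G.prune_isolated()
    return RealizationOutcome("ok", "none", G, Me)


def realize(
    G: RedBlackGraph,
    Me: ExtendedMatrix,
    x: SignedCharacter,
    F: ConstraintSet = ConstraintSet(),
) -> RealizationOutcome:
    """Realize a signed character on copies of the graph and matrix.

    On success the outcome carries the updated graph and matrix (isolated
    vertices pruned); on an impossible realization the inputs are untouched
    and the outcome names the reason.
    """
    G2, Me2 = G.copy(), Me.copy()
    return _realize_in_place(G2, Me2, x, F)


def detect_red_sigma(G: RedBlackGraph) -> Optional[tuple]:
    """Find a red-sigma: a red path s1 - a - s2 - b - s3 on three species.

    Equivalent formulation: two characters whose red-neighbor sets properly
    cross (nonempty intersection and both differences nonempty).  The
    crossing of the two loss-columns then exhibits the forbidden
    (0,1), (1,0), (1,1) triple, so no completion of the current state admits
    a directed perfect phylogeny.  Returns (s1, a, s2, b, s3) or None.
    """
    red_sets = {}
    for c in G.characters_present():
        reds = G.red_neighbors(c)
        if len(reds) >= 1:
            red_sets[c] = reds
    chars = sorted(red_sets)
    for i, a in enumerate(chars):
        Ra = red_sets[a]
        for b in chars[i + 1 :]:
            Rb = red_sets[b]
            inter = Ra & Rb
            only_a = Ra - Rb
            only_b = Rb - Ra
            if inter and only_a and only_b:
                return (min(only_a), a, min(inter), b, min(only_b))
    return None


def validate_c_reduction(seq: Sequence[SignedCharacter]) -> None:
    """Each signed character at most once; c- never precedes c+."""
    seen = set()
    gained = set()
    for x in seq:
        if x in seen:
            raise ValueError(f"signed character {x} repeated in c-reduction")
        seen.add(x)
        if x.sign == "+":
            gained.add(x.name)
        elif x.name not in gained:
            raise ValueError(f"{x} appears before {x.name}+ in c-reduction")


@dataclass
class ReductionResult:
    """Outcome of applying a c-reduction left to right."""

    success: bool
    graph: RedBlackGraph
    matrix: ExtendedMatrix
    failed_at: Optional[int] = None  # step index of the first impossible label
    reason: str = "none"

    @property
    def edgeless(self) -> bool:
        return self.graph.is_edgeless()


def apply_c_reduction(
    Me: ExtendedMatrix,
    F: ConstraintSet,
    seq: Sequence[SignedCharacter],
    G: Optional[RedBlackGraph] = None,
) -> ReductionResult:
    """Realize the labels of ``seq`` in order from (a copy of) the start state.

    ``success`` means every realization was possible *and* the final graph is
    edgeless (a successful c-reduction).
    """
    validate_c_reduction(seq)
    G = build_red_black(Me) if G is None else G.copy()
    Me = Me.copy()
    for k, x in enumerate(seq):
        out = _realize_in_place(G, Me, x, F)
        if not out.ok:
            return ReductionResult(False, G, Me, failed_at=k, reason=out.reason)
    return ReductionResult(G.is_edgeless(), G, Me)


def residual_conflict_graph(G: RedBlackGraph) -> nx.Graph:
    """Conflict graph of the residual instance at a search state.

    The residual matrix has the species still present in the red-black graph
    as rows, the inactive characters still present as columns, and a 1 exactly
    where a black edge remains.
    """
    species = G.species_present()
    chars = [c for c in G.characters_present() if G.status[c] == INACTIVE]
    Gc = nx.Graph()
    Gc.add_nodes_from(chars)
    if not species or not chars:
        return Gc
    A = np.zeros((len(species), len(chars)), dtype=np.int8)
    s_idx = {s: i for i, s in enumerate(species)}
    for j, c in enumerate(chars):
        for s in G.black_neighbors(c):
            A[s_idx[s], j] = 1
    M = BinaryMatrix(A, species, chars)
    return build_conflict_graph(M)


def reconcile(G: RedBlackGraph, Me: ExtendedMatrix) -> List[str]:
    """Check the black/red edge invariants of G against Me (test helper).

    Returns a list of human-readable discrepancies (empty = consistent).
    """
    problems = []
    edge_set = {(s, c): color for s, c, color in G.edges()}
    for s in Me.species_names:
        for c in Me.character_names:
            plus, minus = Me.pair(s, c)
            color = edge_set.get((s, c))
            expected = None
            if plus == 1 and minus == 0 and G.status[c] == INACTIVE:
                expected = "black"
            elif plus == 1 and minus == 1 and G.status[c] == ACTIVE:
                expected = "red"
            if expected != color:
                problems.append(f"edge ({s},{c}): expected {expected}, found {color}")
    for c in Me.character_names:
        st = G.status[c]
        reds = G.red_neighbors(c)
        if st == INACTIVE and reds:
            problems.append(f"inactive character {c} has red edges {sorted(reds)}")
        if st == FREE and (reds or G.black_neighbors(c)):
            problems.append(f"free character {c} has incident edges")
    return problems
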