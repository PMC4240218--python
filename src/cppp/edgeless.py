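"""Polynomial-time CPPP on matrices whose conflict graph is edgeless.

When no two characters conflict, a successful c-reduction can be found
greedily: per connected component of the red-black graph, realize the
realizable maximal characters of the containment order (a character is below
another when its 1-set is contained in the other's), then free every active
character that has become red-adjacent to its whole component, and repeat.
If at some iteration no maximal character of a component can be realized the
instance has no solution.  With no constraints a solution always exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .matrix import BinaryMatrix, ConstraintSet, ExtendedMatrix, SignedCharacter
from .matrix import build_extended_matrix, gain, loss
from .graphs import (
    ACTIVE,
    INACTIVE,
    RedBlackGraph,
    _realize_in_place,
    build_red_black,
    detect_red_sigma,
    residual_conflict_graph,
)

__all__ = [
    "CharacterPoset",
    "build_partial_order",
    "build_adjacency_graph",
    "EdgelessOutcome",
    "solve_edgeless",
    "ConflictedInstanceError",
]


class ConflictedInstanceError(ValueError):
    """solve_edgeless was called on an instance with conflicting characters."""


@dataclass(frozen=True)
class CharacterPoset:
    """Containment order on character columns: c < c' iff 1-set(c) ⊂ 1-set(c').

    Equal columns are tied: they form one element class and are maximal (or
    not) together.
    """

    one_sets: Dict[str, FrozenSet[str]]

    def less(self, c: str, cp: str) -> bool:
        a, b = self.one_sets[c], self.one_sets[cp]
        return a < b

    def tied(self, c: str, cp: str) -> bool:
        return c != cp and self.one_sets[c] == self.one_sets[cp]

    def maximal(self, among: Sequence[str]) -> List[str]:
        among = list(among)
        out = []
        for c in among:
            if not any(self.less(c, cp) for cp in among):
                out.append(c)
        return sorted(out)

    def tie_class(self, c: str) -> List[str]:
        return sorted(cp for cp in self.one_sets if self.one_sets[cp] == self.one_sets[c])


def build_partial_order(M: BinaryMatrix) -> CharacterPoset:
    one_sets = {
        c: frozenset(
            M.species_names[i] for i in np.nonzero(M.column(c))[0]
        )
        for c in M.character_names
    }
    return CharacterPoset(one_sets)


def build_adjacency_graph(G: RedBlackGraph) -> nx.Graph:
    """Characters joined when some species is adjacent to both in G."""
    A = nx.Graph()
    chars = G.characters_present()
    A.add_nodes_from(chars)
    for s in G.species_present():
        nbrs = sorted(
            n for _, n in G.graph.neighbors(("S", s))
        )
        for i, u in enumerate(nbrs):
            for v in nbrs[i + 1 :]:
                A.add_edge(u, v)
    return A


@dataclass
class EdgelessOutcome:
    """A successful run: the c-reduction found and the final state."""

    reduction: List[SignedCharacter]
    graph: RedBlackGraph
    matrix: ExtendedMatrix
    trace: List[dict] = field(default_factory=list)


def _components(G: RedBlackGraph) -> List[Tuple[List[str], List[str]]]:
    """Nontrivial components as (species, characters), ordered by least species."""
    comps = []
    for comp in nx.connected_components(G.graph):
        if len(comp) < 2:
            continue
        species = sorted(n for k, n in comp if k == "S")
        chars = sorted(n for k, n in comp if k == "C")
        comps.append((species, chars))
    comps.sort(key=lambda sc: sc[0][0] if sc[0] else "")
    return comps


def _residual_black_matrix(G: RedBlackGraph) -> Optional[BinaryMatrix]:
    species = G.species_present()
    chars = [c for c in G.characters_present() if G.status[c] == INACTIVE]
    if not species or not chars:
        return None
    A = np.zeros((len(species), len(chars)), dtype=np.int8)
    idx = {s: i for i, s in enumerate(species)}
    for j, c in enumerate(chars):
        for s in G.black_neighbors(c):
            A[idx[s], j] = 1
    return BinaryMatrix(A, species, chars)


def _realization_order(poset: CharacterPoset, chars: Sequence[str]) -> List[str]:
    """Deterministic order: decreasing 1-count, equal columns consecutive, name."""
    def key(c):
        s = poset.one_sets[c]
        return (-len(s), tuple(sorted(s)), c)

    return sorted(chars, key=key)


def _free_exhaustively(G: RedBlackGraph, Me: ExtendedMatrix, F: ConstraintSet,
                       seq: List[SignedCharacter]) -> bool:
    """Realize c- for every active character red-adjacent to its whole
    component, repeating until stable.  Returns whether anything was freed."""
    progress = False
    while True:
        freed_one = False
        for c in G.active_characters():
            if not G.has_character(c):
                continue
            comp = set(G.component_species(c))
            if comp and G.red_neighbors(c) == comp:
                out = _realize_in_place(G, Me, loss(c), F)
                assert out.ok, f"freeing {c} unexpectedly {out.reason}"
                seq.append(loss(c))
                freed_one = progress = True
        if not freed_one:
            return progress


def finalize_reduction(G: RedBlackGraph, Me: ExtendedMatrix, F: ConstraintSet,
                       seq: List[SignedCharacter]) -> None:
    """Append a gain for every character never realized (isolated / all-zero
    columns); their components are empty so realization completes the
    remaining (?,?) pairs as (0,0).  Requires an edgeless graph."""
    assert G.is_edgeless()
    for c in sorted(c for c, st in G.status.items() if st == INACTIVE):
        out = _realize_in_place(G, Me, gain(c), F)
        assert out.ok, f"finalizing {c} unexpectedly {out.reason}"
        seq.append(gain(c))


def solve_edgeless(
    M: BinaryMatrix,
    F: ConstraintSet = ConstraintSet(),
    start_state: Optional[Tuple[RedBlackGraph, ExtendedMatrix]] = None,
    assert_no_red_sigma: bool = False,
    keep_trace: bool = False,
) -> Optional[EdgelessOutcome]:
    """Greedy maximal-character algorithm; None means no solution.

    With ``start_state`` the run continues from an interior solver state (the
    state is copied, not mutated); a None answer then only means "this branch
    fails", not global unsatisfiability.  ``assert_no_red_sigma`` turns on the
    invariant check used in tests.
    """
    if start_state is None:
        F.validate(M)
        Me = build_extended_matrix(M, F)
        G = build_red_black(Me)
    else:
        G, Me = start_state[0].copy(), start_state[1].copy()
    if residual_conflict_graph(G).number_of_edges() > 0:
        raise ConflictedInstanceError(
            "the residual conflict graph has edges; use the general solver"
        )
    residual = _residual_black_matrix(G)
    poset = build_partial_order(residual) if residual is not None else None
    seq: List[SignedCharacter] = []
    trace: List[dict] = []
    while not G.is_edgeless():
        progress = False
        for species, chars in _components(G):
            inactive = [c for c in chars if G.status[c] == INACTIVE]
            if not inactive:
                continue
            cm = poset.maximal(inactive)
            D = []
            for c in cm:
                blocked = any(
                    (c, s) in F
                    for s in set(G.component_species(c))
                    - G.black_neighbors(c)
                    - G.red_neighbors(c)
                )
                if not blocked:
                    D.append(c)
            if keep_trace:
                trace.append(
                    {"component_species": species, "maximal": cm, "realizable": D}
                )
            if not D:
                return None
            for c in _realization_order(poset, D):
                out = _realize_in_place(G, Me, gain(c), F)
                if not out.ok:  # component drift; treat as failure of the branch
                    return None
                seq.append(gain(c))
                progress = True
                if assert_no_red_sigma:
                    assert detect_red_sigma(G) is None, "red-sigma during edgeless run"
        if _free_exhaustively(G, Me, F, seq):
            progress = True
        if assert_no_red_sigma:
            assert detect_red_sigma(G) is None, "red-sigma during edgeless run"
        if not progress:
            return None
    finalize_reduction(G, Me, F, seq)
    return EdgelessOutcome(seq, G, Me, trace)
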