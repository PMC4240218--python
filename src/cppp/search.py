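"""Depth-first search over c-reduction prefixes: the general CPPP solver.

The decision tree has a node per feasible c-reduction prefix, so at most
(2m)! leaves; three devices keep the explored part small in practice:

* a branch whose red-black graph contains a red-sigma (two active characters
  with properly crossing red-neighbor sets) is pruned — no completion of that
  state admits a directed perfect phylogeny;
* when the residual conflict graph is edgeless the greedy polynomial
  algorithm is invoked from the node's state; success ends the search (its
  reduction is spliced onto the prefix), failure falls back to normal
  expansion (the greedy algorithm is only known to be complete from fresh
  states);
* the search stops at the first solution — there is no optimisation
  criterion among solutions.

The solver is fixed-parameter in the number of characters m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .matrix import (
    BinaryMatrix,
    ConstraintSet,
    ExtendedMatrix,
    SignedCharacter,
    build_extended_matrix,
    gain,
    loss,
)
from .graphs import (
    ACTIVE,
    INACTIVE,
    RedBlackGraph,
    _realize_in_place,
    build_red_black,
    detect_red_sigma,
    residual_conflict_graph,
)
from .edgeless import (
    CharacterPoset,
    build_partial_order,
    finalize_reduction,
    solve_edgeless,
)

__all__ = ["SolveResult", "feasible_moves", "solve_cppp", "BudgetExceeded"]


class BudgetExceeded(Exception):
    pass


@dataclass
class SolveResult:
    """Outcome of a CPPP solve.

    status is 'solution', 'no-solution' or 'budget-exceeded'.  On a solution,
    ``reduction`` is a successful c-reduction, ``completed`` the fully
    completed extended matrix and ``tree`` the persistent phylogeny built
    from it (already verified by construction postconditions).
    """

    status: str
    reduction: Optional[List[SignedCharacter]] = None
    completed: Optional[ExtendedMatrix] = None
    tree: Optional[object] = None  # PersistentPhylogeny
    stats: dict = field(default_factory=dict)


def feasible_moves(
    G: RedBlackGraph,
    Me: ExtendedMatrix,
    F: ConstraintSet,
    poset: Optional[CharacterPoset] = None,
) -> List[SignedCharacter]:
    """Signed characters whose realization at this state is possible.

    Loss moves come first (freeing shrinks the graph), then gains ordered
    with maximal characters first, then by decreasing 1-count, then name.
    """
    moves: List[SignedCharacter] = []
    for c in G.active_characters():
        if not G.has_character(c):
            continue
        comp = set(G.component_species(c))
        if comp and G.red_neighbors(c) == comp:
            moves.append(loss(c))
    gains = []
    inactive_present = [c for c in G.characters_present() if G.status[c] == INACTIVE]
    maximal = set(poset.maximal(inactive_present)) if poset is not None else set()
    for c in inactive_present:
        pending = (
            set(G.component_species(c)) - G.black_neighbors(c) - G.red_neighbors(c)
        )
        if any((c, s) in F for s in pending):
            continue
        gains.append(c)

    def gain_key(c):
        ones = -int(Me.restrict_to_binary().column(c).sum()) if poset is None else -len(
            poset.one_sets.get(c, ())
        )
        return (c not in maximal, ones, c)

    gains.sort(key=gain_key)
    moves.extend(gain(c) for c in gains)
    return moves


def solve_cppp(
    M: BinaryMatrix,
    F: ConstraintSet = ConstraintSet(),
    max_nodes: int = 10**6,
    collect_prunes: Optional[list] = None,
    max_collected_prunes: int = 50,
    trace: Optional[list] = None,
) -> SolveResult:
    """Decide CPPP for (M, F) and construct a verified phylogeny if solvable.

    ``collect_prunes`` (a list) receives copies of the extended matrix at
    red-sigma-pruned nodes, up to ``max_collected_prunes`` — used to audit
    prune soundness against the exhaustive oracle.
    ``trace`` (a list) receives one dict per visited node.
    """
    from .phylogeny import build_tree  # deferred: phylogeny imports nothing from here

    F.validate(M)
    Me0 = build_extended_matrix(M, F)
    G0 = build_red_black(Me0)
    poset = build_partial_order(M)
    stats = {"nodes": 0, "prunes": {"red-sigma": 0}, "shortcut_calls": 0,
             "shortcut_successes": 0}

    def dfs(G: RedBlackGraph, Me: ExtendedMatrix, prefix: List[SignedCharacter],
            depth: int) -> Optional[tuple]:
        stats["nodes"] += 1
        if stats["nodes"] > max_nodes:
            raise BudgetExceeded
        if G.is_edgeless():
            seq = list(prefix)
            Gf, Mf = G.copy(), Me.copy()
            finalize_reduction(Gf, Mf, F, seq)
            if trace is not None:
                trace.append({"depth": depth, "event": "solution"})
            return seq, Mf
        witness = detect_red_sigma(G)
        if witness is not None:
            stats["prunes"]["red-sigma"] += 1
            if collect_prunes is not None and len(collect_prunes) < max_collected_prunes:
                collect_prunes.append(Me.copy())
            if trace is not None:
                trace.append({"depth": depth, "event": "prune", "reason": "red-sigma"})
            return None
        if residual_conflict_graph(G).number_of_edges() == 0:
            stats["shortcut_calls"] += 1
            outcome = solve_edgeless(M, F, start_state=(G, Me))
            if outcome is not None:
                stats["shortcut_successes"] += 1
                if trace is not None:
                    trace.append({"depth": depth, "event": "shortcut-solution"})
                return list(prefix) + outcome.reduction, outcome.matrix
            # greedy failure from an interior state is not a proof of
            # unsatisfiability: fall through and branch normally
        for x in feasible_moves(G, Me, F, poset):
            G2, Me2 = G.copy(), Me.copy()
            out = _realize_in_place(G2, Me2, x, F)
            if not out.ok:
                continue
            if trace is not None:
                trace.append({"depth": depth, "event": "expand", "move": str(x)})
            found = dfs(G2, Me2, prefix + [x], depth + 1)
            if found is not None:
                return found
        return None

    try:
        found = dfs(G0, Me0, [], 0)
    except BudgetExceeded:
        return SolveResult("budget-exceeded", stats=stats)
    if found is None:
        return SolveResult("no-solution", stats=stats)
    seq, completed = found
    tree = build_tree(completed, M)
    return SolveResult("solution", reduction=seq, completed=completed,
                       tree=tree, stats=stats)
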