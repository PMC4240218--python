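"""Exhaustive ground truth for small instances.

A matrix admits a persistent phylogeny (under constraints F) iff some
completion of its extended matrix admits a directed perfect phylogeny.  The
oracle makes that equivalence executable: it enumerates all 2^q completions
of the q incomplete conjugate pairs and tests each with the pairwise-column
criterion.  It deliberately never touches the red-black machinery, so it is
an independent check on the solvers, not a solver itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .matrix import (
    UNKNOWN,
    BinaryMatrix,
    ConstraintSet,
    CpppError,
    ExtendedMatrix,
    admits_directed_pp,
    build_extended_matrix,
)

__all__ = ["OracleReport", "InstanceTooLargeError", "oracle_decide", "oracle_decide_extended"]

_CHUNK = 4096


class InstanceTooLargeError(CpppError):
    """More incomplete pairs than the enumeration limit allows."""


@dataclass
class OracleReport:
    solvable: bool
    witness: Optional[ExtendedMatrix] = None  # a completion admitting a directed pp
    n_completions: Optional[int] = None  # total enumerated (when counting)
    n_solutions: Optional[int] = None  # completions admitting a directed pp


def _chunk_admits(base: np.ndarray, pair_pos, assignments: np.ndarray) -> np.ndarray:
    """Vectorized directed-pp test for a block of completions.

    base: (n, 2m) with -1 at incomplete cells; pair_pos: list of (s, 2c) column
    positions of the '?' pairs; assignments: (k, q) 0/1 matrix of persistence
    choices.  Returns a boolean vector of length k.
    """
    k, q = assignments.shape
    n, w = base.shape
    A = np.broadcast_to(base, (k, n, w)).copy()
    for j, (s, col) in enumerate(pair_pos):
        A[:, s, col] = assignments[:, j]
        A[:, s, col + 1] = assignments[:, j]
    A = A.astype(np.int32)
    B = 1 - A
    c11 = np.einsum("kns,knt->kst", A, A) > 0
    c10 = np.einsum("kns,knt->kst", A, B) > 0
    bad = c11 & c10 & c10.transpose(0, 2, 1)
    for i in range(w):
        bad[:, i, i] = False
    return ~bad.any(axis=(1, 2))


def oracle_decide_extended(
    Me: ExtendedMatrix, limit: int = 20, count: bool = False
) -> OracleReport:
    """Decide by exhausting the completions of a (possibly partial) matrix."""
    pairs = Me.incomplete_pairs()
    q = len(pairs)
    if q > limit:
        raise InstanceTooLargeError(
            f"{q} incomplete pairs exceed the enumeration limit of {limit}"
        )
    base = Me.flat().copy()
    pair_pos = [
        (Me.species_index(s), 2 * Me.character_index(c)) for s, c in pairs
    ]
    total = 1 << q
    n_solutions = 0
    witness_bits: Optional[int] = None
    shifts = np.arange(q, dtype=np.uint64)
    for start in range(0, total, _CHUNK):
        stop = min(start + _CHUNK, total)
        codes = np.arange(start, stop, dtype=np.uint64)
        assignments = ((codes[:, None] >> shifts[None, :]) & 1).astype(np.int8)
        ok = _chunk_admits(base, pair_pos, assignments)
        if ok.any():
            if witness_bits is None:
                witness_bits = start + int(np.nonzero(ok)[0][0])
            if not count:
                break
            n_solutions += int(ok.sum())
    if witness_bits is None:
        return OracleReport(False, n_completions=total if count else None,
                            n_solutions=0 if count else None)
    witness = Me.copy()
    for j, (s, c) in enumerate(pairs):
        witness.complete(s, c, persistent=bool((witness_bits >> j) & 1))
    assert admits_directed_pp(witness)
    return OracleReport(
        True,
        witness=witness,
        n_completions=total if count else None,
        n_solutions=n_solutions if count else None,
    )


def oracle_decide(
    M: BinaryMatrix,
    F: ConstraintSet = ConstraintSet(),
    limit: int = 20,
    count: bool = False,
) -> OracleReport:
    """Exhaustively decide CPPP for (M, F).

    Constrained cells are fixed at (0,0) before enumeration, so every
    enumerated completion respects F by construction.
    """
    return oracle_decide_extended(build_extended_matrix(M, F), limit=limit, count=count)
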