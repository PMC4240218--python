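"""Shared fixtures and independent brute-force oracles for the test suite."""

from itertools import product

import numpy as np
import pytest

from cppp import BinaryMatrix, ConstraintSet


@pytest.fixture
def sigma():
    """The 3x2 matrix whose only explanation makes c1 persistent for s3."""
    return BinaryMatrix([[1, 0], [1, 1], [0, 1]])


@pytest.fixture
def sigma_unsat_constraints():
    """Constraining both zero cells of sigma leaves a single, invalid completion."""
    return ConstraintSet([("c1", "s3"), ("c2", "s1")])


def random_instance(trial, n_max=5, m_max=5, k_choices=(0, 1, 2)):
    """Seeded random (M, F) with |F| drawn from k_choices (capped by zero cells)."""
    rng = np.random.default_rng(trial)
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    M = BinaryMatrix(rng.integers(0, 2, size=(n, m)))
    zeros = [
        (M.character_names[c], M.species_names[s])
        for s in range(n)
        for c in range(m)
        if M.data[s, c] == 0
    ]
    k = min(int(rng.choice(k_choices)), len(zeros))
    picks = rng.choice(len(zeros), size=k, replace=False) if k else []
    F = ConstraintSet(zeros[i] for i in picks)
    return M, F


def dpp_by_forest_enumeration(A) -> bool:
    """Directed perfect phylogeny existence by exhaustive tree enumeration.

    Independent of the pairwise-configuration test: the distinct nonempty
    column supports are arranged into every forest in which each support's
    parent is a strict superset (or the root), and the matrix is explained
    iff some forest's node vectors cover every row.  Sound because mutation
    edges of a directed phylogeny are nested along root-to-leaf paths;
    complete because any witness forest rebuilds a phylogeny.
    """
    A = np.asarray(A, dtype=np.int8)
    n, k = A.shape
    supports = sorted(
        {frozenset(np.nonzero(A[:, j])[0]) for j in range(k)} - {frozenset()},
        key=lambda s: (-len(s), sorted(s)),
    )
    t = len(supports)
    rows = {frozenset(np.nonzero(A[r, :])[0]) for r in range(n)}

    def row_sets_of(parent):
        # vector of node(i) = set of columns whose support lies on i's chain
        vectors = []
        for i in range(t):
            chain = set()
            j = i
            while j is not None:
                chain.add(j)
                j = parent[j]
            cols = frozenset(
                c for c in range(k)
                if frozenset(np.nonzero(A[:, c])[0]) in {supports[x] for x in chain}
            )
            vectors.append(cols)
        return vectors

    candidates = []
    for i, s in enumerate(supports):
        cands = [None] + [j for j in range(t) if supports[j] > s]
        candidates.append(cands)
    for parent in product(*candidates):
        vectors = row_sets_of(parent)
        covered = set(vectors) | {frozenset()}
        if rows <= covered:
            return True
    return False
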