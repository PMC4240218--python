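"""Synthetic instance generator.

Emulates the coalescent / infinite-sites protocol used to exercise the
solvers: a random rooted binary genealogy over n leaves, m mutations dropped
on uniformly random branches (each mutation a character whose 1-set is the
clade below it), so the raw matrix always admits a perfect phylogeny but may
contain duplicated rows and columns.  Back mutations are then injected by
flipping at most one entry of each duplicated row, and optional random
constraints are sampled from the zero cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .matrix import BinaryMatrix, ConstraintSet

__all__ = [
    "SimulationConfig",
    "generate_pp_matrix",
    "inject_back_mutations",
    "generate_constraints",
    "generate_instance",
    "run_protocol",
]


@dataclass(frozen=True)
class SimulationConfig:
    n: int  # species (leaves)
    m: int  # characters (mutations)
    duplicate_row_rate: float = 0.0
    duplicate_col_rate: float = 0.0
    constraints_k: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least two species")
        if self.m < 1:
            raise ValueError("need at least one character")
        for rate in (self.duplicate_row_rate, self.duplicate_col_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("duplication rates must be in [0, 1]")
        if self.constraints_k < 0:
            raise ValueError("constraints_k must be nonnegative")


def _random_genealogy(n: int, rng: np.random.Generator):
    """Random rooted binary tree by uniform pairwise coalescence.

    Returns (parent, order): parent[v] for every node, nodes 0..n-1 the
    leaves, higher ids internal, root last.
    """
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        active = [v for v in active if v not in (a, b)] + [nxt]
        nxt += 1
    return parent


def _leaf_sets(parent: np.ndarray, n: int) -> List[set]:
    total = parent.shape[0]
    below = [set() for _ in range(total)]
    for leaf in range(n):
        v = leaf
        while v != -1:
            below[v].add(leaf)
            v = parent[v]
    return below


def generate_pp_matrix(config: SimulationConfig) -> BinaryMatrix:
    """Infinite-sites matrix: every column is a clade of a random genealogy.

    The output always admits a (directed) perfect phylogeny; duplicated rows
    and columns can occur naturally and extra ones are forced by the
    duplication rates (the overwritten rows/columns copy earlier ones, which
    preserves the perfect phylogeny).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n, config.m
    parent = _random_genealogy(n, rng)
    below = _leaf_sets(parent, n)
    # branches = all non-root nodes (the edge above each)
    branches = [v for v in range(2 * n - 1) if parent[v] != -1]
    data = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        v = branches[rng.integers(len(branches))]
        for leaf in below[v]:
            data[leaf, j] = 1
    d = int(round(config.duplicate_row_rate * n))
    if d >= n:
        d = n - 1
    for t in range(n - d, n):
        data[t, :] = data[rng.integers(n - d), :]
    dc = int(round(config.duplicate_col_rate * m))
    if dc >= m:
        dc = m - 1
    for t in range(m - dc, m):
        data[:, t] = data[:, rng.integers(m - dc)]
    return BinaryMatrix(data)


def inject_back_mutations(
    M: BinaryMatrix, seed: int, strict: bool = True
) -> BinaryMatrix:
    """Flip at most one entry of each row that duplicates an earlier row.

    With ``strict`` (default) exactly one entry per duplicated row is
    flipped; otherwise each duplicated row is flipped with probability 1/2,
    so some duplicates survive untouched.  Non-duplicate rows are never
    modified.
    """
    rng = np.random.default_rng(seed)
    data = M.data.copy()
    seen = set()
    for i in range(M.n):
        key = M.data[i, :].tobytes()
        if key in seen:
            if strict or rng.random() < 0.5:
                j = int(rng.integers(M.m))
                data[i, j] ^= 1
        else:
            seen.add(key)
    return BinaryMatrix(data, M.species_names, M.character_names)


def generate_constraints(M: BinaryMatrix, k: int, seed: int) -> ConstraintSet:
    """k distinct uniformly chosen (character, species) pairs with M[s,c]=0."""
    zero_cells = [
        (M.character_names[c], M.species_names[s])
        for s in range(M.n)
        for c in range(M.m)
        if M.data[s, c] == 0
    ]
    if k > len(zero_cells):
        raise ValueError(
            f"requested {k} constraints but the matrix has only "
            f"{len(zero_cells)} zero cells"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(zero_cells), size=k, replace=False)
    return ConstraintSet(zero_cells[i] for i in picks)


def generate_instance(
    config: SimulationConfig, perturb: bool = True
) -> Tuple[BinaryMatrix, ConstraintSet]:
    """Full protocol: clade matrix (+ forced duplicates), back mutations on
    duplicated rows, then random constraints.  Sub-seeds are derived from
    config.seed so the whole instance is reproducible from one integer."""
    M = generate_pp_matrix(config)
    if perturb:
        M = inject_back_mutations(M, seed=config.seed + 1)
    F = generate_constraints(M, config.constraints_k, seed=config.seed + 2)
    return M, F


def run_protocol(
    seed: int,
    n: int = 10,
    ms: Tuple[int, ...] = (5, 7, 10),
    replicates: int = 20,
    constraints_k: int = 0,
    max_nodes: int = 200_000,
) -> dict:
    """Desk-scale replica of the simulated-instance study.

    For each character count in ``ms``, generate ``replicates`` instances
    (clade matrices whose naturally duplicated rows receive one random flip
    each), solve with a node budget, and report the decisions.  Returns
    {(n, m): {"solution": ..., "no-solution": ..., "budget-exceeded": ...}}.
    """
    from .search import solve_cppp  # local import: simulate stays solver-free

    results = {}
    for m in ms:
        counts = {"solution": 0, "no-solution": 0, "budget-exceeded": 0}
        for i in range(replicates):
            config = SimulationConfig(
                n=n, m=m, constraints_k=constraints_k,
                seed=(seed * 10_000 + m * 100 + i) % (2**31 - 1),
            )
            M, F = generate_instance(config)
            res = solve_cppp(M, F, max_nodes=max_nodes)
            counts[res.status] += 1
        results[(n, m)] = counts
    return results
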