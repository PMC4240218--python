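"""Core domain types for persistent-phylogeny instances.

A binary species × character matrix ``M`` records which species possess which
characters.  The persistent model allows each character to be gained once and
lost once; a character that is gained and later lost on the path to a species
is *persistent* for that species.  Deciding whether a persistent phylogeny
exists reduces to completing the *extended matrix*: each character ``c`` is
split into a conjugate column pair ``(c+, c-)`` (gain / loss), entries over
``{0, 1, ?}``, and the question becomes whether the ``?`` pairs can be
completed so that the resulting ``2m``-column matrix admits a directed
(all-zero-root) perfect phylogeny.

Constraints ``(c, s)`` forbid persistence of ``c`` anywhere on the path to
``s``; they pin the conjugate pair of ``(s, c)`` to ``(0, 0)``.

All indexing is 0-based internally; every user-facing report uses names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "BinaryMatrix",
    "ConstraintSet",
    "ExtendedMatrix",
    "SignedCharacter",
    "CpppError",
    "InvalidConstraintError",
    "IllegalRecompletionError",
    "ConstraintViolationError",
    "IncompleteMatrixError",
    "build_extended_matrix",
    "complete_pair",
    "admits_directed_pp",
    "deduplicate",
]

# Sentinel for '?' in the cells array.  Never serialized as a number: all
# serializations write the literal "?" character (see cppp.io).
UNKNOWN = -1


class CpppError(Exception):
    """Base class for package errors."""


class InvalidConstraintError(CpppError):
    """A constraint names a cell whose matrix entry is 1 (must be 0)."""


class IllegalRecompletionError(CpppError):
    """Attempt to complete a conjugate pair that is no longer (?, ?)."""


class ConstraintViolationError(CpppError):
    """A persistent completion was requested for a constrained cell."""


class IncompleteMatrixError(CpppError):
    """An operation requiring a fully completed matrix saw a '?' cell."""


class SignedCharacter(NamedTuple):
    """A character together with a gain (+) or loss (-) sign."""

    name: str
    sign: str  # '+' or '-'

    def __str__(self) -> str:  # e.g. "c1+"
        return f"{self.name}{self.sign}"

    @classmethod
    def parse(cls, token: str) -> "SignedCharacter":
        token = token.strip()
        if not token or token[-1] not in "+-":
            raise ValueError(f"malformed signed character {token!r}")
        return cls(token[:-1], token[-1])


def gain(name: str) -> SignedCharacter:
    return SignedCharacter(name, "+")


def loss(name: str) -> SignedCharacter:
    return SignedCharacter(name, "-")


@dataclass(frozen=True)
class BinaryMatrix:
    """An n × m binary matrix over named species (rows) and characters (columns)."""

    species_names: tuple
    character_names: tuple
    data: np.ndarray  # shape (n, m), values in {0, 1}

    def __init__(
        self,
        data,
        species_names: Optional[Sequence[str]] = None,
        character_names: Optional[Sequence[str]] = None,
    ):
        arr = np.asarray(data, dtype=np.int8)
        if arr.ndim != 2:
            raise ValueError("matrix data must be 2-dimensional")
        n, m = arr.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one species and one character")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix entries must all be 0 or 1")
        sp = tuple(species_names) if species_names is not None else tuple(
            f"s{i + 1}" for i in range(n)
        )
        ch = tuple(character_names) if character_names is not None else tuple(
            f"c{j + 1}" for j in range(m)
        )
        if len(sp) != n:
            raise ValueError("species_names length does not match row count")
        if len(ch) != m:
            raise ValueError("character_names length does not match column count")
        if len(set(sp)) != n:
            raise ValueError("species names must be unique")
        if len(set(ch)) != m:
            raise ValueError("character names must be unique")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "species_names", sp)
        object.__setattr__(self, "character_names", ch)
        object.__setattr__(self, "data", arr)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def character_index(self, name: str) -> int:
        try:
            return self.character_names.index(name)
        except ValueError:
            raise KeyError(f"unknown character {name!r}") from None

    def __getitem__(self, key) -> int:
        s, c = key
        if isinstance(s, str):
            s = self.species_index(s)
        if isinstance(c, str):
            c = self.character_index(c)
        return int(self.data[s, c])

    def column(self, c) -> np.ndarray:
        if isinstance(c, str):
            c = self.character_index(c)
        return self.data[:, c]

    def row(self, s) -> np.ndarray:
        if isinstance(s, str):
            s = self.species_index(s)
        return self.data[s, :]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinaryMatrix)
            and self.species_names == other.species_names
            and self.character_names == other.character_names
            and np.array_equal(self.data, other.data)
        )

    def __repr__(self) -> str:
        return f"BinaryMatrix({self.n}x{self.m})"


@dataclass(frozen=True)
class ConstraintSet:
    """A set of forbidden-persistence pairs (character_name, species_name).

    Every constrained cell must be 0 in the matrix: a species that already has
    the character cannot be forbidden from ever having had it.
    """

    pairs: frozenset = field(default_factory=frozenset)

    def __init__(self, pairs: Iterable = ()):  # pairs of (character, species)
        object.__setattr__(self, "pairs", frozenset((c, s) for c, s in pairs))

    def validate(self, M: BinaryMatrix) -> None:
        for c, s in sorted(self.pairs):
            if M[s, c] != 0:
                raise InvalidConstraintError(
                    f"constraint ({c}, {s}) names a cell with M[{s}, {c}] = 1"
                )

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def __iter__(self) -> Iterator:
        return iter(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __or__(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet(self.pairs | other.pairs)


class ExtendedMatrix:
    """The n × 2m partial matrix over {0, 1, ?} with conjugate column pairs.

    ``cells`` has shape (n, m, 2): ``cells[s, c, 0]`` is the ``c+`` entry and
    ``cells[s, c, 1]`` the ``c-`` entry, with -1 standing for '?'.  A cell
    pair is always one of (1,0), (0,0), (1,1) or (?,?).  Constrained pairs
    are pinned at (0,0) and may never be recompleted.
    """

    __slots__ = ("species_names", "character_names", "cells", "forbidden")

    def __init__(
        self,
        species_names: Sequence[str],
        character_names: Sequence[str],
        cells: np.ndarray,
        forbidden: frozenset = frozenset(),
    ):
        self.species_names = tuple(species_names)
        self.character_names = tuple(character_names)
        self.cells = np.asarray(cells, dtype=np.int8)
        if self.cells.shape != (len(self.species_names), len(self.character_names), 2):
            raise ValueError("cells shape does not match names")
        self.forbidden = frozenset(forbidden)  # (char_idx, species_idx) pairs

    # -- indexing helpers -------------------------------------------------
    @property
    def n(self) -> int:
        return self.cells.shape[0]

    @property
    def m(self) -> int:
        return self.cells.shape[1]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def character_index(self, name: str) -> int:
        try:
            return self.character_names.index(name)
        except ValueError:
            raise KeyError(f"unknown character {name!r}") from None

    def _resolve(self, s, c):
        if isinstance(s, str):
            s = self.species_index(s)
        if isinstance(c, str):
            c = self.character_index(c)
        return s, c

    def pair(self, s, c):
        """Return the (c+, c-) cell pair for species s as a tuple of ints (-1 = ?)."""
        s, c = self._resolve(s, c)
        return int(self.cells[s, c, 0]), int(self.cells[s, c, 1])

    def is_incomplete(self, s, c) -> bool:
        s, c = self._resolve(s, c)
        return self.cells[s, c, 0] == UNKNOWN

    def incomplete_pairs(self):
        """All (species_name, character_name) pairs still (?,?), sorted by name."""
        out = [
            (self.species_names[s], self.character_names[c])
            for s in range(self.n)
            for c in range(self.m)
            if self.cells[s, c, 0] == UNKNOWN
        ]
        return sorted(out)

    def is_complete(self) -> bool:
        return not (self.cells == UNKNOWN).any()

    def is_constrained(self, s, c) -> bool:
        s, c = self._resolve(s, c)
        return (c, s) in self.forbidden

    # -- mutation ---------------------------------------------------------
    def complete(self, s, c, persistent: bool) -> None:
        """Complete the (?,?) pair of (s, c): (1,1) if persistent else (0,0)."""
        s, c = self._resolve(s, c)
        if self.cells[s, c, 0] != UNKNOWN:
            raise IllegalRecompletionError(
                f"pair ({self.species_names[s]}, {self.character_names[c]}) "
                f"is already completed as {self.pair(s, c)}"
            )
        if persistent and (c, s) in self.forbidden:
            raise ConstraintViolationError(
                f"({self.character_names[c]}, {self.species_names[s]}) is "
                "constrained and cannot be completed as persistent"
            )
        v = 1 if persistent else 0
        self.cells[s, c, 0] = v
        self.cells[s, c, 1] = v

    def copy(self) -> "ExtendedMatrix":
        return ExtendedMatrix(
            self.species_names, self.character_names, self.cells.copy(), self.forbidden
        )

    # -- views ------------------------------------------------------------
    def flat(self) -> np.ndarray:
        """The n × 2m view with columns ordered c1+, c1-, c2+, c2-, ..."""
        return self.cells.reshape(self.n, 2 * self.m)

    def flat_column_names(self):
        out = []
        for c in self.character_names:
            out.append(f"{c}+")
            out.append(f"{c}-")
        return out

    def restrict_to_binary(self) -> BinaryMatrix:
        """Recover the original matrix from the (1,0)/(?,?)-or-(0,0) pattern.

        M[s,c] = 1 exactly where the pair is (1,0).
        """
        data = (self.cells[:, :, 0] == 1) & (self.cells[:, :, 1] == 0)
        return BinaryMatrix(
            data.astype(np.int8), self.species_names, self.character_names
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExtendedMatrix)
            and self.species_names == other.species_names
            and self.character_names == other.character_names
            and np.array_equal(self.cells, other.cells)
            and self.forbidden == other.forbidden
        )

    def __repr__(self) -> str:
        q = int((self.cells[:, :, 0] == UNKNOWN).sum())
        return f"ExtendedMatrix({self.n}x2*{self.m}, {q} incomplete pairs)"


def build_extended_matrix(M: BinaryMatrix, F: ConstraintSet = ConstraintSet()) -> ExtendedMatrix:
    """Build the extended matrix of (M, F).

    M[s,c] = 1 → (1, 0); M[s,c] = 0 and (c,s) ∈ F → (0, 0) pinned;
    M[s,c] = 0 otherwise → (?, ?).
    """
    F.validate(M)
    n, m = M.n, M.m
    cells = np.full((n, m, 2), UNKNOWN, dtype=np.int8)
    ones = M.data == 1
    cells[ones, 0] = 1
    cells[ones, 1] = 0
    forbidden = set()
    for c_name, s_name in F:
        s = M.species_index(s_name)
        c = M.character_index(c_name)
        cells[s, c, :] = 0
        forbidden.add((c, s))
    return ExtendedMatrix(M.species_names, M.character_names, cells, frozenset(forbidden))


def complete_pair(Me: ExtendedMatrix, s, c, mode: str) -> ExtendedMatrix:
    """Pure completion of one conjugate pair; returns a new matrix.

    mode is 'persistent' → (1,1) or 'not-persistent' → (0,0).
    """
    if mode not in ("persistent", "not-persistent"):
        raise ValueError(f"unknown completion mode {mode!r}")
    out = Me.copy()
    out.complete(s, c, persistent=(mode == "persistent"))
    return out


def _forbidden_pair_matrix(A: np.ndarray) -> np.ndarray:
    """Boolean k×k matrix: True where columns i, j jointly show (1,1), (1,0), (0,1)."""
    A = A.astype(np.int32)
    B = 1 - A
    c11 = (A.T @ A) > 0
    c10 = (A.T @ B) > 0
    return c11 & c10 & c10.T


def admits_directed_pp(Me: ExtendedMatrix) -> bool:
    """Does the fully completed 2m-column matrix admit a directed perfect phylogeny?

    A directed (all-zero-root) perfect phylogeny exists iff no two columns
    jointly exhibit all three configurations (0,1), (1,0), (1,1) — i.e. the
    column 1-sets form a laminar family.
    """
    if not Me.is_complete():
        raise IncompleteMatrixError("matrix still contains '?' cells")
    bad = _forbidden_pair_matrix(Me.flat())
    np.fill_diagonal(bad, False)
    return not bad.any()


def deduplicate(M: BinaryMatrix):
    """Remove duplicated rows and columns, keeping first occurrences.

    Returns (M', row_map, col_map) where the maps send each removed name to
    the name of its kept representative (identity for kept names).
    """
    row_map, keep_rows, seen = {}, [], {}
    for i, name in enumerate(M.species_names):
        key = M.data[i, :].tobytes()
        if key in seen:
            row_map[name] = M.species_names[seen[key]]
        else:
            seen[key] = i
            keep_rows.append(i)
            row_map[name] = name
    sub = M.data[keep_rows, :]
    col_map, keep_cols, seen_c = {}, [], {}
    for j, name in enumerate(M.character_names):
        key = sub[:, j].tobytes()
        if key in seen_c:
            col_map[name] = M.character_names[seen_c[key]]
        else:
            seen_c[key] = j
            keep_cols.append(j)
            col_map[name] = name
    out = BinaryMatrix(
        sub[:, keep_cols],
        [M.species_names[i] for i in keep_rows],
        [M.character_names[j] for j in keep_cols],
    )
    return out, row_map, col_map
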