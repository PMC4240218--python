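"""Reading and writing matrices, constraints, extended matrices and the
general-character-compatibility (GCC) export.

Matrix formats: ``plain`` (whitespace-separated 0/1 rows), ``csv`` and
``tsv``.  An optional first header line of character names and an optional
first column of species names are auto-detected by non-binary tokens.
Species are always rows and characters columns; transposed input is never
guessed at.

The GCC export maps a constrained instance to the set-valued compatibility
formulation: a 1-cell becomes {1}, a constrained 0-cell {0}, any other
0-cell {0, 2}, with allowed state transitions 0→1 and 1→2 (state 2 plays the
role of "had it, lost it").
"""

from __future__ import annotations

import csv as _csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

from .matrix import (
    BinaryMatrix,
    ConstraintSet,
    CpppError,
    ExtendedMatrix,
    SignedCharacter,
)

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_constraints",
    "write_constraints",
    "GccInstance",
    "export_gcc",
    "write_gcc",
    "write_extended",
    "write_reduction",
    "read_reduction",
]


class MatrixParseError(CpppError):
    pass


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".tsv":
        return "tsv"
    return "plain"


def _tokenize(path, fmt: str) -> List[List[str]]:
    text = Path(path).read_text()
    rows: List[List[str]] = []
    if fmt in ("csv", "tsv"):
        delim = "," if fmt == "csv" else "\t"
        for row in _csv.reader(text.splitlines(), delimiter=delim):
            if row and any(tok.strip() for tok in row):
                rows.append([tok.strip() for tok in row])
    else:
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                rows.append(line.split())
    return rows


def read_matrix(path, fmt: Optional[str] = None) -> BinaryMatrix:
    """Parse a binary matrix; see the module docstring for format rules."""
    fmt = _infer_format(path, fmt)
    rows = _tokenize(path, fmt)
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix file")
    def is_binary(tok: str) -> bool:
        return tok in ("0", "1")

    header: Optional[List[str]] = None
    if not all(is_binary(t) for t in rows[0]):
        # first line contains a non-binary token → header of character names
        header = rows[0]
        rows = rows[1:]
        if not rows:
            raise MatrixParseError(f"{path}: header but no data rows")
    row_names: Optional[List[str]] = None
    if any(not is_binary(r[0]) for r in rows):
        row_names = [r[0] for r in rows]
        rows = [r[1:] for r in rows]
        if header is not None and len(header) == len(rows[0]) + 1:
            header = header[1:]  # header had a corner label for the name column
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MatrixParseError(f"{path}: ragged rows (widths {sorted(widths)})")
    for i, r in enumerate(rows):
        for j, tok in enumerate(r):
            if not is_binary(tok):
                raise MatrixParseError(
                    f"{path}: non-binary token {tok!r} at data row {i + 1}, "
                    f"column {j + 1}"
                )
    data = [[int(tok) for tok in r] for r in rows]
    if header is not None and len(header) != len(rows[0]):
        raise MatrixParseError(
            f"{path}: header names {len(header)} columns but rows have "
            f"{len(rows[0])}"
        )
    return BinaryMatrix(data, species_names=row_names, character_names=header)


def write_matrix(M: BinaryMatrix, path, fmt: Optional[str] = None,
                 names: bool = True) -> None:
    fmt = _infer_format(path, fmt)
    delim = {"csv": ",", "tsv": "\t", "plain": " "}[fmt]
    lines = []
    if names:
        lines.append(delim.join(("id",) + M.character_names))
    for i, s in enumerate(M.species_names):
        row = [str(int(v)) for v in M.data[i, :]]
        lines.append(delim.join(([s] if names else []) + row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraints(path, M: BinaryMatrix) -> ConstraintSet:
    """One constraint per line: ``species character``; # comments allowed."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        if len(toks) != 2:
            raise MatrixParseError(
                f"{path}:{lineno}: expected 'species character', got {line!r}"
            )
        s, c = toks
        M.species_index(s)  # raises KeyError on unknown names
        M.character_index(c)
        pairs.append((c, s))
    F = ConstraintSet(pairs)
    F.validate(M)
    return F


def write_constraints(F: ConstraintSet, path) -> None:
    lines = [f"{s} {c}" for c, s in F]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass(frozen=True)
class GccInstance:
    """Set-valued compatibility instance over states {0, 1, 2}."""

    species_names: tuple
    character_names: tuple
    cell_states: tuple  # n × m nested tuples of state tuples
    transitions: tuple = ((0, 1), (1, 2))

    def histogram(self) -> dict:
        counts = {}
        for row in self.cell_states:
            for states in row:
                counts[states] = counts.get(states, 0) + 1
        return counts


def export_gcc(M: BinaryMatrix, F: ConstraintSet = ConstraintSet()) -> GccInstance:
    F.validate(M)
    cells = []
    for s in M.species_names:
        row = []
        for c in M.character_names:
            if M[s, c] == 1:
                row.append((1,))
            elif (c, s) in F:
                row.append((0,))
            else:
                row.append((0, 2))
        cells.append(tuple(row))
    return GccInstance(M.species_names, M.character_names, tuple(cells))


def write_gcc(instance: GccInstance, path) -> None:
    payload = {
        "species": list(instance.species_names),
        "characters": list(instance.character_names),
        "cells": [[list(states) for states in row] for row in instance.cell_states],
        "transitions": [list(t) for t in instance.transitions],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_extended(Me: ExtendedMatrix, path) -> None:
    """CSV dump of the n × 2m matrix; '?' is written literally."""
    def cell(v: int) -> str:
        return "?" if v < 0 else str(int(v))

    lines = [",".join(["id"] + Me.flat_column_names())]
    flat = Me.flat()
    for i, s in enumerate(Me.species_names):
        lines.append(",".join([s] + [cell(v) for v in flat[i, :]]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_reduction(seq: Sequence[SignedCharacter], path) -> None:
    Path(path).write_text(" ".join(str(x) for x in seq) + "\n")


def read_reduction(path) -> List[SignedCharacter]:
    return [SignedCharacter.parse(tok) for tok in Path(path).read_text().split()]
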