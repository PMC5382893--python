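"""Reading, writing and basic transforms of bipartite interaction matrices.

An interaction matrix records observed interaction values between two guilds
of species (e.g. plants x pollinators).  Nonzero entries are *positive*
interactions (observed links), zeros are *negative* interactions (unobserved
links) in the statistical sense; a zero may be a true negative (the species
cannot interact) or a false negative (undersampling).  There is no NA
sentinel: an unobserved cell is a zero.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "InteractionMatrix",
    "ForbiddenMask",
    "read_matrix",
    "write_matrix",
    "read_mask",
    "write_mask",
    "binarize",
    "density",
]


@dataclasses.dataclass
class InteractionMatrix:
    """An n x m non-negative interaction matrix with species labels.

    Parameters
    ----------
    values : ndarray of shape (n, m)
        Interaction values Y_ij; unitless counts or strengths, finite, >= 0.
    row_labels, col_labels : sequence of str
        Unique species identifiers per axis.
    name : str
        Free-text dataset identifier.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("interaction matrix must be two-dimensional")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError(f"matrix must be at least 2x2, got {n}x{m}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at cell ({i}, {j})")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at cell ({i}, {j}); "
                "interaction values must be >= 0"
            )
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]
        if len(self.row_labels) != n:
            raise ValueError(f"{len(self.row_labels)} row labels for {n} rows")
        if len(self.col_labels) != m:
            raise ValueError(f"{len(self.col_labels)} column labels for {m} columns")
        for axis, labels in (("row", self.row_labels), ("column", self.col_labels)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {axis} labels")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def positive_mask(self) -> np.ndarray:
        """Boolean mask of positive (observed) interactions."""
        return self.values > 0

    def with_values(self, values: np.ndarray, name: str | None = None) -> "InteractionMatrix":
        """New matrix with the same labels and different values."""
        return InteractionMatrix(
            values=np.asarray(values, dtype=float),
            row_labels=list(self.row_labels),
            col_labels=list(self.col_labels),
            name=self.name if name is None else name,
        )


@dataclasses.dataclass
class ForbiddenMask:
    """Boolean mask of known true negatives (forbidden links).

    A flagged cell marks a species pair that genuinely cannot interact, e.g.
    through phenological uncoupling or a morphological mismatch.  Flags are
    only meaningful on zero cells of the paired matrix; flagging a positive
    cell is an error (`validate_for`).
    """

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError("forbidden mask must be two-dimensional")

    def validate_for(self, matrix: InteractionMatrix) -> None:
        if self.flags.shape != matrix.shape:
            raise ValueError(
                f"mask shape {self.flags.shape} does not match matrix {matrix.shape}"
            )
        bad = self.flags & matrix.positive_mask
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"cell ({i}, {j}) is flagged forbidden but holds a positive "
                f"interaction value {matrix.values[i, j]}"
            )


def _read_grid(path: str | Path, delimiter: str) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter) if row]
    if not rows:
        raise ValueError(f"{path}: empty file")
    width = len(rows[0])
    for k, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: non-rectangular table, row {k + 1} has "
                f"{len(row)} cells, expected {width}"
            )
    return rows


def _parse_cells(rows: list[list[str]], path: str | Path) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0])), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{path}: invalid value {cell!r} at row {i}, column {j}; "
                    "cells must be finite and >= 0"
                )
            out[i, j] = v
    return out


def read_matrix(
    path: str | Path,
    delimiter: str = ",",
    has_labels: bool = True,
    name: str | None = None,
) -> InteractionMatrix:
    """Read a delimited-text interaction matrix.

    With ``has_labels`` the first row holds column labels and the first column
    row labels (the top-left cell is ignored); otherwise labels are generated
    as ``R1..Rn`` / ``C1..Cm``.
    """
    rows = _read_grid(path, delimiter)
    if has_labels:
        if len(rows) < 3 or len(rows[0]) < 3:
            raise ValueError(f"{path}: labelled matrix needs at least 3x3 cells")
        col_labels = rows[0][1:]
        row_labels = [r[0] for r in rows[1:]]
        values = _parse_cells([r[1:] for r in rows[1:]], path)
    else:
        values = _parse_cells(rows, path)
        row_labels = [f"R{i + 1}" for i in range(values.shape[0])]
        col_labels = [f"C{j + 1}" for j in range(values.shape[1])]
    return InteractionMatrix(
        values=values,
        row_labels=row_labels,
        col_labels=col_labels,
        name=name if name is not None else Path(path).stem,
    )


def write_matrix(
    matrix: InteractionMatrix, path: str | Path, delimiter: str = ","
) -> None:
    """Write a labelled delimited-text matrix at full float precision.

    ``repr`` formatting is used so that read_matrix(write_matrix(M)) == M
    exactly for any representable values.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([""] + list(matrix.col_labels))
        for label, row in zip(matrix.row_labels, matrix.values):
            writer.writerow([label] + [repr(float(v)) for v in row])


def read_mask(
    path: str | Path,
    matrix: InteractionMatrix | None = None,
    delimiter: str = ",",
    has_labels: bool = True,
) -> ForbiddenMask:
    """Read a same-shaped 0/1 grid of forbidden links.

    Cells must be exactly 0 or 1.  If ``matrix`` is given the mask is
    validated against it (shape match; no flag on a positive cell).
    """
    rows = _read_grid(path, delimiter)
    if has_labels:
        rows = [r[1:] for r in rows[1:]]
    values = _parse_cells(rows, path)
    bad = (values != 0) & (values != 1)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: mask cell at row {i}, column {j} is {values[i, j]}; "
            "must be 0 or 1"
        )
    mask = ForbiddenMask(flags=values.astype(bool))
    if matrix is not None:
        mask.validate_for(matrix)
    return mask


def write_mask(
    mask: ForbiddenMask,
    path: str | Path,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
    delimiter: str = ",",
) -> None:
    n, m = mask.flags.shape
    row_labels = list(row_labels) if row_labels is not None else [f"R{i+1}" for i in range(n)]
    col_labels = list(col_labels) if col_labels is not None else [f"C{j+1}" for j in range(m)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([""] + col_labels)
        for label, row in zip(row_labels, mask.flags.astype(int)):
            writer.writerow([label] + [str(v) for v in row])


def binarize(matrix: InteractionMatrix) -> InteractionMatrix:
    """Set every strictly positive entry to one; zeros stay zero.

    The threshold is exact zero: values are counts or strengths and no
    epsilon is applied.
    """
    return matrix.with_values((matrix.values > 0).astype(float))


def density(matrix: InteractionMatrix) -> float:
    """Fraction of cells holding a positive interaction (rho, in [0, 1])."""
    return float(np.count_nonzero(matrix.values > 0)) / matrix.values.size
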