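"""The four-term linear filter and its closed-form leave-one-out imputation.

The filter replaces every entry of a bipartite interaction matrix Y with a
weighted average of four quantities::

    F_ij = a1 * Y_ij + a2 * mean(column j) + a3 * mean(row i) + a4 * mean(Y)

The column and row means capture the promiscuity (generalism) of the two
species, the global mean the overall density of the network.

To score a cell without using its own observed value, the entry is *imputed*:
beta is the value that, substituted at (i, j) and passed through the filter,
comes back unchanged.  Solving this scalar fixed-point equation gives the
closed form

    beta = [ (a2/n) C' + (a3/m) R' + (a4/(n m)) T' ] / D
    D    = 1 - a1 - a2/n - a3/m - a4/(n m)

where C', R', T' are the column, row and total sums *excluding* Y_ij.  The
result is independent of the stored Y_ij, which is what makes it a
leave-one-out (LOO) score: a zero cell with a high beta is a candidate false
negative.  This is the classic LOO shortcut — all n*m imputations come from
one pass over the matrix instead of n*m refits.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix_io import ForbiddenMask, InteractionMatrix

__all__ = [
    "FilterParams",
    "ScoreMatrix",
    "LinearFilter",
    "apply_filter",
    "loo_impute_entry",
    "loo_impute_oracle",
    "loo_impute_all",
    "rank_negatives",
    "write_ranking",
]


@dataclasses.dataclass(frozen=True)
class FilterParams:
    """Weights of the four filter terms (all unitless, >= 0).

    alpha1 weighs the observed value itself, alpha2 the column average,
    alpha3 the row average, alpha4 the global average.  The default
    (0.25, 0.25, 0.25, 0.25) reduces the filter to a plain average of the
    four terms.  Weights need not sum to one (a warning is emitted if they
    do not), but at least one of alpha2..alpha4 must be positive, otherwise
    the imputation would be identically zero.
    """

    alpha1: float = 0.25
    alpha2: float = 0.25
    alpha3: float = 0.25
    alpha4: float = 0.25

    def __post_init__(self) -> None:
        vals = (self.alpha1, self.alpha2, self.alpha3, self.alpha4)
        if any(not np.isfinite(a) or a < 0 for a in vals):
            raise ValueError(f"filter weights must be finite and >= 0, got {vals}")
        if self.alpha2 == 0 and self.alpha3 == 0 and self.alpha4 == 0:
            raise ValueError(
                "at least one of alpha2, alpha3, alpha4 must be positive; "
                "otherwise LOO imputation is degenerate (identically zero)"
            )
        if abs(sum(vals) - 1.0) > 1e-9:
            warnings.warn(
                f"filter weights sum to {sum(vals)}, not 1; the filter is then "
                "not a weighted average",
                stacklevel=3,
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3, self.alpha4)

    def loo_denominator(self, n: int, m: int) -> float:
        """D = 1 - a1 - a2/n - a3/m - a4/(n m); must be > 0 for LOO."""
        return 1.0 - self.alpha1 - self.alpha2 / n - self.alpha3 / m - self.alpha4 / (n * m)


DEFAULT_PARAMS = FilterParams()


@dataclasses.dataclass
class ScoreMatrix:
    """Per-cell scores aligned with an InteractionMatrix.

    ``mode`` is "filtered" for the plain filter output F and "loo" for the
    leave-one-out imputation beta.  ``params`` is None for scores not
    produced by the linear filter (e.g. the SVD baseline).
    """

    scores: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    params: FilterParams | None
    mode: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.mode not in ("filtered", "loo"):
            raise ValueError(f"mode must be 'filtered' or 'loo', got {self.mode!r}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.scores.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("scores shape does not match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def to_matrix(self, name: str = "") -> InteractionMatrix:
        """View as an InteractionMatrix for writing (scores must be >= 0)."""
        return InteractionMatrix(
            values=self.scores, row_labels=self.row_labels,
            col_labels=self.col_labels, name=name,
        )


class LinearFilter(TransformerMixin, BaseEstimator):
    """Linear matrix filter / LOO imputer as a scikit-learn transformer.

    The transformer is stateless with respect to training data (like
    ``sklearn.preprocessing.Normalizer``): ``transform(X)`` filters or
    LOO-imputes the matrix X it is given, using only X itself.

    Parameters
    ----------
    alpha1, alpha2, alpha3, alpha4 : float, default 0.25
        Weights of the observed value, column mean, row mean and global mean.
    mode : {"loo", "filtered"}, default "loo"
        "filtered" applies the plain filter; "loo" returns for every cell the
        closed-form leave-one-out imputation, which does not depend on that
        cell's observed value.

    Attributes
    ----------
    n_rows_, n_cols_ : int
        Shape of the matrix seen in ``fit``.
    denominator_ : float
        The LOO denominator D for that shape (mode "loo" only); fitting
        fails if D <= 0, which signals alpha1 too close to 1.
    """

    def __init__(
        self,
        alpha1: float = 0.25,
        alpha2: float = 0.25,
        alpha3: float = 0.25,
        alpha4: float = 0.25,
        mode: str = "loo",
    ) -> None:
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.alpha3 = alpha3
        self.alpha4 = alpha4
        self.mode = mode

    def _params(self) -> FilterParams:
        return FilterParams(self.alpha1, self.alpha2, self.alpha3, self.alpha4)

    def fit(self, X, y=None) -> "LinearFilter":
        X = check_array(X, dtype=float)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError(f"matrix must be at least 2x2, got {X.shape}")
        params = self._params()
        if self.mode not in ("loo", "filtered"):
            raise ValueError(f"mode must be 'loo' or 'filtered', got {self.mode!r}")
        n, m = X.shape
        self.n_rows_, self.n_cols_ = n, m
        if self.mode == "loo":
            D = params.loo_denominator(n, m)
            if D <= 0:
                raise ValueError(
                    f"LOO denominator D = {D} <= 0 for shape {n}x{m}; "
                    "alpha1 is too close to 1 for this matrix size"
                )
            self.denominator_ = D
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_rows_")
        X = check_array(X, dtype=float)
        params = self._params()
        if self.mode == "filtered":
            return _filter_values(X, params)
        return _loo_values(X, params)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).transform(X)


def _filter_values(values: np.ndarray, p: FilterParams) -> np.ndarray:
    col_means = values.mean(axis=0, keepdims=True)
    row_means = values.mean(axis=1, keepdims=True)
    return (
        p.alpha1 * values
        + p.alpha2 * col_means
        + p.alpha3 * row_means
        + p.alpha4 * values.mean()
    )


def _loo_values(values: np.ndarray, p: FilterParams) -> np.ndarray:
    n, m = values.shape
    D = p.loo_denominator(n, m)
    if D <= 0:
        raise ValueError(
            f"LOO denominator D = {D} <= 0 for shape {n}x{m}; "
            "alpha1 is too close to 1 for this matrix size"
        )
    col_excl = values.sum(axis=0, keepdims=True) - values  # C'
    row_excl = values.sum(axis=1, keepdims=True) - values  # R'
    tot_excl = values.sum() - values                       # T'
    numer = (
        p.alpha2 / n * col_excl
        + p.alpha3 / m * row_excl
        + p.alpha4 / (n * m) * tot_excl
    )
    return numer / D


def apply_filter(
    matrix: InteractionMatrix, params: FilterParams | None = None
) -> ScoreMatrix:
    """Apply the four-term filter to every cell (no leave-one-out)."""
    p = params or DEFAULT_PARAMS
    est = LinearFilter(*p.as_tuple(), mode="filtered")
    return ScoreMatrix(
        scores=est.fit_transform(matrix.values),
        row_labels=list(matrix.row_labels),
        col_labels=list(matrix.col_labels),
        params=p,
        mode="filtered",
    )


def loo_impute_all(
    matrix: InteractionMatrix, params: FilterParams | None = None
) -> ScoreMatrix:
    """Closed-form LOO imputation of every cell in O(n m) total time."""
    p = params or DEFAULT_PARAMS
    est = LinearFilter(*p.as_tuple(), mode="loo")
    return ScoreMatrix(
        scores=est.fit_transform(matrix.values),
        row_labels=list(matrix.row_labels),
        col_labels=list(matrix.col_labels),
        params=p,
        mode="loo",
    )


def loo_impute_entry(
    matrix: InteractionMatrix,
    row: int,
    col: int,
    params: FilterParams | None = None,
) -> float:
    """Closed-form LOO imputation of a single cell.

    The excluded sums are computed on a copy with the cell zeroed, so the
    stored value Y_ij never enters the arithmetic: the result is bit-for-bit
    invariant under any overwrite of Y_ij, however extreme.
    """
    p = params or DEFAULT_PARAMS
    values = matrix.values
    n, m = values.shape
    if not (0 <= row < n and 0 <= col < m):
        raise IndexError(f"cell ({row}, {col}) outside {n}x{m} matrix")
    D = p.loo_denominator(n, m)
    if D <= 0:
        raise ValueError(
            f"LOO denominator D = {D} <= 0 for shape {n}x{m}; "
            "alpha1 is too close to 1 for this matrix size"
        )
    tmp = values.copy()
    tmp[row, col] = 0.0
    col_excl = tmp[:, col].sum()
    row_excl = tmp[row, :].sum()
    tot_excl = tmp.sum()
    numer = p.alpha2 / n * col_excl + p.alpha3 / m * row_excl + p.alpha4 / (n * m) * tot_excl
    return float(numer / D)


def loo_impute_oracle(
    matrix: InteractionMatrix,
    row: int,
    col: int,
    params: FilterParams | None = None,
    method: str = "solve",
    tol: float = 1e-14,
    max_iter: int = 10_000,
) -> float:
    """Numerically solve the defining fixed-point equation for beta.

    beta is defined by: substitute beta at (row, col), apply the filter at
    that cell, and require the output to equal beta.  This routine treats the
    filter as a black box and never uses the closed-form shortcut, so it
    serves as an independent oracle for ``loo_impute_entry``.

    method="solve" evaluates the (affine) map g at 0 and 1 and solves
    g(beta) = beta exactly; method="iterate" iterates beta <- g(beta) from 0,
    which converges because |g'| = a1 + a2/n + a3/m + a4/(nm) = 1 - D < 1
    whenever D > 0.
    """
    p = params or DEFAULT_PARAMS
    values = matrix.values
    n, m = values.shape
    D = p.loo_denominator(n, m)
    if D <= 0:
        raise ValueError(f"fixed point does not exist/converge: D = {D} <= 0")

    def g(beta: float) -> float:
        tmp = values.copy()
        tmp[row, col] = beta
        return float(
            p.alpha1 * beta
            + p.alpha2 * tmp[:, col].mean()
            + p.alpha3 * tmp[row, :].mean()
            + p.alpha4 * tmp.mean()
        )

    if method == "solve":
        g0 = g(0.0)
        slope = g(1.0) - g0
        return g0 / (1.0 - slope)
    if method == "iterate":
        beta = 0.0
        for _ in range(max_iter):
            new = g(beta)
            if abs(new - beta) <= tol * max(1.0, abs(new)):
                return new
            beta = new
        raise RuntimeError(f"fixed-point iteration did not converge in {max_iter} steps")
    raise ValueError(f"unknown method {method!r}")


def rank_negatives(
    matrix: InteractionMatrix,
    scores: ScoreMatrix,
    exclude: ForbiddenMask | None = None,
) -> list[tuple[str, str, float]]:
    """Rank the zero cells by LOO score, best candidates first.

    Returns (row_label, col_label, score) triples for every negative
    (zero) cell not covered by ``exclude``, sorted by score descending with
    deterministic positional tie-breaking (row index, then column index).
    High-ranking cells are the candidate false negatives.
    """
    if scores.mode != "loo":
        raise ValueError(f"rank_negatives requires loo scores, got mode {scores.mode!r}")
    if scores.shape != matrix.shape:
        raise ValueError(
            f"score shape {scores.shape} does not match matrix {matrix.shape}"
        )
    keep = ~matrix.positive_mask
    if exclude is not None:
        exclude.validate_for(matrix)
        keep &= ~exclude.flags
    cells = np.argwhere(keep)
    order = sorted(
        range(len(cells)),
        key=lambda k: (-scores.scores[cells[k][0], cells[k][1]], cells[k][0], cells[k][1]),
    )
    return [
        (
            matrix.row_labels[cells[k][0]],
            matrix.col_labels[cells[k][1]],
            float(scores.scores[cells[k][0], cells[k][1]]),
        )
        for k in order
    ]


def write_ranking(
    ranking: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write a ranked candidate list as TSV (score with 6 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row_label\tcol_label\tscore\n")
        for row_label, col_label, score in ranking:
            fh.write(f"{row_label}\t{col_label}\t{score:.6g}\n")
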