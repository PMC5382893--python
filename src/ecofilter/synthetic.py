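"""Seeded generators of bipartite interaction matrices with known structure.

Real species interaction networks are sparse and structured — nested
(specialists interact with subsets of the partners of generalists) or
modular (interactions concentrate in blocks, e.g. pollination syndromes).
This module builds such matrices with controllable size, density and
interaction-strength noise, plants false negatives by zeroing known
positives, and places forbidden-link masks, so that every experiment in the
package can run end to end without external data.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` so sub-draws are reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .matrix_io import ForbiddenMask, InteractionMatrix

__all__ = [
    "SyntheticConfig",
    "generate",
    "plant_false_negatives",
    "make_forbidden_mask",
]

_STRUCTURES = ("nested", "modular", "random")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic bipartite network.

    target_density is the desired fraction of positive cells; the generator
    places exactly round(target_density * n * m) positives for the nested and
    random structures.  strength_noise is the sigma of the lognormal
    multiplicative noise applied to positive entries (0 keeps the matrix
    binary).  n_modules is used by the modular structure only.
    """

    n_rows: int
    n_cols: int
    structure: str = "nested"
    target_density: float = 0.25
    n_modules: int = 2
    strength_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("n_rows and n_cols must be >= 2")
        if self.structure not in _STRUCTURES:
            raise ValueError(
                f"structure must be one of {_STRUCTURES}, got {self.structure!r}"
            )
        if not 0 < self.target_density < 1:
            raise ValueError(f"target_density must be in (0, 1), got {self.target_density}")
        if self.structure == "modular" and not (
            1 <= self.n_modules <= min(self.n_rows, self.n_cols)
        ):
            raise ValueError(
                f"n_modules must be in [1, {min(self.n_rows, self.n_cols)}]"
            )
        if self.strength_noise < 0:
            raise ValueError("strength_noise must be >= 0")


def _nested_cells(n: int, m: int, n_pos: int) -> np.ndarray:
    """Flat indices of a perfectly nested staircase with n_pos positives.

    Cells are ranked by (i+0.5)/n + (j+0.5)/m and the n_pos lowest taken:
    the positive region is then downward-closed in both indices, so each
    row's positive set is a prefix of the columns and rows are in
    containment order.
    """
    i = np.arange(n)[:, None]
    j = np.arange(m)[None, :]
    depth = ((i + 0.5) / n + (j + 0.5) / m).ravel()
    order = np.lexsort((np.arange(n * m), depth))
    return order[:n_pos]


def generate(config: SyntheticConfig) -> InteractionMatrix:
    """Generate one matrix; deterministic given the config (incl. seed)."""
    n, m = config.n_rows, config.n_cols
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_pos = int(round(config.target_density * n * m))
    n_pos = min(max(n_pos, 1), n * m - 1)

    values = np.zeros(n * m)
    if config.structure == "nested":
        cells = _nested_cells(n, m, n_pos)
    elif config.structure == "random":
        cells = rng.choice(n * m, size=n_pos, replace=False)
    else:  # modular: block-diagonal positives
        row_block = np.arange(n) * config.n_modules // n
        col_block = np.arange(m) * config.n_modules // m
        within = np.nonzero(
            (row_block[:, None] == col_block[None, :]).ravel()
        )[0]
        if n_pos > within.size:
            raise ValueError(
                f"target density {config.target_density} needs {n_pos} positives "
                f"but only {within.size} within-module cells exist; "
                "reduce density or n_modules"
            )
        cells = rng.choice(within, size=n_pos, replace=False)

    if config.strength_noise > 0:
        values[cells] = rng.lognormal(mean=0.0, sigma=config.strength_noise, size=cells.size)
    else:
        values[cells] = 1.0

    return InteractionMatrix(
        values=values.reshape(n, m),
        row_labels=[f"R{i + 1}" for i in range(n)],
        col_labels=[f"C{j + 1}" for j in range(m)],
        name=f"synthetic-{config.structure}-{n}x{m}-seed{config.seed}",
    )


def plant_false_negatives(
    matrix: InteractionMatrix, fraction: float, seed: int
) -> tuple[InteractionMatrix, list[tuple[int, int]]]:
    """Zero a random fraction of the positive cells.

    Removes round(fraction * #positives), at least 1, positives chosen
    uniformly without replacement; at least one positive must remain.
    Returns the degraded matrix and the planted (row, col) cells.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    positives = np.argwhere(matrix.positive_mask)
    n_pos = len(positives)
    if n_pos < 2:
        raise ValueError("need at least 2 positives to plant false negatives")
    k = max(1, int(round(fraction * n_pos)))
    if k >= n_pos:
        raise ValueError(
            f"fraction {fraction} would remove all {n_pos} positives"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = positives[rng.choice(n_pos, size=k, replace=False)]
    degraded = matrix.values.copy()
    degraded[chosen[:, 0], chosen[:, 1]] = 0.0
    return (
        matrix.with_values(degraded, name=f"{matrix.name}-degraded"),
        [(int(i), int(j)) for i, j in chosen],
    )


def make_forbidden_mask(
    matrix: InteractionMatrix,
    fraction_of_negatives: float,
    placement: str = "lowest_degree",
    seed: int = 0,
) -> ForbiddenMask:
    """Flag a fraction of the zero cells as forbidden links.

    placement="lowest_degree" flags the zero cells with the smallest
    row-sum + column-sum (mimicking pairs that are impossible through
    phenological or morphological mismatch); "random" flags uniformly.
    """
    if not 0 < fraction_of_negatives <= 1:
        raise ValueError(
            f"fraction_of_negatives must be in (0, 1], got {fraction_of_negatives}"
        )
    zeros = np.argwhere(~matrix.positive_mask)
    if len(zeros) == 0:
        raise ValueError("matrix has no zero cells to flag")
    k = max(1, int(round(fraction_of_negatives * len(zeros))))
    k = min(k, len(zeros))
    flags = np.zeros(matrix.shape, dtype=bool)
    if placement == "lowest_degree":
        row_sums = matrix.values.sum(axis=1)
        col_sums = matrix.values.sum(axis=0)
        degree = row_sums[zeros[:, 0]] + col_sums[zeros[:, 1]]
        order = np.lexsort((zeros[:, 1], zeros[:, 0], degree))
        chosen = zeros[order[:k]]
    elif placement == "random":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        chosen = zeros[rng.choice(len(zeros), size=k, replace=False)]
    else:
        raise ValueError(f"placement must be 'lowest_degree' or 'random', got {placement!r}")
    flags[chosen[:, 0], chosen[:, 1]] = True
    mask = ForbiddenMask(flags=flags)
    mask.validate_for(matrix)
    return mask
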