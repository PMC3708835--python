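"""Observed/expected intron density maps over (splice-site score, intron size).

Introns are partitioned into 20 equal-count fractions along each axis
(quantile bins; left-inclusive, last bin closed). The observed grid counts the
real (size, score) pairs per cell. The expected grid is the mean over
randomizations in which the pairing of sizes and scores is permuted uniformly —
both marginal distributions are preserved exactly — and each cell reports the
observed/expected ratio. Under independence of the two axes the ratio
converges to 1 everywhere; coupling concentrates mass on few cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DensityGrid", "make_density_grid", "locate_in_grid"]

N_BINS_DEFAULT = 20


@dataclass
class DensityGrid:
    """A bins x bins observed/expected intron density grid.

    ``axis_score`` / ``axis_size`` hold the (bins+1) quantile edges; rows index
    size bins, columns score bins. ``undefined`` marks 0/0 cells, where
    ``ratio`` is NaN by construction (never silently produced elsewhere).
    """

    axis_score: np.ndarray  # column edges
    axis_size: np.ndarray  # row edges
    obs: np.ndarray
    exp: np.ndarray
    ratio: np.ndarray
    undefined: np.ndarray
    n_randomizations: int
    seed: int
    n: int

    @property
    def bins(self) -> int:
        return self.obs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (row, col, obs, exp, ratio)."""
        rows, cols = np.indices(self.obs.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "obs": self.obs.ravel(),
                "exp": self.exp.ravel(),
                "ratio": self.ratio.ravel(),
            }
        )


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-inclusive quantile-bin assignment; last bin closed on the right."""
    idx = np.searchsorted(edges[1:-1], values, side="right")
    return np.clip(idx, 0, len(edges) - 2)


def make_density_grid(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    n_randomizations: int = 100,
    seed: int = 0,
    bins: int = N_BINS_DEFAULT,
) -> DensityGrid:
    """Build the observed/expected density grid from (size, score) pairs.

    Expected counts are the mean over *n_randomizations* uniform permutations
    of the score column against the size column.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("pairs must be an (n, 2) array of (size, score)")
    n = arr.shape[0]
    if n < bins * bins:
        raise ValueError(f"need at least {bins * bins} pairs for a {bins}x{bins} grid, got {n}")
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    sizes, scores = arr[:, 0], arr[:, 1]
    if np.unique(sizes).size < bins or np.unique(scores).size < bins:
        raise ValueError("too few distinct values on an axis; quantile bins collapse")

    q = np.linspace(0.0, 1.0, bins + 1)
    size_edges = np.quantile(sizes, q)
    score_edges = np.quantile(scores, q)
    row = _bin_index(sizes, size_edges)
    col = _bin_index(scores, score_edges)

    obs = np.zeros((bins, bins), dtype=float)
    np.add.at(obs, (row, col), 1.0)

    rng = np.random.default_rng(seed)
    exp = np.zeros((bins, bins), dtype=float)
    flat = np.zeros(bins * bins, dtype=np.int64)
    for _ in range(n_randomizations):
        perm_col = rng.permutation(col)
        flat[:] = 0
        np.add.at(flat, row * bins + perm_col, 1)
        exp += flat.reshape(bins, bins)
    exp /= n_randomizations

    undefined = (obs == 0) & (exp == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp > 0, obs / np.where(exp > 0, exp, 1.0), np.inf)
    ratio = np.where(undefined, np.nan, ratio)

    return DensityGrid(
        axis_score=score_edges,
        axis_size=size_edges,
        obs=obs,
        exp=exp,
        ratio=ratio,
        undefined=undefined,
        n_randomizations=n_randomizations,
        seed=seed,
        n=n,
    )


def locate_in_grid(grid: DensityGrid, size: float, score: float) -> tuple[int, int, float]:
    """Locate a (size, score) query; returns (row, col, ratio of that cell).

    Queries outside the data range are clamped to the boundary bin.
    """
    row = int(_bin_index(np.asarray([size]), grid.axis_size)[0])
    col = int(_bin_index(np.asarray([score]), grid.axis_score)[0])
    return row, col, float(grid.ratio[row, col])
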