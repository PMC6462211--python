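"""Nestedness by overlap and decreasing fill (NODF) and its weighted variant.

NODF scores, on a 0-100 scale, the degree to which the partner sets of
species with few interactions are subsets of the partner sets of species with
many.  Every unordered pair of rows and every unordered pair of columns
contributes: if the better-filled line of the pair has *strictly* larger fill,
the contribution is 100 x (shared presences) / (fill of the poorer line);
pairs with tied fill contribute 0 (the decreasing-fill condition).  The index
is the mean contribution over all r(r-1)/2 + c(c-1)/2 pairs.

The weighted variant (wNODF) applies the same pair scheme to the quantitative
matrix: a pair counts only if the marginal totals strictly decrease, and the
overlap numerator counts cells where the poorer line is positive but strictly
smaller than the richer line.  Ties in marginal totals contribute 0 in both
variants, which materially lowers the score of matrices with repeated
rows/columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network_model import BipartiteNetwork, binarize


@dataclass(frozen=True)
class NestednessValue:
    value: float
    variant: Literal["NODF", "wNODF"]
    n_row_pairs: int
    n_col_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0 + 1e-9:
            raise ValueError(f"nestedness out of [0, 100]: {self.value}")


def _as_matrix(x: BipartiteNetwork | np.ndarray) -> np.ndarray:
    w = x.weights if isinstance(x, BipartiteNetwork) else np.asarray(x, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError("nestedness requires a pruned matrix of at least 2x2")
    if (w.sum(axis=1) == 0).any() or (w.sum(axis=0) == 0).any():
        raise ValueError("matrix has empty rows or columns; prune first")
    return w


def _axis_paired_nodf(b: np.ndarray) -> float:
    """Sum of NODF pair contributions over row pairs of a binary matrix."""
    fill = b.sum(axis=1)
    overlap = b @ b.T  # shared presences for every row pair
    total = 0.0
    n = b.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            hi, lo = (i, j) if fill[i] > fill[j] else (j, i)
            if fill[hi] > fill[lo]:
                total += 100.0 * overlap[hi, lo] / fill[lo]
    return total


def nodf(b: BipartiteNetwork | np.ndarray) -> NestednessValue:
    """Binary NODF of a pruned incidence matrix (counts are binarized)."""
    m = binarize(_as_matrix(b))
    r, c = m.shape
    total = _axis_paired_nodf(m) + _axis_paired_nodf(m.T)
    n_pairs = r * (r - 1) // 2 + c * (c - 1) // 2
    return NestednessValue(total / n_pairs, "NODF", r * (r - 1) // 2, c * (c - 1) // 2)


def _axis_paired_wnodf(w: np.ndarray) -> float:
    totals = w.sum(axis=1)
    total = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            hi, lo = (i, j) if totals[i] > totals[j] else (j, i)
            if totals[hi] > totals[lo]:
                poor = w[lo]
                pos = poor > 0
                if pos.any():
                    total += 100.0 * np.count_nonzero(pos & (poor < w[hi])) / pos.sum()
    return total


def wnodf(w: BipartiteNetwork | np.ndarray) -> NestednessValue:
    """Weighted NODF of a pruned count matrix."""
    m = _as_matrix(w)
    r, c = m.shape
    total = _axis_paired_wnodf(m) + _axis_paired_wnodf(m.T)
    n_pairs = r * (r - 1) // 2 + c * (c - 1) // 2
    return NestednessValue(total / n_pairs, "wNODF", r * (r - 1) // 2, c * (c - 1) // 2)
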