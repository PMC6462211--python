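"""Shared fixtures and independent brute-force oracles.

The oracles re-derive each metric straight from its definition (explicit
pair-by-pair or cell-by-cell evaluation, exhaustive enumeration) and share no
code with the package implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


# -- brute-force metric oracles ---------------------------------------


def nodf_oracle(b: np.ndarray) -> float:
    """Pair-by-pair NODF straight from the definition."""
    b = (np.asarray(b) > 0).astype(int)
    contributions = []
    for mat in (b, b.T):
        n = mat.shape[0]
        fill = mat.sum(axis=1)
        for i, j in itertools.combinations(range(n), 2):
            hi, lo = (i, j) if fill[i] >= fill[j] else (j, i)
            if fill[hi] > fill[lo]:
                shared = int(((mat[hi] > 0) & (mat[lo] > 0)).sum())
                contributions.append(100.0 * shared / fill[lo])
            else:
                contributions.append(0.0)
    return float(np.mean(contributions))


def wnodf_oracle(w: np.ndarray) -> float:
    """Pair-by-pair weighted NODF straight from the definition."""
    w = np.asarray(w, dtype=float)
    contributions = []
    for mat in (w, w.T):
        n = mat.shape[0]
        totals = mat.sum(axis=1)
        for i, j in itertools.combinations(range(n), 2):
            hi, lo = (i, j) if totals[i] >= totals[j] else (j, i)
            if totals[hi] > totals[lo]:
                poor, rich = mat[lo], mat[hi]
                npos = int((poor > 0).sum())
                k = int(((poor > 0) & (poor < rich)).sum())
                contributions.append(100.0 * k / npos if npos else 0.0)
            else:
                contributions.append(0.0)
    return float(np.mean(contributions))


def barber_q_oracle(w: np.ndarray, row_mod, col_mod) -> float:
    """Cell-by-cell evaluation of the bipartite modularity sum."""
    w = np.asarray(w, dtype=float)
    F = w.sum()
    K = w.sum(axis=1)
    L = w.sum(axis=0)
    q = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if row_mod[i] == col_mod[j]:
                q += w[i, j] - K[i] * L[j] / F
    return q / F


# -- exhaustive enumeration helpers (entropy bounds, d') ----------------


def compositions(n: int, k: int):
    """All ways to write n as k ordered positive parts."""
    for cuts in itertools.combinations(range(1, n), k - 1):
        prev, parts = 0, []
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(n - prev)
        yield tuple(parts)


def integer_tables(row_margins, col_margins):
    """All nonnegative integer tables with the given margins."""
    r, c = tuple(row_margins), tuple(col_margins)
    nr, nc = len(r), len(c)

    def fill_row(j, rem, colrem, acc):
        if j == nc - 1:
            if rem <= colrem[j]:
                yield acc + (rem,)
            return
        for v in range(min(rem, colrem[j]) + 1):
            yield from fill_row(j + 1, rem - v, colrem, acc + (v,))

    def rec(i, colrem):
        if i == nr - 1:
            if sum(colrem) == r[i] and all(v <= r[i] for v in colrem):
                yield (tuple(colrem),)
            return
        for row in fill_row(0, r[i], colrem, ()):
            newc = tuple(cr - v for cr, v in zip(colrem, row))
            for rest in rec(i + 1, newc):
                yield (row,) + rest

    yield from rec(0, c)


def table_entropy(t) -> float:
    a = np.asarray(t, dtype=float)
    p = a[a > 0] / a.sum()
    return float(-(p * np.log(p)).sum())


def allocations(total: int, k: int):
    """All nonnegative integer allocations of `total` over k partners."""
    if k == 1:
        yield (total,)
        return
    for v in range(total + 1):
        for rest in allocations(total - v, k - 1):
            yield (v,) + rest


def kl_oracle(x, q) -> float:
    x = np.asarray(x, dtype=float)
    q = np.asarray(q, dtype=float)
    a = x.sum()
    pos = x > 0
    p = x[pos] / a
    return float((p * np.log(p / q[pos])).sum())


# -- fixtures ----------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(20190307)


def random_count_matrix(rng, shape=(6, 6), high=5):
    """A random nonnegative integer matrix with no empty margins."""
    while True:
        w = rng.integers(0, high, size=shape)
        if (w.sum(1) > 0).all() and (w.sum(0) > 0).all():
            return w
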