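"""Complementary specialization: network-level H2' and species-level d'.

H2 is the two-dimensional Shannon entropy (nats) of the interaction
frequency table.  Because the attainable entropy range depends on the
marginal totals, the index standardizes the observed entropy between the
least and most even integer tables consistent with the margins:

    H2' = (H2max - H2) / (H2max - H2min),  clamped to [0, 1].

H2' = 0 means species share partners as evenly as the margins allow (maximal
niche overlap); H2' = 1 means maximal partitioning of partners.

d' is the species-level analogue: the Kullback-Leibler divergence between a
species' partner-use distribution and partner availability, standardized
between its attainable integer-allocation extremes.  d' = 0 for a species
using partners in proportion to availability, d' = 1 for a perfect
specialist concentrating on the rarest partner.

Bound computation
-----------------
Both H2 bounds are entropies of *valid integer tables* with the observed
margins.  For small tables (up to ``_EXACT_CELL_LIMIT`` cells and
``_EXACT_TOTAL_LIMIT`` interactions) they are computed exactly: the
minimum-entropy table is found by dynamic programming over vertices of the
transportation polytope (entropy is strictly concave, so its minimum over
the polytope - and hence over its integer points - is attained at a vertex,
and every vertex arises from sequential margin saturation), and the
maximum-entropy table by branch-and-bound over integer tables with a
continuous-entropy pruning bound.  For larger tables the bounds fall back
to fast constructions: the most even table starts from the real-valued
expected table r_i c_j / m, rounded to the margins by largest-remainder
allocation; the most concentrated table pairs the largest remaining
margins greedily; both are then polished by steepest 2x2 swaps (+1/-1 on
the corners of a rectangle, which preserves the margins).  The fallback is
a heuristic and can be slightly inside the true range, which is why H2' is
clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network_model import BipartiteNetwork

_SWAP_CELL_LIMIT = 400
_EXACT_CELL_LIMIT = 16   # exact H2 bounds up to this many cells ...
_EXACT_TOTAL_LIMIT = 24  # ... and this many interactions
_EPS = 1e-12


@dataclass(frozen=True)
class SpecializationResult:
    H2: float
    H2min: float
    H2max: float
    H2prime: float
    degenerate: bool = False


@dataclass(frozen=True)
class SpeciesSpecialization:
    species: str
    axis: Literal["row", "col"]
    d: float
    d_min: float
    d_max: float
    d_prime: float
    degenerate: bool = False


def _counts(w: BipartiteNetwork | np.ndarray) -> np.ndarray:
    m = w.weights if isinstance(w, BipartiteNetwork) else np.asarray(w, dtype=float)
    if m.sum() <= 0:
        raise ValueError("matrix has no interactions")
    return m


def shannon_H2(w: BipartiteNetwork | np.ndarray) -> float:
    """Two-dimensional Shannon entropy of the interaction table, in nats."""
    m = _counts(w)
    p = m[m > 0] / m.sum()
    return float(-(p * np.log(p)).sum())


def _xlogx_sum(t: np.ndarray) -> float:
    """Sum of w ln w over positive cells; entropy = ln m - this / m."""
    pos = t[t > 0]
    return float((pos * np.log(pos)).sum())


def _entropy_of_table(t: np.ndarray) -> float:
    m = t.sum()
    return float(np.log(m) - _xlogx_sum(t) / m)


def _largest_remainder_table(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Integer table with margins (r, c), close to the expected table r c / m."""
    m = r.sum()
    expected = np.outer(r, c) / m
    t = np.floor(expected).astype(np.int64)
    dr = r - t.sum(axis=1)
    dc = c - t.sum(axis=0)
    frac = expected - np.floor(expected)
    # place remaining units at the largest fractional remainders first,
    # restricted to cells whose row and column still have a deficit
    order = np.argsort(-frac, axis=None, kind="stable")
    for flat in order:
        if dr.sum() == 0:
            break
        i, j = divmod(int(flat), len(c))
        if dr[i] > 0 and dc[j] > 0:
            t[i, j] += 1
            dr[i] -= 1
            dc[j] -= 1
    # mop up any remainder (possible when high-remainder cells were blocked)
    while dr.sum() > 0:
        i = int(np.argmax(dr))
        j = int(np.argmax(dc))
        t[i, j] += 1
        dr[i] -= 1
        dc[j] -= 1
    return t


def _greedy_concentrated_table(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Maximally concentrated table: pair the largest remaining margins."""
    rr = r.astype(np.int64).copy()
    cc = c.astype(np.int64).copy()
    t = np.zeros((len(r), len(c)), dtype=np.int64)
    while rr.sum() > 0:
        i = int(np.argmax(rr))
        j = int(np.argmax(cc))
        v = min(rr[i], cc[j])
        t[i, j] += v
        rr[i] -= v
        cc[j] -= v
    return t


def _swap_improve(t: np.ndarray, maximize_entropy: bool) -> np.ndarray:
    """Steepest ascent/descent on entropy with margin-preserving 2x2 swaps.

    A swap adds 1 at (i, j) and (k, l) and removes 1 at (i, l) and (k, j);
    it is feasible when both removed cells are positive.  Entropy is ordered
    by S = sum w ln w (entropy decreases as S increases).
    """
    if t.size > _SWAP_CELL_LIMIT:
        return t
    t = t.copy()
    g = lambda x: 0.0 if x <= 0 else x * np.log(x)
    sign = -1.0 if maximize_entropy else 1.0  # we maximize sign * delta_S
    nr, nc = t.shape
    while True:
        best, move = _EPS, None
        for i in range(nr):
            for k in range(nr):
                if i == k:
                    continue
                for j in range(nc):
                    for l in range(nc):
                        if j == l or t[i, l] < 1 or t[k, j] < 1:
                            continue
                        delta = (
                            g(t[i, j] + 1) - g(t[i, j]) + g(t[k, l] + 1) - g(t[k, l])
                            + g(t[i, l] - 1) - g(t[i, l]) + g(t[k, j] - 1) - g(t[k, j])
                        )
                        if sign * delta > best:
                            best, move = sign * delta, (i, j, k, l)
        if move is None:
            return t
        i, j, k, l = move
        t[i, j] += 1
        t[k, l] += 1
        t[i, l] -= 1
        t[k, j] -= 1


def _vertex_min_entropy(r: np.ndarray, c: np.ndarray) -> float:
    """Exact minimum entropy over integer tables with margins (r, c).

    DP over multisets of remaining margins: a vertex of the transportation
    polytope is built by repeatedly placing min(row remainder, column
    remainder) in some cell, exhausting at least one of the two; maximizing
    the accumulated sum of v ln v over all saturation orders yields the
    entropy minimum.
    """
    m = float(r.sum())
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best_S(rr: tuple, cc: tuple) -> float:
        if not rr:
            return 0.0
        out = -np.inf
        for a in set(rr):
            rr2 = list(rr)
            rr2.remove(a)
            for b in set(cc):
                v = min(a, b)
                cc2 = list(cc)
                cc2.remove(b)
                if a > v:
                    rr2_ = tuple(sorted(rr2 + [a - v]))
                else:
                    rr2_ = tuple(sorted(rr2))
                if b > v:
                    cc2_ = tuple(sorted(cc2 + [b - v]))
                else:
                    cc2_ = tuple(sorted(cc2))
                s = v * np.log(v) + best_S(rr2_, cc2_)
                if s > out:
                    out = s
            rr2.append(a)
        return out

    S = best_S(tuple(sorted(r.tolist())), tuple(sorted(c.tolist())))
    return float(np.log(m) - S / m)


def _bb_max_entropy(r: np.ndarray, c: np.ndarray) -> float:
    """Exact maximum entropy over integer tables by branch-and-bound.

    Cells are filled row by row; a partial assignment is pruned when even
    the continuous entropy optimum of the remaining sub-problem (the outer
    product of the remaining margins) cannot beat the incumbent.
    """
    m = float(r.sum())
    nr, nc = len(r), len(c)
    g = lambda v: 0.0 if v <= 0 else v * np.log(v)
    # incumbent from the heuristic construction
    t0 = _swap_improve(_largest_remainder_table(r, c), maximize_entropy=True)
    best = [float(_xlogx_sum(t0))]

    def cont_bound(rrem: list[float], crem: np.ndarray) -> float:
        # continuous min of sum v ln v given margins = outer-product table
        tot = float(sum(rrem))
        if tot <= 0:
            return 0.0
        ra = np.array([x for x in rrem if x > 0])
        ca = crem[crem > 0]
        e = np.outer(ra, ca) / tot
        return float((e[e > 0] * np.log(e[e > 0])).sum())

    crem = c.astype(float).copy()

    def rec(i: int, j: int, row_rem: int, S: float) -> None:
        if i == nr:
            if S < best[0] - 1e-12:
                best[0] = S
            return
        if j == nc - 1:
            v = row_rem
            if v > crem[j] + 1e-9:
                return
            crem[j] -= v
            rrem = [r[k] for k in range(i + 1, nr)]
            if S + g(v) + cont_bound(rrem, crem) < best[0] - 1e-12:
                rec(i + 1, 0, int(r[i + 1]) if i + 1 < nr else 0, S + g(v))
            crem[j] += v
            return
        for v in range(int(min(row_rem, crem[j])) + 1):
            crem[j] -= v
            rrem = [row_rem - v] + [r[k] for k in range(i + 1, nr)]
            if S + g(v) + cont_bound(rrem, crem) < best[0] - 1e-12:
                rec(i, j + 1, row_rem - v, S + g(v))
            crem[j] += v

    rec(0, 0, int(r[0]), 0.0)
    return float(np.log(m) - best[0] / m)


def h2_bounds(
    row_totals: np.ndarray, col_totals: np.ndarray
) -> tuple[float, float]:
    """(H2min, H2max): entropy extremes over integer tables with these margins."""
    r = np.asarray(row_totals)
    c = np.asarray(col_totals)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("margins must be positive; prune empty species first")
    if np.any(np.abs(r - np.round(r)) > 1e-9) or np.any(np.abs(c - np.round(c)) > 1e-9):
        raise ValueError("H2 bounds require integer margins")
    r = np.round(r).astype(np.int64)
    c = np.round(c).astype(np.int64)
    if r.sum() != c.sum():
        raise ValueError(f"margin sums differ: rows {r.sum()} vs cols {c.sum()}")
    if len(r) * len(c) <= _EXACT_CELL_LIMIT and r.sum() <= _EXACT_TOTAL_LIMIT:
        return _vertex_min_entropy(r, c), _bb_max_entropy(r, c)
    t_min = _swap_improve(_greedy_concentrated_table(r, c), maximize_entropy=False)
    t_max = _swap_improve(_largest_remainder_table(r, c), maximize_entropy=True)
    return _entropy_of_table(t_min), _entropy_of_table(t_max)


def h2_prime(w: BipartiteNetwork | np.ndarray) -> SpecializationResult:
    """Standardized complementary specialization H2' of an integer count matrix."""
    m = _counts(w)
    if np.any(np.abs(m - np.round(m)) > 1e-9):
        raise ValueError("H2' requires integer counts")
    m = np.round(m)
    h2 = shannon_H2(m)
    h2min, h2max = h2_bounds(m.sum(axis=1), m.sum(axis=0))
    if h2max - h2min <= _EPS:
        return SpecializationResult(h2, h2min, h2max, 0.0, degenerate=True)
    prime = (h2max - h2) / (h2max - h2min)
    return SpecializationResult(h2, h2min, h2max, float(np.clip(prime, 0.0, 1.0)))


# -- species level -----------------------------------------------------


def _kl(x: np.ndarray, q: np.ndarray) -> float:
    """KL divergence of the allocation x (integer partner counts) from q."""
    a = x.sum()
    pos = x > 0
    p = x[pos] / a
    return float((p * np.log(p / q[pos])).sum())


def _kl_min_allocation(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` minimizing KL from q.

    Starts from largest-remainder rounding of total*q and descends with
    single-unit transfers.  The objective is separable convex on the simplex
    lattice, so unit-transfer local optimality is global.
    """
    expected = total * q
    x = np.floor(expected).astype(np.int64)
    frac = expected - np.floor(expected)
    for j in np.argsort(-frac, kind="stable")[: total - int(x.sum())]:
        x[j] += 1
    g = lambda v, qq: 0.0 if v <= 0 else v * (np.log(v) - np.log(total * qq))
    while True:
        best, move = -_EPS, None
        for j in range(len(q)):
            if x[j] < 1:
                continue
            for k in range(len(q)):
                if k == j:
                    continue
                delta = (
                    g(x[j] - 1, q[j]) - g(x[j], q[j])
                    + g(x[k] + 1, q[k]) - g(x[k], q[k])
                )
                if delta < best:
                    best, move = delta, (j, k)
        if move is None:
            return x
        x[move[0]] -= 1
        x[move[1]] += 1


def d_prime(
    w: BipartiteNetwork | np.ndarray,
    species: str | int,
    axis: Literal["row", "col"] = "row",
) -> SpeciesSpecialization:
    """Standardized species-level specialization d'.

    ``species`` may be a label (if ``w`` is a :class:`BipartiteNetwork`) or an
    integer index along ``axis``.
    """
    if isinstance(w, BipartiteNetwork):
        labels = w.row_labels if axis == "row" else w.col_labels
        idx = labels.index(species) if isinstance(species, str) else int(species)
        label = labels[idx]
        m = w.weights
    else:
        m = np.asarray(w, dtype=float)
        idx = int(species)
        label = f"{axis}{idx}"
    if axis == "col":
        m = m.T
    if np.any(np.abs(m - np.round(m)) > 1e-9):
        raise ValueError("d' requires integer counts")
    m = np.round(m)
    use = m[idx]
    total = int(use.sum())
    if total <= 0:
        raise ValueError(f"species {label!r} has no interactions; prune first")
    avail = m.sum(axis=0)
    q = avail / avail.sum()
    d = _kl(use, q)
    d_max = float(-np.log(q.min()))  # everything on the rarest partner
    d_min = _kl(_kl_min_allocation(total, q), q)
    if d_max - d_min <= _EPS:
        return SpeciesSpecialization(label, axis, d, d_min, d_max, 0.0, degenerate=True)
    prime = float(np.clip((d - d_min) / (d_max - d_min), 0.0, 1.0))
    return SpeciesSpecialization(label, axis, d, d_min, d_max, prime)
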