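"""Weighted bipartite modularity and species roles.

The objective is the Barber-type quantitative bipartite modularity

    Q = (1/F) sum_ij [ w_ij - K_i L_j / F ] 1(module(i) = module(j))

where F is the grand total, K_i the row (host) totals and L_j the column
(partner) totals, and modules are joint groups mixing rows and columns.
Q = 0 for the single-module partition, and increases as interaction weight
concentrates within modules beyond the margin expectation.

Optimization is a stochastic search, so a run can end in a local optimum;
:func:`optimize_modules` therefore restarts the annealer (default 10 times)
with distinct sub-seeds and keeps the configuration with the highest Q.
All results record the master seed and winning restart for reproducibility.

Species roles are summarized by the participation coefficient

    c = 1 - sum_s (k_s / k)^2

computed from quantitative interaction strengths: c = 0 when all of a
species' strength stays in one module, approaching 1 as it spreads evenly
across many.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .network_model import BipartiteNetwork

_ANNEAL_T0_SCALE = 0.05
_ANNEAL_COOLING = 0.995
_ANNEAL_PATIENCE = 2000  # proposals without improvement before stopping
_MERGE_SPLIT_EVERY = 50


@dataclass(frozen=True)
class ModulePartition:
    """Joint module assignment of rows and columns, ids contiguous from 0."""

    row_modules: tuple[int, ...]
    col_modules: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = set(self.row_modules) | set(self.col_modules)
        if ids != set(range(len(ids))):
            raise ValueError("module ids must be contiguous 0..n_modules-1")

    @property
    def n_modules(self) -> int:
        return len(set(self.row_modules) | set(self.col_modules))


def _relabel(row_m: np.ndarray, col_m: np.ndarray) -> ModulePartition:
    ids = {m: i for i, m in enumerate(dict.fromkeys([*row_m, *col_m]))}
    return ModulePartition(
        tuple(ids[m] for m in row_m), tuple(ids[m] for m in col_m)
    )


@dataclass(frozen=True)
class ModularityResult:
    partition: ModulePartition
    Q: float
    n_restarts: int
    best_restart_index: int
    seed: int


@dataclass(frozen=True)
class SpeciesRole:
    species: str
    axis: Literal["row", "col"]
    c_value: float


def _matrix(w: BipartiteNetwork | np.ndarray) -> np.ndarray:
    m = w.weights if isinstance(w, BipartiteNetwork) else np.asarray(w, dtype=float)
    if m.sum() <= 0:
        raise ValueError("matrix has no interactions")
    return m


def barber_modularity(
    w: BipartiteNetwork | np.ndarray, partition: ModulePartition
) -> float:
    """Evaluate the quantitative bipartite modularity of a given partition."""
    m = _matrix(w)
    r, c = m.shape
    if len(partition.row_modules) != r or len(partition.col_modules) != c:
        raise ValueError("partition does not cover the matrix dimensions")
    F = m.sum()
    rm = np.asarray(partition.row_modules)
    cm = np.asarray(partition.col_modules)
    k = partition.n_modules
    K = m.sum(axis=1)
    L = m.sum(axis=0)
    q = 0.0
    for s in range(k):
        q += m[np.ix_(rm == s, cm == s)].sum() - K[rm == s].sum() * L[cm == s].sum() / F
    return float(q / F)


class _AnnealState:
    """Incremental Q bookkeeping: Q = sum_s (e_s - a_s * b_s).

    e_s: within-module weight fraction; a_s, b_s: row/column margin
    fractions in module s.  Reassigning one node touches two modules only.
    """

    def __init__(self, m: np.ndarray, rm: np.ndarray, cm: np.ndarray, kmax: int):
        self.m = m
        self.F = m.sum()
        self.rm = rm
        self.cm = cm
        self.kmax = kmax
        self.K = m.sum(axis=1) / self.F
        self.L = m.sum(axis=0) / self.F
        self.e = np.zeros(kmax)
        self.a = np.zeros(kmax)
        self.b = np.zeros(kmax)
        for s in range(kmax):
            self.e[s] = m[np.ix_(rm == s, cm == s)].sum() / self.F
            self.a[s] = self.K[rm == s].sum()
            self.b[s] = self.L[cm == s].sum()

    def q(self) -> float:
        return float((self.e - self.a * self.b).sum())

    def move_delta(self, is_row: bool, idx: int, target: int) -> float:
        cur = self.rm[idx] if is_row else self.cm[idx]
        if target == cur:
            return 0.0
        if is_row:
            w_cur = self.m[idx, self.cm == cur].sum() / self.F
            w_tgt = self.m[idx, self.cm == target].sum() / self.F
            k = self.K[idx]
            d = (-w_cur + w_tgt
                 - (self.a[cur] - k) * self.b[cur] + self.a[cur] * self.b[cur]
                 - (self.a[target] + k) * self.b[target] + self.a[target] * self.b[target])
        else:
            w_cur = self.m[self.rm == cur, idx].sum() / self.F
            w_tgt = self.m[self.rm == target, idx].sum() / self.F
            k = self.L[idx]
            d = (-w_cur + w_tgt
                 - self.a[cur] * (self.b[cur] - k) + self.a[cur] * self.b[cur]
                 - self.a[target] * (self.b[target] + k) + self.a[target] * self.b[target])
        return float(d)

    def apply(self, is_row: bool, idx: int, target: int) -> None:
        if is_row:
            cur = self.rm[idx]
            w_cur = self.m[idx, self.cm == cur].sum() / self.F
            w_tgt = self.m[idx, self.cm == target].sum() / self.F
            self.e[cur] -= w_cur
            self.e[target] += w_tgt
            self.a[cur] -= self.K[idx]
            self.a[target] += self.K[idx]
            self.rm[idx] = target
        else:
            cur = self.cm[idx]
            w_cur = self.m[self.rm == cur, idx].sum() / self.F
            w_tgt = self.m[self.rm == target, idx].sum() / self.F
            self.e[cur] -= w_cur
            self.e[target] += w_tgt
            self.b[cur] -= self.L[idx]
            self.b[target] += self.L[idx]
            self.cm[idx] = target


def _anneal_once(m: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    r, c = m.shape
    kmax = min(r, c)
    rm = rng.integers(0, kmax, size=r)
    cm = rng.integers(0, kmax, size=c)
    state = _AnnealState(m, rm, cm, kmax)
    temp = _ANNEAL_T0_SCALE * 1.0  # Q is bounded by 1 in magnitude
    best_q = state.q()
    best = (rm.copy(), cm.copy())
    stale = 0
    step = 0
    n_nodes = r + c
    while stale < _ANNEAL_PATIENCE:
        step += 1
        if step % _MERGE_SPLIT_EVERY == 0 and kmax > 1:
            # merge proposal: relabel one whole module into another
            src, dst = rng.integers(0, kmax, size=2)
            if src != dst:
                old_rm, old_cm = state.rm.copy(), state.cm.copy()
                q_before = state.q()
                for i in np.where(state.rm == src)[0]:
                    state.apply(True, int(i), int(dst))
                for j in np.where(state.cm == src)[0]:
                    state.apply(False, int(j), int(dst))
                dq = state.q() - q_before
                if dq < 0 and rng.random() >= np.exp(dq / max(temp, 1e-12)):
                    # revert
                    for i in range(len(old_rm)):
                        if state.rm[i] != old_rm[i]:
                            state.apply(True, i, int(old_rm[i]))
                    for j in range(len(old_cm)):
                        if state.cm[j] != old_cm[j]:
                            state.apply(False, j, int(old_cm[j]))
        else:
            node = int(rng.integers(0, n_nodes))
            is_row = node < r
            idx = node if is_row else node - r
            target = int(rng.integers(0, kmax))
            dq = state.move_delta(is_row, idx, target)
            if dq >= 0 or rng.random() < np.exp(dq / max(temp, 1e-12)):
                state.apply(is_row, idx, target)
        q = state.q()
        if q > best_q + 1e-12:
            best_q = q
            best = (state.rm.copy(), state.cm.copy())
            stale = 0
        else:
            stale += 1
        temp *= _ANNEAL_COOLING
    return best[0], best[1], best_q


def optimize_modules(
    w: BipartiteNetwork | np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
) -> ModularityResult:
    """Maximize Q by simulated annealing with restarts; keep the best run.

    Reproducible: identical (matrix, seed, n_restarts) give identical output.
    """
    m = _matrix(w)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("modularity requires a pruned matrix of at least 2x2")
    master = np.random.SeedSequence(seed)
    best_q, best_part, best_idx = -np.inf, None, -1
    for i, child in enumerate(master.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        rm, cm, q = _anneal_once(m, rng)
        if q > best_q:
            best_q, best_part, best_idx = q, (rm, cm), i
    partition = _relabel(*best_part)
    q_exact = barber_modularity(m, partition)  # canonical recomputation
    return ModularityResult(partition, q_exact, n_restarts, best_idx, seed)


def participation_coefficient(
    w: BipartiteNetwork | np.ndarray,
    partition: ModulePartition,
    species: str | int,
    axis: Literal["row", "col"] = "row",
) -> SpeciesRole:
    """Among-module connectivity c of one species from quantitative strengths."""
    m = _matrix(w)
    if isinstance(species, str):
        if not isinstance(w, BipartiteNetwork):
            raise ValueError("string species labels need a BipartiteNetwork")
        labels = w.row_labels if axis == "row" else w.col_labels
        idx = labels.index(species)
        label = species
    else:
        idx = int(species)
        label = (
            (w.row_labels if axis == "row" else w.col_labels)[idx]
            if isinstance(w, BipartiteNetwork)
            else f"{axis}{idx}"
        )
    strengths = m[idx, :] if axis == "row" else m[:, idx]
    partner_modules = np.asarray(
        partition.col_modules if axis == "row" else partition.row_modules
    )
    k = strengths.sum()
    if k <= 0:
        raise ValueError(f"species {label!r} has no interactions; prune first")
    c = 1.0 - sum(
        (strengths[partner_modules == s].sum() / k) ** 2
        for s in range(partition.n_modules)
    )
    return SpeciesRole(label, axis, float(c))


def all_participation_coefficients(
    net: BipartiteNetwork, partition: ModulePartition
) -> list[SpeciesRole]:
    """c-value for every row and column species of a pruned network."""
    roles = [
        participation_coefficient(net, partition, i, "row")
        for i in range(net.n_rows)
    ]
    roles += [
        participation_coefficient(net, partition, j, "col")
        for j in range(net.n_cols)
    ]
    return roles
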