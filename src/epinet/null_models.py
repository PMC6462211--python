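"""Fixed-fixed null models and Z-tests for NODF and Q.

Observed nestedness and modularity are compared against randomized matrices
with exactly the observed row and column sums (the fixed-fixed ensemble), so
that significance reflects structure beyond what marginal totals impose.
Randomization uses curveball trades: two rows swap a random subset of the
columns where exactly one of them is present, which preserves both margins
and, iterated, samples the fixed-fixed ensemble uniformly.  Each null sample
is an independent chain started from the observed matrix with a burn-in of
5 * (rows * columns) trades.

The default protocol draws 1000 null matrices for NODF and 100 for Q; each
null matrix for Q is re-optimized with the same restart protocol as the
observed one.  The Q null randomizes the binary topology (each null matrix
scored as a 0/1 count matrix); a weight-preserving alternative that shuffles
the integer counts themselves (quasiswap-style) is available with
``quantitative=True``.

The test statistic is the standard score z = (obs - mean) / sd with a
two-sided normal p; the empirical two-sided quantile p is reported alongside
to guard against small null samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .modularity import optimize_modules
from .nestedness import nodf
from .network_model import BipartiteNetwork, binarize

DEFAULT_N_NULL = {"NODF": 1000, "Q": 100}


@dataclass(frozen=True)
class NullTestResult:
    metric_name: Literal["NODF", "Q"]
    observed: float
    null_mean: float
    null_sd: float
    n_null: int
    z: float
    p: float
    p_empirical: float
    significant: bool
    degenerate: bool = False
    seed: int = 0


def fixed_fixed_randomize(
    b: np.ndarray, seed: int | np.random.Generator = 0, n_trades: int | None = None
) -> np.ndarray:
    """One fixed-fixed sample of a binary matrix by curveball trades.

    ``n_trades`` defaults to 5 * (rows * columns), counted as attempted
    row-pair trades from the observed matrix.
    """
    b = np.asarray(b)
    m = (b > 0).astype(np.int8)
    r, c = m.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_trades is None:
        n_trades = 5 * r * c
    # row presence as index lists for fast symmetric-difference trades
    rows = [set(np.flatnonzero(m[i]).tolist()) for i in range(r)]
    for _ in range(n_trades):
        i, j = rng.integers(0, r, size=2)
        if i == j:
            continue
        a, bset = rows[i], rows[j]
        a_only = list(a - bset)
        b_only = list(bset - a)
        n_a = len(a_only)
        pool = a_only + b_only
        if n_a == 0 or len(b_only) == 0:
            continue
        perm = rng.permutation(len(pool))
        new_a = {pool[k] for k in perm[:n_a]}
        new_b = {pool[k] for k in perm[n_a:]}
        common = a & bset
        rows[i] = common | new_a
        rows[j] = common | new_b
    out = np.zeros_like(m)
    for i, cols in enumerate(rows):
        out[i, list(cols)] = 1
    return out.astype(int)


def _quasiswap_counts(
    w: np.ndarray, rng: np.random.Generator, n_moves: int | None = None
) -> np.ndarray:
    """Weight-preserving randomization: unit 2x2 transfers keeping margins."""
    t = np.round(np.asarray(w, dtype=float)).astype(np.int64)
    r, c = t.shape
    if n_moves is None:
        n_moves = 5 * r * c
    for _ in range(n_moves):
        i, k = rng.integers(0, r, size=2)
        j, l = rng.integers(0, c, size=2)
        if i == k or j == l:
            continue
        if rng.random() < 0.5:
            if t[i, l] > 0 and t[k, j] > 0:
                t[i, j] += 1
                t[k, l] += 1
                t[i, l] -= 1
                t[k, j] -= 1
        else:
            if t[i, j] > 0 and t[k, l] > 0:
                t[i, j] -= 1
                t[k, l] -= 1
                t[i, l] += 1
                t[k, j] += 1
    return t


def null_test(
    net: BipartiteNetwork | np.ndarray,
    metric: Literal["NODF", "Q"],
    n_null: int | None = None,
    seed: int = 0,
    n_restarts_q: int = 10,
    quantitative: bool = False,
    alpha: float = 0.05,
) -> NullTestResult:
    """Fixed-fixed significance test of NODF or Q for one network."""
    w = net.weights if isinstance(net, BipartiteNetwork) else np.asarray(net, dtype=float)
    if n_null is None:
        n_null = DEFAULT_N_NULL[metric]
    if n_null < 20:
        raise ValueError("n_null must be at least 20 for a stable null sample")
    b = binarize(w)
    master = np.random.SeedSequence(seed)
    sub = master.spawn(n_null + 1)
    if metric == "NODF":
        observed = nodf(b).value
        null_vals = np.array([
            nodf(fixed_fixed_randomize(b, np.random.default_rng(s))).value
            for s in sub[:n_null]
        ])
    elif metric == "Q":
        if quantitative:
            observed = optimize_modules(w, n_restarts_q, seed=_subseed(sub[n_null])).Q
            null_vals = np.array([
                optimize_modules(
                    _quasiswap_counts(w, np.random.default_rng(s)),
                    n_restarts_q, seed=_subseed(s),
                ).Q
                for s in sub[:n_null]
            ])
        else:
            observed = optimize_modules(b, n_restarts_q, seed=_subseed(sub[n_null])).Q
            null_vals = np.array([
                optimize_modules(
                    fixed_fixed_randomize(b, np.random.default_rng(s)),
                    n_restarts_q, seed=_subseed(s),
                ).Q
                for s in sub[:n_null]
            ])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    mean = float(null_vals.mean())
    sd = float(null_vals.std(ddof=1))
    if sd <= 0:
        return NullTestResult(metric, observed, mean, sd, n_null,
                              float("nan"), float("nan"), float("nan"),
                              significant=False, degenerate=True, seed=seed)
    z = (observed - mean) / sd
    p = float(2 * stats.norm.sf(abs(z)))
    # two-sided empirical quantile p with add-one correction
    n_ge = int((null_vals >= observed).sum())
    n_le = int((null_vals <= observed).sum())
    p_emp = min(1.0, 2 * (min(n_ge, n_le) + 1) / (n_null + 1))
    return NullTestResult(metric, observed, mean, sd, n_null, float(z), p,
                          p_emp, significant=p < alpha, seed=seed)


def _subseed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))
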