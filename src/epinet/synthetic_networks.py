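"""Synthetic bipartite count networks and study-level metric tables.

The generators emulate the inputs of a comparative survey of quantitative
interaction networks: count matrices with controllable marginal heterogeneity
(nestedness via abundance skew), modular block structure, and preferred-
partner specialization, plus a study-level table of metrics with
interaction-type fixed effects, locality random intercepts, and Gaussian
noise.

All generators allocate a fixed grand total of interactions multinomially
over cells, so the total is exact and downstream null models can condition
on it.  Every output records its seed.

The default study composition mirrors a tropical/subtropical compilation:
12 epiphyte-phorophyte (EP), 13 seed dispersal (SD), 86 pollination (PO) and
11 ant-myrmecophyte (AM) networks, with network sizes (rows + columns)
spanning roughly 16-180 species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .network_model import BipartiteNetwork, NetworkMetadata

DEFAULT_TYPE_COUNTS = {"EP": 12, "SD": 13, "PO": 86, "AM": 11}


@dataclass(frozen=True)
class GeneratorConfig:
    """One synthetic network: dimensions, total count and structural regime.

    ``regime`` selects the structure: ``neutral`` (interactions proportional
    to abundance products), ``modular`` (block structure with a
    within:between expected-weight ratio), ``specialized`` (preferred
    one-to-one partners with a concentration knob in [0, 1]).
    """

    n_rows: int = 10
    n_cols: int = 15
    total_interactions: int = 200
    regime: Literal["neutral", "modular", "specialized"] = "neutral"
    abundance_sigma: float = 1.0  # lognormal sigma of species abundances
    n_modules: int = 3
    within_between_ratio: float = 5.0
    concentration: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if self.total_interactions < self.n_rows + self.n_cols:
            raise ValueError("total_interactions too small to fill margins")
        if self.regime == "modular" and self.n_modules > min(self.n_rows, self.n_cols):
            raise ValueError("n_modules cannot exceed min(n_rows, n_cols)")
        if not 0.0 <= self.concentration <= 1.0:
            raise ValueError("concentration must lie in [0, 1]")


def _draw_counts(
    prob: np.ndarray, total: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial allocation of `total` interactions over cell probabilities.

    Species that end up unobserved (empty margins) are legitimate - strongly
    skewed abundances make rare species likely to be missed, exactly as in
    field sampling - and are removed downstream by pruning.  Draws are only
    rejected when fewer than two rows or columns are observed at all.
    """
    p = prob / prob.sum()
    for _ in range(1000):
        flat = rng.multinomial(total, p.ravel())
        w = flat.reshape(p.shape)
        if (w.sum(axis=1) > 0).sum() >= 2 and (w.sum(axis=0) > 0).sum() >= 2:
            return w
    raise RuntimeError("could not draw a usable matrix; "
                       "increase total_interactions")


def _package(w: np.ndarray, config: GeneratorConfig) -> BipartiteNetwork:
    return BipartiteNetwork(
        tuple(f"H{i+1}" for i in range(config.n_rows)),
        tuple(f"P{j+1}" for j in range(config.n_cols)),
        w.astype(float),
        NetworkMetadata(interaction_type="EP", locality=f"sim{config.seed}"),
    )


def gen_neutral(config: GeneratorConfig) -> BipartiteNetwork:
    """Abundance-neutral network: cell probability proportional to the product
    of lognormal row and column abundances (no partner preferences)."""
    rng = np.random.default_rng(config.seed)
    ra = rng.lognormal(0.0, config.abundance_sigma, config.n_rows)
    ca = rng.lognormal(0.0, config.abundance_sigma, config.n_cols)
    prob = np.outer(ra, ca)
    return _package(_draw_counts(prob, config.total_interactions, rng), config)


def gen_modular(config: GeneratorConfig) -> BipartiteNetwork:
    """Planted block structure: both axes split into ``n_modules`` blocks,
    with expected within-block weight ``within_between_ratio`` times the
    between-block weight.  Ratio 1 reduces to the even-abundance neutral
    case."""
    rng = np.random.default_rng(config.seed)
    rmod = np.arange(config.n_rows) % config.n_modules
    cmod = np.arange(config.n_cols) % config.n_modules
    prob = np.where(
        rmod[:, None] == cmod[None, :], config.within_between_ratio, 1.0
    ).astype(float)
    return _package(_draw_counts(prob, config.total_interactions, rng), config)


def planted_modules(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """The block assignment used by :func:`gen_modular` (rows, cols)."""
    return (np.arange(config.n_rows) % config.n_modules,
            np.arange(config.n_cols) % config.n_modules)


def gen_specialized(config: GeneratorConfig) -> BipartiteNetwork:
    """Preferred-partner network: each row has a preferred column (cyclic
    one-to-one assignment); ``concentration`` in [0, 1] mixes a pure diagonal
    preference with the even-abundance neutral expectation.  Concentration 0
    equals the neutral even-abundance case; 1 is a strict diagonal."""
    rng = np.random.default_rng(config.seed)
    pref = np.zeros((config.n_rows, config.n_cols))
    pref[np.arange(config.n_rows), np.arange(config.n_rows) % config.n_cols] = 1.0
    even = np.ones_like(pref) / config.n_cols
    pref = pref / pref.sum(axis=1, keepdims=True)
    prob = config.concentration * pref + (1 - config.concentration) * even
    return _package(_draw_counts(prob, config.total_interactions, rng), config)


def generate(config: GeneratorConfig) -> BipartiteNetwork:
    return {
        "neutral": gen_neutral,
        "modular": gen_modular,
        "specialized": gen_specialized,
    }[config.regime](config)


@dataclass(frozen=True)
class StudyConfig:
    """A synthetic comparative study: per-type network counts, planted type
    shifts per metric, locality random intercepts and residual noise.

    ``type_effects`` maps metric -> {type: shift}; the baseline mean of each
    metric is ``metric_means``.  ``size_slope`` maps metric -> per-species
    slope on network size.  Sizes are drawn log-uniformly over
    ``size_range``.
    """

    type_counts: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_COUNTS))
    metric_means: dict = field(default_factory=lambda: {
        "NODF": 30.0, "H2prime": 0.45, "Q": 0.35,
    })
    type_effects: dict = field(default_factory=lambda: {
        # qualitative pattern of a commensalism-vs-mutualism comparison:
        # EP more nested, less specialized, less modular
        "NODF": {"EP": 15.0}, "H2prime": {"EP": -0.25}, "Q": {"EP": -0.18},
    })
    size_slope: dict = field(default_factory=lambda: {"NODF": -0.05})
    n_localities: int = 40
    sigma_locality: float = 0.5  # scale factor applied per metric (see below)
    sigma_residual: float = 1.0
    metric_scales: dict = field(default_factory=lambda: {
        "NODF": 8.0, "H2prime": 0.08, "Q": 0.05,
    })
    size_range: tuple = (16, 180)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 2 for v in self.type_counts.values()):
            raise ValueError("need at least 2 networks per interaction type")


def gen_comparative_study(study: StudyConfig) -> pd.DataFrame:
    """Network-level metrics table drawn from the linear mixed model

        metric = mean + type_shift + slope * size + u_locality + e

    with u ~ N(0, (sigma_locality * scale)^2), e ~ N(0, (sigma_residual *
    scale)^2) and per-metric scales so all metrics stay near their natural
    ranges.  Values are clipped into each metric's defined range.
    """
    rng = np.random.default_rng(study.seed)
    rows = []
    n_total = sum(study.type_counts.values())
    localities = [f"loc{k+1}" for k in range(study.n_localities)]
    loc_assign = rng.integers(0, study.n_localities, size=n_total)
    loc_effects = {
        metric: rng.normal(0.0, study.sigma_locality * scale, study.n_localities)
        for metric, scale in study.metric_scales.items()
    }
    lo, hi = study.size_range
    idx = 0
    for itype, count in study.type_counts.items():
        for _ in range(count):
            size = int(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            row = {
                "id": f"net{idx+1:03d}",
                "interaction_type": itype,
                "locality": localities[loc_assign[idx]],
                "network_size": size,
            }
            for metric, mu in study.metric_means.items():
                scale = study.metric_scales.get(metric, 1.0)
                val = (
                    mu
                    + study.type_effects.get(metric, {}).get(itype, 0.0)
                    + study.size_slope.get(metric, 0.0) * size
                    + loc_effects[metric][loc_assign[idx]]
                    + rng.normal(0.0, study.sigma_residual * scale)
                )
                row[metric] = val
            rows.append(row)
            idx += 1
    df = pd.DataFrame(rows)
    if "NODF" in df.columns:
        df["NODF"] = df["NODF"].clip(lower=0.5, upper=100.0)
    for m in ("H2prime", "Q"):
        if m in df.columns:
            df[m] = df[m].clip(lower=0.0, upper=1.0)
    return df


def study_true_effects(study: StudyConfig) -> dict:
    """Ground-truth fixed effects of :func:`gen_comparative_study`, keyed as
    (metric, type) shifts relative to the first listed type, for
    parameter-recovery tests."""
    types = list(study.type_counts)
    ref = types[0]
    out = {}
    for metric in study.metric_means:
        shifts = study.type_effects.get(metric, {})
        for t in types[1:]:
            out[(metric, t)] = shifts.get(t, 0.0) - shifts.get(ref, 0.0)
        out[(metric, "size")] = study.size_slope.get(metric, 0.0)
    return out
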