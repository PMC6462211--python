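"""Cross-interaction-type comparison of network metrics with mixed models.

Each metric (network level: NODF, wNODF, H2', Q; species level: d', c) is
modelled as

    metric = intercept + interaction_type + [network_size] + u_locality + e

with a Gaussian random intercept u per locality (spatial non-independence)
and Gaussian residuals, fitted by REML.  Network size enters as a continuous
covariate for network-level metrics only, since several metrics scale with
network size and sampling intensity.  NODF is ln-transformed before fitting.

The interaction-type effect is tested with a Type-II Wald chi-square (all
type coefficients jointly zero, given the size covariate).  Pairwise type
differences use a single-step max-|z| adjustment over the joint normal
approximation to the six contrasts (the Tukey-style familywise correction),
with the adjustment computed by seeded Monte Carlo.  Goodness of fit is
summarized by the marginal and conditional R-squared for mixed models:
Rm2 = var(fixed predictions) / (var(fixed) + s2_u + s2_e) and
Rc2 = (var(fixed) + s2_u) / (same denominator).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .network_model import INTERACTION_TYPES

NETWORK_METRICS = ("NODF", "wNODF", "H2prime", "Q")
SPECIES_METRICS = ("d_prime", "c_value")
LN_TRANSFORMED = ("NODF",)

_TUKEY_MC_DRAWS = 100_000
_TUKEY_MC_SEED = 20_190_307
_BOUNDARY_TOL = 1e-6


class ComparisonError(ValueError):
    """Raised when a metrics table cannot support the requested comparison."""


@dataclass
class LMMFit:
    response: str
    transform: str  # "ln" or "identity"
    params: pd.Series  # fixed-effect estimates
    bse: pd.Series
    cov_params: pd.DataFrame
    var_locality: float  # s2_u
    var_residual: float  # s2_e
    loglike_reml: float
    converged: bool
    boundary: bool  # random-intercept variance pinned at 0
    groups: str
    data: pd.DataFrame = field(repr=False)
    design: pd.DataFrame = field(repr=False)
    type_levels: tuple[str, ...] = ()
    n_obs: int = 0

    def fixed_predictions(self) -> np.ndarray:
        return self.design.to_numpy() @ self.params.to_numpy()

    def residual_table(self) -> pd.DataFrame:
        """Fitted-vs-residual and normal-quantile diagnostics as data."""
        fitted = self.fixed_predictions()
        resid = self.data["_y"].to_numpy() - fitted
        order = np.argsort(resid)
        n = len(resid)
        theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        out = pd.DataFrame({"fitted": fitted, "residual": resid})
        out["normal_quantile"] = np.empty(n)
        out.loc[out.index[order], "normal_quantile"] = theo
        return out


@dataclass(frozen=True)
class ContrastRow:
    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_adjusted: float
    p_unadjusted: float


def _metric_formula_term(response: str) -> tuple[str, str]:
    if response in LN_TRANSFORMED:
        return "ln", f"np.log({response})"
    return "identity", response


def validate_metrics_table(table: pd.DataFrame, unit: str = "network") -> None:
    required = {"interaction_type", "locality"}
    missing = required - set(table.columns)
    if missing:
        raise ComparisonError(f"metrics table missing columns: {sorted(missing)}")
    if table["interaction_type"].isna().any() or table["locality"].isna().any():
        raise ComparisonError("interaction_type and locality must be complete")
    bad = set(table["interaction_type"]) - set(INTERACTION_TYPES)
    if bad:
        raise ComparisonError(f"unknown interaction types: {sorted(bad)}")
    if unit == "network" and "network_size" not in table.columns:
        raise ComparisonError("network-level table needs a network_size column")


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    groups: str = "locality",
    include_size: bool | None = None,
    transform: str = "auto",
) -> LMMFit:
    """REML fit of metric ~ interaction_type (+ size) + (1 | locality).

    ``include_size`` defaults to True for network-level metrics and False for
    species-level ones.  Rows with a missing response are dropped listwise.
    Boundary fits (locality variance estimated at zero, or one observation
    per locality) fall back to ordinary least squares for the fixed effects
    and are flagged, not rejected.
    """
    if include_size is None:
        include_size = response in NETWORK_METRICS
    unit = "network" if response in NETWORK_METRICS else "species"
    validate_metrics_table(table, unit="network" if include_size else unit)
    if response not in table.columns:
        raise ComparisonError(f"response {response!r} not in table")
    df = table.dropna(subset=[response]).copy()
    if response in LN_TRANSFORMED and (df[response] <= 0).any():
        raise ComparisonError(f"{response} must be positive for the ln transform")
    if df[groups].nunique() < 2:
        raise ComparisonError("need at least 2 localities (random-effect groups)")
    if df["interaction_type"].nunique() < 2:
        raise ComparisonError("need at least 2 interaction types to compare")
    if transform == "auto":
        transform, _ = _metric_formula_term(response)
    df["_y"] = np.log(df[response]) if transform == "ln" else df[response].astype(float)
    levels = tuple(t for t in INTERACTION_TYPES if t in set(df["interaction_type"]))
    df["interaction_type"] = pd.Categorical(df["interaction_type"], categories=levels)
    formula = "_y ~ C(interaction_type)"
    if include_size:
        formula += " + network_size"

    n_params = 1 + (len(levels) - 1) + int(include_size)
    if len(df) <= n_params:
        raise ComparisonError(
            f"{len(df)} observations cannot identify {n_params} fixed effects")

    group_sizes = df.groupby(groups, observed=True).size()
    singleton_groups = bool((group_sizes == 1).all())

    if singleton_groups:
        ols = smf.ols(formula, data=df).fit()
        return _fit_from_ols(ols, response, transform, groups, df, levels)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df[groups])
            result = model.fit(reml=True)
    except np.linalg.LinAlgError:
        # near-singular likelihood surface: keep the OLS fixed effects
        ols = smf.ols(formula, data=df).fit()
        fit = _fit_from_ols(ols, response, transform, groups, df, levels)
        fit.converged = False
        return fit
    var_u = float(np.asarray(result.cov_re).ravel()[0])
    var_e = float(result.scale)
    boundary = var_u <= _BOUNDARY_TOL * var_e
    if boundary or not result.converged:
        ols = smf.ols(formula, data=df).fit()
        fit = _fit_from_ols(ols, response, transform, groups, df, levels)
        fit.converged = bool(result.converged)
        return fit
    fe = result.fe_params
    design = pd.DataFrame(
        model.exog, columns=model.exog_names, index=df.index
    )
    return LMMFit(
        response=response, transform=transform,
        params=fe, bse=result.bse_fe,
        cov_params=result.cov_params().loc[fe.index, fe.index],
        var_locality=var_u, var_residual=var_e,
        loglike_reml=float(result.llf), converged=bool(result.converged),
        boundary=False, groups=groups, data=df, design=design,
        type_levels=levels, n_obs=len(df),
    )


def _fit_from_ols(ols, response, transform, groups, df, levels) -> LMMFit:
    design = pd.DataFrame(
        ols.model.exog, columns=ols.model.exog_names, index=df.index
    )
    return LMMFit(
        response=response, transform=transform,
        params=ols.params, bse=ols.bse, cov_params=ols.cov_params(),
        var_locality=0.0, var_residual=float(ols.mse_resid),
        loglike_reml=float(ols.llf), converged=True, boundary=True,
        groups=groups, data=df, design=design,
        type_levels=levels, n_obs=len(df),
    )


def _type_param_names(fit: LMMFit) -> list[str]:
    return [p for p in fit.params.index if p.startswith("C(interaction_type")]


def wald_chisq(fit: LMMFit, term: str = "interaction_type") -> tuple[float, int, float]:
    """Type-II Wald chi-square for a fixed-effect term: (chi2, df, p)."""
    if term == "interaction_type":
        names = _type_param_names(fit)
    elif term in ("network_size", "size"):
        names = [p for p in fit.params.index if p == "network_size"]
    else:
        names = [p for p in fit.params.index if p == term]
    if not names:
        raise ComparisonError(f"term {term!r} not in the fitted model")
    idx = [fit.params.index.get_loc(n) for n in names]
    beta = fit.params.to_numpy()[idx]
    V = fit.cov_params.to_numpy()[np.ix_(idx, idx)]
    chi2 = float(beta @ np.linalg.solve(V, beta))
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _contrast_matrix(fit: LMMFit) -> tuple[list[tuple[str, str]], np.ndarray]:
    levels = fit.type_levels
    p = len(fit.params)
    cols = {name: i for i, name in enumerate(fit.params.index)}
    effect = {levels[0]: np.zeros(p)}
    for lev in levels[1:]:
        vec = np.zeros(p)
        key = next(
            n for n in fit.params.index
            if n.startswith("C(interaction_type") and n.endswith(f"[T.{lev}]")
        )
        vec[cols[key]] = 1.0
        effect[lev] = vec
    pairs = list(itertools.combinations(levels, 2))
    C = np.array([effect[a] - effect[b] for a, b in pairs])
    return pairs, C


def pairwise_contrasts(fit: LMMFit) -> list[ContrastRow]:
    """All pairwise interaction-type differences with familywise-adjusted p.

    The single-step adjustment computes P(max_i |Z_i| >= |z_k|) under the
    joint normal law of the standardized contrasts, by Monte Carlo with a
    fixed seed; with a single contrast it reduces to the unadjusted p.
    """
    if len(fit.type_levels) < 2:
        raise ComparisonError("pairwise contrasts need at least 2 types")
    pairs, C = _contrast_matrix(fit)
    beta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    est = C @ beta
    cov = C @ V @ C.T
    se = np.sqrt(np.diag(cov))
    z = est / se
    corr = cov / np.outer(se, se)
    p_unadj = 2 * stats.norm.sf(np.abs(z))
    if len(pairs) == 1:
        p_adj = p_unadj.copy()
    else:
        rng = np.random.default_rng(_TUKEY_MC_SEED)
        # draw max-|Z| under the joint null with the contrasts' correlation
        L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(pairs)))
        draws = rng.standard_normal((_TUKEY_MC_DRAWS, len(pairs))) @ L.T
        max_abs = np.abs(draws).max(axis=1)
        p_adj = np.array([(max_abs >= abs(zk)).mean() for zk in z])
        p_adj = np.maximum(p_adj, p_unadj)  # adjustment never below unadjusted
    return [
        ContrastRow((a, b), float(est[k]), float(se[k]), float(z[k]),
                    float(p_adj[k]), float(p_unadj[k]))
        for k, (a, b) in enumerate(pairs)
    ]


def compact_letters(
    levels: tuple[str, ...], contrasts: list[ContrastRow], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from adjusted pairwise p-values.

    Levels sharing a letter are not significantly different at ``alpha``.
    """
    differ = {frozenset(c.pair) for c in contrasts if c.p_adjusted < alpha}
    groups: list[set[str]] = []
    for lev in levels:
        placed = False
        for grp in groups:
            if all(frozenset((lev, other)) not in differ for other in grp):
                grp.add(lev)
                placed = True
        if not placed:
            groups.append({lev})
    letters = {lev: "" for lev in levels}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lev in grp:
            letters[lev] += letter
    return letters


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional R2 for a random-intercept Gaussian LMM."""
    var_f = float(np.var(fit.fixed_predictions(), ddof=1))
    denom = var_f + fit.var_locality + fit.var_residual
    rm2 = var_f / denom
    rc2 = (var_f + fit.var_locality) / denom
    return float(rm2), float(rc2)


@dataclass
class ComparisonReport:
    """Per-response Wald test, size effect, contrasts, letters and R2."""

    response: str
    chi2: float
    df: int
    p: float
    size_estimate: float | None
    size_p: float | None
    contrasts: list[ContrastRow]
    letters: dict[str, str]
    rm2: float
    rc2: float
    boundary: bool

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "type_chi2": self.chi2, "type_df": self.df, "type_p": self.p,
            "size_estimate": self.size_estimate, "size_p": self.size_p,
            "contrasts": [
                {"pair": list(c.pair), "estimate": c.estimate, "se": c.se,
                 "z": c.z, "p_adjusted": c.p_adjusted,
                 "p_unadjusted": c.p_unadjusted}
                for c in self.contrasts
            ],
            "letters": self.letters,
            "Rm2": self.rm2, "Rc2": self.rc2,
            "boundary_fit": self.boundary,
        }


def compare_metric(
    table: pd.DataFrame, response: str, groups: str = "locality",
    alpha: float = 0.05,
) -> ComparisonReport:
    """Fit, test and summarize one response metric end to end."""
    fit = fit_lmm(table, response, groups=groups)
    chi2, df, p = wald_chisq(fit, "interaction_type")
    if "network_size" in fit.params.index:
        size_est = float(fit.params["network_size"])
        _, _, size_p = wald_chisq(fit, "network_size")
    else:
        size_est, size_p = None, None
    contrasts = pairwise_contrasts(fit)
    letters = compact_letters(fit.type_levels, contrasts, alpha)
    rm2, rc2 = r2_nakagawa(fit)
    return ComparisonReport(response, chi2, df, p, size_est, size_p,
                            contrasts, letters, rm2, rc2, fit.boundary)
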