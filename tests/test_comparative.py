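import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from epinet.comparative_stats import (
    ComparisonError, compact_letters, compare_metric, fit_lmm,
    pairwise_contrasts, r2_nakagawa, wald_chisq,
)
from epinet.synthetic_networks import StudyConfig, gen_comparative_study


def make_table(rng, n_per_type=15, n_loc=10, sigma_u=0.0, sigma_e=1.0,
               type_shifts=None, types=("EP", "SD", "PO", "AM")):
    """Network-level table with a known linear structure for the Q metric."""
    type_shifts = type_shifts or {}
    locs = [f"L{k}" for k in range(n_loc)]
    u = rng.normal(0, sigma_u, n_loc)
    rows = []
    for t in types:
        for i in range(n_per_type):
            k = int(rng.integers(0, n_loc))
            size = int(rng.integers(16, 180))
            rows.append({
                "id": f"{t}{i}", "interaction_type": t, "locality": locs[k],
                "network_size": size,
                "Q": 0.3 + type_shifts.get(t, 0.0) + u[k]
                + rng.normal(0, sigma_e),
            })
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_boundary_variance_collapses_to_ols(self):
        # with no locality variance in the data the REML estimate sits at the
        # zero boundary and the fixed effects collapse to ordinary least
        # squares (a positive chance estimate is legitimate on other draws)
        tab = make_table(np.random.default_rng(1), sigma_u=0.0)
        fit = fit_lmm(tab, "Q")
        assert fit.boundary
        tab2 = tab.copy()
        tab2["interaction_type"] = pd.Categorical(
            tab2["interaction_type"], categories=list(fit.type_levels))
        ols = smf.ols("Q ~ C(interaction_type) + network_size", tab2).fit()
        for name in fit.params.index:
            assert fit.params[name] == pytest.approx(ols.params[name], abs=1e-6)

    def test_singleton_localities_fall_back_to_ols_with_flag(self, rng):
        tab = make_table(rng, n_per_type=8)
        tab["locality"] = [f"L{k}" for k in range(len(tab))]
        fit = fit_lmm(tab, "Q")
        assert fit.boundary
        assert fit.var_locality == 0.0

    def test_positive_group_variance_recovered(self, rng):
        tab = make_table(rng, n_per_type=40, n_loc=12, sigma_u=0.6, sigma_e=0.3)
        fit = fit_lmm(tab, "Q")
        assert not fit.boundary
        assert 0.1 < fit.var_locality < 1.2
        assert 0.05 < fit.var_residual < 0.3

    def test_missing_responses_dropped_listwise(self, rng):
        tab = make_table(rng)
        tab.loc[tab.index[:5], "Q"] = np.nan
        fit = fit_lmm(tab, "Q")
        assert fit.n_obs == len(tab) - 5

    def test_requires_two_types_and_two_localities(self, rng):
        tab = make_table(rng, types=("EP",))
        with pytest.raises(ComparisonError, match="2 interaction types"):
            fit_lmm(tab, "Q")
        tab2 = make_table(rng)
        tab2["locality"] = "L0"
        with pytest.raises(ComparisonError, match="2 localities"):
            fit_lmm(tab2, "Q")

    def test_nodf_is_ln_transformed(self, rng):
        tab = make_table(rng)
        tab["NODF"] = np.exp(rng.normal(3.5, 0.4, len(tab)))
        fit = fit_lmm(tab, "NODF")
        assert fit.transform == "ln"
        np.testing.assert_allclose(fit.data["_y"], np.log(tab["NODF"]))


class TestWaldChisq:
    def test_reference_level_invariance(self, rng):
        tab = make_table(rng, type_shifts={"SD": 0.4})
        chi_a = wald_chisq(fit_lmm(tab, "Q"), "interaction_type")[0]
        relev = {"EP": "PO", "SD": "EP", "PO": "AM", "AM": "SD"}
        tab2 = tab.assign(interaction_type=tab["interaction_type"].map(relev))
        chi_b = wald_chisq(fit_lmm(tab2, "Q"), "interaction_type")[0]
        assert chi_a == pytest.approx(chi_b, rel=1e-6)

    def test_absent_term_rejected(self, rng):
        fit = fit_lmm(make_table(rng), "Q")
        with pytest.raises(ComparisonError, match="not in the fitted model"):
            wald_chisq(fit, "habitat")

    def test_strong_effect_detected(self, rng):
        tab = make_table(rng, n_per_type=30, sigma_e=0.2,
                         type_shifts={"EP": -0.4})
        chi2, df, p = wald_chisq(fit_lmm(tab, "Q"), "interaction_type")
        assert df == 3
        assert p < 0.001


class TestPairwiseContrasts:
    def test_two_groups_adjustment_is_identity(self, rng):
        tab = make_table(rng, types=("EP", "PO"))
        rows = pairwise_contrasts(fit_lmm(tab, "Q"))
        assert len(rows) == 1
        assert rows[0].p_adjusted == pytest.approx(rows[0].p_unadjusted)

    def test_balanced_groups_estimate_mean_differences_exactly(self, rng):
        tab = make_table(rng, n_per_type=12)
        tab["locality"] = [f"L{k}" for k in range(len(tab))]  # forces OLS path
        fit = fit_lmm(tab, "Q", include_size=False)
        assert fit.boundary
        means = tab.groupby("interaction_type")["Q"].mean()
        for row in pairwise_contrasts(fit):
            a, b = row.pair
            assert row.estimate == pytest.approx(means[a] - means[b], abs=1e-10)

    def test_planted_low_group_lettered_apart(self, rng):
        tab = make_table(rng, n_per_type=25, sigma_e=0.15,
                         type_shifts={"EP": -0.35})
        fit = fit_lmm(tab, "Q")
        rows = pairwise_contrasts(fit)
        letters = compact_letters(fit.type_levels, rows)
        assert all(letters["EP"] != letters[t] for t in ("SD", "PO", "AM"))
        assert letters["SD"] == letters["PO"] == letters["AM"]


class TestR2Nakagawa:
    def test_bounds_and_ordering(self, rng):
        tab = make_table(rng, sigma_u=0.4, type_shifts={"EP": -0.3})
        fit = fit_lmm(tab, "Q")
        rm2, rc2 = r2_nakagawa(fit)
        assert 0.0 <= rm2 <= rc2 <= 1.0

    def test_no_random_variance_makes_marginal_equal_conditional(self, rng):
        tab = make_table(rng, sigma_u=0.0)
        fit = fit_lmm(tab, "Q")
        if fit.boundary:
            rm2, rc2 = r2_nakagawa(fit)
            assert rm2 == pytest.approx(rc2)


class TestCompareMetric:
    def test_report_structure_and_letters(self):
        tab = gen_comparative_study(StudyConfig(seed=7))
        rep = compare_metric(tab, "H2prime")
        d = rep.to_dict()
        assert d["type_df"] == 3
        assert len(d["contrasts"]) == 6
        assert set(d["letters"]) == {"EP", "SD", "PO", "AM"}
        assert 0 <= d["Rm2"] <= d["Rc2"] <= 1
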