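"""Factorial mixed-model post-analysis: REML, Type III ANOVA, LS-means."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from biomepred.post_analysis import (
    assemble_table,
    fit_post_lmm,
    ls_means,
    type3_anova,
)

LEVELS = {
    "Timepoint": ["wean", "wk15", "wk22"],
    "Algorithm": ["BL", "RKHS", "RF", "GBM"],
    "Trait": [f"T{i:02d}" for i in range(12)],
    "Biom": ["null", "biom"],
}


def simulate_records(
    seed=0,
    n_reps=5,
    levels=None,
    biom_effect=0.0,
    cell_sd=0.0,
    noise_sd=0.03,
    timepoint_effects=None,
):
    """Balanced factorial accuracy table with known effect structure."""
    levels = levels or LEVELS
    rng = np.random.default_rng(seed)
    rows = []
    for combo in product(*levels.values()):
        d = dict(zip(levels.keys(), combo))
        cell = rng.normal(0.0, cell_sd) if cell_sd > 0 else 0.0
        mu = 0.30 + cell
        if d["Biom"] == "biom":
            mu += biom_effect
        if timepoint_effects:
            mu += timepoint_effects.get(d["Timepoint"], 0.0)
        for rep in range(1, n_reps + 1):
            rows.append({**d, "replicate": rep, "accuracy": mu + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestAssembleTable:
    def test_full_run_has_1440_rows(self, factorial_cv):
        _, _, results = factorial_cv
        records = assemble_table(results)
        assert len(records) == 5 * 12 * 3 * 4 * 2 == 1440

    def test_disabling_one_algorithm_drops_its_rows(self, factorial_cv):
        _, _, results = factorial_cv
        records = assemble_table(results[results["algorithm"] != "GBM"])
        assert len(records) == 1080

    def test_columns_are_the_factors_plus_accuracy(self, factorial_cv):
        _, _, results = factorial_cv
        records = assemble_table(results)
        assert list(records.columns) == [
            "Timepoint", "Algorithm", "Trait", "Biom", "replicate", "accuracy",
        ]
        assert set(records["Biom"]) == {"null", "biom"}

    def test_nan_accuracy_rows_dropped_with_warning(self):
        df = simulate_records(n_reps=2).rename(
            columns=str
        )
        raw = df.rename(
            columns={
                "Timepoint": "timepoint", "Algorithm": "algorithm",
                "Trait": "trait", "Biom": "biom", "replicate": "repeat",
            }
        )
        raw["biom"] = raw["biom"] == "biom"
        raw.loc[0, "accuracy"] = np.nan
        with pytest.warns(UserWarning, match="undefined accuracy"):
            records = assemble_table(raw)
        assert len(records) == len(raw) - 1


class TestFitPostLmm:
    def test_balanced_fixed_effects_match_ols_when_vc_zero(self):
        records = simulate_records(seed=1, n_reps=3, noise_sd=0.05, biom_effect=0.03)
        fit = fit_post_lmm(records, fix_sigma2_g=0.0)
        import statsmodels.api as sm

        from biomepred.post_analysis import _build_design

        X, _, _ = _build_design(records)
        ols = sm.OLS(records["accuracy"].to_numpy(), X.to_numpy()).fit()
        assert np.allclose(fit.beta, ols.params, atol=1e-8)
        assert fit.sigma2_g == 0.0

    def test_gls_equals_ols_for_balanced_designs_even_with_vc(self):
        records = simulate_records(seed=2, n_reps=3, cell_sd=0.04, biom_effect=0.04)
        fit = fit_post_lmm(records)
        fit0 = fit_post_lmm(records, fix_sigma2_g=0.0)
        assert fit.sigma2_g > 0
        assert np.allclose(fit.beta, fit0.beta, atol=1e-8)

    def test_zero_variance_component_recovered_at_boundary(self):
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            records = simulate_records(seed=100 + s, n_reps=3, cell_sd=0.0)
            fit = fit_post_lmm(records)
            if fit.sigma2_g <= 0.05 * fit.sigma2_e:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_variance_component_recovered_when_present(self):
        records = simulate_records(seed=3, n_reps=5, cell_sd=0.05, noise_sd=0.03)
        fit = fit_post_lmm(records)
        assert 0.5 * 0.05**2 < fit.sigma2_g < 2 * 0.05**2
        assert 0.5 * 0.03**2 < fit.sigma2_e < 2 * 0.03**2

    def test_estimates_invariant_to_level_relabeling(self):
        records = simulate_records(seed=4, n_reps=2, cell_sd=0.03, biom_effect=0.05)
        fit1 = fit_post_lmm(records)
        relabeled = records.replace(
            {"Algorithm": {"BL": "zeta", "RKHS": "alpha"}}
        )
        fit2 = fit_post_lmm(relabeled)
        assert fit1.sigma2_g == pytest.approx(fit2.sigma2_g, rel=1e-6)
        assert fit1.sigma2_e == pytest.approx(fit2.sigma2_e, rel=1e-6)
        lm1 = ls_means(fit1, "Biom").set_index("Biom")["estimate"]
        lm2 = ls_means(fit2, "Biom").set_index("Biom")["estimate"]
        assert np.allclose(lm1, lm2, atol=1e-8)


class TestType3Anova:
    def test_ten_terms_in_the_table(self):
        records = simulate_records(seed=5, n_reps=2)
        fit = fit_post_lmm(records)
        table = type3_anova(fit)
        assert len(table) == 10
        assert list(table.index) == [
            "Timepoint", "Algorithm", "Trait", "Biom",
            "Timepoint:Algorithm", "Timepoint:Trait", "Timepoint:Biom",
            "Algorithm:Trait", "Algorithm:Biom", "Trait:Biom",
        ]
        assert (table["F"] >= 0).all()

    def test_matches_classical_anova_with_zero_variance_component(self):
        records = simulate_records(seed=6, n_reps=3, biom_effect=0.04, noise_sd=0.05)
        fit = fit_post_lmm(records, fix_sigma2_g=0.0)
        table = type3_anova(fit)

        # classical fixed-effects Type III oracle via statsmodels OLS
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        formula = (
            "accuracy ~ (C(Timepoint, Sum) + C(Algorithm, Sum) "
            "+ C(Trait, Sum) + C(Biom, Sum)) ** 2"
        )
        oracle = sm.stats.anova_lm(ols(formula, data=records).fit(), typ=3)
        name_map = {
            "C(Timepoint, Sum)": "Timepoint",
            "C(Algorithm, Sum)": "Algorithm",
            "C(Trait, Sum)": "Trait",
            "C(Biom, Sum)": "Biom",
        }
        for raw, term in name_map.items():
            assert table.loc[term, "F"] == pytest.approx(
                oracle.loc[raw, "F"], abs=1e-6
            )
        for t1, t2 in (
            ("C(Timepoint, Sum)", "C(Algorithm, Sum)"),
            ("C(Trait, Sum)", "C(Biom, Sum)"),
        ):
            term = f"{name_map[t1]}:{name_map[t2]}"
            assert table.loc[term, "F"] == pytest.approx(
                oracle.loc[f"{t1}:{t2}", "F"], abs=1e-6
            )

    def test_balanced_satterthwaite_df_equals_cell_residual_df(self):
        records = simulate_records(seed=7, n_reps=3, cell_sd=0.05)
        fit = fit_post_lmm(records)
        table = type3_anova(fit)
        # 288 cells - 95 fixed-effect df = 193
        assert np.allclose(table["den_df"], 193.0, atol=0.5)

    def test_type_one_error_near_nominal_under_null(self):
        # smaller factorial to keep 200 REML fits cheap; no true effects
        levels = {
            "Timepoint": ["a", "b", "c"],
            "Algorithm": ["x", "y"],
            "Trait": ["t1", "t2", "t3"],
            "Biom": ["null", "biom"],
        }
        n_sim = 200
        rejections = {"Biom": 0, "Timepoint": 0}
        for s in range(n_sim):
            records = simulate_records(
                seed=5000 + s, n_reps=3, levels=levels, cell_sd=0.02, noise_sd=0.03
            )
            fit = fit_post_lmm(records)
            table = type3_anova(fit)
            for term in rejections:
                if table.loc[term, "p_value"] < 0.05:
                    rejections[term] += 1
        for term, count in rejections.items():
            assert 0.02 <= count / n_sim <= 0.10, (term, count / n_sim)


class TestLsMeans:
    def test_balanced_ls_means_equal_raw_marginal_means(self):
        records = simulate_records(seed=8, n_reps=3, biom_effect=0.05)
        fit = fit_post_lmm(records)
        lm = ls_means(fit, "Timepoint").set_index("Timepoint")["estimate"]
        raw = records.groupby("Timepoint")["accuracy"].mean()
        assert np.allclose(lm, raw.loc[lm.index], atol=1e-8)

    def test_biom_term_has_two_estimates(self):
        records = simulate_records(seed=9, n_reps=2)
        fit = fit_post_lmm(records)
        lm = ls_means(fit, "Biom")
        assert len(lm) == 2 and (lm["se"] > 0).all()

    def test_injected_timepoint_ordering_recovered(self):
        records = simulate_records(
            seed=10,
            n_reps=5,
            timepoint_effects={"wean": 0.0, "wk15": 0.08, "wk22": 0.04},
            cell_sd=0.01,
        )
        fit = fit_post_lmm(records)
        lm = ls_means(fit, "Timepoint").set_index("Timepoint")["estimate"]
        assert lm["wk15"] > lm["wk22"] > lm["wean"]

    def test_injected_biom_gain_recovered(self):
        records = simulate_records(seed=11, n_reps=5, biom_effect=0.04, cell_sd=0.02)
        fit = fit_post_lmm(records)
        lm = ls_means(fit, "Biom").set_index("Biom")["estimate"]
        gain = lm["biom"] - lm["null"]
        se = ls_means(fit, "Biom")["se"].iloc[0] * np.sqrt(2)
        assert gain == pytest.approx(0.04, abs=3 * se)

    def test_pairwise_interaction_grid(self):
        records = simulate_records(seed=12, n_reps=2)
        fit = fit_post_lmm(records)
        lm = ls_means(fit, "Timepoint:Biom")
        assert len(lm) == 6

    def test_unknown_term_rejected(self):
        records = simulate_records(seed=13, n_reps=2)
        fit = fit_post_lmm(records)
        with pytest.raises(KeyError, match="unknown term"):
            ls_means(fit, "Sex")
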