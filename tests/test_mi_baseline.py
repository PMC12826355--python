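"""Chained-equations imputation and pooled-posterior ("three-step") inference."""

import numpy as np
import pandas as pd
import pytest

from bgcomp.datamodel import MissingTable
from bgcomp.derive import logbmi_spec, toy_spec
from bgcomp.mi_baseline import ImputationConfig, chained_impute, gelman_three_step
from bgcomp.models import fit_bernoulli, fit_univariate_normal
from bgcomp.synthetic import gen_dutch_boys, gen_toy


class TestChainedImpute:
    def test_no_missingness_returns_identical_copies(self):
        table, _ = gen_toy(n=40, seed=1, mcar_p=0.0)
        out = chained_impute(table, ImputationConfig(K=3, seed=0), toy_spec())
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t.data, table.data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ImputationConfig(K=0)
        with pytest.raises(ValueError):
            ImputationConfig(methods={"Z1": "mean"})

    def test_posterior_predictive_spread_single_cell(self, rng):
        """One missing value with an R²≈0.99 predictor: imputations centre on
        the regression prediction and spread like the residual sd."""
        n = 120
        x = rng.uniform(0, 10, n)
        resid_sd = 0.2
        y = 1.0 + 2.0 * x + resid_sd * rng.standard_normal(n)
        y[0] = np.nan
        table = MissingTable(
            pd.DataFrame({"Z1": x, "Z2": y, "Y": x + np.where(np.isnan(y), np.nan, y)}),
            {"Z1": "source", "Z2": "source", "Y": "derived"},
        )
        out = chained_impute(table, ImputationConfig(K=200, cycles=3, seed=3), toy_spec())
        imputed = np.array([t.data.loc[0, "Z2"] for t in out])
        predicted = 1.0 + 2.0 * x[0]
        pred_se = resid_sd * np.sqrt(1 + 2.0 / n)
        assert abs(imputed.mean() - predicted) < 3 * pred_se / np.sqrt(200) * 10
        assert 0.5 * resid_sd < imputed.std() < 2.0 * resid_sd

    def test_derived_column_consistent_in_every_output(self):
        table, _ = gen_toy(n=80, seed=5)
        out = chained_impute(table, ImputationConfig(K=4, cycles=3, seed=1), toy_spec())
        for t in out:
            assert not t.mask.to_numpy().any()
            t.check_derived(toy_spec())

    def test_binary_imputations_are_binary(self):
        table, _ = gen_toy(n=80, seed=6)
        out = chained_impute(table, ImputationConfig(K=2, cycles=2, seed=2), toy_spec())
        for t in out:
            assert t.data["X"].isin([0.0, 1.0]).all()

    def test_bounds_squeeze_draws(self):
        table, _ = gen_toy(n=80, seed=6)
        cfg = ImputationConfig(K=2, cycles=2, seed=2, bounds={"Z1": (0.0, 0.5)})
        out = chained_impute(table, cfg, toy_spec())
        imputed_rows = table.mask["Z1"]
        for t in out:
            vals = t.data.loc[imputed_rows, "Z1"]
            assert ((vals >= 0.0) & (vals <= 0.5)).all()

    def test_undeclared_variable_with_missingness_errors(self):
        table, _ = gen_toy(n=40, seed=2)
        bad = table.copy()
        bad.binary = frozenset()  # X no longer recognized as binary

        # declare a method for the wrong variable name
        with pytest.raises(ValueError, match="unknown variable"):
            chained_impute(table, ImputationConfig(K=1, methods={"QQ": "bayes-linear"}),
                           toy_spec())


class TestThreeStep:
    def _bernoulli_table(self, y):
        return MissingTable(pd.DataFrame({"Y": y}), {"Y": "derived"},
                            binary=frozenset({"Y"}))

    def test_single_dataset_equals_single_fit(self):
        t = self._bernoulli_table([1.0, 0.0, 1.0, 1.0, 0.0])
        pooled = gelman_three_step([t], lambda tab, M, seed: fit_bernoulli(tab, M=M, seed=seed),
                                   M=2000, seed=4)
        single = fit_bernoulli(t, M=2000, seed=4)
        pd.testing.assert_series_equal(pooled.params["theta"], single.params["theta"],
                                       check_names=False)

    def test_identical_datasets_pool_to_single_fit_quantiles(self):
        t = self._bernoulli_table([1.0] * 30 + [0.0] * 170)
        pooled = gelman_three_step([t] * 10,
                                   lambda tab, M, seed: fit_bernoulli(tab, M=M, seed=seed),
                                   M=3000, seed=0)
        single = fit_bernoulli(t, M=30000, seed=99)
        for p in (2.5, 50, 97.5):
            assert abs(np.percentile(pooled.params["theta"], p)
                       - np.percentile(single.params["theta"], p)) < 0.01

    def test_between_imputation_variance_nonnegative(self):
        table, _ = gen_toy(n=120, seed=8)
        completed = chained_impute(table, ImputationConfig(K=6, cycles=3, seed=0),
                                   toy_spec())
        counts = [t.data["Y"].mean() for t in completed]
        pooled = gelman_three_step(
            [self._bernoulli_table((t.data["Y"] > 2.0).astype(float)) for t in completed],
            lambda tab, M, seed: fit_bernoulli(tab, 1.0, 1.0, M=M, seed=seed),
            M=2000, seed=1)
        pooled_var = pooled.params["theta"].var()
        within = np.mean([
            fit_bernoulli(self._bernoulli_table((t.data["Y"] > 2.0).astype(float)),
                          1.0, 1.0, M=2000, seed=1 + k).params["theta"].var()
            for k, t in enumerate(completed)
        ])
        assert pooled_var >= within * 0.95  # allows MC slack on equality
        assert len(counts) == 6

    def test_three_step_approaches_complete_data_fit_with_one_missing_cell(self):
        """As missingness vanishes the pooled posterior matches the full-data fit."""
        full, _ = gen_dutch_boys(
            n=250, seed=9,
            mechanism={"p_height": 0.0, "p_weight_given_height": 0.0, "p_x": 0.0})
        holed = full.copy()
        holed.data.loc[holed.data.index[0], "height"] = np.nan
        holed.data.loc[holed.data.index[0], "logBMI"] = np.nan
        completed = chained_impute(holed, ImputationConfig(K=3, cycles=3, seed=2),
                                   logbmi_spec())
        fitter = lambda tab, M, seed: fit_univariate_normal(tab, M=M, seed=seed, warmup=500)
        pooled = gelman_three_step(completed, fitter, M=600, seed=5)
        direct = fitter(full, 600, 5)
        for b in ("beta1", "beta2", "sigma"):
            assert abs(pooled.params[b].median() - direct.params[b].median()) \
                < 4 * direct.params[b].std() / np.sqrt(100) + 0.02
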