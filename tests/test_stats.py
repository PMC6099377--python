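"""Regression framework: nested F tests, stepwise selection, Tukey, mixed models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from wingsignal.stats import (
    CollinearityError,
    StepwiseResult,
    among_population_regression,
    dimorphism_model,
    logit_rescale,
    ols_with_f_tests,
    plant_contrast_mixed_model,
    within_population_regression,
)

METRICS = ["fw_luminance", "fw_saturation", "fw_chromatic_jnd",
           "fw_luminance_jnd", "fw_rel_spot_area"]


def _table(rng, n, conc=None, **metric_overrides):
    df = pd.DataFrame({m: rng.normal(size=n) for m in METRICS})
    for k, v in metric_overrides.items():
        df[k] = v
    df["concentration_nmol_per_mg"] = (
        conc if conc is not None else np.exp(rng.normal(-0.5, 0.4, n))
    )
    df["specimen_id"] = [f"S{i:03d}" for i in range(n)]
    return df


class TestOlsWithFTests:
    def test_perfect_fit(self):
        x = np.linspace(0, 1, 10)
        res = ols_with_f_tests(2.0 + 3.0 * x, pd.DataFrame({"x": x}))
        assert res.p < 1e-12
        assert res.r_squared_adj == pytest.approx(1.0)

    def test_adjusted_r_squared_can_be_negative(self):
        rng = np.random.default_rng(0)
        res = ols_with_f_tests(rng.normal(size=9), pd.DataFrame({"x": rng.normal(size=9)}))
        # a useless predictor should usually produce adj-R^2 < plain R^2
        assert res.r_squared_adj < 0.5

    def test_matches_permutation_reference(self):
        """Parametric F-test p agrees with a 100k-draw permutation null on a
        12-point simple regression within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        res = ols_with_f_tests(y, pd.DataFrame({"x": x}))
        n_perm = 100_000
        xs = (x - x.mean()) / x.std()
        perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        r = (perms - perms.mean(axis=1, keepdims=True)) @ xs / (
            12 * perms.std(axis=1)
        )
        f_perm = (12 - 2) * r**2 / (1 - r**2)
        p_perm = np.mean(f_perm >= res.F)
        mc_err = 3 * np.sqrt(res.p * (1 - res.p) / n_perm)
        assert res.p == pytest.approx(p_perm, abs=max(mc_err, 0.01))

    def test_rank_deficiency_rejected(self):
        x = np.ones(10)
        with pytest.raises(ValueError):
            ols_with_f_tests(np.arange(10.0), pd.DataFrame({"a": x, "b": 2 * x}))


class TestAmongPopulation:
    def test_strong_population_slope_detected(self):
        rng = np.random.default_rng(2)
        frames = []
        for i in range(12):
            conc_mean = rng.uniform(0.3, 1.2)
            n = 6
            df = _table(rng, n, conc=conc_mean + rng.normal(0, 0.02, n))
            df["fw_luminance"] = 2.0 * conc_mean + rng.normal(0, 0.05, n)
            df["population"] = f"p{i:02d}"
            df["sex"] = "F"
            frames.append(df)
        res = among_population_regression(pd.concat(frames), "fw_luminance", "F")
        assert res.p < 0.05
        coef = res.coefficients.set_index("term").loc["mean_concentration", "coef"]
        assert coef > 0

    def test_identical_population_means_give_zero_f(self):
        rng = np.random.default_rng(3)
        frames = []
        for i in range(5):
            df = _table(rng, 4, conc=np.full(4, 0.5 + 0.1 * i))
            df["fw_luminance"] = [1.0, 2.0, 3.0, 4.0]  # same mean everywhere
            df["population"] = f"p{i}"
            df["sex"] = "F"
            frames.append(df)
        res = among_population_regression(pd.concat(frames), "fw_luminance", "F")
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_sexes_use_disjoint_subsets(self):
        rng = np.random.default_rng(4)
        df = _table(rng, 60)
        df["population"] = np.repeat([f"p{i}" for i in range(6)], 10)
        df["sex"] = np.tile(["F", "M"], 30)
        females_only = df[df["sex"] == "F"]
        a = among_population_regression(df, "fw_luminance", "F")
        b = among_population_regression(females_only, "fw_luminance", "F")
        assert a.F == pytest.approx(b.F)

    def test_too_few_populations_rejected(self):
        rng = np.random.default_rng(5)
        df = _table(rng, 20)
        df["population"] = np.repeat(["a", "b"], 10)
        df["sex"] = "F"
        with pytest.raises(ValueError):
            among_population_regression(df, "fw_luminance", "F")


class TestWithinPopulation:
    def test_minimal_model_recovers_single_true_predictor(self):
        """When concentration depends only on luminance at high power, the
        backward-eliminated model always retains luminance (with the right
        sign), and each null metric is falsely retained at roughly the
        elimination threshold of 5%."""
        rng = np.random.default_rng(6)
        kept_true = 0
        kept_null = 0
        n_reps = 500
        for _ in range(n_reps):
            df = _table(rng, 25)
            # strong signal: partial r ~ 0.85 -> theoretical power > 0.99
            df["concentration_nmol_per_mg"] = (
                1.0 + 0.8 * df["fw_luminance"] + rng.normal(0, 0.5, 25)
            )
            res = within_population_regression(df, "saturation")
            if "fw_luminance" in res.minimal.terms:
                kept_true += 1
                coef = res.minimal.coefficients.set_index("term")
                assert coef.loc["fw_luminance", "coef"] > 0
            kept_null += len([t for t in res.minimal.terms if t != "fw_luminance"])
        assert kept_true / n_reps >= 0.99
        # 4 null candidates per replicate, each retained ~alpha of the time
        assert 0.02 <= kept_null / (4 * n_reps) <= 0.10

    def test_saturation_and_hue_together_rejected(self):
        rng = np.random.default_rng(7)
        df = _table(rng, 30)
        df["fw_hue"] = df["fw_saturation"] * 1.001 + 1e-4 * rng.normal(size=30)
        with pytest.raises(CollinearityError):
            within_population_regression(
                df, "saturation",
                predictors=["fw_luminance", "fw_saturation", "fw_hue"],
            )

    def test_gross_outlier_flagged_by_cooks_distance(self):
        """A specimen with concentration scaled x0.1 is flagged, and the
        flag set matches a direct hat-matrix evaluation of Cook's distance."""
        rng = np.random.default_rng(8)
        df = _table(rng, 20)
        df.loc[7, METRICS] = [1.5, -1.2, 1.0, -1.4, 1.3]  # moderate leverage point
        df["concentration_nmol_per_mg"] = (
            5.0 + 1.5 * df["fw_luminance"] + rng.normal(0, 0.05, 20)
        )
        df.loc[7, "concentration_nmol_per_mg"] *= 0.1
        res = within_population_regression(df, "saturation")
        # independent Cook's distance via the hat matrix
        X = np.column_stack([np.ones(20), df[METRICS].to_numpy()])
        y = df["concentration_nmol_per_mg"].to_numpy()
        H = X @ np.linalg.solve(X.T @ X, X.T)
        e = y - H @ y
        p = X.shape[1]
        s2 = e @ e / (20 - p)
        h = np.diag(H)
        cooks = e**2 * h / (p * s2 * (1 - h) ** 2)
        expected = {df["specimen_id"].iloc[i] for i in np.flatnonzero(cooks > 1.0)}
        assert df["specimen_id"].iloc[7] in expected
        assert set(res.outliers) == expected
        assert isinstance(res.refit_without_outliers, StepwiseResult)
        assert res.refit_without_outliers.full.excluded_outliers == res.outliers

    def test_stepwise_order_independent_for_orthogonal_predictors(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(40, 5))
        q, _ = np.linalg.qr(base)  # orthogonal design columns
        y = 1.0 + 2.0 * q[:, 0] + rng.normal(0, 0.1, 40)
        results = []
        for order in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
            df = pd.DataFrame(q[:, order], columns=[METRICS[i] for i in order])
            df["concentration_nmol_per_mg"] = y
            df["specimen_id"] = [f"S{i}" for i in range(40)]
            res = within_population_regression(
                df, "saturation", predictors=[METRICS[i] for i in order]
            )
            results.append(sorted(res.minimal.terms))
        assert results[0] == results[1] == results[2]

    def test_small_sample_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            within_population_regression(_table(rng, 6), "saturation")


class TestDimorphism:
    @staticmethod
    def _balanced(rng, n_cell, n_pops=3, sex_shift=0.0, pop_shifts=None):
        pops = [f"p{i}" for i in range(n_pops)]
        rows = []
        for j, pop in enumerate(pops):
            for sex in ("F", "M"):
                m = rng.normal(0, 1, n_cell)
                m += sex_shift * (sex == "M")
                if pop_shifts is not None:
                    m += pop_shifts[j]
                for v in m:
                    rows.append({"population": pop, "sex": sex, "m": v})
        return pd.DataFrame(rows)

    def test_two_sd_sex_offset_is_significant(self):
        rng = np.random.default_rng(11)
        df = self._balanced(rng, 20, sex_shift=2.0)
        res = dimorphism_model(df, "m")
        assert res.sex[3] < 0.001

    def test_population_shift_found_by_tukey(self):
        rng = np.random.default_rng(12)
        df = self._balanced(rng, 20, pop_shifts=[0.0, 0.0, 2.0])
        res = dimorphism_model(df, "m")
        tuk = res.tukey_population.set_index(["level_a", "level_b"])
        assert tuk.loc[("p0", "p2"), "p_adj"] < 0.001
        assert tuk.loc[("p0", "p1"), "p_adj"] > 0.05

    def test_balanced_two_group_tukey_equals_pooled_t_test(self):
        """With two groups, the studentized-range p equals the two-sided
        pooled t-test p (q = sqrt(2) |t|)."""
        rng = np.random.default_rng(13)
        df = self._balanced(rng, 15, n_pops=2, pop_shifts=[0.0, 0.7])
        res = dimorphism_model(df, "m")
        p_tukey = res.tukey_population["p_adj"].iloc[0]
        # pooled t-test on the additive model's population term
        X = pd.DataFrame({
            "sex_M": (df["sex"] == "M").astype(float),
            "pop_p1": (df["population"] == "p1").astype(float),
        })
        fit = sm.OLS(df["m"], sm.add_constant(X)).fit()
        assert p_tukey == pytest.approx(fit.pvalues["pop_p1"], abs=1e-10)

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(14)
        df = self._balanced(rng, 5)
        df = df[~((df["population"] == "p1") & (df["sex"] == "M"))]
        with pytest.raises(ValueError):
            dimorphism_model(df, "m")


class TestMixedModel:
    @staticmethod
    def _long(rng, n_ind, re_sd=1.0, plant_shift=(0.0, 0.0, 0.0), resid_sd=1.0):
        plants = ["flower_a", "flower_b", "leaf"]
        rows = []
        for i in range(n_ind):
            b = rng.normal(0, re_sd)
            sex = "M" if i % 2 else "F"
            pop = f"p{i % 3}"
            for p, shift in zip(plants, plant_shift):
                rows.append({
                    "specimen_id": f"S{i}", "sex": sex, "population": pop,
                    "plant_type": p,
                    "chromatic_jnd": 10.0 + shift + b + rng.normal(0, resid_sd),
                    "luminance_jnd": abs(5.0 + shift + b + rng.normal(0, resid_sd)),
                })
        return pd.DataFrame(rows)

    def test_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(15)
        df = self._long(rng, 40, re_sd=0.0)
        res = plant_contrast_mixed_model(df, "chromatic")
        X = pd.get_dummies(df[["sex", "population", "plant_type"]],
                           drop_first=True, dtype=float)
        ols = sm.OLS(df["chromatic_jnd"], sm.add_constant(X)).fit()
        assert res.random_intercept_var == pytest.approx(0.0, abs=1e-4)
        np.testing.assert_allclose(
            np.sort(res.fe_params.to_numpy()), np.sort(ols.params.to_numpy()),
            atol=1e-5,
        )

    def test_plant_type_effect_detected(self):
        rng = np.random.default_rng(16)
        df = self._long(rng, 30, plant_shift=(8.0, 6.0, 0.0))
        res = plant_contrast_mixed_model(df, "chromatic")
        chi2, dof, p = res.tests["plant_type"]
        assert p < 0.001
        tuk = res.tukey["plant_type"].set_index(["level_a", "level_b"])
        assert tuk.loc[("flower_a", "leaf"), "p_adj"] < 0.001

    def test_random_intercept_variance_recovery(self):
        """Median ML estimate over replicates recovers the simulated
        between-individual variance within 20% at 100 individuals x 3 plants."""
        rng = np.random.default_rng(17)
        estimates = []
        for _ in range(60):
            df = self._long(rng, 100, re_sd=1.0)
            res = plant_contrast_mixed_model(df, "chromatic")
            estimates.append(res.random_intercept_var)
        assert np.median(estimates) == pytest.approx(1.0, rel=0.2)

    def test_singleton_individuals_rejected(self):
        rng = np.random.default_rng(18)
        df = self._long(rng, 10).groupby("specimen_id").head(1)
        with pytest.raises(ValueError, match="random intercept"):
            plant_contrast_mixed_model(df, "chromatic")

    def test_luminance_response_is_logit_rescaled(self):
        y = np.array([0.5, 1.0, 4.0, 9.0])
        z = logit_rescale(y)
        assert np.all(np.isfinite(z))
        assert np.all(np.diff(z) > 0)  # transform is monotone
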