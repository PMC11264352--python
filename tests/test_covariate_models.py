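import numpy as np
import pandas as pd
import pytest

from repcost.covariate_models import (
    MAINS,
    adjusted_year_means,
    all_subsets_lm,
    enumerate_hierarchical_models,
    glm_binomial_outcome,
    glm_poisson_productivity,
    residual_gate,
)
from repcost.synthetic_data import DeeTruth, simulate_dee_dataset

from _oracles import count_hierarchical_models


def balanced_data(year_means, n_per_year, sd, rng, age_slope=0.0):
    """Covariates identical across years (balanced), so adjusted and raw
    year means coincide whenever the slope estimate is shared."""
    rows = []
    ages = list(range(n_per_year))
    for year, mu in year_means.items():
        for i in range(n_per_year):
            age = ages[i] % 10
            rows.append({
                "year": year, "adult_age_y": age, "brood_size": 1 + i % 5,
                "brood_age_d": 7 + i % 30,
                "dee_kj_day": mu + age_slope * age + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestEnumeration:
    def test_matches_independent_count(self):
        got = len(enumerate_hierarchical_models(MAINS))
        assert got == count_hierarchical_models(len(MAINS))

    def test_hierarchy_enforced(self):
        for terms in enumerate_hierarchical_models(MAINS):
            mains = {t for t in terms if ":" not in t}
            for t in terms:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in mains and b in mains


class TestAllSubsets:
    def test_intercept_only_data_keeps_null_model(self):
        rng = np.random.default_rng(1)
        data = balanced_data({2007: 1500, 2008: 1500}, 20, 100, rng)
        table, retained = all_subsets_lm(data)
        assert any(f.terms == () for f in retained)

    def test_year_effect_recovered(self):
        rng = np.random.default_rng(2)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = balanced_data({2007: 1300, 2008: 1750, 2012: 1650,
                                  2018: 1350}, 15, 150, rng)
            _, retained = all_subsets_lm(data)
            if all("C(year)" in f.terms for f in retained[:1]):
                hits += 1
        assert hits >= 19

    def test_ranking_invariant_to_covariate_scaling(self):
        rng = np.random.default_rng(3)
        data = balanced_data({2007: 1400, 2008: 1600}, 15, 120, rng,
                             age_slope=-10)
        t1, _ = all_subsets_lm(data)
        data2 = data.copy()
        data2["adult_age_y"] = (data2["adult_age_y"] - 5.0) / 3.0
        t2, _ = all_subsets_lm(data2)
        assert list(t1["model"]) == list(t2["model"])


class TestAdjustedMeans:
    def test_year_only_model_equals_raw_means(self):
        rng = np.random.default_rng(4)
        data = balanced_data({2007: 1400, 2008: 1700}, 12, 100, rng)
        _, retained = all_subsets_lm(data, mains=("C(year)",))
        fit = retained[0]
        adj = adjusted_year_means(fit, data)
        raw = data.groupby("year")["dee_kj_day"].mean()
        assert np.allclose(adj.means, raw.loc[adj.years].to_numpy(),
                           atol=1e-8)

    def test_balanced_zero_slope_equals_raw_means(self):
        rng = np.random.default_rng(5)
        data = balanced_data({2007: 1400, 2008: 1700}, 12, 100, rng)
        fits, _ = np.empty(0), None
        from repcost.covariate_models import _fit_ols
        fit = _fit_ols(data, "dee_kj_day", ("C(year)", "adult_age_y"))
        adj = adjusted_year_means(fit, data)
        raw = data.groupby("year")["dee_kj_day"].mean()
        # balanced covariates: per-year covariate mean = grand mean
        assert np.allclose(adj.means, raw.loc[adj.years].to_numpy(),
                           atol=1e-8)

    def test_tukey_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        data = balanced_data({2007: 1400, 2008: 1500, 2012: 1600,
                              2018: 1450}, 10, 150, rng, age_slope=-8)
        from repcost.covariate_models import _fit_ols
        fit = _fit_ols(data, "dee_kj_day", ("C(year)", "adult_age_y"))
        adj = adjusted_year_means(fit, data)
        assert (adj.contrasts["p_tukey"] >= adj.contrasts["p_raw"]
                - 1e-12).all()

    def test_strong_contrast_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            data = balanced_data({2007: 1700, 2008: 1300}, 15, 150, rng)
            from repcost.covariate_models import _fit_ols
            fit = _fit_ols(data, "dee_kj_day", ("C(year)",))
            adj = adjusted_year_means(fit, data)
            if (adj.contrasts["p_tukey"] < 0.01).all():
                hits += 1
        assert hits >= 19

    def test_year_required(self):
        rng = np.random.default_rng(7)
        data = balanced_data({2007: 1400, 2008: 1700}, 12, 100, rng)
        from repcost.covariate_models import _fit_ols
        fit = _fit_ols(data, "dee_kj_day", ("adult_age_y",))
        with pytest.raises(ValueError, match="year"):
            adjusted_year_means(fit, data)


class TestResidualGate:
    def test_gaussian_mostly_untransformed(self):
        from repcost.covariate_models import _fit_ols
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            data = balanced_data({2007: 1400, 2008: 1600}, 20, 120, rng)
            fit = _fit_ols(data, "dee_kj_day", ("C(year)",))
            gated = residual_gate(fit, data)
            ok += not gated.response_transformed
        assert ok >= 15

    def test_lognormal_triggers_transform(self):
        from repcost.covariate_models import _fit_ols
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            n = 60
            data = pd.DataFrame({
                "year": [2007] * (n // 2) + [2008] * (n // 2),
                "dee_kj_day": np.exp(rng.normal(7.2, 0.6, n)),
            })
            fit = _fit_ols(data, "dee_kj_day", ("C(year)",))
            gated = residual_gate(fit, data)
            hits += gated.response_transformed
        assert hits >= 18

    def test_transform_flag_recorded(self):
        from repcost.covariate_models import _fit_ols
        rng = np.random.default_rng(8)
        n = 80
        data = pd.DataFrame({
            "year": [2007] * (n // 2) + [2008] * (n // 2),
            "dee_kj_day": np.exp(rng.normal(7.2, 0.7, n)),
        })
        fit = _fit_ols(data, "dee_kj_day", ("C(year)",))
        gated = residual_gate(fit, data)
        assert gated.response_transformed in (True, False)
        assert hasattr(gated, "normality_p")


class TestPoissonGlm:
    def test_constant_counts_zero_lr(self):
        data = pd.DataFrame({
            "fledged": [2] * 40,
            "dee_kj_day": np.linspace(1000, 2000, 40),
            "year": [2007, 2008] * 20})
        table = glm_poisson_productivity(data)
        assert (table["lr_chi2"] < 1e-6).all()

    def test_non_integer_rejected(self):
        data = pd.DataFrame({"fledged": [1.5, 2.0], "dee_kj_day": [1, 2],
                             "year": [2007, 2008]})
        with pytest.raises(ValueError, match="integer"):
            glm_poisson_productivity(data)

    def test_strong_dee_effect_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            n = 60
            dee = rng.normal(1500, 200, n)
            z = (dee - dee.mean()) / dee.std()
            lam = np.exp(np.log(1.5) * z + 0.5)
            data = pd.DataFrame({
                "fledged": rng.poisson(lam),
                "dee_kj_day": dee,
                "year": np.tile([2007, 2008, 2012, 2018], n // 4)})
            table = glm_poisson_productivity(data)
            p = table.loc[table["term"] == "dee_kj_day", "p"].iloc[0]
            hits += p < 0.05
        assert hits >= 16


class TestBinomialGlm:
    def test_null_slope_type_one_close_to_nominal(self):
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(700 + seed)
            n = 50
            data = pd.DataFrame({
                "survived": rng.integers(0, 2, n),
                "dee_kj_day": rng.normal(1500, 200, n)})
            table, sep = glm_binomial_outcome(data, "survived")
            p = table.loc[table["term"] == "dee_kj_day", "p"].iloc[0]
            rejections += p < 0.05
        assert 0 <= rejections <= 12

    def test_perfect_separation_flagged(self):
        data = pd.DataFrame({
            "survived": [0] * 10 + [1] * 10,
            "dee_kj_day": list(range(10)) + list(range(100, 110))})
        table, separated = glm_binomial_outcome(data, "survived")
        assert separated

    def test_moderate_slope_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(800 + seed)
            n = 50
            dee = rng.normal(1500, 200, n)
            z = (dee - dee.mean()) / dee.std()
            prob = 1 / (1 + np.exp(-(0.8 * z)))
            data = pd.DataFrame({
                "survived": (rng.random(n) < prob).astype(int),
                "dee_kj_day": dee})
            table, _ = glm_binomial_outcome(data, "survived")
            p = table.loc[table["term"] == "dee_kj_day", "p"].iloc[0]
            hits += p < 0.05
        assert hits >= 12   # power >= 0.6 at this slope and n
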