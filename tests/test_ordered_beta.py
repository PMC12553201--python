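import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.special import expit, logit

from conftest import TRUE_BETA, TRUE_BETA_ZERO, simulate_hurdle_data
from morbcompress import (
    ModelSpec,
    blup,
    coefficient_table,
    component_probabilities,
    continuous_density,
    fit_ordered_beta,
    marginal_negloglik,
    predict_population,
)

finite = st.floats(min_value=-5, max_value=5)


class TestComponentProbabilities:
    def test_canonical_symmetric_example(self):
        p0, pm, p1 = component_probabilities(0.0, k1=-1.0, k2=1.0, variant="canonical")
        assert p0 == pytest.approx(1 - expit(1.0), abs=1e-5)
        assert p1 == pytest.approx(expit(-1.0), abs=1e-5)
        assert pm == pytest.approx(expit(1.0) - expit(-1.0), abs=1e-5)

    @settings(max_examples=100, deadline=None)
    @given(finite, finite, st.floats(min_value=0.01, max_value=4))
    def test_canonical_components_telescope_to_one(self, eta, k1, dk):
        p0, pm, p1 = component_probabilities(eta, k1=k1, k2=k1 + dk, variant="canonical")
        assert p0 + pm + p1 == pytest.approx(1.0, abs=1e-12)
        assert min(p0, pm, p1) >= 0

    @settings(max_examples=100, deadline=None)
    @given(finite, finite, finite)
    def test_hurdle_components_sum_to_one(self, eta, eta_zero, k2):
        p0, pm, p1 = component_probabilities(eta, eta_zero=eta_zero, k2=k2)
        assert p0 + pm + p1 == pytest.approx(1.0, abs=1e-12)

    def test_hurdle_degenerate_zero_part(self):
        p0, pm, p1 = component_probabilities(0.5, eta_zero=-40.0, k2=1.0)
        assert p0 == pytest.approx(0.0, abs=1e-12)
        assert p1 == pytest.approx(expit(-0.5), abs=1e-9)

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="k1 < k2"):
            component_probabilities(0.0, k1=1.0, k2=1.0, variant="canonical")


class TestContinuousDensity:
    def test_uniform_special_case(self):
        y = np.array([0.1, 0.5, 0.9])
        assert np.allclose(continuous_density(y, 0.0, 0.0, 2.0), 1.0)

    def test_symmetry_at_half_mean(self):
        assert continuous_density(0.3, 0.0, 0.0, 7.0) == pytest.approx(
            continuous_density(0.7, 0.0, 0.0, 7.0)
        )

    def test_integrates_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            eta, u = rng.uniform(-2, 2, 2)
            psi = rng.uniform(0.5, 20)
            val, _ = integrate.quad(
                lambda t: continuous_density(t, eta, u, psi), 0, 1, limit=200
            )
            assert val == pytest.approx(1.0, abs=1e-7)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            continuous_density(0.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            continuous_density(0.5, 0.0, 0.0, -1.0)


@pytest.fixture(scope="module")
def toy(request):
    df, _ = simulate_hurdle_data(3, n=150, n_regions=3, sigma_u=0.4)
    return df


class TestMarginalNegloglik:
    def params(self, **kw):
        p = dict(beta=TRUE_BETA, beta_zero=TRUE_BETA_ZERO, k2=2.0, psi=8.0)
        p.update(kw)
        return p

    def test_vanishing_random_effect_matches_plain_likelihood(self, toy):
        with_re = marginal_negloglik(
            self.params(sigma_u=1e-6), toy, ModelSpec("hurdle", "region")
        )
        plain = marginal_negloglik(self.params(), toy, ModelSpec("hurdle", "none"))
        assert with_re == pytest.approx(plain, abs=1e-4)

    def test_laplace_agrees_with_adaptive_quadrature(self, toy):
        spec = ModelSpec("hurdle", "region")
        lap = marginal_negloglik(self.params(sigma_u=0.4), toy, spec, method="laplace")
        quad = marginal_negloglik(self.params(sigma_u=0.4), toy, spec, method="aghq")
        assert lap == pytest.approx(quad, abs=0.05)

    def test_single_zero_observation_is_pure_point_mass(self, toy):
        from morbcompress.ordered_beta import _build_design

        one = toy[toy["y"] == 0].iloc[[0]]
        nll = marginal_negloglik(self.params(), one, ModelSpec("hurdle", "none"))
        gamma = expit(_build_design(one, int(one["year"].iloc[0])) @ TRUE_BETA_ZERO)[0]
        assert nll == pytest.approx(-np.log(gamma), abs=1e-12)

    def test_out_of_range_outcome_rejected(self, toy):
        bad = toy.copy()
        bad.loc[bad.index[0], "y"] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            marginal_negloglik(self.params(), bad, ModelSpec("hurdle", "none"))

    def test_variants_coincide_on_constructed_case(self):
        """With constant covariates the hurdle family reproduces the canonical
        likelihood exactly once its zero line and cutpoint are matched."""
        rng = np.random.default_rng(8)
        n = 60
        df = pd.DataFrame(
            {
                "region": 1,
                "year": 2010,
                "age": 40,
                "sex": "female",
                "education": "high",
                "economic": "none",
                "y": np.concatenate(
                    [[0.0] * 10, [1.0] * 5, rng.uniform(0.05, 0.95, n - 15)]
                ),
            }
        )
        beta = np.array([0.4, 0, 0, 0, 0, 0, 0])
        k1, k2, psi = -1.2, 1.5, 6.0
        eta = 0.4
        s1, s2 = expit(eta - k1), expit(eta - k2)
        canonical = marginal_negloglik(
            dict(beta=beta, k1=k1, k2=k2, psi=psi),
            df,
            ModelSpec("canonical", "none"),
        )
        beta_zero = np.array([logit(1 - s1), 0, 0, 0, 0, 0, 0])
        k2_h = eta - logit(s2 / s1)
        hurdle = marginal_negloglik(
            dict(beta=beta, beta_zero=beta_zero, k2=k2_h, psi=psi),
            df,
            ModelSpec("hurdle", "none"),
        )
        assert hurdle == pytest.approx(canonical, abs=1e-10)


@pytest.fixture(scope="module")
def fitted():
    df, u = simulate_hurdle_data(21, n=4000, sigma_u=0.0)
    fit = fit_ordered_beta(df, ModelSpec("hurdle", "none"))
    return df, fit


class TestFit:
    def test_no_re_recovery(self, fitted):
        _, fit = fitted
        assert np.abs(fit.coef.to_numpy() - TRUE_BETA).max() < 0.15
        assert np.abs(fit.coef_zero.to_numpy() - TRUE_BETA_ZERO).max() < 0.15
        assert abs(fit.psi - 8.0) / 8.0 < 0.15
        assert fit.converged

    def test_row_permutation_invariance(self, fitted):
        df, fit = fitted
        shuffled = df.sample(frac=1.0, random_state=5)
        refit = fit_ordered_beta(shuffled, ModelSpec("hurdle", "none"))
        assert np.abs(fit.coef.to_numpy() - refit.coef.to_numpy()).max() < 1e-8
        assert fit.loglik == pytest.approx(refit.loglik, abs=1e-8)

    def test_year_recoding_invariance(self, fitted):
        """Shifting the calendar origin changes nothing but the origin."""
        df, fit = fitted
        shifted = df.copy()
        shifted["year"] = shifted["year"] + 7
        refit = fit_ordered_beta(shifted, ModelSpec("hurdle", "none"))
        assert fit.loglik == pytest.approx(refit.loglik, abs=1e-6)
        assert np.abs(
            fit.coef.to_numpy()[1:] - refit.coef.to_numpy()[1:]
        ).max() < 1e-6

    def test_missing_boundary_mass_strict_vs_auto(self, fitted):
        df, _ = fitted
        interior_only = df[(df["y"] > 0) & (df["y"] < 1)]
        with pytest.raises(ValueError, match="reduced model"):
            fit_ordered_beta(interior_only, ModelSpec("hurdle", "none"))
        fit = fit_ordered_beta(
            interior_only, ModelSpec("hurdle", "none"), components="auto"
        )
        assert fit.coef_zero is None and fit.k2 is None

    def test_coefficient_table_layout(self, fitted):
        _, fit = fitted
        table = coefficient_table(fit)
        assert set(table["model"]) == {"Conditional model", "Zero-inflation model"}
        assert list(table.columns) == [
            "model",
            "term",
            "Estimate",
            "Std. Error",
            "t value",
            "p-value",
        ]
        assert len(table) == 14


@pytest.fixture(scope="module")
def fit():
    df, _ = simulate_hurdle_data(31, n=6000, sigma_u=0.0)
    return fit_ordered_beta(df, ModelSpec("hurdle", "none"), compute_se=False)


class TestPrediction:
    def grid(self, **kw):
        base = dict(
            sex="female", age=50, education="high", economic="none", year=2010
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_population_estimate_combines_components(self, fit):
        out = predict_population(fit, self.grid()).table
        assert np.allclose(out["yhat"], (1 - out["gamma"]) * out["mu"])
        assert 0 <= out["yhat"].iloc[0] <= 1
        assert 0 < out["mu"].iloc[0] <= 1

    def test_certain_zero_gives_zero_estimate(self, fit):
        import copy

        sure_zero = copy.copy(fit)
        sure_zero.coef_zero = fit.coef_zero.copy()
        sure_zero.coef_zero["(Intercept)"] = 50.0
        out = predict_population(sure_zero, self.grid()).table
        assert out["gamma"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert out["yhat"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_multimorbidity_rises_with_age(self, fit):
        """Truth has conditional age effect > 0 and zero-part age effect < 0,
        the published sign pattern, so the population estimate grows with age."""
        ages = pd.concat([self.grid(age=a) for a in (25, 45, 65)], ignore_index=True)
        out = predict_population(fit, ages).table
        assert out["yhat"].is_monotonic_increasing

    def test_unknown_level_rejected(self, fit):
        with pytest.raises(ValueError, match="unknown covariate level"):
            predict_population(fit, self.grid(sex="other"))


class TestBlup:
    def test_null_random_effect_yields_tiny_blups(self):
        df, _ = simulate_hurdle_data(41, n=6000, n_regions=10, sigma_u=0.0)
        fit = fit_ordered_beta(df, ModelSpec("hurdle", "region"), compute_se=False)
        table = blup(fit)
        assert len(table) == 10
        assert np.abs(table["estimate"]).max() < 0.05

    def test_blups_shrink_toward_zero_and_center(self):
        from morbcompress.ordered_beta import _inner_modes, _unpack

        df, _ = simulate_hurdle_data(43, n=6000, n_regions=8, sigma_u=0.4)
        fit = fit_ordered_beta(df, ModelSpec("hurdle", "region"), compute_se=False)
        table = blup(fit)
        # unpenalised per-region offsets: same inner problem with a flat prior
        par = _unpack(fit.theta, fit._prep, fit.spec)
        par["sigma_u"] = 1e6
        fit._prep.u_cache = None
        saturated, _ = _inner_modes(par, fit._prep, fit.spec)
        centered = saturated - saturated.mean()
        assert np.all(np.abs(table["estimate"]) <= np.abs(centered) + 0.02)
        assert abs(table["estimate"].sum() / len(table)) < 0.05

    def test_requires_random_effect(self):
        df, _ = simulate_hurdle_data(45, n=500, sigma_u=0.0)
        fit = fit_ordered_beta(df, ModelSpec("hurdle", "none"), compute_se=False)
        with pytest.raises(ValueError, match="random effect"):
            blup(fit)
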