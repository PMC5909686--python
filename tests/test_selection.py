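"""AICc weights, variance explained, effect sizes, model averaging."""

import numpy as np
import pandas as pd
import pytest

from reeftransfer import (
    MODEL_SETS,
    NegativeBinomialGLM,
    aicc,
    deviance_explained,
    effect_sizes,
    model_average_predictions,
    model_set,
    r2_nakagawa,
    waicc_rank,
)
from reeftransfer.selection import top_models

from conftest import simulate_glmm_counts
from reeftransfer import NegativeBinomialGLMM


def _sim(seed=0, n=300, beta=(1.2, 0.6, 0.0), theta=3.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    mu = np.exp(beta[0] + beta[1] * X["a"] + beta[2] * X["b"])
    y = rng.negative_binomial(theta, theta / (theta + mu)).astype(int)
    return X, np.asarray(y)


@pytest.fixture(scope="module")
def fitted_pair():
    X, y = _sim()
    full = NegativeBinomialGLM().fit(X, y)
    single = NegativeBinomialGLM().fit(X[["a"]], y)
    null = NegativeBinomialGLM().fit(X[[]], y)
    return X, y, {1: full, 2: single, 12: null}


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-50.0, k=3, n=100) == pytest.approx(106.25)

    def test_converges_to_aic_for_large_n(self):
        assert aicc(-50.0, k=3, n=10**7) == pytest.approx(106.0, abs=1e-4)

    def test_equal_inputs_equal_outputs(self):
        assert aicc(-12.5, k=4, n=60) == aicc(-12.5, k=4, n=60)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, k=10, n=11)


class TestWaicc:
    def test_single_model_weight_one(self, fitted_pair):
        _, _, fits = fitted_pair
        tab = waicc_rank({1: fits[1]})
        assert tab["wAICc"].iloc[0] == pytest.approx(1.0)

    def test_delta_two_closed_form(self):
        # dAICc (0, 2) -> weights (0.7311, 0.2689)
        d = np.array([0.0, 2.0])
        w = np.exp(-d / 2) / np.exp(-d / 2).sum()
        assert w == pytest.approx([0.73106, 0.26894], abs=5e-5)

    def test_weights_sum_to_one_and_best_delta_zero(self, fitted_pair):
        _, _, fits = fitted_pair
        tab = waicc_rank(fits)
        assert tab["wAICc"].sum() == pytest.approx(1.0, abs=1e-12)
        assert tab["dAICc"].iloc[0] == 0.0
        # the data were generated from model "single"+noise coef 0: full and
        # single should share nearly all weight
        assert tab.loc[12, "wAICc"] < 0.01

    def test_weight_invariance_to_constant_aicc_shift(self, fitted_pair):
        _, _, fits = fitted_pair
        tab = waicc_rank(fits)
        shifted = np.exp(-0.5 * (tab["AICc"] + 123.4 - (tab["AICc"] + 123.4).min()))
        assert np.allclose(shifted / shifted.sum(), tab["wAICc"])

    def test_mismatched_responses_rejected(self, fitted_pair):
        X, y, fits = fitted_pair
        other = NegativeBinomialGLM().fit(X, np.roll(y, 1))
        with pytest.raises(ValueError):
            waicc_rank({1: fits[1], 2: other})

    def test_pure_noise_predictor_can_lower_weight(self, fitted_pair):
        _, _, fits = fitted_pair
        tab = waicc_rank(fits)
        assert fits[1].loglik_ >= fits[2].loglik_ - 1e-8  # ll never decreases
        assert tab.loc[2, "wAICc"] > tab.loc[1, "wAICc"]  # but weight penalises k


class TestR2:
    def test_direct_formula(self):
        class F:  # minimal stand-in exposing the variance components
            fitted_ = np.exp(np.array([0.0, 2.0]))  # var of log fitted = 1
            ranef_ = None
            sigma_alpha2_ = 1.0
            y_ = np.ones(2)
            theta_ = 1.0

        # var_f = 1, var_a = 1; choose lambda/theta so var_d = ln(1+1/1+1/1) ~ 1.0986
        r2m, r2c = r2_nakagawa(F())
        total = 1 + 1 + np.log(3.0)
        assert r2m == pytest.approx(1 / total)
        assert r2c == pytest.approx(2 / total)

    def test_null_model_marginal_zero(self):
        X, y, g = simulate_glmm_counts(3, n_reefs=10, sites=10)
        null = NegativeBinomialGLMM().fit(X[[]], y, groups=g)
        r2m, r2c = r2_nakagawa(null)
        assert r2m == pytest.approx(0.0, abs=1e-10)
        assert r2c >= r2m

    def test_marginal_below_conditional_in_unit_interval(self):
        X, y, g = simulate_glmm_counts(6, n_reefs=15, sites=10)
        f = NegativeBinomialGLMM().fit(X, y, groups=g)
        for variant in ("lognormal", "trigamma"):
            r2m, r2c = r2_nakagawa(f, variant=variant)
            assert 0.0 <= r2m <= r2c <= 1.0


class TestDevianceExplained:
    def test_null_model_zero(self, fitted_pair):
        _, _, fits = fitted_pair
        assert deviance_explained(fits[12]) == pytest.approx(0.0, abs=1e-6)

    def test_informative_model_positive_below_100(self, fitted_pair):
        _, _, fits = fitted_pair
        de = deviance_explained(fits[1])
        assert 0.0 < de < 100.0


class TestEffectSizes:
    def test_single_model_equals_standardised_coefs(self, fitted_pair):
        X, _, fits = fitted_pair
        tab = waicc_rank({1: fits[1]})
        sd = X.std(ddof=1).to_dict()
        eff = effect_sizes(tab, {1: fits[1]}, sd)
        assert eff["a"] == pytest.approx(abs(fits[1].coef_[1]) * sd["a"])
        assert eff.index[0] == "a"  # data built with a as the real driver

    def test_zero_coefficient_zero_effect(self, fitted_pair):
        X, y, fits = fitted_pair
        f = fits[1]
        saved = f.coef_.copy()
        try:
            f.coef_ = np.array([saved[0], saved[1], 0.0])
            tab = waicc_rank({1: f})
            eff = effect_sizes(tab, {1: f}, X.std(ddof=1).to_dict())
            assert eff["b"] == 0.0
        finally:
            f.coef_ = saved


class TestModelAveraging:
    def test_degenerate_weights_select_single_model(self, fitted_pair):
        X, _, fits = fitted_pair
        tab = waicc_rank(fits).copy()
        tab["wAICc"] = [0.0] * len(tab)
        tab.loc[1, "wAICc"] = 1.0
        avg = model_average_predictions(tab, {1: fits[1]}, X)
        assert np.allclose(avg, fits[1].predict(X))

    def test_hand_weighted_mean(self, fitted_pair):
        X, _, fits = fitted_pair
        tab = waicc_rank(fits)
        avg = model_average_predictions(tab, fits, X)
        w = tab["wAICc"]
        manual = sum(w[mid] * fits[mid].predict(X[list(fits[mid].term_names_[1:])])
                     for mid in fits)
        assert np.allclose(avg, manual)


class TestModelCatalogue:
    def test_twelve_models_per_edition(self):
        assert set(MODEL_SETS["GBR"]) == set(range(1, 13))
        assert set(MODEL_SETS["NR"]) == set(range(1, 13))
        assert set(MODEL_SETS["NR+rugosity"]) == set(range(1, 14))

    def test_null_model_is_intercept_only(self):
        assert MODEL_SETS["GBR"][12].terms == ()

    def test_system_specific_omissions(self):
        assert "NO3_av" in MODEL_SETS["GBR"][1].terms
        assert "NO3_av" not in MODEL_SETS["NR"][1].terms
        assert "crbnt" in MODEL_SETS["GBR"][4].terms
        assert MODEL_SETS["NR"][4].terms == ("gravel",)

    def test_quadratic_terms_follow_their_bases(self):
        for edition in MODEL_SETS:
            for spec in MODEL_SETS[edition].values():
                for t in spec.terms:
                    if t.endswith("2") and t != "O2_av":
                        assert t[:-1] in spec.terms

    def test_rugosity_model_is_quadratic(self):
        assert MODEL_SETS["NR+rugosity"][13].terms == ("rugosity", "rugosity2")

    def test_random_intercept_toggle(self):
        glmm_set = model_set("GBR", "reef")
        glm_set = model_set("NR", None)
        assert all(s.random_intercept == "reef" for s in glmm_set.values())
        assert all(s.random_intercept is None for s in glm_set.values())


def test_top_models_cover_cumulative_weight(fitted_pair):
    _, _, fits = fitted_pair
    tab = waicc_rank(fits)
    ids = top_models(tab, cum_weight=0.9)
    assert ids[0] == tab.index[0]
    assert tab.loc[ids, "wAICc"].sum() >= 0.9 or len(ids) == len(tab)
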