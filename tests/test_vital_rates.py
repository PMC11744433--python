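"""Vital-rate fitters, AICc arithmetic, and model-selection rules."""

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

import skewipm._skewnorm as sn
from skewipm import synthetic
from skewipm.vital_rates import (
    BinomialGLM,
    GaussianSizeModel,
    ModelSet,
    NegativeBinomialGLM,
    RatioLinearModel,
    SkewNormalGrowth,
    aicc,
    confidence_set,
    dredge,
    fit_seedling_survival,
    fit_seedlings_per_flower,
    select_parsimonious,
)
from skewipm.terms import enumerate_hierarchical


# ---------------------------------------------------------------------------
# AICc


def test_aicc_arithmetic():
    assert aicc(-10.0, 2, 100) == pytest.approx(24.1237, abs=5e-5)
    # large-n limit is plain AIC
    assert aicc(-10.0, 2, 10**9) == pytest.approx(24.0, abs=1e-6)
    with pytest.raises(ValueError):
        aicc(-10.0, 2, 3)


def test_aicc_matches_direct_formula_on_random_inputs():
    rng = np.random.default_rng(4)
    for _ in range(20):
        ll = rng.uniform(-500, 0)
        k = int(rng.integers(1, 15))
        n = int(rng.integers(k + 2, 1000))
        expected = -2 * ll + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
        assert aicc(ll, k, n) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# binomial


def test_logit_closed_form_two_point_design():
    # successes 5/10 at size 0 and 9/10 at size 1: intercept log(1), slope log(9)
    df = pd.DataFrame({"size": [0.0] * 10 + [1.0] * 10})
    y = [1] * 5 + [0] * 5 + [1] * 9 + [0] * 1
    m = BinomialGLM(("size",)).fit(df, y)
    assert m.coef_[0] == pytest.approx(0.0, abs=1e-6)
    assert m.coef_[1] == pytest.approx(np.log(9.0), abs=1e-6)


def test_all_successes_flagged_as_separation():
    df = pd.DataFrame({"size": np.linspace(0, 1, 20)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = BinomialGLM(()).fit(df, np.ones(20))
    assert m.separation_


def test_confounded_factors_raise_rank_deficiency():
    # site and year partition the data identically: aliased dummies
    df = pd.DataFrame(
        {
            "size": np.r_[np.linspace(0, 1, 10), np.linspace(0, 1, 10)],
            "site": ["A"] * 10 + ["B"] * 10,
            "year": [1] * 10 + [2] * 10,
        }
    )
    y = np.tile([0, 1], 10)
    with pytest.raises(ValueError, match="rank-deficient"):
        BinomialGLM(("site", "year", "site:year")).fit(df, y)


# ---------------------------------------------------------------------------
# negative binomial


def test_nb_constant_response_clamps_dispersion():
    df = pd.DataFrame({"size": np.zeros(30)})
    with pytest.warns(UserWarning, match="clamped"):
        m = NegativeBinomialGLM(()).fit(df, np.full(30, 4.0))
    assert m.theta_ == NegativeBinomialGLM.THETA_MAX
    assert m.coef_[0] == pytest.approx(np.log(4.0), abs=1e-6)


def test_nb_intercept_only_mean_equals_sample_mean():
    rng = np.random.default_rng(7)
    y = rng.negative_binomial(2.0, 2.0 / 7.0, size=500).astype(float)
    df = pd.DataFrame({"size": np.zeros_like(y)})
    m = NegativeBinomialGLM(()).fit(df, y)
    assert m.predict(df)[0] == pytest.approx(y.mean(), rel=1e-5)


def test_nb_dispersion_recovery():
    theta, mu = 2.0, 5.0
    rng = np.random.default_rng(21)
    y = rng.negative_binomial(theta, theta / (theta + mu), size=10_000).astype(float)
    m = NegativeBinomialGLM(()).fit(pd.DataFrame({"size": np.zeros_like(y)}), y)
    assert abs(m.theta_ - theta) / theta < 0.2


def test_shifted_nb_predicts_on_count_scale():
    rng = np.random.default_rng(3)
    y = 1.0 + rng.negative_binomial(2.0, 2.0 / 5.0, size=2000)
    m = NegativeBinomialGLM((), shifted=True).fit(
        pd.DataFrame({"size": np.zeros_like(y)}), y
    )
    assert m.predict(pd.DataFrame({"size": [0.0]}))[0] == pytest.approx(
        y.mean(), rel=0.05
    )
    with pytest.raises(ValueError):
        NegativeBinomialGLM((), shifted=True).fit(
            pd.DataFrame({"size": [0.0]}), [0.0]
        )


# ---------------------------------------------------------------------------
# skew normal


def test_skewnorm_density_integrates_to_one():
    rng = np.random.default_rng(11)
    for _ in range(20):
        xi = rng.uniform(-2, 2)
        omega = rng.uniform(0.3, 3.0)
        alpha = rng.uniform(-5, 5)
        val, err = integrate.quad(
            lambda z: sn.pdf(z, xi, omega, alpha), -np.inf, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-6)


def test_skewnorm_cdf_matches_scipy():
    rng = np.random.default_rng(2)
    z = rng.uniform(-4, 4, 50)
    for alpha in (-3.0, 0.0, 0.7, 4.0):
        np.testing.assert_allclose(
            sn.cdf(z, 0.0, 1.0, alpha), stats.skewnorm.cdf(z, alpha), atol=1e-12
        )


def test_skewnorm_reduces_to_gaussian_when_data_symmetric():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 4, 3000)
    y = 0.5 + 0.9 * x + 0.4 * rng.standard_normal(3000)
    df = pd.DataFrame({"size": x})
    skew = SkewNormalGrowth(("size",), (), ()).fit(df, y)
    gauss = GaussianSizeModel(("size",), ()).fit(df, y)
    # shape block near zero; log-likelihood within 1 unit of the gaussian fit
    assert abs(skew._split_coef()[2][0]) < 0.5
    assert abs(skew.loglik_ - gauss.loglik_) < 1.0
    assert skew.loglik_ >= gauss.loglik_ - 1e-6  # nesting


def test_skewnorm_parameter_recovery_within_3_se():
    rng = np.random.default_rng(17)
    n = 10_000
    x = rng.uniform(0, 5, n)
    xi = 1.0 + 0.9 * x
    y = sn.rvs(xi, 0.4, 2.0, n, rng)
    m = SkewNormalGrowth(("size",), (), ()).fit(pd.DataFrame({"size": x}), y)
    truth = np.array([1.0, 0.9, np.log(0.4), 2.0])
    se = np.sqrt(np.diag(m.cov_))
    assert np.all(np.abs(m.coef_ - truth) < 3 * se)


def test_skewnorm_loglik_nesting_across_term_sets(adults):
    g = adults.dropna(subset=["size_t1"])
    sub = SkewNormalGrowth(("size",), (), ()).fit(g, g["size_t1"])
    sup = SkewNormalGrowth(("size", "site"), ("size",), ()).fit(g, g["size_t1"])
    assert sup.loglik_ >= sub.loglik_ - 1e-6


# ---------------------------------------------------------------------------
# gaussian recruit size / seedling rates


def test_gaussian_closed_form_mle():
    df = pd.DataFrame({"size": np.zeros(3)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # AICc undefined at n=3, k=2
        m = GaussianSizeModel((), ()).fit(df, [1.0, 2.0, 3.0])
    assert m.coef_[0] == pytest.approx(2.0, abs=1e-5)
    assert np.exp(m.coef_[1]) == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-4)
    with pytest.raises(ValueError):
        GaussianSizeModel((), ()).fit(pd.DataFrame({"size": [0.0, 0.0]}), [1.0, 2.0])


def test_seedling_survival_closed_form():
    df = pd.DataFrame(
        {"stage": ["seedling"] * 10, "survived": [1] * 3 + [0] * 7, "site": "A"}
    )
    m = fit_seedling_survival(df, ())
    assert special.expit(m.coef_[0]) == pytest.approx(0.3, abs=1e-6)
    assert m.coef_[0] == pytest.approx(-0.847, abs=5e-4)
    with pytest.raises(ValueError):
        fit_seedling_survival(df, ("year",))


def test_ratio_model_closed_forms():
    df = pd.DataFrame({"site": ["A", "B", "C"], "year": [1, 1, 1]})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = RatioLinearModel(()).fit(df, [0.2, 0.4, 0.6])
    assert m.coef_[0] == pytest.approx(0.4, abs=1e-12)
    assert m.sigma_ == pytest.approx(np.sqrt(0.08 / 3.0), rel=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        single = RatioLinearModel(()).fit(df.iloc[:1], [0.4])
    assert single.coef_[0] == pytest.approx(0.4)
    with pytest.raises(ValueError):
        RatioLinearModel(("size",))


def test_ratio_recovery_from_generated_quadrats():
    params = synthetic.single_cell_params()
    census = synthetic.generate_census(params, 400, seed=31)
    seedl = synthetic.generate_seedlings(params, census, n_quadrats=10_000, seed=32)
    m = fit_seedlings_per_flower(seedl, ())
    assert m.coef_[0] == pytest.approx(0.6, rel=0.10)


# ---------------------------------------------------------------------------
# model sets


@dataclass
class _Dummy:
    aicc_: float
    k_: int = 1


def _model_set(aiccs, ks=None):
    ks = ks or [1] * len(aiccs)
    return ModelSet([_Dummy(a, k) for a, k in zip(aiccs, ks)])


def test_weights_sum_to_one():
    ms = _model_set([10.0, 11.5, 14.0])
    assert ms.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_parsimonious_selection_prefers_fewest_parameters():
    # (k, delta) = (5, 0), (3, 1.9), (4, 0.5): the k=3 model wins
    ms = _model_set([100.0, 101.9, 100.5], ks=[5, 3, 4])
    assert select_parsimonious(ms, 2.0).k_ == 3
    only = _model_set([50.0])
    assert select_parsimonious(only) is only.models[0]
    with pytest.raises(ValueError):
        select_parsimonious(ModelSet([]))


def test_confidence_set_prefix_and_renormalization():
    # Akaike weights 0.7 / 0.25 / 0.05: the 95% set keeps the first two
    target = np.array([0.7, 0.25, 0.05])
    aiccs = -2.0 * np.log(target)
    ms = _model_set(list(aiccs))
    np.testing.assert_allclose(ms.weights, target, atol=1e-12)
    models, w = confidence_set(ms, 0.95)
    assert len(models) == 2
    np.testing.assert_allclose(w, [0.7368, 0.2632], atol=1e-4)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    one, w1 = confidence_set(_model_set([5.0]), 0.95)
    assert len(one) == 1 and w1[0] == 1.0


def test_confidence_set_renormalizes_on_random_weight_vectors():
    rng = np.random.default_rng(9)
    for _ in range(20):
        raw = rng.uniform(0.05, 1.0, size=rng.integers(2, 8))
        ms = _model_set(list(-2.0 * np.log(raw / raw.sum())))
        _, w = confidence_set(ms, 0.95)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_dredge_drops_failing_candidates_and_ranks_rest(adults):
    def fit_fn(terms):
        if terms == ("size",):
            raise RuntimeError("synthetic failure")
        return BinomialGLM(terms).fit(adults, adults["survived"])

    with pytest.warns(UserWarning, match="dropped"):
        ms = dredge(fit_fn, [(), ("size",)], "survival")
    assert len(ms) == 1


def test_glm_nesting_increases_loglik(adults):
    lls = []
    for terms in [(), ("size",), ("size", "site"), ("size", "site", "year")]:
        lls.append(BinomialGLM(terms).fit(adults, adults["survived"]).loglik_)
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_no_effect_data_selects_no_site_year_terms():
    """Dredging survival on data with no site/year structure keeps them out.

    With 19 hierarchical candidates and the simplest-within-2-AICc rule,
    the chance that some spurious factor term beats the true size-only
    model by more than 2 AICc is roughly 15-20% under the null, so the
    exclusion frequency is bounded at 70% rather than higher.
    """
    base = synthetic.single_cell_params()
    row = base.cells.iloc[0]
    cells = synthetic._cells_frame(
        ("A", "B", "C"), (1, 2, 3), {k: row[k] for k in base.cells.columns}
    )
    params = synthetic.TrueParams(cells=cells)
    term_sets = enumerate_hierarchical(
        ("size", "site", "year", "size:site", "size:year", "site:year", "size:site:year")
    )
    hits = 0
    n_rep = 50
    for rep in range(n_rep):
        census = synthetic.generate_census(params, 100, seed=500 + rep)
        ad = census[census["stage"] == "adult"].rename(columns={"size_t": "size"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = dredge(
                lambda t: BinomialGLM(t).fit(ad, ad["survived"]), term_sets, "survival"
            )
            best = select_parsimonious(ms, 2.0)
        if not any(("site" in t) or ("year" in t) for t in best.terms):
            hits += 1
    assert hits >= 0.7 * n_rep


def test_growth_full_dredge_on_tiny_block_space(adults):
    from skewipm.vital_rates import dredge_growth

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ms = dredge_growth(
            adults.rename(columns={"size": "size_t"}),
            maximal_mu=("size",),
            maximal_sigma=("size",),
            maximal_nu=(),
            mode="full",
        )
    assert len(ms) == 4  # 2 mu x 2 sigma x 1 nu candidates
    assert ms.weights.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="dredge mode"):
        dredge_growth(adults.rename(columns={"size": "size_t"}), mode="nope")
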