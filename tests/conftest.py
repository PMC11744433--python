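"""Shared fixtures: the reference synthetic study and a fitted pipeline."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import special

import skewipm as ski
from skewipm import synthetic


@pytest.fixture(scope="session")
def ref_params():
    return ski.reference_params()


@pytest.fixture(scope="session")
def ref_census(ref_params):
    return ski.generate_census(ref_params, n_per_cell=200, seed=11)


@pytest.fixture(scope="session")
def ref_seedlings(ref_params, ref_census):
    return ski.generate_seedlings(ref_params, ref_census, n_quadrats=40, seed=12)


@pytest.fixture(scope="session")
def analysis(ref_census, ref_seedlings):
    """Fitted pipeline on the reference data (stochastic steps reduced)."""
    cfg = ski.PipelineConfig(seed=7, shifted_counts=True, n_steps_stochastic=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ski.DemographyAnalysis(cfg).fit(ref_census, ref_seedlings)


@pytest.fixture(scope="session")
def adults(ref_census):
    return ref_census[ref_census["stage"] == "adult"].rename(columns={"size_t": "size"})


def one_site_three_year_params():
    """1 site x 3 transitions with year effects; used by coverage-style tests."""
    years = (1, 2, 3)
    yoff = {1: 0.0, 2: -0.2, 3: 0.3}
    values = {
        ("survival", "intercept"): [0.2 + yoff[y] for y in years],
        ("survival", "slope"): 0.5,
        ("flowering", "intercept"): [-3.5 + 1.4 * yoff[y] for y in years],
        ("flowering", "slope"): 0.9,
        ("flower_count", "intercept"): -1.5,
        ("flower_count", "slope"): 0.35,
        ("growth_mu", "intercept"): [1.1 + 0.5 * yoff[y] for y in years],
        ("growth_mu", "slope"): 0.84,
        ("growth_sigma", "intercept"): -0.4,
        ("growth_sigma", "slope"): -0.03,
        ("growth_nu", "intercept"): -1.5,
        ("growth_nu", "slope"): 0.0,
        ("seedling_survival", "intercept"): special.logit(0.4),
        ("recruit_mu", "intercept"): 2.2,
        ("recruit_sigma", "intercept"): np.log(0.6),
        ("seedlings_per_flower", "intercept"): 0.6,
    }
    return synthetic.TrueParams(
        cells=synthetic._cells_frame(("A",), years, values)
    )


def fit_true_structure(census, seedlings, shifted=True):
    """Fit every vital rate with its generating term structure (no dredge)."""
    from skewipm.vital_rates import (
        BinomialGLM,
        GaussianSizeModel,
        NegativeBinomialGLM,
        RatioLinearModel,
        SkewNormalGrowth,
        seedling_ratio_observations,
    )

    ad = census[census["stage"] == "adult"].rename(columns={"size_t": "size"})
    n_years = census["year"].nunique()
    yterm = ("size", "year") if n_years > 1 else ("size",)
    models = {}
    models["survival"] = BinomialGLM(yterm).fit(ad, ad["survived"])
    models["flowering"] = BinomialGLM(yterm).fit(ad, ad["flowered"])
    flw = ad[ad["flowered"] == 1]
    models["flower_count"] = NegativeBinomialGLM(("size",), shifted=shifted).fit(
        flw, flw["flower_count"]
    )
    g = ad.dropna(subset=["size_t1"])
    models["growth"] = SkewNormalGrowth(yterm, ("size",), ()).fit(g, g["size_t1"])
    sdl = census[census["stage"] == "seedling"]
    models["seedling_survival"] = BinomialGLM(()).fit(sdl, sdl["survived"])
    rec = sdl[(sdl["survived"] == 1) & sdl["size_t1"].notna()]
    models["recruit_size"] = GaussianSizeModel((), ()).fit(rec, rec["size_t1"])
    obs = seedling_ratio_observations(seedlings)
    models["seedlings_per_flower"] = RatioLinearModel(()).fit(obs, obs["ratio"])
    return models
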