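"""Vital-rate regressions, AICc model selection, and confidence model sets.

Each demographic transition (survival, flowering, flower count, growth,
seedling rates, per-flower recruitment) is fitted by an estimator class in
the scikit-learn style: constructor parameters describe the model (term
sets, family options), ``fit(X, y)`` takes a covariate DataFrame with
``size``/``site``/``year`` columns, and fitted state lives in trailing-
underscore attributes (``coef_``, ``cov_``, ``loglik_``, ``aicc_``).

Model selection follows small-sample AIC: all marginality-respecting
sub-models of a maximal formula are fitted ("dredging"), ranked by AICc,
and the simplest model within 2 AICc of the minimum is selected.  Akaike
weights over the candidates define a 95% confidence model set used by the
parametric bootstrap.

The growth distribution is a skew normal whose location (identity link),
scale (log link) and shape (identity link) are each linear in covariates
and estimated jointly by maximum likelihood — the feature that lets the
projection model carry size-dependent variance and skewness (shrinkage)
as first-class vital rates.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from sklearn.base import BaseEstimator
from statsmodels.discrete.discrete_model import NegativeBinomial as _SMNegBin
from statsmodels.tools import numdiff

from . import _skewnorm
from .terms import canonical, design_matrix, enumerate_hierarchical

__all__ = [
    "aicc",
    "VitalRateEstimator",
    "BinomialGLM",
    "NegativeBinomialGLM",
    "SkewNormalGrowth",
    "GaussianSizeModel",
    "RatioLinearModel",
    "ModelSet",
    "dredge",
    "dredge_growth",
    "select_parsimonious",
    "confidence_set",
    "akaike_weights",
    "fit_binomial",
    "fit_negative_binomial",
    "fit_skew_normal_growth",
    "fit_gaussian_recruit_size",
    "fit_seedling_survival",
    "fit_seedlings_per_flower",
    "seedling_ratio_observations",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _levels(data: pd.DataFrame, col: str):
    if col in data.columns:
        return tuple(sorted(pd.unique(data[col])))
    return ()


class VitalRateEstimator(BaseEstimator):
    """Shared surface for fitted vital-rate models.

    Fitted attributes: ``coef_`` (full coefficient vector across predictor
    blocks), ``coef_names_``, ``cov_`` (covariance of ``coef_``),
    ``loglik_``, ``k_``, ``n_``, ``aicc_``, and the factor levels seen at
    fit time.  ``linear_predictors`` returns one link-scale predictor per
    block ("mean" for single-block families; "mu"/"sigma"/"nu" for
    growth-type families).
    """

    #: block names, overridden by multi-block subclasses
    blocks = ("mean",)

    def _store_levels(self, X: pd.DataFrame):
        self.site_levels_ = _levels(X, "site")
        self.year_levels_ = _levels(X, "year")

    def _design(self, X: pd.DataFrame, terms):
        return design_matrix(X, terms, self.site_levels_, self.year_levels_)

    def linear_predictors(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def clone_with_coef(self, coef: np.ndarray) -> "VitalRateEstimator":
        """Copy of this fitted estimator with ``coef_`` replaced.

        Used by the parametric bootstrap: draw a coefficient vector from
        the estimated sampling distribution and push it through the same
        prediction machinery.
        """
        import copy

        coef = np.asarray(coef, dtype=float)
        if coef.shape != np.shape(self.coef_):
            raise ValueError("coefficient vector has wrong length")
        new = copy.copy(self)
        new.coef_ = coef
        return new

    def _finalize(self, loglik: float, k: int, n: int):
        self.loglik_ = float(loglik)
        self.k_ = int(k)
        self.n_ = int(n)
        if n > k + 1:
            self.aicc_ = aicc(self.loglik_, self.k_, self.n_)
        else:
            # the fit itself is fine; it just cannot be AICc-ranked
            warnings.warn(
                f"AICc undefined at n={n}, k={k}; model unrankable", stacklevel=2
            )
            self.aicc_ = np.inf


class BinomialGLM(VitalRateEstimator):
    """Logistic regression for a binary vital rate (survival, flowering).

    Delegates the IRLS fit to statsmodels; flags (quasi-)complete
    separation so such fits can be excluded from AICc ranking, where their
    likelihood is not comparable.
    """

    def __init__(self, terms=()):
        self.terms = tuple(canonical(terms))

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        self._store_levels(X)
        mat, names = self._design(X, self.terms)
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            raise ValueError(f"rank-deficient design for terms {self.terms}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, mat, family=sm.families.Binomial()).fit(maxiter=200)
        self.coef_ = np.asarray(res.params, dtype=float)
        self.coef_names_ = names
        self.cov_ = np.asarray(res.cov_params(), dtype=float)
        self.separation_ = bool(np.max(np.abs(self.coef_)) > 15.0)
        if self.separation_:
            warnings.warn(
                f"possible complete separation in binomial fit (terms={self.terms}); "
                "model flagged and excluded from AICc ranking",
                stacklevel=2,
            )
        self._finalize(res.llf, mat.shape[1], len(y))
        return self

    def linear_predictors(self, X):
        mat, _ = self._design(X, self.terms)
        return {"mean": mat @ self.coef_}

    def predict(self, X):
        """Predicted probability."""
        return special.expit(self.linear_predictors(X)["mean"])


class NegativeBinomialGLM(VitalRateEstimator):
    """NB2 regression (Var = mu + mu^2/theta) for flower counts.

    ``shifted=True`` models (count - 1), so that plants scored as flowering
    always carry at least one flower; ``predict`` then returns 1 + exp(eta).
    When the data show no overdispersion the dispersion is clamped at
    theta = 1e6 and the mean model refitted as Poisson.
    """

    THETA_MAX = 1e6

    def __init__(self, terms=(), shifted=False):
        self.terms = tuple(canonical(terms))
        self.shifted = shifted

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if self.shifted:
            if np.any(y < 1):
                raise ValueError("shifted NB requires counts >= 1")
            y = y - 1.0
        self._store_levels(X)
        mat, names = self._design(X, self.terms)
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            raise ValueError(f"rank-deficient design for terms {self.terms}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = _SMNegBin(y, mat, loglike_method="nb2")
            try:
                res = model.fit(disp=0, maxiter=500)
                alpha = float(res.params[-1])
            except Exception:
                alpha = 0.0
                res = None
        if res is None or alpha < 1e-4 or not np.isfinite(alpha):
            warnings.warn(
                "no overdispersion detected; NB dispersion clamped at theta=1e6",
                stacklevel=2,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pres = sm.GLM(y, mat, family=sm.families.Poisson()).fit(maxiter=200)
            self.coef_ = np.asarray(pres.params, dtype=float)
            self.cov_ = np.asarray(pres.cov_params(), dtype=float)
            self.theta_ = self.THETA_MAX
            loglik = float(pres.llf)
        else:
            self.coef_ = np.asarray(res.params[:-1], dtype=float)
            self.cov_ = np.asarray(res.cov_params(), dtype=float)[:-1, :-1]
            self.theta_ = 1.0 / alpha
            loglik = float(res.llf)
        self.coef_names_ = names
        # k counts the dispersion parameter alongside the mean coefficients
        self._finalize(loglik, mat.shape[1] + 1, len(y))
        return self

    def linear_predictors(self, X):
        mat, _ = self._design(X, self.terms)
        return {"mean": mat @ self.coef_}

    def predict(self, X):
        """Predicted mean count (on the original count scale)."""
        mu = np.exp(self.linear_predictors(X)["mean"])
        return mu + 1.0 if self.shifted else mu


class _JointLocScaleShape(VitalRateEstimator):
    """Shared machinery for joint location/log-scale(/shape) MLE."""

    def _blocks_design(self, X):
        raise NotImplementedError

    def _negloglik_grad(self, params, y, mats):
        raise NotImplementedError

    def _starts(self, y, mats, rng):
        raise NotImplementedError

    def _fit_mle(self, X, y, n_restarts):
        y = np.asarray(y, dtype=float)
        self._store_levels(X)
        mats, names, splits = self._blocks_design(X)
        p = sum(m.shape[1] for m in mats)
        if len(y) < max(3, p):
            raise ValueError(f"too few observations ({len(y)}) for {p} coefficients")
        # deterministic jitter stream derived from the data, so refits of
        # the same data take identical optimizer paths
        seed = zlib.crc32(np.ascontiguousarray(y).tobytes()) % (2**31)
        rng = np.random.default_rng(seed)
        best = None
        for start in self._starts(y, mats, rng)[:n_restarts]:
            res = optimize.minimize(
                self._negloglik_grad,
                start,
                args=(y, mats),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500},
            )
            if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"{type(self).__name__} failed to converge after restarts; "
                f"last status: {None if best is None else best.message}"
            )
        self.coef_ = np.asarray(best.x, dtype=float)
        self.coef_names_ = names
        self._splits = splits
        hess = numdiff.approx_hess1(
            self.coef_, lambda b: self._negloglik_grad(b, y, mats)[0]
        )
        hess = 0.5 * (hess + hess.T)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        self.cov_ = cov
        self._finalize(-best.fun, p, len(y))
        return self

    def _split_coef(self, coef=None):
        coef = self.coef_ if coef is None else coef
        return np.split(coef, self._splits)


class SkewNormalGrowth(_JointLocScaleShape):
    """Joint skew-normal regression for growth to next year's size.

    Location xi (identity link), scale omega (log link) and shape alpha
    (identity link) each get their own term set.  alpha < 0 produces the
    left-skewed growth typical of shrinkage or herbivory; alpha = 0 nests
    the Gaussian growth model exactly.
    """

    blocks = ("mu", "sigma", "nu")
    ALPHA_MAX = 50.0

    def __init__(self, terms_mu=("size",), terms_sigma=(), terms_nu=(), n_restarts=5):
        self.terms_mu = tuple(canonical(terms_mu))
        self.terms_sigma = tuple(canonical(terms_sigma))
        self.terms_nu = tuple(canonical(terms_nu))
        self.n_restarts = n_restarts

    def _blocks_design(self, X):
        mats, names = [], []
        for block, terms in zip(
            self.blocks, (self.terms_mu, self.terms_sigma, self.terms_nu)
        ):
            mat, nm = self._design(X, terms)
            mats.append(mat)
            names.extend(f"{block}:{n}" for n in nm)
        p1, p2 = mats[0].shape[1], mats[1].shape[1]
        return mats, names, [p1, p1 + p2]

    @staticmethod
    def _negloglik_grad(params, y, mats):
        Xm, Xs, Xn = mats
        pm, ps = Xm.shape[1], Xs.shape[1]
        bm, bs, bn = params[:pm], params[pm : pm + ps], params[pm + ps :]
        xi = Xm @ bm
        eta = Xs @ bs
        eta = np.clip(eta, -30.0, 30.0)
        omega = np.exp(eta)
        a = Xn @ bn
        z = (y - xi) / omega
        u = a * z
        nll_i = (
            -np.log(2.0) + eta + 0.5 * z * z + _LOG_SQRT_2PI - special.log_ndtr(u)
        )
        zeta = _skewnorm.inverse_mills(u)
        r = z - a * zeta  # d nll / d z
        g_m = Xm.T @ (-r / omega)
        g_s = Xs.T @ (1.0 - z * z + a * zeta * z)
        g_n = Xn.T @ (-zeta * z)
        return float(np.sum(nll_i)), np.concatenate([g_m, g_s, g_n])

    def _starts(self, y, mats, rng):
        Xm, Xs, Xn = mats
        bm0, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ bm0
        bs0 = np.zeros(Xs.shape[1])
        bs0[0] = np.log(max(np.std(resid), 1e-3))
        starts = []
        for a0 in (0.0, 1.5, -1.5, 3.0, -3.0):
            bn0 = np.zeros(Xn.shape[1])
            bn0[0] = a0
            start = np.concatenate([bm0, bs0, bn0])
            if a0 != 0.0:
                start = start + 0.01 * rng.standard_normal(start.shape)
                start[len(bm0)] = bs0[0]  # keep the scale start sane
            starts.append(start)
        return starts

    def fit(self, X: pd.DataFrame, y):
        self._fit_mle(X, y, self.n_restarts)
        bn = self._split_coef()[2]
        # guard against the near-half-normal boundary
        amax = np.max(np.abs(self.linear_predictors(X)["nu"]))
        if amax > self.ALPHA_MAX:
            warnings.warn(
                f"fitted shape reaches |alpha|={amax:.1f}; clamped to "
                f"{self.ALPHA_MAX} (near-half-normal boundary)",
                stacklevel=2,
            )
            self.coef_[self._splits[1]:] = bn * (self.ALPHA_MAX / amax)
        return self

    def linear_predictors(self, X):
        bm, bs, bn = self._split_coef()
        out = {}
        for block, terms, b in zip(
            self.blocks, (self.terms_mu, self.terms_sigma, self.terms_nu), (bm, bs, bn)
        ):
            mat, _ = self._design(X, terms)
            out[block] = mat @ b
        return out

    def predict_params(self, X):
        """(xi, omega, alpha) at each row of X."""
        lp = self.linear_predictors(X)
        return lp["mu"], np.exp(lp["sigma"]), lp["nu"]

    def clone_with_coef(self, coef):
        new = super().clone_with_coef(coef)
        new._splits = self._splits
        return new


class GaussianSizeModel(_JointLocScaleShape):
    """Gaussian location/log-scale regression (recruit second-year size)."""

    blocks = ("mu", "sigma")

    def __init__(self, terms_mu=(), terms_sigma=(), n_restarts=1):
        self.terms_mu = tuple(canonical(terms_mu))
        self.terms_sigma = tuple(canonical(terms_sigma))
        self.n_restarts = n_restarts

    def _blocks_design(self, X):
        mats, names = [], []
        for block, terms in zip(self.blocks, (self.terms_mu, self.terms_sigma)):
            mat, nm = self._design(X, terms)
            mats.append(mat)
            names.extend(f"{block}:{n}" for n in nm)
        return mats, names, [mats[0].shape[1]]

    @staticmethod
    def _negloglik_grad(params, y, mats):
        Xm, Xs = mats
        pm = Xm.shape[1]
        bm, bs = params[:pm], params[pm:]
        xi = Xm @ bm
        eta = np.clip(Xs @ bs, -30.0, 30.0)
        omega = np.exp(eta)
        z = (y - xi) / omega
        nll = float(np.sum(eta + 0.5 * z * z + _LOG_SQRT_2PI))
        g_m = Xm.T @ (-z / omega)
        g_s = Xs.T @ (1.0 - z * z)
        return nll, np.concatenate([g_m, g_s])

    def _starts(self, y, mats, rng):
        Xm, Xs = mats
        bm0, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        bs0 = np.zeros(Xs.shape[1])
        bs0[0] = np.log(max(np.std(y - Xm @ bm0), 1e-3))
        return [np.concatenate([bm0, bs0])]

    def fit(self, X: pd.DataFrame, y):
        if len(y) < 3:
            raise ValueError("need at least 3 observations to fit mean and SD")
        return self._fit_mle(X, y, self.n_restarts)

    def linear_predictors(self, X):
        bm, bs = self._split_coef()
        out = {}
        for block, terms, b in zip(
            self.blocks, (self.terms_mu, self.terms_sigma), (bm, bs)
        ):
            mat, _ = self._design(X, terms)
            out[block] = mat @ b
        return out

    def predict_params(self, X):
        lp = self.linear_predictors(X)
        return lp["mu"], np.exp(lp["sigma"])

    def clone_with_coef(self, coef):
        new = super().clone_with_coef(coef)
        new._splits = self._splits
        return new


class RatioLinearModel(VitalRateEstimator):
    """OLS on per-(site, year) seedlings-per-flower ratio observations.

    The response is seedling density divided by the previous year's flower
    density, one observation per cell.  The Gaussian log-likelihood (MLE
    error variance) feeds AICc; negative fitted ratios are clamped to zero
    at prediction time.
    """

    def __init__(self, terms=()):
        terms = tuple(canonical(terms))
        bad = set(terms) - {"site", "year"}
        if bad:
            raise ValueError(f"ratio model admits only site/year terms, got {bad}")
        self.terms = terms

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        self._store_levels(X)
        mat, names = self._design(X, self.terms)
        if len(y) < mat.shape[1]:
            raise ValueError("fewer ratio observations than coefficients")
        res = sm.OLS(y, mat).fit()
        self.coef_ = np.asarray(res.params, dtype=float)
        self.coef_names_ = names
        self.cov_ = np.asarray(res.cov_params(), dtype=float)
        n = len(y)
        sigma2 = float(np.sum(res.resid**2)) / n  # MLE variance
        sigma2 = max(sigma2, 1e-300)
        self.sigma_ = np.sqrt(sigma2)
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
        self._finalize(loglik, mat.shape[1] + 1, n)
        return self

    def linear_predictors(self, X):
        mat, _ = self._design(X, self.terms)
        return {"mean": mat @ self.coef_}

    def predict(self, X):
        pred = self.linear_predictors(X)["mean"]
        if np.any(pred < 0):
            warnings.warn(
                "negative fitted seedlings-per-flower clamped to 0", stacklevel=2
            )
        return np.clip(pred, 0.0, None)


# ---------------------------------------------------------------------------
# model sets: dredging, parsimonious selection, confidence sets


def akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    delta = aiccs - np.min(aiccs)
    w = np.exp(-0.5 * delta)
    return w / np.sum(w)


@dataclass
class ModelSet:
    """AICc-ranked candidate models for one vital rate.

    ``models`` keeps the enumeration order (a deterministic simplest-first
    ordering); ``weights`` are Akaike weights over all candidates.
    """

    models: list = field(default_factory=list)
    vital_rate: str = ""

    def __post_init__(self):
        self.aicc = np.array([m.aicc_ for m in self.models], dtype=float)
        self.delta = self.aicc - np.min(self.aicc) if len(self.models) else self.aicc
        self.weights = akaike_weights(self.aicc) if len(self.models) else self.aicc

    def __len__(self):
        return len(self.models)


def dredge(fit_fn, term_sets, vital_rate="") -> ModelSet:
    """Fit every candidate term set; failed fits are dropped with a warning."""
    models = []
    for terms in term_sets:
        try:
            m = fit_fn(terms)
        except Exception as exc:  # noqa: BLE001 - candidate failure is data-driven
            warnings.warn(f"candidate {terms} dropped: {exc}", stacklevel=2)
            continue
        if getattr(m, "separation_", False):
            continue
        models.append(m)
    if not models:
        raise RuntimeError(f"no candidate model could be fitted for {vital_rate!r}")
    return ModelSet(models, vital_rate=vital_rate)


def _model_k(m) -> int:
    return m.k_


def select_parsimonious(model_set: ModelSet, delta: float = 2.0):
    """Simplest model within ``delta`` AICc of the minimum.

    Ties on the parameter count go to the lower AICc, then to the
    enumeration (simplest-first) order.
    """
    if len(model_set) == 0:
        raise ValueError("empty model set")
    idx = [i for i in range(len(model_set)) if model_set.delta[i] <= delta]
    idx.sort(key=lambda i: (_model_k(model_set.models[i]), model_set.aicc[i], i))
    return model_set.models[idx[0]]


def confidence_set(model_set: ModelSet, level: float = 0.95):
    """Smallest weight-ranked prefix with cumulative Akaike weight >= level.

    Returns (models, renormalized weights); the renormalized weights sum
    to 1 and drive model sampling in the parametric bootstrap.
    """
    order = np.argsort(model_set.weights)[::-1]
    cum = np.cumsum(model_set.weights[order])
    cut = int(np.searchsorted(cum, level) + 1)
    keep = order[:cut]
    w = model_set.weights[keep]
    return [model_set.models[i] for i in keep], w / np.sum(w)


# ---------------------------------------------------------------------------
# spec-level convenience wrappers


def fit_binomial(data: pd.DataFrame, response: str, terms=()) -> BinomialGLM:
    return BinomialGLM(terms).fit(data, data[response])


def fit_negative_binomial(
    data: pd.DataFrame, terms=(), shifted: bool = False
) -> NegativeBinomialGLM:
    """Fit flower counts of flowering plants; callers pass the subset."""
    return NegativeBinomialGLM(terms, shifted=shifted).fit(data, data["flower_count"])


def fit_skew_normal_growth(
    data: pd.DataFrame,
    terms_mu=("size",),
    terms_sigma=(),
    terms_nu=(),
) -> SkewNormalGrowth:
    """Fit survivor growth (rows with size_t1 present)."""
    surv = data.dropna(subset=["size_t1"])
    X = surv.rename(columns={"size_t": "size"})
    return SkewNormalGrowth(terms_mu, terms_sigma, terms_nu).fit(X, surv["size_t1"])


def fit_gaussian_recruit_size(
    data: pd.DataFrame, terms=(), terms_sigma=()
) -> GaussianSizeModel:
    """Fit second-year sizes of surviving recruits."""
    rec = data[(data["stage"] == "seedling") & (data["survived"] == 1)]
    rec = rec.dropna(subset=["size_t1"])
    return GaussianSizeModel(terms, terms_sigma).fit(rec, rec["size_t1"])


def fit_seedling_survival(data: pd.DataFrame, terms=()) -> BinomialGLM:
    bad = set(canonical(terms)) - {"site"}
    if bad:
        raise ValueError(f"seedling survival admits only a site term, got {bad}")
    sdl = data[data["stage"] == "seedling"]
    return BinomialGLM(terms).fit(sdl, sdl["survived"])


def seedling_ratio_observations(seedlings: pd.DataFrame) -> pd.DataFrame:
    """Per-(site, year) seedlings-per-flower ratio observations.

    Seedling density is total count over total quadrat area (per m^2);
    the ratio divides it by that cell's previous-year flower density
    (``flower_density`` column, flowers per m^2).
    """
    grouped = seedlings.groupby(["site", "year"], sort=True)
    rows = []
    for (site, year), g in grouped:
        area_m2 = g["quadrat_area_cm2"].sum() / 1e4
        density = g["seedling_count"].sum() / area_m2
        fd = float(g["flower_density"].iloc[0])
        if fd <= 0:
            warnings.warn(
                f"zero flower density at ({site}, {year}); ratio set to 0",
                stacklevel=2,
            )
            ratio = 0.0
        else:
            ratio = density / fd
        rows.append({"site": site, "year": year, "ratio": ratio})
    return pd.DataFrame(rows)


def fit_seedlings_per_flower(seedlings: pd.DataFrame, terms=()) -> RatioLinearModel:
    obs = seedling_ratio_observations(seedlings)
    return RatioLinearModel(terms).fit(obs, obs["ratio"])


# ---------------------------------------------------------------------------
# growth dredging

SIGMA_NU_MAXIMAL = ("size", "site", "year", "size:site", "size:year")


def dredge_growth(
    data: pd.DataFrame,
    maximal_mu=("size", "site", "year", "size:site", "size:year", "site:year", "size:site:year"),
    maximal_sigma=SIGMA_NU_MAXIMAL,
    maximal_nu=SIGMA_NU_MAXIMAL,
    mode: str = "stagewise",
    delta: float = 2.0,
) -> ModelSet:
    """Dredge the three growth blocks.

    ``stagewise`` (default) selects the location block over its 19
    hierarchical candidates with scale and shape at intercept-only, then
    the scale block with the chosen location, then the shape block —
    about 45 joint MLEs.  ``full`` fits the complete cross-product
    (19 x 13 x 13 candidates), which is exhaustive but slow.
    """
    surv = data.dropna(subset=["size_t1"])
    X = surv.rename(columns={"size_t": "size"})
    y = surv["size_t1"]

    def fit_one(tm, ts, tn):
        return SkewNormalGrowth(tm, ts, tn).fit(X, y)

    mu_sets = enumerate_hierarchical(maximal_mu)
    sig_sets = enumerate_hierarchical(maximal_sigma)
    nu_sets = enumerate_hierarchical(maximal_nu)

    seen: dict[tuple, SkewNormalGrowth] = {}

    def fit_cached(tm, ts, tn):
        key = (tuple(tm), tuple(ts), tuple(tn))
        if key not in seen:
            seen[key] = fit_one(*key)
        return seen[key]

    if mode == "full":
        for tm in mu_sets:
            for ts in sig_sets:
                for tn in nu_sets:
                    try:
                        fit_cached(tm, ts, tn)
                    except Exception as exc:  # noqa: BLE001
                        warnings.warn(
                            f"growth candidate {(tm, ts, tn)} dropped: {exc}",
                            stacklevel=2,
                        )
    elif mode == "stagewise":
        def stage(candidates, build):
            fitted = []
            for cand in candidates:
                try:
                    fitted.append(fit_cached(*build(cand)))
                except Exception as exc:  # noqa: BLE001
                    warnings.warn(
                        f"growth candidate {cand} dropped: {exc}", stacklevel=2
                    )
            ms = ModelSet(fitted, vital_rate="growth")
            return select_parsimonious(ms, delta)

        # stage 1: location; stage 2: scale; stage 3: shape
        best_mu = stage(mu_sets, lambda tm: (tm, (), ()))
        tm = best_mu.terms_mu
        best_sig = stage(sig_sets, lambda ts: (tm, ts, ()))
        ts = best_sig.terms_sigma
        stage(nu_sets, lambda tn: (tm, ts, tn))
    else:
        raise ValueError(f"unknown growth dredge mode {mode!r}")

    return ModelSet(list(seen.values()), vital_rate="growth")
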