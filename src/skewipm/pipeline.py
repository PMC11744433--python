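"""End-to-end analysis driver: data IO, model selection, kernels, report.

`DemographyAnalysis` is the top-level estimator: construct it with a
`PipelineConfig` (whose defaults are the standard analysis settings:
100 size classes, 5000-step stochastic simulations, 5000 bootstrap
iterations, a 2-AICc parsimony window, 95% confidence sets, and a 1e-5
coefficient perturbation), call ``fit(census, seedlings)``, and read the
fitted attributes: ``model_sets_``, ``selected_``, ``cells_``,
``lambda_``, ``lambda_s_``, ``lifespan_``, ``sensitivities_``,
``elasticities_``, ``ltre_``.  ``bootstrap()`` then attaches
bias-corrected intervals to every output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import perturbation, uncertainty
from .cells import reduce_to_cells
from .ipm import build_kernel, build_mesh, cohort_lifespan, lambda_deterministic, lambda_stochastic
from .terms import enumerate_hierarchical
from .vital_rates import (
    BinomialGLM,
    GaussianSizeModel,
    ModelSet,
    NegativeBinomialGLM,
    RatioLinearModel,
    dredge,
    dredge_growth,
    seedling_ratio_observations,
    select_parsimonious,
)

__all__ = [
    "PipelineConfig",
    "DemographyAnalysis",
    "read_census",
    "write_census",
    "read_seedlings",
    "write_seedlings",
    "summarize_dormancy",
    "run_pipeline",
]

CENSUS_COLUMNS = [
    "site",
    "year",
    "id",
    "stage",
    "size_t",
    "survived",
    "size_t1",
    "flowered",
    "flower_count",
]
SEEDLING_COLUMNS = [
    "site",
    "year",
    "quadrat",
    "quadrat_area_cm2",
    "seedling_count",
    "flower_density",
]

MAXIMAL_ADULT = (
    "size",
    "site",
    "year",
    "size:site",
    "size:year",
    "site:year",
    "size:site:year",
)


@dataclass
class PipelineConfig:
    """Analysis settings; the defaults are the standard values."""

    m_classes: int = 100
    n_steps_stochastic: int = 5000
    n_iter_bootstrap: int = 5000
    delta_aicc: float = 2.0
    confidence_level: float = 0.95
    perturbation_h: float = 1e-5
    seed: int = 0
    shifted_counts: bool = False
    central_difference: bool = False
    growth_dredge: str = "stagewise"
    bootstrap_perturbation: bool = True


# ---------------------------------------------------------------------------
# CSV IO with row-level validation


def write_census(census: pd.DataFrame, path) -> None:
    census.to_csv(path, index=False, columns=CENSUS_COLUMNS)


def read_census(path) -> pd.DataFrame:
    """Read and validate a census CSV; raises with row numbers on bad rows."""
    df = pd.read_csv(path)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census file missing required columns: {missing}")
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["survived"] == 0 and pd.notna(row["size_t1"]):
            errors.append(f"line {line}: size_t1 present for a non-survivor")
        if row["flowered"] == 1 and pd.isna(row["flower_count"]):
            errors.append(f"line {line}: flowered=1 but flower_count is blank")
        if pd.notna(row["flower_count"]) and row["flowered"] == 1 and row["flower_count"] < 1:
            errors.append(f"line {line}: flowered=1 with flower_count < 1")
        if row["stage"] not in ("adult", "seedling"):
            errors.append(f"line {line}: stage must be adult or seedling")
    if errors:
        raise ValueError("census validation failed:\n" + "\n".join(errors))
    return df


def write_seedlings(seedlings: pd.DataFrame, path) -> None:
    seedlings.to_csv(path, index=False, columns=SEEDLING_COLUMNS)


def read_seedlings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SEEDLING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"seedling file missing required columns: {missing}")
    if (df["quadrat_area_cm2"] <= 0).any():
        raise ValueError("quadrat areas must be positive")
    if (df["seedling_count"] < 0).any():
        raise ValueError("seedling counts must be non-negative")
    return df


def summarize_dormancy(census: pd.DataFrame) -> tuple[int, float]:
    """Plants absent in one survey but recorded again later.

    Presence is having a census record in a survey year; the survey-year
    range is taken from the whole table.  Returns (count, fraction of all
    marked plants).
    """
    years = sorted(pd.unique(census["year"]))
    gaps = 0
    ids = pd.unique(census["id"])
    for pid, g in census.groupby("id"):
        present = set(g["year"])
        span = [y for y in years if min(present) <= y <= max(present)]
        if any(y not in present for y in span):
            gaps += 1
    return gaps, gaps / len(ids) if len(ids) else 0.0


# ---------------------------------------------------------------------------
# the analysis estimator


class DemographyAnalysis:
    """Fit the full demographic analysis on census + seedling tables."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- model selection ----------------------------------------------------

    def _dredge_all(self, census: pd.DataFrame, seedlings: pd.DataFrame):
        cfg = self.config
        adults = census[census["stage"] == "adult"].copy()
        adults = adults.rename(columns={"size_t": "size"})
        model_sets: dict[str, ModelSet] = {}

        adult_sets = enumerate_hierarchical(MAXIMAL_ADULT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model_sets["survival"] = dredge(
                lambda t: BinomialGLM(t).fit(adults, adults["survived"]),
                adult_sets,
                "survival",
            )
            model_sets["flowering"] = dredge(
                lambda t: BinomialGLM(t).fit(adults, adults["flowered"]),
                adult_sets,
                "flowering",
            )
            flw = adults[adults["flowered"] == 1]
            model_sets["flower_count"] = dredge(
                lambda t: NegativeBinomialGLM(t, shifted=cfg.shifted_counts).fit(
                    flw, flw["flower_count"]
                ),
                adult_sets,
                "flower_count",
            )
            model_sets["growth"] = dredge_growth(
                census[census["stage"] == "adult"],
                mode=cfg.growth_dredge,
                delta=cfg.delta_aicc,
            )
            sdl = census[census["stage"] == "seedling"]
            model_sets["seedling_survival"] = dredge(
                lambda t: BinomialGLM(t).fit(sdl, sdl["survived"]),
                [(), ("site",)],
                "seedling_survival",
            )
            rec = sdl[(sdl["survived"] == 1) & sdl["size_t1"].notna()]
            model_sets["recruit_size"] = dredge(
                lambda t: GaussianSizeModel(t, ()).fit(rec, rec["size_t1"]),
                [(), ("site",)],
                "recruit_size",
            )
            obs = seedling_ratio_observations(seedlings)
            model_sets["seedlings_per_flower"] = dredge(
                lambda t: RatioLinearModel(t).fit(obs, obs["ratio"]),
                [(), ("site",), ("year",), ("site", "year")],
                "seedlings_per_flower",
            )
        return model_sets

    # -- fit ---------------------------------------------------------------

    def fit(self, census: pd.DataFrame, seedlings: pd.DataFrame):
        cfg = self.config
        sizes = pd.concat([census["size_t"], census["size_t1"]]).dropna()
        self.L_, self.U_ = float(sizes.min()), float(sizes.max())
        self.sites_ = tuple(sorted(pd.unique(census["site"])))
        self.years_ = tuple(sorted(pd.unique(census["year"])))
        self.mesh_ = build_mesh(self.L_, self.U_, cfg.m_classes, sizes)

        self.model_sets_ = self._dredge_all(census, seedlings)
        self.selected_ = {
            k: select_parsimonious(ms, cfg.delta_aicc)
            for k, ms in self.model_sets_.items()
        }
        self.cells_ = reduce_to_cells(self.selected_, self.sites_, self.years_)

        self.kernels_ = {}
        lam = pd.DataFrame(index=self.sites_, columns=self.years_, dtype=float)
        for site in self.sites_:
            for year in self.years_:
                k = build_kernel(
                    self.cells_.loc[(site, year)], self.mesh_,
                    site=site, year=year, shifted_counts=cfg.shifted_counts,
                )
                self.kernels_[(site, year)] = k
                lam.loc[site, year] = lambda_deterministic(k)
        self.lambda_ = lam
        self.lambda_s_ = pd.Series(
            {
                site: lambda_stochastic(
                    [self.kernels_[(site, y)] for y in self.years_],
                    n_steps=cfg.n_steps_stochastic,
                    seed=cfg.seed + i,
                )
                for i, site in enumerate(self.sites_)
            }
        )
        self.mean_coefs_ = perturbation.mean_model(self.cells_)
        mean_kernel = build_kernel(
            self.mean_coefs_, self.mesh_, shifted_counts=cfg.shifted_counts
        )
        self.lambda_mean_ = lambda_deterministic(mean_kernel)
        self.lifespan_ = cohort_lifespan(mean_kernel)
        self.sensitivities_ = perturbation.all_sensitivities(
            self.mean_coefs_, self.mesh_, h=cfg.perturbation_h,
            shifted_counts=cfg.shifted_counts, central=cfg.central_difference,
        )
        self.elasticities_ = perturbation.all_elasticities(
            self.mean_coefs_, self.sensitivities_, self.lambda_mean_
        )
        self.ltre_ = perturbation.ltre_contributions(
            self.cells_, self.mean_coefs_, self.sensitivities_
        )
        return self

    # -- uncertainty --------------------------------------------------------

    def bootstrap(self, n_iter: int | None = None, seed: int | None = None):
        cfg = self.config
        self.bootstrap_ = uncertainty.run_bootstrap(
            self.model_sets_,
            self.sites_,
            self.years_,
            self.mesh_,
            n_iter=cfg.n_iter_bootstrap if n_iter is None else n_iter,
            seed=cfg.seed if seed is None else seed,
            level=cfg.confidence_level,
            shifted_counts=cfg.shifted_counts,
            n_steps_stochastic=cfg.n_steps_stochastic,
            h=cfg.perturbation_h,
            include_perturbation=cfg.bootstrap_perturbation,
            delta=cfg.delta_aicc,
        )
        return self.bootstrap_

    # -- reporting ----------------------------------------------------------

    def aicc_table(self, rate: str) -> pd.DataFrame:
        ms = self.model_sets_[rate]
        rows = []
        for i, m in enumerate(ms.models):
            if hasattr(m, "terms_nu"):
                terms = f"mu={m.terms_mu} sigma={m.terms_sigma} nu={m.terms_nu}"
            elif hasattr(m, "terms_mu"):
                terms = f"mu={m.terms_mu} sigma={m.terms_sigma}"
            else:
                terms = str(getattr(m, "terms", ()))
            rows.append(
                {
                    "terms": terms,
                    "k": m.k_,
                    "loglik": m.loglik_,
                    "AICc": ms.aicc[i],
                    "delta": ms.delta[i],
                    "weight": ms.weights[i],
                }
            )
        return pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)

    def selected_summary(self) -> dict:
        out = {}
        for rate, m in self.selected_.items():
            entry = {
                "coefficients": dict(zip(m.coef_names_, np.asarray(m.coef_).tolist())),
                "covariance": np.asarray(m.cov_).tolist(),
                "loglik": m.loglik_,
                "k": m.k_,
                "n": m.n_,
                "AICc": m.aicc_,
            }
            if hasattr(m, "theta_"):
                entry["theta"] = float(m.theta_)
            out[rate] = entry
        return out


def run_pipeline(
    census: pd.DataFrame,
    seedlings: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir=None,
    bootstrap: bool = True,
) -> DemographyAnalysis:
    """Fit everything and (optionally) write a report bundle of CSV + JSON."""
    analysis = DemographyAnalysis(config).fit(census, seedlings)
    if bootstrap:
        analysis.bootstrap()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        analysis.lambda_.to_csv(outdir / "lambda.csv")
        analysis.lambda_s_.rename("lambda_s").to_csv(outdir / "lambda_s.csv")
        elas = pd.DataFrame(
            {
                "sensitivity": analysis.sensitivities_,
                "elasticity": analysis.elasticities_,
            }
        )
        elas.index.names = ["rate", "coefficient"]
        elas.to_csv(outdir / "perturbation.csv")
        analysis.ltre_.cellwise.to_csv(outdir / "ltre_cellwise.csv")
        analysis.ltre_.per_rate_site.to_csv(outdir / "ltre_by_site.csv")
        analysis.ltre_.per_rate_year.to_csv(outdir / "ltre_by_year.csv")
        for rate in analysis.model_sets_:
            analysis.aicc_table(rate).to_csv(
                outdir / f"aicc_{rate}.csv", index=False
            )
        summary = {
            "config": dataclasses.asdict(analysis.config),
            "L": analysis.L_,
            "U": analysis.U_,
            "lifespan": analysis.lifespan_,
            "lambda_mean_model": analysis.lambda_mean_,
            "selected_models": analysis.selected_summary(),
        }
        if bootstrap:
            b = analysis.bootstrap_
            summary["bootstrap"] = {
                "n_iter": b.n_iter,
                "n_skipped": b.n_skipped,
                "intervals": {
                    name: [b.intervals.loc[name, "lower"], b.intervals.loc[name, "upper"]]
                    for name in b.intervals.index
                },
                "significant": {k: bool(v) for k, v in b.significant.items()},
            }
            b.samples.to_csv(outdir / "bootstrap_samples.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return analysis
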