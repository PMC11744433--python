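"""Parametric bootstrap over model-selection and coefficient uncertainty.

Each bootstrap iteration draws, independently for every vital rate, a
candidate model from its 95% AICc-weight confidence set (with probability
proportional to the renormalized weight) and a coefficient vector from
that model's multivariate-normal sampling distribution, then recomputes
the entire downstream pipeline: kernels, per-cell lambda, per-site
stochastic lambda, cohort lifespan, sensitivities/elasticities of the
mean model, and LTRE aggregates.  Bias-corrected percentile intervals
summarize the replicate arrays; a quantity is flagged significant when
its null value (1 for lambda-type outputs, 0 otherwise) falls outside the
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from . import perturbation
from .cells import reduce_to_cells, validate_cells
from .ipm import Mesh, build_kernel, cohort_lifespan, lambda_deterministic, lambda_stochastic
from .vital_rates import ModelSet, confidence_set, select_parsimonious

__all__ = [
    "bc_interval",
    "pairwise_difference_test",
    "BootstrapResult",
    "run_bootstrap",
    "compute_outputs",
]


def bc_interval(samples, point_estimate: float, level: float = 0.95):
    """Bias-corrected percentile interval.

    The bias correction z0 is Phi^{-1} of the fraction of replicates
    below the point estimate (ties counted half); bounds sit at
    percentiles Phi(2*z0 +/- z_{alpha/2}).  If every replicate falls on
    one side of the point estimate, z0 is infinite and the plain
    percentile interval is returned with a warning.
    """
    s = np.asarray(samples, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 2:
        raise ValueError("need at least 2 finite replicates for an interval")
    tail = (1.0 - level) / 2.0
    frac = (np.sum(s < point_estimate) + 0.5 * np.sum(s == point_estimate)) / s.size
    if frac <= 0.0 or frac >= 1.0:
        warnings.warn(
            "all bootstrap replicates on one side of the point estimate; "
            "falling back to the plain percentile interval",
            stacklevel=2,
        )
        lo, hi = np.percentile(s, [100 * tail, 100 * (1 - tail)])
        return float(lo), float(hi)
    z0 = special.ndtri(frac)
    z_alpha = special.ndtri(tail)  # negative
    p_lo = special.ndtr(2.0 * z0 + z_alpha)
    p_hi = special.ndtr(2.0 * z0 - z_alpha)
    lo, hi = np.percentile(s, [100 * p_lo, 100 * p_hi])
    return float(lo), float(hi)


def pairwise_difference_test(
    replicates_a,
    replicates_b,
    null: float = 0.0,
    point_a: float | None = None,
    point_b: float | None = None,
    level: float = 0.95,
):
    """Paired per-iteration differences with a BC interval and a null test."""
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate arrays must be paired (same length)")
    diffs = a - b
    if point_a is not None and point_b is not None:
        estimate = float(point_a - point_b)
    else:
        estimate = float(np.nanmean(diffs))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo, hi = bc_interval(diffs, estimate, level)
    return estimate, (lo, hi), bool(null < lo or null > hi)


# ---------------------------------------------------------------------------
# full-pipeline replicates


@dataclass
class BootstrapResult:
    """Replicate arrays plus BC intervals for every pipeline output."""

    samples: pd.DataFrame  # n_iter rows, one column per output
    point: pd.Series
    intervals: pd.DataFrame  # columns: lower, upper
    significant: pd.Series
    null_values: pd.Series
    n_iter: int
    n_skipped: int
    level: float = 0.95

    def save(self, outdir) -> None:
        """Write replicate arrays (CSV) and an interval summary (JSON)."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(outdir / "replicates.csv", index=False)
        summary = {
            "n_iter": self.n_iter,
            "n_skipped": self.n_skipped,
            "level": self.level,
            "outputs": {
                name: {
                    "point": float(self.point[name]),
                    "lower": float(self.intervals.loc[name, "lower"]),
                    "upper": float(self.intervals.loc[name, "upper"]),
                    "null": float(self.null_values[name]),
                    "significant": bool(self.significant[name]),
                }
                for name in self.samples.columns
            },
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def compute_outputs(
    models: Mapping[str, object],
    sites: Sequence,
    years: Sequence,
    mesh: Mesh,
    shifted_counts: bool = False,
    n_steps_stochastic: int = 5000,
    stochastic_seed: int = 0,
    h: float = perturbation.DEFAULT_H,
    include_perturbation: bool = True,
    include_lifespan: bool = True,
    include_stochastic: bool = True,
) -> dict[str, float]:
    """All scalar pipeline outputs for one set of fitted/resampled models."""
    cells = reduce_to_cells(models, sites, years)
    validate_cells(cells)
    # plain-dict cell views: hot path for kernel assembly
    cols = list(cells.columns)
    cell_dicts = {
        key: dict(zip(cols, row)) for key, row in zip(cells.index, cells.to_numpy())
    }
    out: dict[str, float] = {}
    kernels = {}
    for site in sites:
        for year in years:
            k = build_kernel(
                cell_dicts[(site, year)], mesh, site=site, year=year,
                shifted_counts=shifted_counts,
            )
            kernels[(site, year)] = k
            out[f"lambda[{site},{year}]"] = lambda_deterministic(k)
    for i, site in enumerate(sites) if include_stochastic else []:
        out[f"lambda_s[{site}]"] = lambda_stochastic(
            [kernels[(site, y)] for y in years],
            n_steps=n_steps_stochastic,
            seed=stochastic_seed + i,
        )
    mean = perturbation.mean_model(cells)
    if include_lifespan:
        mean_kernel = build_kernel(mean, mesh, shifted_counts=shifted_counts)
        out["lifespan"] = float(cohort_lifespan(mean_kernel))
    if include_perturbation:
        lam0 = perturbation.lambda_from_coefs(mean, mesh, shifted_counts)
        sens = perturbation.all_sensitivities(
            mean, mesh, h=h, shifted_counts=shifted_counts
        )
        elas = perturbation.all_elasticities(mean, sens, lam0)
        for (rate, coef), v in sens.items():
            out[f"sens[{rate}.{coef}]"] = float(v)
        for (rate, coef), v in elas.items():
            out[f"elas[{rate}.{coef}]"] = float(v)
        ltre = perturbation.ltre_contributions(cells, mean, sens)
        for rate in ltre.per_rate_site.index:
            for site in ltre.per_rate_site.columns:
                out[f"ltre_site[{rate},{site}]"] = float(ltre.per_rate_site.loc[rate, site])
            for year in ltre.per_rate_year.columns:
                out[f"ltre_year[{rate},{year}]"] = float(ltre.per_rate_year.loc[rate, year])
    return out


def _null_value(name: str) -> float:
    return 1.0 if name.startswith(("lambda[", "lambda_s[")) else 0.0


def bootstrap_iteration(
    model_sets: Mapping[str, ModelSet | object],
    rng: np.random.Generator,
    level: float = 0.95,
    max_redraws: int = 20,
    **output_kwargs,
) -> dict[str, float] | None:
    """One replicate: sample models, resample coefficients, recompute.

    Model and coefficient draws are independent across vital rates.
    Coefficient vectors that make the downstream pipeline fail (e.g. a
    degenerate kernel) are redrawn up to ``max_redraws`` times; after
    that the iteration is skipped (returns None).
    """
    for _ in range(max_redraws):
        drawn: dict[str, object] = {}
        for key, ms in model_sets.items():
            if isinstance(ms, ModelSet):
                cand, w = confidence_set(ms, level)
                model = cand[rng.choice(len(cand), p=w)]
            else:
                model = ms
            coef = rng.multivariate_normal(
                model.coef_, model.cov_, method="svd", check_valid="ignore"
            )
            drawn[key] = model.clone_with_coef(coef)
        try:
            return compute_outputs(drawn, **output_kwargs)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            continue
    return None


def run_bootstrap(
    model_sets: Mapping[str, ModelSet | object],
    sites: Sequence,
    years: Sequence,
    mesh: Mesh,
    n_iter: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    shifted_counts: bool = False,
    n_steps_stochastic: int = 5000,
    h: float = perturbation.DEFAULT_H,
    include_perturbation: bool = True,
    include_lifespan: bool = True,
    include_stochastic: bool = True,
    delta: float = 2.0,
    max_skip_fraction: float = 0.05,
) -> BootstrapResult:
    """Full parametric bootstrap; deterministic given ``seed``.

    Point estimates come from each vital rate's parsimonious-best model;
    intervals are bias-corrected percentiles of the replicate arrays.
    Pairwise per-iteration differences (lambda across years within each
    site; stochastic lambda across sites) are included as outputs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    selected = {
        key: (select_parsimonious(ms, delta) if isinstance(ms, ModelSet) else ms)
        for key, ms in model_sets.items()
    }
    kw = dict(
        sites=sites,
        years=years,
        mesh=mesh,
        shifted_counts=shifted_counts,
        n_steps_stochastic=n_steps_stochastic,
        h=h,
        include_perturbation=include_perturbation,
        include_lifespan=include_lifespan,
        include_stochastic=include_stochastic,
    )
    point = pd.Series(
        compute_outputs(selected, stochastic_seed=int(rng.integers(2**31)), **kw)
    )
    rows = []
    n_skipped = 0
    for _ in range(n_iter):
        stoch_seed = int(rng.integers(2**31))
        rep = bootstrap_iteration(
            model_sets, rng, level=level, stochastic_seed=stoch_seed, **kw
        )
        if rep is None:
            n_skipped += 1
        else:
            rows.append(rep)
    if n_skipped > max_skip_fraction * n_iter:
        raise RuntimeError(
            f"{n_skipped}/{n_iter} bootstrap iterations skipped; "
            "coefficient draws are too unstable for reliable intervals"
        )
    samples = pd.DataFrame(rows)

    # paired differences: lambda across years within site, lambda_s across sites
    diff_cols = {}
    for site in sites:
        for i, y1 in enumerate(years):
            for y2 in years[i + 1 :]:
                name = f"dlambda[{site}:{y2}-{y1}]"
                diff_cols[name] = (f"lambda[{site},{y2}]", f"lambda[{site},{y1}]")
    if include_stochastic:
        for i, s1 in enumerate(sites):
            for s2 in sites[i + 1 :]:
                diff_cols[f"dlambda_s[{s2}-{s1}]"] = (f"lambda_s[{s2}]", f"lambda_s[{s1}]")
    for name, (ca, cb) in diff_cols.items():
        samples[name] = samples[ca] - samples[cb]
        point[name] = point[ca] - point[cb]

    nulls, lowers, uppers, sig = {}, {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in samples.columns:
            nulls[name] = _null_value(name)
            vals = samples[name].to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size == 0:
                lowers[name] = uppers[name] = np.nan
                sig[name] = False
                continue
            if finite.size == 1:  # degenerate single-replicate run
                lowers[name] = uppers[name] = float(finite[0])
                sig[name] = bool(nulls[name] != finite[0])
                continue
            lo, hi = bc_interval(vals, float(point[name]), level)
            lowers[name], uppers[name] = lo, hi
            sig[name] = bool(nulls[name] < lo or nulls[name] > hi)
    intervals = pd.DataFrame({"lower": lowers, "upper": uppers})
    return BootstrapResult(
        samples=samples,
        point=point[samples.columns],
        intervals=intervals,
        significant=pd.Series(sig),
        null_values=pd.Series(nulls),
        n_iter=n_iter,
        n_skipped=n_skipped,
        level=level,
    )
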