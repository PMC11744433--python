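"""Per-(site, year) affine coefficients on the link scale.

Every selected vital-rate model, whatever its term set, is affine in size
within a given (site, year) cell: eta(x) = b0 + b1*x on the link scale.
This module reduces fitted models to that per-cell (b0, b1) form exactly,
which is what the kernel builder, the mean model, and the LTRE operate on.

Coefficient table layout: a DataFrame indexed by (site, year) with
MultiIndex columns (vital rate, coefficient).  Adult rates carry an
intercept and a size slope; seedling-stage rates are size-independent and
carry an intercept only.

Link scales: survival, flowering, seedling_survival — logit;
flower_count, growth_sigma, recruit_sigma — log;
growth_mu, growth_nu, recruit_mu, seedlings_per_flower — identity.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ADULT_RATES = (
    "survival",
    "flowering",
    "flower_count",
    "growth_mu",
    "growth_sigma",
    "growth_nu",
)
SEEDLING_RATES = (
    "seedling_survival",
    "recruit_mu",
    "recruit_sigma",
    "seedlings_per_flower",
)

#: (model key, linear-predictor block) behind each coefficient-table rate
RATE_SOURCES = {
    "survival": ("survival", "mean"),
    "flowering": ("flowering", "mean"),
    "flower_count": ("flower_count", "mean"),
    "growth_mu": ("growth", "mu"),
    "growth_sigma": ("growth", "sigma"),
    "growth_nu": ("growth", "nu"),
    "seedling_survival": ("seedling_survival", "mean"),
    "recruit_mu": ("recruit_size", "mu"),
    "recruit_sigma": ("recruit_size", "sigma"),
    "seedlings_per_flower": ("seedlings_per_flower", "mean"),
}


def coefficient_index() -> pd.MultiIndex:
    """Canonical (rate, coefficient) column index: 12 adult + 4 seedling."""
    pairs = [(r, c) for r in ADULT_RATES for c in ("intercept", "slope")]
    pairs += [(r, "intercept") for r in SEEDLING_RATES]
    return pd.MultiIndex.from_tuples(pairs, names=["rate", "coefficient"])


def reduce_to_cells(
    models: Mapping[str, object], sites: Sequence, years: Sequence
) -> pd.DataFrame:
    """Reduce selected models to the per-cell coefficient table.

    ``models`` maps "survival", "flowering", "flower_count", "growth",
    "seedling_survival", "recruit_size", "seedlings_per_flower" to fitted
    estimators.  The reduction is exact: the link-scale predictor is
    probed at sizes 0, 1 and 2 in every cell, (b0, b1) = (eta(0),
    eta(1) - eta(0)), and the third probe asserts affinity so any
    non-linear size term is rejected rather than silently linearized.
    """
    index = pd.MultiIndex.from_product([sites, years], names=["site", "year"])
    n_cells = len(index)
    # one probe frame covering all cells at sizes 0, 1, 2
    probe = pd.DataFrame(
        {
            "size": np.tile([0.0, 1.0, 2.0], n_cells),
            "site": np.repeat(index.get_level_values("site"), 3),
            "year": np.repeat(index.get_level_values("year"), 3),
        }
    )
    columns = coefficient_index()
    values = np.full((n_cells, len(columns)), np.nan)
    col_pos = {c: i for i, c in enumerate(columns)}
    cache: dict[int, dict] = {}
    for rate in ADULT_RATES + SEEDLING_RATES:
        key, block = RATE_SOURCES[rate]
        model = models[key]
        if id(model) not in cache:
            cache[id(model)] = model.linear_predictors(probe)
        eta = np.asarray(cache[id(model)][block], dtype=float).reshape(n_cells, 3)
        b0 = eta[:, 0]
        b1 = eta[:, 1] - eta[:, 0]
        scale = np.maximum(1.0, np.abs(eta).max(axis=1))
        curvature = np.abs(eta[:, 2] - (2.0 * eta[:, 1] - eta[:, 0]))
        if np.any(curvature > 1e-8 * scale):
            bad = index[curvature > 1e-8 * scale].tolist()
            raise ValueError(
                f"linear predictor for rate {rate!r} is not affine in size at "
                f"cells {bad}; only linear size terms are supported"
            )
        values[:, col_pos[(rate, "intercept")]] = b0
        if rate in ADULT_RATES:
            values[:, col_pos[(rate, "slope")]] = b1
        elif np.any(np.abs(b1) > 1e-12):
            raise ValueError(f"seedling rate {rate!r} must be size-independent")
    return pd.DataFrame(values, index=index, columns=columns)


def validate_cells(cells: pd.DataFrame) -> None:
    if not np.all(np.isfinite(cells.to_numpy())):
        bad = cells.index[~np.isfinite(cells.to_numpy()).all(axis=1)].tolist()
        raise ValueError(f"non-finite link-scale coefficients in cells {bad}")
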