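"""Model terms, hierarchical ("dredge") enumeration, and design matrices.

A candidate vital-rate model is identified by a set of terms drawn from

    size, site, year, size:site, size:year, site:year, size:site:year

(the intercept is always present).  Enumeration respects marginality: an
interaction may only enter together with all of its lower-order terms, so
the full three-way space contains 19 hierarchical candidates.

Design matrices use treatment (reference-level) coding for the factors,
which keeps fits full-rank on balanced designs; downstream code reduces any
fitted model to exact per-(site, year) affine coefficients, so the coding
choice is internal.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TERM_ORDER = (
    "size",
    "site",
    "year",
    "size:site",
    "size:year",
    "site:year",
    "size:site:year",
)

_PARENTS = {
    "size": frozenset(),
    "site": frozenset(),
    "year": frozenset(),
    "size:site": frozenset({"size", "site"}),
    "size:year": frozenset({"size", "year"}),
    "site:year": frozenset({"site", "year"}),
    "size:site:year": frozenset(
        {"size", "site", "year", "size:site", "size:year", "site:year"}
    ),
}


def canonical(terms: Iterable[str]) -> tuple[str, ...]:
    """Normalize a term collection to canonical order; validates names."""
    terms = set(terms)
    unknown = terms - set(TERM_ORDER)
    if unknown:
        raise ValueError(f"unknown model terms: {sorted(unknown)}")
    return tuple(t for t in TERM_ORDER if t in terms)


def is_hierarchical(terms: Iterable[str]) -> bool:
    """True if every interaction has all its lower-order terms present."""
    ts = set(terms)
    return all(_PARENTS[t] <= ts for t in ts)


def enumerate_hierarchical(maximal: Iterable[str]) -> list[tuple[str, ...]]:
    """All marginality-respecting sub-models of ``maximal``, smallest first.

    Returned term sets are canonical tuples ordered by (number of terms,
    canonical order), which gives the deterministic tie-break ordering used
    by parsimonious selection.
    """
    maximal = canonical(maximal)
    if not is_hierarchical(maximal):
        raise ValueError(f"maximal term set is not hierarchical: {maximal}")
    out = []
    for r in range(len(maximal) + 1):
        for combo in combinations(maximal, r):
            if is_hierarchical(combo):
                out.append(canonical(combo))
    return out


def _dummies(values: pd.Series, levels: Sequence) -> np.ndarray:
    """Treatment-coded indicator columns for levels[1:]; shape (n, L-1)."""
    arr = np.asarray(values)
    if len(levels) < 2:  # single level: factor contributes no columns
        return np.empty((len(arr), 0))
    return np.column_stack([(arr == lev).astype(float) for lev in levels[1:]])


def design_matrix(
    data: pd.DataFrame,
    terms: Iterable[str],
    site_levels: Sequence,
    year_levels: Sequence,
) -> tuple[np.ndarray, list[str]]:
    """Build the treatment-coded design matrix for a term set.

    ``data`` needs a ``size`` column when any size term is present, and
    ``site``/``year`` columns for factor terms.  Returns (X, column names).
    """
    terms = canonical(terms)
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]

    size = np.asarray(data["size"], dtype=float) if "size" in data.columns else None
    site_d = _dummies(data["site"], site_levels) if "site" in data.columns else None
    year_d = _dummies(data["year"], year_levels) if "year" in data.columns else None

    def add(col, name):
        cols.append(col)
        names.append(name)

    for term in terms:
        if term == "size":
            add(size, "size")
        elif term == "site":
            for j, lev in enumerate(site_levels[1:]):
                add(site_d[:, j], f"site[{lev}]")
        elif term == "year":
            for j, lev in enumerate(year_levels[1:]):
                add(year_d[:, j], f"year[{lev}]")
        elif term == "size:site":
            for j, lev in enumerate(site_levels[1:]):
                add(size * site_d[:, j], f"size:site[{lev}]")
        elif term == "size:year":
            for j, lev in enumerate(year_levels[1:]):
                add(size * year_d[:, j], f"size:year[{lev}]")
        elif term == "site:year":
            for j, s in enumerate(site_levels[1:]):
                for k, y in enumerate(year_levels[1:]):
                    add(site_d[:, j] * year_d[:, k], f"site[{s}]:year[{y}]")
        elif term == "size:site:year":
            for j, s in enumerate(site_levels[1:]):
                for k, y in enumerate(year_levels[1:]):
                    add(size * site_d[:, j] * year_d[:, k], f"size:site[{s}]:year[{y}]")
    return np.column_stack(cols), names


def n_columns(terms: Iterable[str], n_sites: int, n_years: int) -> int:
    """Number of design columns (including intercept) for a term set."""
    terms = canonical(terms)
    p = 1
    for term in terms:
        if term == "size":
            p += 1
        elif term == "site":
            p += n_sites - 1
        elif term == "year":
            p += n_years - 1
        elif term == "size:site":
            p += n_sites - 1
        elif term == "size:year":
            p += n_years - 1
        elif term in ("site:year", "size:site:year"):
            p += (n_sites - 1) * (n_years - 1)
    return p
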