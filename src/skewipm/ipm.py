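"""Kernel discretization and population growth rates.

The projection model couples a continuous size distribution n(x, t) with a
discrete seedling stage B(t):

    n(y, t+1) = integral over [L, U] of [ S(x) G(y, x) ] n(x, t) dx
                + G_s(y) S_s B(t)
    B(t+1)    = integral over [L, U] of [ P_f(x) f_w(x) P_r ] n(x, t) dx

S is survival, G the skew-normal growth density, P_f flowering
probability, f_w flowers conditional on flowering, P_r seedlings per
flower, S_s seedling survival and G_s the recruit-size density.  The
census is pre-reproductive: flowers made at t appear as seedlings at t+1,
and seedlings cannot flower in their first year (seedling-to-seedling
entry is zero).

Discretization follows the CDF-difference scheme: m equal-width size
classes over [L, U]; vital rates are evaluated at per-class points (the
median of observed sizes in the class, with midpoints for the five
largest and any empty classes); growth transition probabilities are
differences of the skew-normal CDF at class edges, renormalized per
source size so no probability mass is evicted past the size limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special

from . import _skewnorm

__all__ = [
    "Mesh",
    "IPMKernel",
    "build_mesh",
    "growth_block",
    "build_kernel",
    "lambda_deterministic",
    "lambda_stochastic",
    "cohort_lifespan",
    "write_kernel",
]

N_MIDPOINT_TOP = 5  # largest classes always use midpoints (few observations)


@dataclass(frozen=True)
class Mesh:
    """Size mesh: m equal-width classes over [L, U] plus a seedling stage."""

    L: float
    U: float
    m: int
    edges: np.ndarray = field(repr=False)
    points: np.ndarray = field(repr=False)

    @property
    def n_classes(self) -> int:
        """Matrix dimension: m size classes + 1 seedling class."""
        return self.m + 1

    @property
    def seedling_index(self) -> int:
        return self.m


def build_mesh(L: float, U: float, m: int = 100, observed_sizes=None) -> Mesh:
    """Equal-width mesh with median-of-class evaluation points.

    With ``observed_sizes`` given, each class's evaluation point is the
    median of the observed sizes falling in it; the five largest classes
    and any empty class use the midpoint instead.  Without observations,
    all points are midpoints.
    """
    if not L < U:
        raise ValueError(f"need L < U, got L={L}, U={U}")
    if m < 2:
        raise ValueError("need at least 2 size classes")
    edges = np.linspace(L, U, m + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    points = mids.copy()
    if observed_sizes is not None:
        sizes = np.asarray(observed_sizes, dtype=float)
        sizes = sizes[np.isfinite(sizes)]
        if sizes.size and (sizes.min() < L or sizes.max() > U):
            raise ValueError(
                "observed sizes outside [L, U]; the bounds are the data extremes"
            )
        bins = np.clip(np.searchsorted(edges, sizes, side="right") - 1, 0, m - 1)
        for j in range(m - N_MIDPOINT_TOP):
            in_bin = sizes[bins == j]
            if in_bin.size:
                points[j] = float(np.median(in_bin))
    return Mesh(L=float(L), U=float(U), m=int(m), edges=edges, points=points)


@dataclass
class IPMKernel:
    """Discretized (m+1) x (m+1) projection matrix for one site and year."""

    K: np.ndarray
    mesh: Mesh
    site: object = None
    year: object = None

    @property
    def matrix(self) -> np.ndarray:
        return self.K


def _cell_slope(cell: Mapping, rate: str) -> float:
    try:
        v = cell[(rate, "slope")]
    except KeyError:
        return 0.0
    return 0.0 if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def _rate_eta(cell, rate, x):
    b0 = float(cell[(rate, "intercept")])
    b1 = _cell_slope(cell, rate)
    eta = b0 + b1 * np.asarray(x, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError(f"non-finite link-scale predictor for rate {rate!r}")
    return eta


def _cdf_diff_columns(cdf_at_edges: np.ndarray, what: str) -> np.ndarray:
    """Per-column CDF differences renormalized to sum to one (anti-eviction)."""
    probs = np.clip(np.diff(cdf_at_edges, axis=0), 0.0, None)
    colsum = probs.sum(axis=0)
    if np.any(colsum < 1e-8):
        j = int(np.argmin(colsum))
        raise ValueError(
            f"all {what} probability mass evicted for source class {j} "
            f"(column sum {colsum[j]:.2e}); check scale predictions"
        )
    return probs / colsum


def growth_block(cell: Mapping, mesh: Mesh) -> np.ndarray:
    """Survival/growth block: column j maps source size x_j across classes.

    Column sums equal the survival prediction S(x_j) exactly, by the
    renormalization construction.
    """
    x = mesh.points
    surv = special.expit(_rate_eta(cell, "survival", x))
    xi = _rate_eta(cell, "growth_mu", x)
    omega = np.exp(_rate_eta(cell, "growth_sigma", x))
    alpha = _rate_eta(cell, "growth_nu", x)
    F = _skewnorm.cdf(mesh.edges[:, None], xi[None, :], omega[None, :], alpha[None, :])
    return _cdf_diff_columns(F, "growth") * surv[None, :]


def build_kernel(
    cell: Mapping,
    mesh: Mesh,
    site=None,
    year=None,
    shifted_counts: bool = False,
) -> IPMKernel:
    """Assemble the full (m+1) x (m+1) kernel from one cell's coefficients."""
    m = mesh.m
    x = mesh.points
    K = np.zeros((m + 1, m + 1))
    K[:m, :m] = growth_block(cell, mesh)

    # seedling column: survive at S_s, enter the size distribution G_s
    s_s = special.expit(float(cell[("seedling_survival", "intercept")]))
    mu_r = float(cell[("recruit_mu", "intercept")])
    sd_r = np.exp(float(cell[("recruit_sigma", "intercept")]))
    Fg = special.ndtr((mesh.edges - mu_r) / sd_r)
    K[:m, m] = _cdf_diff_columns(Fg[:, None], "recruit size")[:, 0] * s_s

    # fecundity row: flowers made at t recruit as seedlings at t+1
    p_r = float(cell[("seedlings_per_flower", "intercept")])
    if p_r < 0:
        warnings.warn("negative seedlings-per-flower clamped to 0", stacklevel=2)
        p_r = 0.0
    p_f = special.expit(_rate_eta(cell, "flowering", x))
    f_w = np.exp(_rate_eta(cell, "flower_count", x))
    if shifted_counts:
        f_w = f_w + 1.0
    K[m, :m] = p_f * f_w * p_r
    K[m, m] = 0.0  # seedlings do not flower in their first year

    if not np.all(np.isfinite(K)) or np.any(K < 0):
        raise ValueError("kernel has non-finite or negative entries")
    return IPMKernel(K=K, mesh=mesh, site=site, year=year)


def write_kernel(kernel: IPMKernel, csv_path) -> None:
    """Export a kernel as dense CSV with a JSON mesh sidecar (.json)."""
    import json
    from pathlib import Path

    csv_path = Path(csv_path)
    np.savetxt(csv_path, kernel.K, delimiter=",")
    sidecar = {
        "L": kernel.mesh.L,
        "U": kernel.mesh.U,
        "m": kernel.mesh.m,
        "edges": kernel.mesh.edges.tolist(),
        "points": kernel.mesh.points.tolist(),
        "seedling_index": kernel.mesh.seedling_index,
        "site": None if kernel.site is None else str(kernel.site),
        "year": None if kernel.year is None else str(kernel.year),
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def _as_matrix(kernel) -> np.ndarray:
    return kernel.K if isinstance(kernel, IPMKernel) else np.asarray(kernel, dtype=float)


def lambda_deterministic(kernel, return_vector: bool = False):
    """Dominant eigenvalue (deterministic lambda) of a projection matrix.

    With ``return_vector=True`` also returns the right eigenvector
    (stable stage structure) normalized to sum to one.
    """
    K = _as_matrix(kernel)
    vals, vecs = np.linalg.eig(K)
    i = int(np.argmax(np.abs(vals)))
    lam = float(np.real(vals[i]))
    if not return_vector:
        return lam
    w = np.real(vecs[:, i])
    w = np.abs(w)
    return lam, w / w.sum()


def lambda_stochastic(kernels: Sequence, n_steps: int = 5000, seed: int = 0) -> float:
    """Stochastic growth rate by simulation with i.i.d. annual kernels.

    Each step draws one annual kernel uniformly at random, projects the
    population vector, records the log growth increment and renormalizes.
    Returns exp(mean log increment) over ``n_steps`` steps.
    """
    mats = [_as_matrix(k) for k in kernels]
    if not mats:
        raise ValueError("need at least one annual kernel")
    dim = mats[0].shape[0]
    for M in mats:
        if np.max(np.abs(np.linalg.eigvals(M))) <= 0:
            raise ValueError("kernel with zero spectral radius")
    rng = np.random.default_rng(seed)
    choices = rng.integers(0, len(mats), size=n_steps)
    v = np.full(dim, 1.0 / dim)
    log_sum = 0.0
    for k in choices:
        v = mats[k] @ v
        r = v.sum()
        log_sum += np.log(r)
        v /= r
    return float(np.exp(log_sum / n_steps))


def cohort_lifespan(
    kernel,
    n0: int = 100,
    mortality_fraction: float = 0.99,
    max_steps: int = 10_000,
) -> int:
    """Years until ``mortality_fraction`` of a seedling cohort has died.

    Reproduction is ignored: the fecundity row is zeroed and a cohort of
    ``n0`` seedlings is projected through the survival/growth pathway
    until total abundance falls to (1 - mortality_fraction) * n0.
    """
    K = _as_matrix(kernel).copy()
    sdl = K.shape[0] - 1
    K[sdl, :] = 0.0
    n = np.zeros(K.shape[0])
    n[sdl] = float(n0)
    threshold = (1.0 - mortality_fraction) * n0
    for t in range(1, max_steps + 1):
        n = K @ n
        if n.sum() <= threshold:
            return t
    raise RuntimeError(
        f"cohort not {mortality_fraction:.0%} dead after {max_steps} steps; "
        "survival may be too close to 1"
    )
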