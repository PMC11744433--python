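"""Mesh construction, kernel assembly, growth rates, lifespan."""

import numpy as np
import pytest
from scipy import integrate, special

import skewipm._skewnorm as sn
from skewipm import ipm, synthetic


def power_iteration(K, iters=20_000, tol=1e-14):
    """Independent dominant-eigenvalue oracle."""
    v = np.full(K.shape[0], 1.0 / K.shape[0])
    lam = 0.0
    for _ in range(iters):
        w = K @ v
        lam_new = w.sum()
        v = w / lam_new
        if abs(lam_new - lam) < tol * max(1.0, abs(lam_new)):
            return lam_new
        lam = lam_new
    return lam


def random_kernel(rng, n):
    return rng.uniform(0.0, 1.0, (n, n)) * rng.random((n, n))


# ---------------------------------------------------------------------------
# mesh


def test_mesh_uses_bin_medians():
    mesh = ipm.build_mesh(0.0, 10.0, 10, observed_sizes=[0.2, 0.4])
    assert mesh.points[0] == pytest.approx(0.3)  # median of the bin's sizes


def test_mesh_empty_bins_fall_back_to_midpoints():
    mesh = ipm.build_mesh(0.0, 10.0, 10, observed_sizes=[0.2, 0.4])
    mids = 0.5 * (mesh.edges[:-1] + mesh.edges[1:])
    np.testing.assert_allclose(mesh.points[1:], mids[1:])


def test_mesh_top_five_classes_always_midpoints():
    rng = np.random.default_rng(0)
    sizes = rng.uniform(0.0, 10.0, 5000)  # plenty of data everywhere
    mesh = ipm.build_mesh(0.0, 10.0, 20, observed_sizes=sizes)
    mids = 0.5 * (mesh.edges[:-1] + mesh.edges[1:])
    np.testing.assert_allclose(mesh.points[-5:], mids[-5:])
    # interior, populated bins use medians (differ from midpoints)
    assert not np.allclose(mesh.points[:5], mids[:5])


def test_mesh_rejects_out_of_range_sizes_and_bad_bounds():
    with pytest.raises(ValueError, match="outside"):
        ipm.build_mesh(0.0, 1.0, 10, observed_sizes=[2.0])
    with pytest.raises(ValueError):
        ipm.build_mesh(1.0, 1.0, 10)
    with pytest.raises(ValueError):
        ipm.build_mesh(0.0, 1.0, 1)


def test_points_lie_within_their_bins():
    rng = np.random.default_rng(1)
    mesh = ipm.build_mesh(0.0, 8.0, 25, observed_sizes=rng.uniform(0, 8, 300))
    assert np.all(mesh.points >= mesh.edges[:-1])
    assert np.all(mesh.points <= mesh.edges[1:])


# ---------------------------------------------------------------------------
# kernel blocks


@pytest.fixture(scope="module")
def cell():
    return synthetic.single_cell_params().cell("A", 1)


def test_growth_columns_sum_to_survival(cell):
    mesh = ipm.build_mesh(0.5, 8.5, 60)
    block = ipm.growth_block(cell, mesh)
    surv = special.expit(0.2 + 0.5 * mesh.points)
    np.testing.assert_allclose(block.sum(axis=0), surv, atol=1e-12)


def test_cdf_differences_match_quadrature():
    rng = np.random.default_rng(8)
    for _ in range(10):
        xi = rng.uniform(1, 6)
        omega = rng.uniform(0.3, 1.5)
        alpha = rng.uniform(-4, 4)
        a, b = np.sort(rng.uniform(0, 8, 2))
        diff = sn.cdf(b, xi, omega, alpha) - sn.cdf(a, xi, omega, alpha)
        quad, _ = integrate.quad(lambda z: sn.pdf(z, xi, omega, alpha), a, b)
        assert diff == pytest.approx(quad, abs=1e-8)


def test_tight_growth_gives_near_identity_block(cell):
    c = cell.copy()
    c[("growth_mu", "intercept")] = 0.0
    c[("growth_mu", "slope")] = 1.0  # stay at current size
    c[("growth_sigma", "intercept")] = np.log(1e-4)
    c[("growth_sigma", "slope")] = 0.0
    c[("growth_nu", "intercept")] = 0.0
    c[("survival", "intercept")] = 50.0  # survival ~ 1
    c[("survival", "slope")] = 0.0
    mesh = ipm.build_mesh(0.5, 8.5, 30)
    block = ipm.growth_block(c, mesh)
    np.testing.assert_allclose(block, np.eye(30), atol=1e-10)


def test_zero_scale_mass_eviction_is_an_error(cell):
    c = cell.copy()
    c[("growth_mu", "intercept")] = 100.0  # all mass far above U
    c[("growth_sigma", "intercept")] = np.log(1e-3)
    mesh = ipm.build_mesh(0.5, 8.5, 20)
    with pytest.raises(ValueError, match="evicted"):
        ipm.growth_block(c, mesh)


def test_symmetric_growth_kernel_equals_gaussian_kernel(cell):
    c = cell.copy()
    c[("growth_nu", "intercept")] = 0.0
    c[("growth_nu", "slope")] = 0.0
    mesh = ipm.build_mesh(0.5, 8.5, 40)
    block = ipm.growth_block(c, mesh)
    # gaussian reference built from the normal CDF directly
    x = mesh.points
    xi = c[("growth_mu", "intercept")] + c[("growth_mu", "slope")] * x
    omega = np.exp(
        c[("growth_sigma", "intercept")] + c[("growth_sigma", "slope")] * x
    )
    F = special.ndtr((mesh.edges[:, None] - xi[None, :]) / omega[None, :])
    probs = np.diff(F, axis=0)
    probs /= probs.sum(axis=0)
    surv = special.expit(0.2 + 0.5 * x)
    np.testing.assert_allclose(block, probs * surv, atol=1e-8)


def test_full_kernel_structure(cell):
    mesh = ipm.build_mesh(0.5, 8.5, 30)
    kern = ipm.build_kernel(cell, mesh, shifted_counts=True)
    K = kern.K
    assert K.shape == (31, 31)
    assert np.all(K >= 0) and np.all(np.isfinite(K))
    # seedling column (above the fecundity row) sums to seedling survival
    assert K[:30, 30].sum() == pytest.approx(0.4, abs=1e-10)
    # seedlings cannot flower in their first year
    assert K[30, 30] == 0.0
    # fecundity row equals flowering prob x flowers x seedlings-per-flower
    x = mesh.points
    expected = (
        special.expit(-3.5 + 0.9 * x) * (1.0 + np.exp(-1.5 + 0.35 * x)) * 0.6
    )
    np.testing.assert_allclose(K[30, :30], expected, atol=1e-12)


def test_no_recruitment_kernel_is_subcritical(cell):
    c = cell.copy()
    c[("seedlings_per_flower", "intercept")] = 0.0
    mesh = ipm.build_mesh(0.5, 8.5, 30)
    kern = ipm.build_kernel(c, mesh)
    assert np.all(kern.K[30, :] == 0.0)
    assert ipm.lambda_deterministic(kern) < 1.0


def test_survival_growth_kernel_subcritical_when_survival_below_one(cell):
    mesh = ipm.build_mesh(0.5, 8.5, 40)
    block = ipm.growth_block(cell, mesh)
    assert np.max(np.abs(np.linalg.eigvals(block))) < 1.0


# ---------------------------------------------------------------------------
# lambda


def test_lambda_of_diagonal_matrix():
    assert ipm.lambda_deterministic(np.diag([0.5, 0.2])) == pytest.approx(0.5)


def test_two_by_two_closed_form_eigenvalue():
    S, Ss, F = 0.7, 0.4, 0.9  # F = P_f * f_w * P_r
    K = np.array([[S, Ss], [F, 0.0]])
    closed = 0.5 * (S + np.sqrt(S**2 + 4 * Ss * F))
    assert ipm.lambda_deterministic(K) == pytest.approx(closed, abs=1e-10)


def test_lambda_matches_power_iteration_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        K = random_kernel(rng, int(rng.integers(5, 40)))
        assert ipm.lambda_deterministic(K) == pytest.approx(
            power_iteration(K), abs=1e-8
        )


def test_stable_structure_is_a_probability_vector(cell):
    mesh = ipm.build_mesh(0.5, 8.5, 30)
    lam, w = ipm.lambda_deterministic(
        ipm.build_kernel(cell, mesh, shifted_counts=True), return_vector=True
    )
    assert w.sum() == pytest.approx(1.0)
    assert np.all(w >= 0)


def test_lambda_nondecreasing_in_kernel_entries(cell):
    mesh = ipm.build_mesh(0.5, 8.5, 20)
    K = ipm.build_kernel(cell, mesh, shifted_counts=True).K
    lam = ipm.lambda_deterministic(K)
    rng = np.random.default_rng(3)
    for _ in range(10):
        i, j = rng.integers(0, K.shape[0], 2)
        bumped = K.copy()
        bumped[i, j] += 0.01
        assert ipm.lambda_deterministic(bumped) >= lam - 1e-12


# ---------------------------------------------------------------------------
# stochastic lambda and lifespan


def test_stochastic_lambda_of_scalar_coin_flip_kernels():
    # kernels {2, 0.5} equally likely: log-growth averages to zero
    lam_s = ipm.lambda_stochastic([np.array([[2.0]]), np.array([[0.5]])], 5000, seed=4)
    assert lam_s == pytest.approx(1.0, abs=0.05)


def test_stochastic_lambda_rejects_nilpotent_kernels():
    with pytest.raises(ValueError, match="spectral radius"):
        ipm.lambda_stochastic([np.array([[0.0]])], 100, seed=0)
    with pytest.raises(ValueError):
        ipm.lambda_stochastic([], 100, seed=0)


def test_stochastic_lambda_independent_reimplementation(cell):
    """Cross-check against a separately-coded long-run simulation."""
    params = synthetic.single_cell_params()
    K1 = synthetic.truth_kernel(params, "A", 1, m=30).K
    K2 = 0.9 * K1
    lam_s = ipm.lambda_stochastic([K1, K2], n_steps=5000, seed=5)
    # independent route: different RNG (RandomState), different bookkeeping
    rs = np.random.RandomState(99)
    v = np.ones(K1.shape[0])
    logs = []
    for _ in range(5000):
        M = K1 if rs.rand() < 0.5 else K2
        v = M @ v
        tot = v.sum()
        logs.append(np.log(tot))
        v /= tot
    lam_ref = np.exp(np.mean(logs))
    mc_se = np.std(logs) / np.sqrt(5000)
    assert abs(np.log(lam_s) - np.log(lam_ref)) < 2 * mc_se + 1e-3


@pytest.mark.parametrize("s, expected", [(0.5, 7), (0.9, 44)])
def test_cohort_lifespan_scalar_survival(s, expected):
    # seedlings promote into a single adult class with survival s:
    # total abundance is 100 * s^t, and 99% mortality needs s^t <= 0.01
    K = np.array([[s, s], [0.0, 0.0]])
    assert ipm.cohort_lifespan(K, n0=100, mortality_fraction=0.99) == expected


def test_cohort_lifespan_errors_when_nobody_dies():
    K = np.array([[1.0, 1.0], [0.0, 0.0]])
    with pytest.raises(RuntimeError, match="survival"):
        ipm.cohort_lifespan(K, n0=100, max_steps=200)


def test_lifespan_monotone_in_survival(cell):
    mesh = ipm.build_mesh(0.5, 8.5, 30)
    base = ipm.cohort_lifespan(ipm.build_kernel(cell, mesh).K)
    rng = np.random.default_rng(6)
    for _ in range(10):
        c = cell.copy()
        c[("survival", "intercept")] += rng.uniform(0.05, 0.6)
        bumped = ipm.cohort_lifespan(ipm.build_kernel(c, mesh).K)
        assert bumped >= base


def test_kernel_csv_export_round_trip(tmp_path, cell):
    mesh = ipm.build_mesh(0.5, 8.5, 20)
    kern = ipm.build_kernel(cell, mesh, site="A", year=1, shifted_counts=True)
    path = tmp_path / "kernel.csv"
    ipm.write_kernel(kern, path)
    back = np.loadtxt(path, delimiter=",")
    np.testing.assert_allclose(back, kern.K, rtol=1e-12)
    import json

    sidecar = json.loads(path.with_suffix(".json").read_text())
    assert sidecar["m"] == 20 and sidecar["site"] == "A"
    np.testing.assert_allclose(sidecar["edges"], mesh.edges)
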