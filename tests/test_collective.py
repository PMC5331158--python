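import math

import numpy as np
import pytest
from scipy.linalg import solve

from ramadens.basis import DirectionSpec, TensorBasis
from ramadens.collective import (
    CollectiveDensityEstimator,
    component_energy,
    normalizing_constant,
    orthonormalize,
    penalized_criterion,
    penalty_trace,
    update_lambda,
)
from ramadens.dataset import AngularDataset

AREA = 4 * math.pi**2


class TestNormalizingConstant:
    def test_uniform_and_shift(self, torus_basis):
        n = torus_basis.B.shape[0]
        ca = torus_basis.cell_area
        assert normalizing_constant(np.zeros(n), ca) == \
            pytest.approx(-math.log(AREA), abs=1e-12)
        assert normalizing_constant(np.full(n, 5.0), ca) == \
            pytest.approx(-5.0 - math.log(AREA), abs=1e-12)

    def test_defines_a_proper_density(self, torus_basis, rng):
        om = rng.standard_normal(torus_basis.B.shape[0]) * 3
        c = normalizing_constant(om, torus_basis.cell_area)
        total = np.exp(c) * np.sum(np.exp(om)) * torus_basis.cell_area
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalizing_constant(np.array([0.0, np.inf]), 0.1)


class TestPenalizedCriterion:
    def test_zero_coefficients_have_no_penalty(self, torus_basis):
        Theta = np.zeros((torus_basis.L, 2))
        assert penalized_criterion(-10.0, Theta, torus_basis.D, 3.0) == 20.0

    def test_penalty_linear_in_lambda_and_trace_identity(self, torus_basis,
                                                         rng):
        Theta = rng.standard_normal((torus_basis.L, 3))
        D = torus_basis.D
        p1 = penalized_criterion(0.0, Theta, D, 1.0)
        p2 = penalized_criterion(0.0, Theta, D, 2.0)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)
        by_columns = sum(Theta[:, k] @ D @ Theta[:, k] for k in range(3))
        assert penalty_trace(Theta, D) == pytest.approx(by_columns, rel=1e-12)

    def test_nonpositive_lambda_rejected(self, torus_basis):
        with pytest.raises(ValueError):
            penalized_criterion(0.0, np.zeros((torus_basis.L, 1)),
                                torus_basis.D, 0.0)


class TestLambdaUpdate:
    def test_direct_arithmetic(self):
        # lambda = (df - (a-1)) / trace
        Theta = np.array([[math.sqrt(2.0)], [0.0]])
        D = np.eye(2)  # trace = 2
        assert update_lambda(Theta, D, df=5.0, a=2, previous=1.0) == \
            pytest.approx(2.0)
        Theta1 = np.array([[2.0], [0.0]])  # trace 4 = df - (a-1)
        assert update_lambda(Theta1, D, df=5.0, a=2, previous=1.0) == \
            pytest.approx(1.0)

    def test_degenerate_cases_keep_previous(self):
        D = np.eye(2)
        Theta = np.array([[1.0], [0.0]])
        assert update_lambda(Theta, D, df=0.5, a=2, previous=7.0) == 7.0
        assert update_lambda(np.zeros((2, 1)), D, df=5.0, a=2,
                             previous=7.0) == 7.0


class TestOrthonormalize:
    def test_orthonormal_input_unchanged_up_to_sign(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        A = rng.standard_normal((6, 3)) * [3.0, 2.0, 1.0]
        T2, A2 = orthonormalize(q, A)
        np.testing.assert_allclose(T2.T @ T2, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T2 @ A2.T, q @ A.T, atol=1e-10)

    def test_mixing_invariance_of_reconstruction(self, rng):
        Theta = rng.standard_normal((20, 3))
        A = rng.standard_normal((6, 3))
        M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        T1, A1 = orthonormalize(Theta, A)
        T2, A2 = orthonormalize(Theta @ M, A @ np.linalg.inv(M).T)
        np.testing.assert_allclose(T1 @ A1.T, T2 @ A2.T, atol=1e-8)

    def test_energy_ordering(self, rng):
        Theta = rng.standard_normal((20, 3))
        A = rng.standard_normal((8, 3))
        _, A2 = orthonormalize(Theta, A)
        g, _ = component_energy(A2)
        assert np.all(np.diff(g) <= 1e-12)


class TestComponentEnergy:
    def test_single_component_takes_all_energy(self):
        A = np.zeros((5, 3))
        A[:, 1] = 2.0
        g, share = component_energy(A)
        assert g[1] == pytest.approx(20.0)
        np.testing.assert_allclose(share, [0.0, 100.0, 0.0])

    def test_energies_sum_to_frobenius_norm(self, rng):
        A = rng.standard_normal((7, 4))
        g, _ = component_energy(A)
        assert g.sum() == pytest.approx(np.linalg.norm(A) ** 2, rel=1e-12)


class TestLogLikelihood:
    def test_matches_brute_force_point_loop(self, small_fit,
                                            small_shared_data):
        data, _, _ = small_shared_data
        est = small_fit
        _, c, _ = est._grid_state(est.Theta_, est.A_)
        ll_internal = est._loglik(est.Theta_, est.A_, c)
        brute = 0.0
        for i, g in enumerate(data.groups):
            for point in g:
                om = float(
                    est.basis_.evaluate(point[None, :])[0]
                    @ (est.Theta_ @ est.A_[i])
                )
                brute += om + c[i]
        assert ll_internal == pytest.approx(brute, rel=1e-10)


class TestNewtonGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Single group, K=1: the exponential-family gradient (empirical
        basis sum minus n * expected basis moment, minus the penalty pull)
        agrees with central finite differences of the criterion."""
        d = DirectionSpec(df=6)
        basis = TensorBasis(d, d, grid_points=25)
        X = rng.vonmises(0.3, 2.0, size=(40, 2))
        theta = rng.standard_normal(basis.L) * 0.1
        lam = 2.0
        Bx = basis.evaluate(X)
        s = Bx.sum(axis=0)

        def criterion(t):
            c = normalizing_constant(basis.B @ t, basis.cell_area)
            ll = float(np.sum(Bx @ t) + X.shape[0] * c)
            return -2 * ll + lam * float(t @ basis.D @ t)

        om = basis.B @ theta
        c = normalizing_constant(om, basis.cell_area)
        w = np.exp(om + c) * basis.cell_area
        mu = basis.B.T @ w
        grad = -2 * (s - X.shape[0] * mu) + 2 * lam * (basis.D @ theta)
        h = 1e-6
        for idx in rng.choice(basis.L, size=10, replace=False):
            e = np.zeros(basis.L)
            e[idx] = h
            fd = (criterion(theta + e) - criterion(theta - e)) / (2 * h)
            assert fd == pytest.approx(grad[idx], rel=1e-6, abs=1e-8)


def _standalone_penalized_fit(basis, X, a=2, tol=1e-12, max_iter=300):
    """Independent single-density penalized log-spline fit with the in-loop
    smoothing update (full Newton on the coefficient vector).

    The constant coefficient direction is excluded (centered
    parameterization): it is in the penalty nullspace and the normalizing
    constant absorbs it, so it is not identified by the likelihood.
    """
    Bx = basis.evaluate(X)
    s = Bx.sum(axis=0)
    n = X.shape[0]
    beta = np.zeros(basis.L)
    v0 = np.full(basis.L, 1.0 / math.sqrt(basis.L))
    lam = 1.0

    def crit(b, lam):
        c = normalizing_constant(basis.B @ b, basis.cell_area)
        return -2 * (np.sum(Bx @ b) + n * c) + lam * float(b @ basis.D @ b)

    prev = None
    for _ in range(max_iter):
        om = basis.B @ beta
        c = normalizing_constant(om, basis.cell_area)
        w = np.exp(om + c) * basis.cell_area
        mu = basis.B.T @ w
        H = n * (basis.B.T @ (basis.B * w[:, None]) - np.outer(mu, mu))
        df = float(np.trace(solve(H + lam * basis.D, H, assume_a="sym")))
        tr = float(beta @ basis.D @ beta)
        if df > a - 1 and tr > 1e-12:
            lam = (df - (a - 1)) / tr
        g = s - n * mu
        step = solve(H + lam * basis.D + 1e-10 * np.eye(basis.L),
                     g - lam * (basis.D @ beta), assume_a="sym")
        step = step - v0 * (step @ v0)
        base = crit(beta, lam)
        gamma = 1.0
        for _ in range(40):
            if crit(beta + gamma * step, lam) <= base + 1e-12 * abs(base):
                beta = beta + gamma * step
                break
            gamma /= 2
        cur = crit(beta, lam)
        if prev is not None and abs(prev - cur) <= tol * (abs(prev) + 1):
            break
        prev = cur
    c = normalizing_constant(basis.B @ beta, basis.cell_area)
    return np.exp(basis.B @ beta + c)


class TestFit:
    def test_single_group_matches_standalone_penalized_fit(self, rng):
        d = DirectionSpec(df=8)
        X = rng.vonmises(0.5, 2.0, size=(300, 2))
        est = CollectiveDensityEstimator(
            n_components=1, dir1=d, dir2=d, grid_points=40, tol=1e-12,
            max_iter=500,
        ).fit(X)
        basis = est.basis_
        f_standalone = _standalone_penalized_fit(basis, X)
        f_collective = np.exp(est.log_density_values(0))
        assert np.max(np.abs(f_collective - f_standalone)) < 1e-6

    def test_uniform_data_recovers_flat_density(self, rng):
        X = rng.uniform(-math.pi, math.pi, size=(20000, 2))
        d = DirectionSpec(df=8)
        est = CollectiveDensityEstimator(
            n_components=1, dir1=d, dir2=d, grid_points=30, max_iter=100,
        ).fit(X, np.zeros(len(X), int))
        vals = est.density(0).values
        assert np.all(np.abs(vals * AREA - 1.0) < 0.05)

    def test_densities_normalized_and_criterion_descends(self, small_fit):
        est = small_fit
        assert est.converged_ and est.n_iter_ <= 200
        for d in est.densities():
            assert d.integral() == pytest.approx(1.0, abs=1e-3)
        end = np.asarray(est.criterion_trace_)
        start = np.asarray(est.criterion_start_trace_)
        assert np.all(end <= start + 1e-8 * (np.abs(start) + 1))

    def test_identifiability_under_mixed_initialization(self,
                                                        small_shared_data,
                                                        rng):
        """Runs whose initializations differ by an invertible mixing of
        (Theta, A) converge to the same density grids."""
        data, _, _ = small_shared_data
        kw = dict(n_components=2, dir1=DirectionSpec(df=8),
                  dir2=DirectionSpec(df=8), grid_points=40,
                  lambda_mode="fixed", lambda_init=1.0, tol=1e-9,
                  max_iter=400)
        est1 = CollectiveDensityEstimator(**kw).fit_dataset(data)
        est2 = CollectiveDensityEstimator(**kw)
        M = rng.standard_normal((2, 2)) + 3 * np.eye(2)
        init = est1._initialize  # same KDE-projection initializer

        def mixed_init(data, basis, K, _init=init, _M=M):
            Theta, A = _init(data, basis, K)
            return Theta @ _M, A @ np.linalg.inv(_M).T

        est2._initialize = mixed_init
        est2.fit_dataset(data)
        for i in range(data.m):
            f1 = est1.density(i).values
            f2 = est2.density(i).values
            assert np.max(np.abs(f1 - f2)) < 1e-6

    def test_effective_df_monotone_in_lambda(self, small_fit):
        est = small_fit
        dfs = [est.effective_df(lam=l) for l in (1e-2, 1.0, 1e2, 1e4)]
        assert np.all(np.diff(dfs) < 0)
        K, L = est.A_.shape[1], est.basis_.L
        assert dfs[0] <= K * L + 1e-6

    def test_initialization_is_rank_k_svd_of_projected_kde(self,
                                                           small_shared_data):
        data, _, _ = small_shared_data
        est = CollectiveDensityEstimator(
            n_components=2, dir1=DirectionSpec(df=8), dir2=DirectionSpec(df=8),
            grid_points=40,
        )
        basis = TensorBasis(DirectionSpec(df=8), DirectionSpec(df=8),
                            grid_points=40)
        est.basis_ = basis
        Theta, A = est._initialize(data, basis, 2)
        # columns orthogonal, scale carried by the singular values
        off = Theta.T @ Theta
        assert abs(off[0, 1]) < 1e-8
        # reconstruction equals the rank-2 SVD truncation of the centered
        # projected KDE log-density matrix
        from ramadens.kde import CircularKDE

        logf = np.empty((basis.B.shape[0], data.m))
        for i, g in enumerate(data.groups):
            kde = CircularKDE(dir1=basis.dir1, dir2=basis.dir2).fit(g)
            f = kde.density_on_basis_grid(basis).values.ravel()
            logf[:, i] = np.log(np.maximum(f, 1e-10))
        C, *_ = np.linalg.lstsq(basis.B, logf, rcond=None)
        v0 = np.full(basis.L, 1.0 / math.sqrt(basis.L))
        C = C - np.outer(v0, v0 @ C)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        truncated = U[:, :2] @ np.diag(s[:2]) @ Vt[:2]
        np.testing.assert_allclose(Theta @ A.T, truncated, atol=1e-8)

    def test_evaluate_density_consistency(self, small_fit):
        est = small_fit
        d = est.density(1)
        recomputed = np.exp(
            est.basis_.B @ (est.Theta_ @ est.A_[1]) + est.c_[1]
        ).reshape(d.values.shape)
        np.testing.assert_allclose(d.values, recomputed, atol=1e-12)
        with pytest.raises(IndexError):
            est.density(99)

    def test_k_larger_than_m_rejected(self, small_shared_data):
        data, _, _ = small_shared_data
        est = CollectiveDensityEstimator(n_components=10,
                                         dir1=DirectionSpec(df=8),
                                         dir2=DirectionSpec(df=8),
                                         grid_points=30)
        with pytest.raises(ValueError, match="n_components"):
            est.fit_dataset(data)

    def test_points_outside_bounded_domain_rejected(self):
        d1 = DirectionSpec(periodic=False, df=5,
                           range=(math.radians(75), math.radians(165)))
        d2 = DirectionSpec(df=8)
        X = np.array([[math.radians(60.0), 0.0]] * 5)
        est = CollectiveDensityEstimator(n_components=1, dir1=d1, dir2=d2,
                                         grid_points=20)
        with pytest.raises(ValueError, match="domain"):
            est.fit(X)

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        est = CollectiveDensityEstimator(n_components=4, lambda_init=2.0)
        c = clone(est)
        assert c.get_params()["n_components"] == 4
        assert c.get_params()["lambda_init"] == 2.0
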