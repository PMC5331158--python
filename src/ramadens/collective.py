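"""Collective penalized log-spline estimation of multiple angular densities.

Model
-----
Each of the ``m`` group densities is written as ``log f_i(x) = w_i(x) + c_i``
where ``w_i = b(x)^T Theta alpha_i`` is a linear combination of ``K`` shared
components, themselves expansions in a rich tensor-product spline basis
``b(x)`` of dimension ``L``, and ``c_i`` normalizes each density.  On the
evaluation grid this is the low-rank factorization ``Omega = B Theta A^T``.

The parameters minimize the penalized criterion

    -2 * loglik(Theta, A) + lambda * trace(Theta^T D Theta)

by an alternating blockwise Newton-Raphson: one damped Newton step per shared
component (columns of ``Theta``), one per group score vector (rows of ``A``),
an SVD re-orthonormalization that fixes the factorization indeterminacy, and
an in-loop update of the smoothing parameter

    lambda <- (df(lambda) - (a - 1)) / trace(Theta^T D Theta)

which replaces an AIC grid search.  ``df(lambda)`` is the effective model
dimension ``sum_k trace((H_k + lambda D)^{-1} H_k)`` with ``H_k`` the
likelihood curvature of component ``k``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve
from sklearn.base import BaseEstimator

from .basis import DirectionSpec, TensorBasis
from .dataset import AngularDataset
from .grids import DensityGrid
from .kde import CircularKDE

__all__ = [
    "CollectiveDensityEstimator",
    "normalizing_constant",
    "log_likelihood_terms",
    "penalized_criterion",
    "update_lambda",
    "orthonormalize",
    "component_energy",
    "fit_pscde_t",
]

_DENSITY_FLOOR = 1e-10


def normalizing_constant(omega: np.ndarray, cell_area: float) -> float:
    """``c = -log sum_j exp(omega_j) * cell_area``, max-shifted for stability."""
    omega = np.asarray(omega, float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("non-finite log-density values")
    mx = float(omega.max())
    return -(mx + np.log(np.exp(omega - mx).sum() * cell_area))


def log_likelihood_terms(
    SufT: np.ndarray, A: np.ndarray, c: np.ndarray, n_i: np.ndarray
) -> float:
    """Log-likelihood from sufficient statistics.

    ``SufT`` is the K x m matrix ``Theta^T s_i`` of projected per-group basis
    sums (``s_i = sum_j b(x_ij)``); the data enter only through it and the
    group sizes.
    """
    return float(np.sum(A.T * SufT) + np.dot(n_i, c))


def penalty_trace(Theta: np.ndarray, D: np.ndarray) -> float:
    return float(np.sum(Theta * (D @ Theta)))


def penalized_criterion(loglik: float, Theta: np.ndarray, D: np.ndarray,
                        lam: float) -> float:
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return -2.0 * loglik + lam * penalty_trace(Theta, D)


def update_lambda(Theta: np.ndarray, D: np.ndarray, df: float, a: int,
                  previous: float) -> float:
    """In-loop smoothing-parameter update; degenerate cases keep ``previous``.

    The update equates the penalty trace with the surplus model dimension:
    ``lambda = (df - (a - 1)) / trace(Theta^T D Theta)``.
    """
    tr = penalty_trace(Theta, D)
    if df <= a - 1 or tr <= 1e-12:
        return previous
    return (df - (a - 1)) / tr


def _signed_svd(P: np.ndarray, K: int):
    U, s, Vt = np.linalg.svd(P, full_matrices=False)
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    # deterministic sign: largest-magnitude loading positive per component
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, s, Vt * signs[:, None]


def orthonormalize(Theta: np.ndarray, A: np.ndarray):
    """SVD identifiability step: orthonormal ``Theta``, energy-ordered
    components, unchanged reconstruction ``B Theta A^T``."""
    U, s, Vt = _signed_svd(Theta @ A.T, Theta.shape[1])
    return U, Vt.T * s


def canonicalize(Theta: np.ndarray, A: np.ndarray, null_vec=None):
    """Canonical factorization used inside the optimizer: scale in ``Theta``.

    ``Theta`` columns are orthogonal with norms equal to the singular values
    of ``Theta A^T`` and ``A`` has orthonormal columns, so the roughness
    penalty sees the amplitude of each fitted component, exactly as a
    standalone penalized log-spline fit would.  If ``null_vec`` is given,
    that coefficient direction (the constant surface, which the normalizing
    constants absorb) is projected out first.
    """
    P = Theta @ A.T
    if null_vec is not None:
        P = P - np.outer(null_vec, null_vec @ P)
    U, s, Vt = _signed_svd(P, Theta.shape[1])
    return U * s, Vt.T


def component_energy(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scree energies ``g(k) = sum_i alpha_ik^2`` and their percentage shares."""
    g = np.sum(np.asarray(A, float) ** 2, axis=0)
    total = g.sum()
    share = 100.0 * g / total if total > 0 else np.zeros_like(g)
    return g, share


class CollectiveDensityEstimator(BaseEstimator):
    """Shared-basis penalized maximum-likelihood estimator of many densities.

    Parameters
    ----------
    n_components : int
        Number of shared log-density components ``K``.
    dir1, dir2 : DirectionSpec, optional
        Domain geometry; defaults to the fully periodic torus with a cubic
        trigonometric basis of 15 functions per direction.
    diff_order : int
        Order ``a`` of the difference penalty.
    cyclic_penalty : bool
        Wrap the difference stencils on periodic directions.
    grid_points : int
        Evaluation-grid resolution per direction.
    lambda_init : float
        Starting smoothing parameter.
    lambda_mode : {"auto", "fixed", "aic_grid"}
        "auto" updates lambda inside the Newton loop; "fixed" keeps
        ``lambda_init``; "aic_grid" refits on ``aic_grid`` values and keeps
        the AIC minimizer.
    aic_grid : sequence of float, optional
        Candidate lambdas for ``lambda_mode="aic_grid"``.
    tol : float
        Relative change of the penalized criterion declaring convergence.
    max_iter : int
        Hard iteration cap.

    Attributes
    ----------
    Theta_ : ndarray (L, K)
        Shared component coefficients, orthonormal columns.
    A_ : ndarray (m, K)
        Per-group scores.
    c_ : ndarray (m,)
        Normalizing constants.
    lambda_ : float
        Final smoothing parameter.
    lambda_trace_, criterion_trace_ : list of float
        Per-iteration smoothing parameter and penalized criterion.
    df_, aic_, loglik_ : float
        Effective degrees of freedom, AIC and log-likelihood at convergence.
    energies_ : ndarray (K,)
        Scree energies of the components.
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int = 3,
        dir1: DirectionSpec | None = None,
        dir2: DirectionSpec | None = None,
        diff_order: int = 2,
        cyclic_penalty: bool = True,
        grid_points: int = 90,
        lambda_init: float = 1.0,
        lambda_mode: str = "auto",
        aic_grid=None,
        tol: float = 1e-6,
        max_iter: int = 500,
        max_halvings: int = 30,
    ):
        self.n_components = n_components
        self.dir1 = dir1
        self.dir2 = dir2
        self.diff_order = diff_order
        self.cyclic_penalty = cyclic_penalty
        self.grid_points = grid_points
        self.lambda_init = lambda_init
        self.lambda_mode = lambda_mode
        self.aic_grid = aic_grid
        self.tol = tol
        self.max_iter = max_iter
        self.max_halvings = max_halvings

    # ------------------------------------------------------------------ #
    # fitting                                                            #
    # ------------------------------------------------------------------ #

    def fit(self, X, groups=None, y=None):
        """Fit from stacked angle pairs ``X`` (radians) with group labels."""
        if groups is None:
            groups = np.zeros(np.asarray(X).shape[0], dtype=int)
        data = AngularDataset.from_arrays(X, groups)
        return self.fit_dataset(data)

    def fit_dataset(self, data: AngularDataset):
        K = int(self.n_components)
        basis = TensorBasis(
            self.dir1 if self.dir1 is not None else DirectionSpec(),
            self.dir2 if self.dir2 is not None else DirectionSpec(),
            diff_order=self.diff_order,
            cyclic_penalty=self.cyclic_penalty,
            grid_points=self.grid_points,
        )
        if K > min(data.m, basis.L):
            raise ValueError(
                f"n_components={K} exceeds min(m, L)="
                f"{min(data.m, basis.L)}"
            )
        X, _ = data.stacked()
        if not np.all(basis.in_domain(X)):
            raise ValueError("observations outside the configured domain")
        self.basis_ = basis
        self.labels_ = list(data.labels)
        self._n_i = data.n_i.astype(float)
        # constant coefficient direction: in the penalty nullspace and
        # absorbed by the normalizing constants, so excluded from Theta
        self._v0 = np.full(basis.L, 1.0 / np.sqrt(basis.L))
        # per-group empirical basis sums s_i = sum_j b(x_ij)
        self._S = np.stack(
            [basis.evaluate(g).sum(axis=0) for g in data.groups], axis=1
        )
        Theta, A = self._initialize(data, basis, K)

        if self.lambda_mode == "aic_grid":
            grid = self.aic_grid
            if grid is None or len(grid) == 0:
                raise ValueError("aic_grid mode needs a non-empty aic_grid")
            best = None
            # warm-start along the descending-lambda path: each fit begins
            # from the previous (smoother) solution, giving a clean profile
            T0, A0 = Theta, A
            for lam in sorted(float(l) for l in grid)[::-1]:
                res = self._run(T0.copy(), A0.copy(), lam, auto=False)
                T0, A0 = res["Theta"], res["A"]
                if best is None or res["aic"] < best["aic"]:
                    best = res
            self._adopt(best)
        else:
            auto = self.lambda_mode == "auto"
            if self.lambda_mode not in ("auto", "fixed"):
                raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")
            self._adopt(self._run(Theta, A, float(self.lambda_init), auto=auto))
        return self

    def _initialize(self, data: AngularDataset, basis: TensorBasis, K: int):
        """KDE log-densities projected onto the basis, factored by rank-K SVD."""
        logf = np.empty((basis.B.shape[0], data.m))
        for i, g in enumerate(data.groups):
            kde = CircularKDE(dir1=basis.dir1, dir2=basis.dir2).fit(g)
            f = kde.density_on_basis_grid(basis).values.ravel()
            logf[:, i] = np.log(np.maximum(f, _DENSITY_FLOOR))
        C, *_ = np.linalg.lstsq(basis.B, logf, rcond=None)  # L x m
        v0 = np.full(basis.L, 1.0 / np.sqrt(basis.L))
        C = C - np.outer(v0, v0 @ C)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        return U[:, :K] * s[:K], Vt[:K].T

    # grid-level quantities shared by all update steps ------------------ #

    def _grid_state(self, Theta: np.ndarray, A: np.ndarray):
        B, ca = self.basis_.B, self.basis_.cell_area
        W = B @ Theta                      # n_grid x K
        Om = W @ A.T                       # n_grid x m
        mx = Om.max(axis=0)
        z = np.exp(Om - mx)
        c = -(mx + np.log(z.sum(axis=0) * ca))
        w = z * (np.exp(mx + c) * ca)      # n_grid x m, columns sum to 1
        return W, c, w

    def _loglik(self, Theta: np.ndarray, A: np.ndarray, c: np.ndarray) -> float:
        return log_likelihood_terms(Theta.T @ self._S, A, c, self._n_i)

    def _pl(self, Theta: np.ndarray, A: np.ndarray, lam: float) -> float:
        _, c, _ = self._grid_state(Theta, A)
        return penalized_criterion(self._loglik(Theta, A, c), Theta,
                                   self.basis_.D, lam)

    def _component_hessian(self, w: np.ndarray, Mu: np.ndarray,
                           A: np.ndarray, k: int) -> np.ndarray:
        """Negative log-likelihood curvature of component k:
        ``H_k = sum_i n_i alpha_ik^2 Cov_i[b]``."""
        B = self.basis_.B
        wt = self._n_i * A[:, k] ** 2
        u = w @ wt
        return B.T @ (B * u[:, None]) - (Mu * wt) @ Mu.T

    def _accept_damped(self, Theta, A, lam, pl0, propose):
        """Step-halving acceptance on the orthonormalized representative.

        The factorization ``(Theta, A)`` is only identified up to an
        invertible mixing; the penalty is only meaningful on the canonical
        representative with orthonormal ``Theta``.  Every candidate step is
        therefore re-orthonormalized before the criterion comparison, which
        makes the accepted sequence non-increasing at fixed lambda.
        """
        gamma = 1.0
        for _ in range(self.max_halvings):
            cand_T, cand_A = propose(gamma)
            cand_T, cand_A = canonicalize(cand_T, cand_A, self._v0)
            pl = self._pl(cand_T, cand_A, lam)
            if pl <= pl0 + 1e-12 * (abs(pl0) + 1.0):
                return cand_T, cand_A, pl
            gamma *= 0.5
        return Theta, A, pl0

    def _theta_sweep(self, Theta, A, lam, pl0):
        B, D = self.basis_.B, self.basis_.D
        for k in range(Theta.shape[1]):
            _, c, w = self._grid_state(Theta, A)
            Mu = B.T @ w                                   # L x m
            resid = self._S - Mu * self._n_i[None, :]
            g_ll = resid @ A[:, k]
            Hk = self._component_hessian(w, Mu, A, k)
            Hpen = Hk + lam * D
            rhs = g_ll - lam * (D @ Theta[:, k])
            try:
                step = cho_solve(cho_factor(Hpen), rhs)
            except np.linalg.LinAlgError:
                step = solve(Hpen + 1e-8 * np.eye(Hpen.shape[0]), rhs,
                             assume_a="sym")
            if not np.all(np.isfinite(step)):
                raise FloatingPointError("non-finite Newton step")

            def propose(gamma, k=k, step=step, Theta=Theta, A=A):
                cand = Theta.copy()
                cand[:, k] = Theta[:, k] + gamma * step
                return cand, A

            Theta, A, pl0 = self._accept_damped(Theta, A, lam, pl0, propose)
        return Theta, A, pl0

    def _a_sweep(self, Theta, A, lam, pl0):
        ca = self.basis_.cell_area
        for i in range(A.shape[0]):
            W = self.basis_.B @ Theta
            SufT_i = Theta.T @ self._S[:, i]
            om = W @ A[i]
            ci = normalizing_constant(om, ca)
            wi = np.exp(om + ci) * ca
            mu = W.T @ wi
            g = SufT_i - self._n_i[i] * mu
            Hi = self._n_i[i] * (W.T @ (W * wi[:, None]) - np.outer(mu, mu))
            step = solve(Hi + 1e-8 * np.eye(Hi.shape[0]), g, assume_a="sym")

            def propose(gamma, i=i, step=step, Theta=Theta, A=A):
                cand = A.copy()
                cand[i] = A[i] + gamma * step
                return Theta, cand

            Theta, A, pl0 = self._accept_damped(Theta, A, lam, pl0, propose)
        return Theta, A, pl0

    def effective_df(self, Theta=None, A=None, lam=None) -> float:
        """``df(lambda) = sum_k trace((H_k + lambda D)^{-1} H_k)``."""
        Theta = self._Theta_c if Theta is None else Theta
        A = self._A_c if A is None else A
        lam = self.lambda_ if lam is None else lam
        _, _, w = self._grid_state(Theta, A)
        Mu = self.basis_.B.T @ w
        D = self.basis_.D
        df = 0.0
        for k in range(Theta.shape[1]):
            Hk = self._component_hessian(w, Mu, A, k)
            df += float(np.trace(solve(Hk + lam * D, Hk, assume_a="sym")))
        return df

    def _run(self, Theta, A, lam, auto: bool) -> dict:
        lam_trace, crit_trace, crit_start = [], [], []
        prev = None
        prev_lam = lam
        converged = False
        Theta, A = canonicalize(Theta, A, self._v0)
        if auto:
            # pre-stabilize the scalar lambda fixed point at the initial fit
            for _ in range(20):
                df = self.effective_df(Theta, A, lam)
                new = update_lambda(Theta, self.basis_.D, df,
                                    self.diff_order, lam)
                if abs(new - lam) <= 1e-3 * lam:
                    lam = new
                    break
                lam = new
        for it in range(self.max_iter):
            if auto and it > 0:
                df = self.effective_df(Theta, A, lam)
                lam = update_lambda(Theta, self.basis_.D, df,
                                    self.diff_order, lam)
            pl0 = self._pl(Theta, A, lam)
            crit_start.append(pl0)
            Theta, A, pl0 = self._theta_sweep(Theta, A, lam, pl0)
            Theta, A, pl = self._a_sweep(Theta, A, lam, pl0)
            lam_trace.append(lam)
            crit_trace.append(pl)
            lam_settled = abs(lam - prev_lam) <= 1e-4 * (abs(lam) + 1.0)
            if (
                prev is not None
                and abs(prev - pl) <= self.tol * (abs(prev) + 1.0)
                and (not auto or lam_settled)
            ):
                converged = True
                prev = pl
                break
            prev = pl
            prev_lam = lam
        _, c, _ = self._grid_state(Theta, A)
        ll = self._loglik(Theta, A, c)
        df = self.effective_df(Theta, A, lam)
        return {
            "Theta": Theta, "A": A, "c": c, "lambda": lam,
            "lambda_trace": lam_trace, "criterion_trace": crit_trace,
            "criterion_start_trace": crit_start,
            "loglik": ll, "df": df, "aic": -2.0 * ll + 2.0 * df,
            "converged": converged, "n_iter": len(crit_trace),
        }

    def _adopt(self, res: dict) -> None:
        # canonical (scale-in-Theta) pair for internal reuse; reported
        # attributes follow the SVD convention: orthonormal components,
        # scores carrying the energy
        self._Theta_c = res["Theta"]
        self._A_c = res["A"]
        self.Theta_, self.A_ = orthonormalize(res["Theta"], res["A"])
        self.c_ = res["c"]
        self.lambda_ = res["lambda"]
        self.lambda_trace_ = res["lambda_trace"]
        self.criterion_trace_ = res["criterion_trace"]
        self.criterion_start_trace_ = res["criterion_start_trace"]
        self.loglik_ = res["loglik"]
        self.df_ = res["df"]
        self.aic_ = res["aic"]
        self.converged_ = res["converged"]
        self.n_iter_ = res["n_iter"]
        self.energies_, self.energy_share_ = component_energy(self.A_)
        if not self.converged_:
            warnings.warn(
                f"collective fit did not converge in {self.max_iter} iterations",
                RuntimeWarning,
            )

    # ------------------------------------------------------------------ #
    # inspection                                                         #
    # ------------------------------------------------------------------ #

    def log_density_values(self, index: int) -> np.ndarray:
        if not 0 <= index < self.A_.shape[0]:
            raise IndexError(f"group index {index} out of range")
        om = self.basis_.B @ (self.Theta_ @ self.A_[index])
        return om + self.c_[index]

    def density(self, index: int) -> DensityGrid:
        """Fitted density of one group on the evaluation grid."""
        b = self.basis_
        vals = np.exp(self.log_density_values(index))
        return DensityGrid(
            vals.reshape(b.grid1.size, b.grid2.size), b.grid1, b.grid2,
            b.cell_area,
        )

    def densities(self) -> list[DensityGrid]:
        return [self.density(i) for i in range(self.A_.shape[0])]

    def score(self, X, groups=None) -> float:
        """Mean fitted log-density of stacked points under their groups."""
        data = AngularDataset.from_arrays(
            X, np.zeros(len(X), int) if groups is None else groups
        )
        total, n = 0.0, 0
        for i, g in enumerate(data.groups):
            om = self.basis_.evaluate(g) @ (self.Theta_ @ self.A_[i])
            total += float(np.sum(om + self.c_[i]))
            n += g.shape[0]
        return total / n


def fit_pscde_t(data: AngularDataset, config: dict) -> CollectiveDensityEstimator:
    """Configuration-dict front end used by the command-line tool."""
    est = CollectiveDensityEstimator(
        n_components=int(config.get("K", 3)),
        dir1=DirectionSpec.from_config(config.get("direction1", {})),
        dir2=DirectionSpec.from_config(config.get("direction2", {})),
        diff_order=int(config.get("diff_order", 2)),
        cyclic_penalty=bool(config.get("cyclic_penalty", True)),
        grid_points=int(config.get("grid_points", 90)),
        lambda_init=float(config.get("lambda_init", 1.0)),
        lambda_mode=str(config.get("lambda_mode", "auto")),
        aic_grid=config.get("aic_grid"),
        tol=float(config.get("tol", 1e-6)),
        max_iter=int(config.get("max_iter", 500)),
    )
    return est.fit_dataset(data)
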