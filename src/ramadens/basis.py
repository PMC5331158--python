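"""Spline bases and roughness penalties on (partially) periodic angular domains.

The density model represents each log-density in a rich tensor-product spline
space.  Periodic directions (backbone dihedrals phi, psi, or the pseudo-torsion
tau) use trigonometric B-splines, which are built from sin/cos half-angle
weights and are intrinsically continuous on the circle, so no wrap-around
constraints are needed.  Bounded directions (the pseudo-bond angle theta) use
ordinary polynomial B-splines.  Smoothness is controlled by a difference
penalty on adjacent spline coefficients, extended to the bivariate domain by
Kronecker products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

TWO_PI = 2.0 * math.pi

__all__ = [
    "KnotVector",
    "DirectionSpec",
    "TensorBasis",
    "trig_bspline_basis",
    "poly_bspline_basis",
    "tensor_product",
    "difference_matrix",
    "penalty_matrix",
    "make_knots",
]


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing simple knots with a spline order.

    Parameters
    ----------
    values : ndarray
        Knot positions in radians, strictly increasing.  For a periodic
        direction all knots lie in one period of length ``2*pi``; the knot
        sequence is extended cyclically during evaluation.
    periodic : bool
        Whether basis functions wrap around the circle.
    order : int
        Spline order ``nu`` (number of knot intervals supporting each basis
        function); ``nu = 1`` gives indicator functions, ``nu = 4`` cubics.
    """

    values: np.ndarray
    periodic: bool = False
    order: int = 4

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.order < 1:
            raise ValueError(f"spline order must be >= 1, got {self.order}")
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("need at least two knots")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.periodic:
            if vals[-1] - vals[0] >= TWO_PI:
                raise ValueError("periodic knots must lie within one period")
            # every nu-interval span of the cyclically extended sequence must
            # stay below 2*pi, otherwise a sine denominator degenerates
            ext = np.concatenate([vals, vals[: self.order] + TWO_PI])
            spans = ext[self.order:] - ext[: ext.size - self.order]
            if np.any(spans >= TWO_PI):
                raise ValueError(
                    "knot spacing too coarse: a basis support spans >= 2*pi"
                )

    @property
    def n_basis(self) -> int:
        if self.periodic:
            return self.values.size
        return self.values.size - self.order

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])


def make_knots(
    df: int, order: int, lo: float, hi: float, periodic: bool
) -> KnotVector:
    """Equally spaced knots yielding ``df`` basis functions on ``[lo, hi]``.

    Periodic directions place ``df`` knots over one period (the last interval
    closes the circle); bounded directions place ``df - order + 2`` breakpoints
    so that the clamped polynomial basis has exactly ``df`` functions.
    """
    if periodic:
        if not math.isclose(hi - lo, TWO_PI, rel_tol=1e-9):
            raise ValueError("periodic direction must span a full period 2*pi")
        if df <= order:
            raise ValueError("periodic basis needs df > order")
        vals = lo + np.arange(df) * (TWO_PI / df)
        return KnotVector(vals, periodic=True, order=order)
    n_breaks = df - order + 2
    if n_breaks < 2:
        raise ValueError(f"df={df} too small for order {order}")
    return KnotVector(np.linspace(lo, hi, n_breaks), periodic=False, order=order)


def _trig_recursion(t: np.ndarray, x: np.ndarray, nu: int) -> np.ndarray:
    """Evaluate non-periodic trigonometric B-splines on knot sequence ``t``.

    Order-1 splines are interval indicators on ``[t_i, t_{i+1})``; higher
    orders combine two lower-order splines with sin half-angle weights.
    Returns an ``len(x) x (len(t) - nu)`` matrix.
    """
    B = np.empty((x.size, t.size - 1))
    for i in range(t.size - 1):
        B[:, i] = (t[i] <= x) & (x < t[i + 1])
    for k in range(2, nu + 1):
        nb = t.size - k
        Bk = np.zeros((x.size, nb))
        for i in range(nb):
            d1 = math.sin((t[i + k - 1] - t[i]) / 2.0)
            d2 = math.sin((t[i + k] - t[i + 1]) / 2.0)
            if d1 > 1e-14:
                Bk[:, i] += np.sin((x - t[i]) / 2.0) / d1 * B[:, i]
            if d2 > 1e-14:
                Bk[:, i] += np.sin((t[i + k] - x) / 2.0) / d2 * B[:, i + 1]
        B = Bk
    return B


def trig_bspline_basis(knots: KnotVector, points) -> np.ndarray:
    """Evaluate the trigonometric B-spline basis at ``points`` (radians).

    For periodic knots the index arithmetic wraps modulo the knot count, so
    every basis function is continuous across the +/-pi seam; points are first
    reduced modulo the period.  Rows index points, columns basis functions.
    """
    x = np.atleast_1d(np.asarray(points, dtype=float))
    nu = knots.order
    if knots.periodic:
        lo = knots.lo
        xr = lo + np.mod(x - lo, TWO_PI)
        t = np.concatenate([knots.values, knots.values[: nu] + TWO_PI])
        # each wrapped basis function is the sum of the two period-shifted
        # copies of its open-line counterpart; supports span < 2*pi so at most
        # one copy is nonzero per point
        return _trig_recursion(t, xr, nu) + _trig_recursion(t, xr + TWO_PI, nu)
    if np.any(x < knots.lo) or np.any(x > knots.hi):
        raise ValueError("points outside the knot range")
    return _trig_recursion(knots.values, x, nu)


def poly_bspline_basis(knots: KnotVector, points) -> np.ndarray:
    """Evaluate the clamped polynomial B-spline basis (Cox-de Boor).

    The breakpoints in ``knots.values`` are augmented with ``order``-fold
    boundary knots, so rows form a partition of unity over the full range.
    """
    if knots.periodic:
        raise ValueError("polynomial basis is for non-periodic directions")
    x = np.atleast_1d(np.asarray(points, dtype=float))
    if np.any(x < knots.lo) or np.any(x > knots.hi):
        raise ValueError("points outside the knot range")
    k = knots.order - 1
    t = np.concatenate(
        [np.full(k, knots.lo), knots.values, np.full(k, knots.hi)]
    )
    out = BSpline.design_matrix(x, t, k, extrapolate=False).toarray()
    return out


def tensor_product(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Row-wise tensor (Kronecker) product basis over the 2-D grid.

    ``B1`` (n1 x M) and ``B2`` (n2 x N) evaluated on the two univariate grids
    combine into an ``(n1*n2) x (M*N)`` matrix.  Rows and columns both run
    direction-1 outer, direction-2 inner: row ``i*n2 + j`` is the elementwise
    outer product of row ``i`` of ``B1`` with row ``j`` of ``B2``.
    """
    B1 = np.asarray(B1, float)
    B2 = np.asarray(B2, float)
    if B1.size == 0 or B2.size == 0:
        raise ValueError("empty basis matrix")
    return np.kron(B1, B2)


def row_tensor(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Khatri-Rao (row-by-row) product for scattered 2-D points."""
    if B1.shape[0] != B2.shape[0]:
        raise ValueError("row mismatch")
    return np.einsum("nm,nk->nmk", B1, B2).reshape(B1.shape[0], -1)


def difference_matrix(a: int, M: int, cyclic: bool = False) -> np.ndarray:
    """Order-``a`` difference operator ``L_a`` on ``M`` coefficients.

    Non-cyclic: ``(M - a) x M`` with rows carrying the alternating binomial
    stencil (``(1, -1)`` for a=1, ``(1, -2, 1)`` for a=2).  Cyclic: ``M x M``
    with the stencil wrapping modulo ``M`` so roughness is measured across the
    periodic seam as well.
    """
    if a < 1:
        raise ValueError("difference order must be >= 1")
    if M <= a:
        raise ValueError(f"need M > a, got M={M}, a={a}")
    stencil = np.array(
        [(-1) ** j * math.comb(a, j) for j in range(a + 1)], dtype=float
    )
    if cyclic:
        L = np.zeros((M, M))
        for i in range(M):
            for j, s in enumerate(stencil):
                L[i, (i + j) % M] = s
    else:
        L = np.zeros((M - a, M))
        for i in range(M - a):
            L[i, i : i + a + 1] = stencil
    return L


def penalty_matrix(
    a: int, M: int, N: int, cyclic_1: bool = False, cyclic_2: bool = False
) -> np.ndarray:
    """Bivariate difference penalty ``D`` on the tensor-product coefficients.

    With coefficients vectorised direction-1 outer (matching
    :func:`tensor_product`), penalising order-``a`` differences along each
    direction gives ``D = D1 (x) I_N + I_M (x) D2`` with ``Di = L_a^T L_a``.
    ``D`` is symmetric positive semi-definite and annihilates constants.
    """
    L1 = difference_matrix(a, M, cyclic_1)
    L2 = difference_matrix(a, N, cyclic_2)
    D1 = L1.T @ L1
    D2 = L2.T @ L2
    return np.kron(D1, np.eye(N)) + np.kron(np.eye(M), D2)


@dataclass(frozen=True)
class DirectionSpec:
    """Configuration of one angular direction of the domain.

    ``range`` is in radians; periodic directions must span exactly ``2*pi``.
    Defaults follow the Ramachandran setting: a cubic basis with 15 functions
    on a periodic direction, 5 on a bounded one.
    """

    periodic: bool = True
    df: int = 15
    order: int = 4
    range: tuple[float, float] = (-math.pi, math.pi)

    @classmethod
    def from_config(cls, cfg: dict) -> "DirectionSpec":
        kw = {}
        if "periodic" in cfg:
            kw["periodic"] = bool(cfg["periodic"])
        if "df" in cfg:
            kw["df"] = int(cfg["df"])
        if "order" in cfg:
            kw["order"] = int(cfg["order"])
        if "range_deg" in cfg:
            lo, hi = cfg["range_deg"]
            kw["range"] = (math.radians(lo), math.radians(hi))
        return cls(**kw)

    @property
    def span(self) -> float:
        return self.range[1] - self.range[0]


class TensorBasis:
    """Tensor-product spline basis with its penalty on a regular grid.

    Attributes
    ----------
    B : ndarray, (n_grid, L)
        Basis evaluated at the midpoint grid (direction-1 outer).
    D : ndarray, (L, L)
        Difference penalty matrix.
    grid1, grid2 : ndarray
        Cell-midpoint coordinates per direction.
    cell_area : float
        Quadrature weight of one grid cell.
    """

    def __init__(
        self,
        dir1: DirectionSpec,
        dir2: DirectionSpec,
        diff_order: int = 2,
        cyclic_penalty: bool = True,
        grid_points: int = 90,
    ):
        self.dir1 = dir1
        self.dir2 = dir2
        self.diff_order = diff_order
        self.cyclic_penalty = cyclic_penalty
        self.grid_points = grid_points
        self._knots1 = make_knots(
            dir1.df, dir1.order, dir1.range[0], dir1.range[1], dir1.periodic
        )
        self._knots2 = make_knots(
            dir2.df, dir2.order, dir2.range[0], dir2.range[1], dir2.periodic
        )
        # periodic: df wrapped trig functions; bounded: df clamped poly ones
        self.M = dir1.df
        self.N = dir2.df
        self.L = self.M * self.N
        h1 = dir1.span / grid_points
        h2 = dir2.span / grid_points
        self.grid1 = dir1.range[0] + (np.arange(grid_points) + 0.5) * h1
        self.grid2 = dir2.range[0] + (np.arange(grid_points) + 0.5) * h2
        self.cell_area = h1 * h2
        self.area = dir1.span * dir2.span
        B1 = self._eval_dir(1, self.grid1)
        B2 = self._eval_dir(2, self.grid2)
        self.B = tensor_product(B1, B2)
        self.D = penalty_matrix(
            diff_order,
            self.M,
            self.N,
            cyclic_1=cyclic_penalty and dir1.periodic,
            cyclic_2=cyclic_penalty and dir2.periodic,
        )

    def _eval_dir(self, which: int, pts) -> np.ndarray:
        knots = self._knots1 if which == 1 else self._knots2
        if knots.periodic:
            return trig_bspline_basis(knots, pts)
        return poly_bspline_basis(knots, pts)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Basis matrix at scattered 2-D points (radians), shape (n, L)."""
        points = np.asarray(points, float)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        B1 = self._eval_dir(1, points[:, 0])
        B2 = self._eval_dir(2, points[:, 1])
        return row_tensor(B1, B2)

    def in_domain(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the configured domain."""
        points = np.asarray(points, float)
        ok = np.ones(points.shape[0], dtype=bool)
        for j, d in enumerate((self.dir1, self.dir2)):
            if not d.periodic:
                ok &= (points[:, j] >= d.range[0]) & (points[:, j] <= d.range[1])
        return ok

    @classmethod
    def from_config(cls, cfg: dict) -> "TensorBasis":
        """Build from a JSON-style dict with keys ``direction1``,
        ``direction2``, ``diff_order``, ``cyclic_penalty``, ``grid_points``."""
        return cls(
            DirectionSpec.from_config(cfg.get("direction1", {})),
            DirectionSpec.from_config(cfg.get("direction2", {})),
            diff_order=int(cfg.get("diff_order", 2)),
            cyclic_penalty=bool(cfg.get("cyclic_penalty", True)),
            grid_points=int(cfg.get("grid_points", 90)),
        )


def phi_psi_basis(df: int = 15, order: int = 4, grid_points: int = 90,
                  diff_order: int = 2, cyclic_penalty: bool = True) -> TensorBasis:
    """Torus domain for backbone dihedrals (phi, psi), both periodic."""
    d = DirectionSpec(periodic=True, df=df, order=order)
    return TensorBasis(d, d, diff_order=diff_order,
                       cyclic_penalty=cyclic_penalty, grid_points=grid_points)


def theta_tau_basis(theta_df: int = 5, tau_df: int = 15, order: int = 4,
                    theta_range_deg: tuple[float, float] = (75.0, 165.0),
                    grid_points: int = 90, diff_order: int = 2,
                    cyclic_penalty: bool = True) -> TensorBasis:
    """Mixed domain for C-alpha pseudo-angles: bounded theta, periodic tau."""
    d1 = DirectionSpec(
        periodic=False, df=theta_df, order=order,
        range=(math.radians(theta_range_deg[0]), math.radians(theta_range_deg[1])),
    )
    d2 = DirectionSpec(periodic=True, df=tau_df, order=order)
    return TensorBasis(d1, d2, diff_order=diff_order,
                       cyclic_penalty=cyclic_penalty, grid_points=grid_points)
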