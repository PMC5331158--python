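"""Distances between fitted densities used for structure clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import DensityGrid

__all__ = ["DistanceMatrix", "skld", "pairwise_distances", "score_distances"]

_EPS = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative m x m distances with group labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        V = np.asarray(self.values, float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(V) != 0) or np.any(V < 0):
            raise ValueError("need zero diagonal and nonnegative entries")
        self.values = V
        if len(self.labels) != V.shape[0]:
            raise ValueError("one label per row required")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(c) for c in df.columns])


def skld(p: DensityGrid, q: DensityGrid) -> float:
    """Symmetrized Kullback-Leibler divergence ``(KL(p||q) + KL(q||p)) / 2``.

    Both densities must share the evaluation grid; values are floored at
    1e-12 before taking logarithms and the integrals use the midpoint rule.
    """
    if not p.same_grid(q):
        raise ValueError("densities live on different grids")
    pv = np.maximum(p.values, _EPS)
    qv = np.maximum(q.values, _EPS)
    log_ratio = np.log(pv) - np.log(qv)
    kl_pq = float(np.sum(pv * log_ratio) * p.cell_area)
    kl_qp = float(np.sum(qv * -log_ratio) * p.cell_area)
    return 0.5 * (kl_pq + kl_qp)


def pairwise_distances(densities: list[DensityGrid], labels=None) -> DistanceMatrix:
    """Fill the symmetric SKLD matrix over a list of densities."""
    m = len(densities)
    if m < 2:
        raise ValueError("need at least two densities")
    for d in densities[1:]:
        if not densities[0].same_grid(d):
            raise ValueError("densities live on different grids")
    if labels is None:
        labels = [str(i) for i in range(m)]
    V = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            V[i, j] = V[j, i] = skld(densities[i], densities[j])
    return DistanceMatrix(V, list(labels))


def score_distances(A: np.ndarray, labels=None) -> DistanceMatrix:
    """Euclidean distances between per-group score vectors (rows of ``A``).

    The low-dimensional scores of the collective fit can be clustered
    directly; this is the coefficient-space alternative to SKLD.
    """
    A = np.asarray(A, float)
    diff = A[:, None, :] - A[None, :, :]
    V = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(V, 0.0)
    if labels is None:
        labels = [str(i) for i in range(A.shape[0])]
    return DistanceMatrix(V, list(labels))
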