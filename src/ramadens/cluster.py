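"""Ward agglomeration of density distances and external cluster agreement.

The hierarchical clustering follows the classic Ward linkage applied directly
to the supplied dissimilarities (the ``ward.D`` dialect of R's ``hclust``: no
squaring of the input), with merge ties broken by lowest cluster index.
Agreement with a gold-standard labeling is scored by normalized mutual
information (normalized by the larger entropy) and the adjusted Rand index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import DistanceMatrix

__all__ = [
    "ContingencyTable",
    "WardResult",
    "ward_linkage",
    "ward_cluster",
    "contingency",
    "nmi",
    "ari",
    "to_newick",
]


@dataclass
class WardResult:
    """Merge agenda of the agglomeration.

    ``merges[t] = (i, j)`` are the member sets' representative indices merged
    at step ``t`` (negative-free, in internal node numbering like scipy:
    leaves are ``0..m-1``, the step-``t`` merge creates node ``m + t``).
    ``heights[t]`` is the linkage distance of that merge.
    """

    merges: list[tuple[int, int]]
    heights: list[float]
    n_leaves: int
    labels: list[str]

    def cut(self, k: int) -> np.ndarray:
        """Labels (0-based, renumbered by first appearance) for k clusters."""
        m = self.n_leaves
        if not 1 <= k <= m:
            raise ValueError(f"k={k} out of range 1..{m}")
        parent = list(range(m + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t in range(m - k):
            i, j = self.merges[t]
            node = m + t
            parent[find(i)] = node
            parent[find(j)] = node
        roots = {}
        out = np.empty(m, dtype=int)
        for leaf in range(m):
            r = find(leaf)
            out[leaf] = roots.setdefault(r, len(roots))
        return out


def ward_linkage(D: DistanceMatrix) -> WardResult:
    """Agglomerative Ward (ward.D) clustering of a dissimilarity matrix.

    Uses the Lance-Williams recurrence on the unsquared dissimilarities:
    ``d(i+j, k) = ((n_i + n_k) d_ik + (n_j + n_k) d_jk - n_k d_ij) / n_ijk``.
    """
    m = D.m
    d = D.values.astype(float).copy()
    size = {i: 1 for i in range(m)}
    node = {i: i for i in range(m)}  # active row -> tree node id
    active = list(range(m))
    merges, heights = [], []
    for t in range(m - 1):
        best, bi, bj = math.inf, -1, -1
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if d[i, j] < best:  # strict < keeps the lowest-index tie
                    best, bi, bj = d[i, j], i, j
        ni, nj = size[bi], size[bj]
        for k in active:
            if k in (bi, bj):
                continue
            nk = size[k]
            d[bi, k] = d[k, bi] = (
                (ni + nk) * d[bi, k] + (nj + nk) * d[bj, k] - nk * d[bi, bj]
            ) / (ni + nj + nk)
        merges.append((node[bi], node[bj]))
        heights.append(best)
        size[bi] = ni + nj
        node[bi] = m + t
        active.remove(bj)
    return WardResult(merges, heights, m, list(D.labels))


def ward_cluster(D: DistanceMatrix, k: int) -> np.ndarray:
    """Cluster labels from cutting the Ward dendrogram into ``k`` groups."""
    return ward_linkage(D).cut(k)


def to_newick(tree: WardResult) -> str:
    """Newick export of the dendrogram with merge heights as node heights
    (branch length = parent height - child height; leaves at height zero)."""
    m = tree.n_leaves
    height = {i: 0.0 for i in range(m)}
    rep = {i: tree.labels[i] for i in range(m)}
    for t, (i, j) in enumerate(tree.merges):
        h = tree.heights[t]
        left = f"{rep[i]}:{max(h - height[i], 0.0):.10g}"
        right = f"{rep[j]}:{max(h - height[j], 0.0):.10g}"
        node = m + t
        rep[node] = f"({left},{right})"
        height[node] = h
    return rep[m + len(tree.merges) - 1] + ";" if tree.merges else rep[0] + ";"


@dataclass
class ContingencyTable:
    """Cross-tabulation ``n_ij`` of two labelings with its margins."""

    counts: np.ndarray
    row_values: np.ndarray
    col_values: np.ndarray

    @property
    def a(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def b(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def contingency(labels_a, labels_b) -> ContingencyTable:
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if la.shape != lb.shape or la.ndim != 1 or la.size < 1:
        raise ValueError("labelings must be equal-length non-empty vectors")
    ra, ia = np.unique(la, return_inverse=True)
    rb, ib = np.unique(lb, return_inverse=True)
    counts = np.zeros((ra.size, rb.size), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    return ContingencyTable(counts, ra, rb)


def _entropy(margin: np.ndarray, n: int) -> float:
    p = margin[margin > 0] / n
    return float(-np.sum(p * np.log(p)))


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by ``max(H(A), H(B))`` (natural log).

    Two identical single-cluster labelings give 1 (the 0/0 convention).
    """
    tab = contingency(labels_a, labels_b)
    n = tab.n
    ha = _entropy(tab.a, n)
    hb = _entropy(tab.b, n)
    if max(ha, hb) == 0.0:
        return 1.0
    nz = tab.counts > 0
    nij = tab.counts[nz] / n
    outer = np.outer(tab.a, tab.b)[nz] / (n * n)
    mi = float(np.sum(nij * np.log(nij / outer)))
    return mi / max(ha, hb)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from binomial pair counts of the contingency
    table; 1 for identical partitions, 0 in expectation under chance."""
    tab = contingency(labels_a, labels_b)
    if tab.n < 2:
        raise ValueError("need at least two items")

    def c2(x):
        x = np.asarray(x, dtype=float)
        return np.sum(x * (x - 1) / 2.0)

    sum_ij = c2(tab.counts.ravel())
    sum_a = c2(tab.a)
    sum_b = c2(tab.b)
    total = tab.n * (tab.n - 1) / 2.0
    expected = sum_a * sum_b / total
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        return 1.0
    return float((sum_ij - expected) / denom)
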