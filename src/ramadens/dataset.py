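"""Grouped angular observations and their TSV interchange format.

One group is one population of angle pairs (one protein's Ramachandran or
pseudo-Ramachandran point cloud).  Angles are stored in radians internally;
the file interface is in degrees with columns ``group_id``, ``angle1_deg``,
``angle2_deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AngularDataset", "read_angles_tsv", "write_angles_tsv"]


@dataclass
class AngularDataset:
    """m groups of bivariate angle observations (radians)."""

    groups: list[np.ndarray]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("need at least one group")
        if len(self.labels) != len(self.groups):
            raise ValueError("one label per group required")
        cleaned = []
        for g in self.groups:
            g = np.asarray(g, dtype=float)
            if g.ndim != 2 or g.shape[1] != 2:
                raise ValueError("each group must be an (n_i, 2) array")
            if g.shape[0] < 1:
                raise ValueError("empty group")
            if not np.all(np.isfinite(g)):
                raise ValueError("non-finite angle value")
            cleaned.append(g)
        self.groups = cleaned

    @property
    def m(self) -> int:
        return len(self.groups)

    @property
    def n_i(self) -> np.ndarray:
        return np.array([g.shape[0] for g in self.groups])

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All points stacked with an integer group index per row."""
        X = np.vstack(self.groups)
        idx = np.repeat(np.arange(self.m), self.n_i)
        return X, idx

    @classmethod
    def from_arrays(cls, X: np.ndarray, group_idx) -> "AngularDataset":
        """Build from stacked points plus per-row group identifiers."""
        X = np.asarray(X, float)
        group_idx = np.asarray(group_idx)
        labels = [str(g) for g in pd.unique(group_idx)]
        groups = [X[group_idx == g] for g in pd.unique(group_idx)]
        return cls(groups, labels)


def read_angles_tsv(path) -> AngularDataset:
    """Read the degree-valued angle table (group_id, angle1_deg, angle2_deg)."""
    df = pd.read_csv(path, sep="\t")
    required = {"group_id", "angle1_deg", "angle2_deg"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"angle TSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    X = np.deg2rad(df[["angle1_deg", "angle2_deg"]].to_numpy(float))
    return AngularDataset.from_arrays(X, df["group_id"].to_numpy())


def write_angles_tsv(path, data: AngularDataset) -> None:
    rows = []
    for label, g in zip(data.labels, data.groups):
        deg = np.rad2deg(g)
        for a1, a2 in deg:
            rows.append((label, a1, a2))
    pd.DataFrame(rows, columns=["group_id", "angle1_deg", "angle2_deg"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def wrap_angles(x: np.ndarray, lo: float = -math.pi) -> np.ndarray:
    """Reduce angles into ``[lo, lo + 2*pi)``."""
    return lo + np.mod(np.asarray(x, float) - lo, 2.0 * math.pi)
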