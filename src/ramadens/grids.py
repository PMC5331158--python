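"""Densities evaluated on the regular midpoint grid, with TSV round-trip."""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = ["DensityGrid", "read_density_tsv", "write_density_tsv"]


@dataclass
class DensityGrid:
    """A bivariate density tabulated at cell midpoints.

    ``values[i, j]`` is the density at ``(grid1[i], grid2[j])``; the integral
    is approximated by the midpoint rule with weight ``cell_area``.
    """

    values: np.ndarray
    grid1: np.ndarray
    grid2: np.ndarray
    cell_area: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.grid1 = np.asarray(self.grid1, float)
        self.grid2 = np.asarray(self.grid2, float)
        if self.values.shape != (self.grid1.size, self.grid2.size):
            raise ValueError("values shape must be (len(grid1), len(grid2))")

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_area)

    def same_grid(self, other: "DensityGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.cell_area - other.cell_area) < tol
            and np.allclose(self.grid1, other.grid1, atol=tol)
            and np.allclose(self.grid2, other.grid2, atol=tol)
        )


def write_density_tsv(path, grid: DensityGrid) -> None:
    """Write a density grid; header comments record the grid convention."""
    with open(path, "w") as fh:
        fh.write("# density grid: rows = direction 1, columns = direction 2\n")
        fh.write("# grid1_rad\t" + "\t".join(f"{v:.10g}" for v in grid.grid1) + "\n")
        fh.write("# grid2_rad\t" + "\t".join(f"{v:.10g}" for v in grid.grid2) + "\n")
        fh.write(f"# cell_area\t{grid.cell_area:.12g}\n")
        np.savetxt(fh, grid.values, delimiter="\t", fmt="%.10g")


def read_density_tsv(path) -> DensityGrid:
    grid1 = grid2 = None
    cell_area = None
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "grid1_rad":
                    grid1 = np.array([float(v) for v in parts[1:]])
                elif parts[0] == "grid2_rad":
                    grid2 = np.array([float(v) for v in parts[1:]])
                elif parts[0] == "cell_area":
                    cell_area = float(parts[1])
            else:
                body.append(line)
    if grid1 is None or grid2 is None or cell_area is None:
        raise ValueError("density TSV missing grid header")
    values = np.loadtxt(io.StringIO("".join(body)), delimiter="\t")
    return DensityGrid(np.atleast_2d(values), grid1, grid2, cell_area)
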