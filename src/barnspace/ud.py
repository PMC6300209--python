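"""Cell-count utilization distributions and discrete isopleth ranges.

A daily UD is built by binning smoothed in-barn fixes onto a rectangular
grid and normalizing the counts to a probability distribution. Core and
full ranges are the highest-mass cell sets accumulating 50% / 95% of the
total mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import GridSpec, Rect
from .prep import Trajectory

_SUM_TOL = 1e-9


class GridMismatchError(ValueError):
    """Two UDs on different grids cannot be compared."""


class BinningError(RuntimeError):
    """A point survived cleaning but falls outside the grid extent."""


@dataclass
class UtilityDistribution:
    """Normalized space-use mass over a rectangular grid.

    ``mass`` has shape (ny, nx), row-major over cells; it sums to 1 unless
    ``total_count`` is 0, in which case the UD is flagged empty.
    """

    grid: GridSpec
    mass: np.ndarray
    total_count: int

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"mass shape {self.mass.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if (self.mass < -_SUM_TOL).any():
            raise ValueError("negative cell mass")
        if self.total_count > 0 and abs(self.mass.sum() - 1.0) > _SUM_TOL:
            raise ValueError("normalized UD must sum to 1")

    @property
    def empty(self) -> bool:
        return self.total_count == 0

    @property
    def flat(self) -> np.ndarray:
        """Row-major flattened mass vector."""
        return self.mass.ravel()

    def copy(self) -> "UtilityDistribution":
        return UtilityDistribution(self.grid, self.mass.copy(), self.total_count)


@dataclass
class IsoplethRange:
    """Highest-mass cell set accumulating at least ``level`` of the UD."""

    level: float
    cells: frozenset[int] = field(default_factory=frozenset)
    flagged_empty: bool = False

    @property
    def size(self) -> int:
        return len(self.cells)


def bin_points(x, y, grid: GridSpec, *, clamp_max_y: float | None = None):
    """Map coordinates to row-major cell indices, clamping top/right edges.

    Points up to ``clamp_max_y`` (the barn edge beyond the last full grid
    row) are folded into the top row. Anything outside raises BinningError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_max = grid.x0 + grid.nx * grid.cell
    y_max = grid.y0 + grid.ny * grid.cell
    y_lim = y_max if clamp_max_y is None else max(y_max, clamp_max_y)
    bad = (x < grid.x0) | (x > x_max) | (y < grid.y0) | (y > y_lim)
    if bad.any():
        i = int(np.argmax(bad))
        raise BinningError(
            f"point ({x[i]:.3f}, {y[i]:.3f}) outside grid extent; "
            "cleaning should have removed it"
        )
    ix = np.clip(np.floor((x - grid.x0) / grid.cell).astype(int), 0, grid.nx - 1)
    iy = np.clip(np.floor((y - grid.y0) / grid.cell).astype(int), 0, grid.ny - 1)
    return iy * grid.nx + ix


def build_ud(
    day_traj: Trajectory, grid: GridSpec, *, clamp_max_y: float | None = 30.0
) -> UtilityDistribution:
    """Bin one day's cleaned fixes onto the grid and normalize.

    An empty trajectory yields an all-zero UD with ``total_count`` 0.
    Binning is permutation-invariant in sample order.
    """
    if len(day_traj) == 0:
        return UtilityDistribution(grid, np.zeros((grid.ny, grid.nx)), 0)
    cells = bin_points(
        day_traj.df["x"].to_numpy(float),
        day_traj.df["y"].to_numpy(float),
        grid,
        clamp_max_y=clamp_max_y,
    )
    counts = np.bincount(cells, minlength=grid.n_cells).astype(float)
    total = int(counts.sum())
    return UtilityDistribution(grid, (counts / total).reshape(grid.ny, grid.nx), total)


def isopleth(
    ud: UtilityDistribution, level: float, *, ties: str = "index"
) -> IsoplethRange:
    """Smallest prefix of mass-sorted cells whose cumulative mass >= level.

    The cell that crosses the threshold is included. Equal-mass ties at the
    boundary break deterministically by row-major cell index (``ties=
    "index"``, the default); ``ties="all"`` includes every cell whose mass
    equals the boundary cell's.
    """
    if not (0 < level <= 1):
        raise ValueError("isopleth level must be in (0, 1]")
    if ties not in ("index", "all"):
        raise ValueError("ties must be 'index' or 'all'")
    if ud.empty:
        return IsoplethRange(level, frozenset(), flagged_empty=True)
    flat = ud.flat
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - _SUM_TOL)) + 1
    chosen = order[:k]
    chosen = chosen[flat[chosen] > 0]
    if ties == "all" and len(chosen):
        boundary = flat[chosen].min()
        chosen = np.flatnonzero(flat >= boundary - _SUM_TOL)
    return IsoplethRange(level, frozenset(int(c) for c in chosen))


def truncate_ud(ud: UtilityDistribution, level: float) -> UtilityDistribution:
    """Zero mass outside the isopleth cell set and renormalize."""
    iso = isopleth(ud, level)
    if iso.flagged_empty:
        return ud.copy()
    keep = np.zeros(ud.grid.n_cells, dtype=bool)
    keep[list(iso.cells)] = True
    m = np.where(keep, ud.flat, 0.0)
    m /= m.sum()
    return UtilityDistribution(ud.grid, m.reshape(ud.mass.shape), ud.total_count)


def restrict_ud(ud: UtilityDistribution, region: Rect) -> UtilityDistribution:
    """Keep cells whose centre lies in ``region`` and renormalize.

    If no mass remains the result is flagged empty (total_count 0).
    """
    centers = ud.grid.cell_centers()
    inside = (
        (centers[:, 0] >= region.xmin)
        & (centers[:, 0] < region.xmax)
        & (centers[:, 1] >= region.ymin)
        & (centers[:, 1] < region.ymax)
    )
    m = np.where(inside, ud.flat, 0.0)
    s = m.sum()
    if ud.empty or s <= 0:
        return UtilityDistribution(ud.grid, np.zeros_like(ud.mass), 0)
    return UtilityDistribution(ud.grid, (m / s).reshape(ud.mass.shape), ud.total_count)


def export_ud(ud: UtilityDistribution, matrix_path, sidecar_path=None) -> None:
    """Write the dense mass matrix as delimited text plus a JSON sidecar."""
    np.savetxt(matrix_path, ud.mass, delimiter=",", fmt="%.10g")
    if sidecar_path is not None:
        g = ud.grid
        meta = {
            "grid": {"x0": g.x0, "y0": g.y0, "cell": g.cell, "nx": g.nx, "ny": g.ny},
            "total_count": ud.total_count,
            "isopleth_convention": "crossing cell included; ties by row-major index",
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def plot_ud(ud: UtilityDistribution, levels=(0.95, 0.50), ax=None):
    """Intensity plot with isopleth contour overlays; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    g = ud.grid
    extent = (g.x0, g.x0 + g.nx * g.cell, g.y0, g.y0 + g.ny * g.cell)
    ax.imshow(ud.mass, origin="lower", extent=extent, cmap="Greys", aspect="equal")
    styles = {0.95: "--", 0.50: "-"}
    for level in levels:
        iso = isopleth(ud, level)
        member = np.zeros(g.n_cells)
        if iso.cells:
            member[list(iso.cells)] = 1.0
        ax.contour(
            member.reshape(g.ny, g.nx),
            levels=[0.5],
            extent=extent,
            colors="k",
            linestyles=styles.get(level, ":"),
            linewidths=1.0,
        )
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax
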