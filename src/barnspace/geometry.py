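"""Barn geometry: rectangles, named zones, grid specification, milking schedule.

Coordinates are metres in a barn-local frame. The analysed ("upper") barn
area is the rectangle x in [0, 60], y in [10, 30]. Zone membership uses
half-open intervals [min, max) on each axis, with the global barn maximum
edge treated as closed, so every in-barn point belongs to exactly one zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a geometry/zone/grid configuration is inconsistent."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [xmin, xmax] x [ymin, ymax]."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ConfigurationError(f"degenerate rectangle: {self}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def contains(self, x: float, y: float, *, closed: bool = False) -> bool:
        """Half-open membership test; ``closed=True`` also accepts max edges."""
        if closed:
            return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax
        return self.xmin <= x < self.xmax and self.ymin <= y < self.ymax


@dataclass(frozen=True)
class MilkingWindow:
    """Daily recurring absence window, e.g. start 05:00 for 90 minutes."""

    start_hour: int
    start_minute: int = 0
    duration_min: float = 90.0

    @property
    def start_s(self) -> float:
        """Window start as seconds after local midnight."""
        return 3600.0 * self.start_hour + 60.0 * self.start_minute

    @property
    def end_s(self) -> float:
        return self.start_s + 60.0 * self.duration_min

    def contains_second_of_day(self, s: float) -> bool:
        return self.start_s <= s < self.end_s


#: canonical zone names in reporting order
ZONE_NAMES = ("F", "P", "C1", "C2", "C3")


@dataclass(frozen=True)
class BarnGeometry:
    """Upper-barn rectangle, named zones, and the milking schedule.

    Defaults reproduce the study barn layout: a feeding strip F and a
    passage P along the lower half, three cubicle blocks C1..C3 along the
    upper half; C_T is the union of the cubicle blocks.
    """

    barn: Rect = Rect(0.0, 60.0, 10.0, 30.0)
    zones: dict[str, Rect] = field(
        default_factory=lambda: {
            "F": Rect(0.0, 53.0, 10.0, 20.0),
            "P": Rect(53.0, 60.0, 10.0, 20.0),
            "C1": Rect(40.0, 60.0, 20.0, 30.0),
            "C2": Rect(20.0, 40.0, 20.0, 30.0),
            "C3": Rect(0.0, 20.0, 20.0, 30.0),
        }
    )
    milking: tuple[MilkingWindow, ...] = (
        MilkingWindow(5),
        MilkingWindow(13),
        MilkingWindow(21),
    )

    def __post_init__(self) -> None:
        for name in ZONE_NAMES:
            if name not in self.zones:
                raise ConfigurationError(f"zone {name!r} missing from geometry")
        for name, z in self.zones.items():
            if not (
                z.xmin >= self.barn.xmin
                and z.xmax <= self.barn.xmax
                and z.ymin >= self.barn.ymin
                and z.ymax <= self.barn.ymax
            ):
                raise ConfigurationError(f"zone {name!r} extends outside the barn")

    @property
    def cubicle_union(self) -> Rect:
        c1, c3 = self.zones["C1"], self.zones["C3"]
        return Rect(
            min(c1.xmin, c3.xmin),
            max(c1.xmax, c3.xmax),
            min(c1.ymin, c3.ymin),
            max(c1.ymax, c3.ymax),
        )

    def region(self, name: str) -> Rect:
        """Resolve a region name: a zone name, 'C_T', or 'barn'."""
        if name == "barn":
            return self.barn
        if name == "C_T":
            return self.cubicle_union
        try:
            return self.zones[name]
        except KeyError:
            raise ConfigurationError(f"unknown region {name!r}") from None

    def in_barn(self, x: float, y: float) -> bool:
        return self.barn.contains(x, y, closed=True)

    def zone_of(self, x: float, y: float) -> str | None:
        """Map an in-barn point to its unique zone (None if out of barn).

        Zones are half-open; a point on the global barn max edge is folded
        into the adjoining zone so the tiling is exhaustive.
        """
        if not self.in_barn(x, y):
            return None
        # fold closed max edges inward by an epsilon-free comparison
        xq = x if x < self.barn.xmax else self.barn.xmax - 1e-9
        yq = y if y < self.barn.ymax else self.barn.ymax - 1e-9
        for name, z in self.zones.items():
            if z.contains(xq, yq):
                return name
        return None  # pragma: no cover - tiling is exhaustive by construction

    def in_milking_window(self, second_of_day: float) -> bool:
        return any(w.contains_second_of_day(second_of_day) for w in self.milking)


@dataclass(frozen=True)
class GridSpec:
    """Virtual square grid overlaid on the upper barn.

    The default 40 x 13 grid of 1.5 m cells spans x in [0, 60] exactly;
    13 rows cover y in [10, 29.5] and the residual 0.5 m strip up to the
    barn edge is merged into the top row so no in-barn point is unbinned.
    """

    x0: float = 0.0
    y0: float = 10.0
    cell: float = 1.5
    nx: int = 40
    ny: int = 13

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ConfigurationError("cell size must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ConfigurationError("grid must have at least one cell per axis")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_centers(self):
        """(n_cells, 2) array of cell-centre coordinates in row-major order."""
        import numpy as np

        ix = np.arange(self.nx)
        iy = np.arange(self.ny)
        cx = self.x0 + (ix + 0.5) * self.cell
        cy = self.y0 + (iy + 0.5) * self.cell
        gx, gy = np.meshgrid(cx, cy)  # shape (ny, nx)
        return np.column_stack([gx.ravel(), gy.ravel()])
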