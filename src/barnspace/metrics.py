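"""Per-cow space-use measures S1-S10.

Daily values are computed from the prepared trajectory and its daily UD,
then averaged across days (missing days are skipped and counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .geometry import BarnGeometry, GridSpec
from .prep import DayPart, Trajectory
from .ud import UtilityDistribution, build_ud, isopleth

#: measure names in canonical order (S11-S16 filled by the fidelity module)
MEASURES = tuple(f"S{i}" for i in range(1, 17))


@dataclass
class SpaceUseSummary:
    """The sixteen per-cow space-use and site-fidelity measures."""

    cow_id: str
    S1: float = math.nan  # mean distance moved per hour (m/h)
    S2: float = math.nan  # mean x (m)
    S3: float = math.nan  # mean y (m)
    S4: float = math.nan  # proportion of upper-barn time in F
    S5: float = math.nan  # proportion in C_T
    S6: float = math.nan  # proportion in C1
    S7: float = math.nan  # proportion in C2
    S8: float = math.nan  # proportion in C3
    S9: float = math.nan  # mean daily full-range size (cells, 95%)
    S10: float = math.nan  # mean daily core-range size (cells, 50%)
    S11: float = math.nan  # fidelity: barn, full range
    S12: float = math.nan  # fidelity: F, full range
    S13: float = math.nan  # fidelity: C_T, full range
    S14: float = math.nan  # fidelity: barn, core range
    S15: float = math.nan  # fidelity: F, core range
    S16: float = math.nan  # fidelity: C_T, core range
    days_used: int = 0

    @property
    def usable(self) -> bool:
        return self.days_used > 0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def distance_per_hour(
    day_traj: Trajectory, *, max_gap_s: float = 40.0
) -> float:
    """Total path length divided by observed duration, gap-robust.

    Steps whose time difference exceeds ``max_gap_s`` (default five nominal
    8 s intervals) are treated as recording gaps: neither their length nor
    their duration contributes. NaN if fewer than 2 samples or no usable
    steps.
    """
    df = day_traj.df
    if len(df) < 2:
        return math.nan
    dt = df["timestamp"].diff().dt.total_seconds().to_numpy(float)[1:]
    dx = np.diff(df["x"].to_numpy(float))
    dy = np.diff(df["y"].to_numpy(float))
    ok = dt <= max_gap_s
    hours = dt[ok].sum() / 3600.0
    if hours <= 0:
        return math.nan
    return float(np.hypot(dx[ok], dy[ok]).sum() / hours)


def mean_position(day_traj: Trajectory) -> tuple[float, float]:
    """Arithmetic mean of retained coordinates; NaNs when empty."""
    if len(day_traj) == 0:
        return (math.nan, math.nan)
    return (
        float(day_traj.df["x"].mean()),
        float(day_traj.df["y"].mean()),
    )


def zone_proportions(
    ud: UtilityDistribution, geometry: BarnGeometry
) -> dict[str, float]:
    """UD mass per zone of interest, by cell centre membership.

    Returns masses for F, C_T, C1, C2, C3 (and P); F + P + C_T sum to 1
    for a normalized UD because the zones tile the barn.
    """
    if ud.empty:
        return {z: math.nan for z in ("F", "P", "C_T", "C1", "C2", "C3")}
    centers = ud.grid.cell_centers()
    flat = ud.flat
    out: dict[str, float] = {}
    for name in ("F", "P", "C1", "C2", "C3"):
        z = geometry.zones[name]
        inside = (
            (centers[:, 0] >= z.xmin)
            & (centers[:, 0] < z.xmax)
            & (centers[:, 1] >= z.ymin)
            & (centers[:, 1] < z.ymax)
        )
        out[name] = float(flat[inside].sum())
    out["C_T"] = out["C1"] + out["C2"] + out["C3"]
    return out


def zone_proportions_from_points(
    day_traj: Trajectory, geometry: BarnGeometry
) -> dict[str, float]:
    """Raw-point zone shares (sensitivity-check alternative to the UD mode)."""
    if len(day_traj) == 0:
        return {z: math.nan for z in ("F", "P", "C_T", "C1", "C2", "C3")}
    zones = [
        geometry.zone_of(x, y)
        for x, y in zip(day_traj.df["x"], day_traj.df["y"])
    ]
    n = len(zones)
    out = {name: zones.count(name) / n for name in ("F", "P", "C1", "C2", "C3")}
    out["C_T"] = out["C1"] + out["C2"] + out["C3"]
    return out


def range_sizes(
    daily_uds: list[UtilityDistribution], *, full: float = 0.95, core: float = 0.50
) -> tuple[float, float]:
    """Across-day mean isopleth sizes (S9 full, S10 core); empty days skipped."""
    fulls, cores = [], []
    for ud in daily_uds:
        if ud.empty:
            continue
        fulls.append(isopleth(ud, full).size)
        cores.append(isopleth(ud, core).size)
    if not fulls:
        return (math.nan, math.nan)
    return (float(np.mean(fulls)), float(np.mean(cores)))


def summarize_cow(
    day_parts: list[DayPart],
    daily_uds: list[UtilityDistribution],
    geometry: BarnGeometry,
    grid: GridSpec,
    *,
    max_gap_s: float = 40.0,
    full_level: float = 0.95,
    core_level: float = 0.50,
) -> SpaceUseSummary:
    """Populate S1-S10 for one cow as across-day means of daily values."""
    if len(day_parts) != len(daily_uds):
        raise ValueError("day parts and daily UDs must align")
    cow_id = day_parts[0].trajectory.cow_id if day_parts else "?"
    rows = []
    for part, ud in zip(day_parts, daily_uds):
        if part.empty or ud.empty:
            continue
        mx, my = mean_position(part.trajectory)
        props = zone_proportions(ud, geometry)
        rows.append(
            {
                "S1": distance_per_hour(part.trajectory, max_gap_s=max_gap_s),
                "S2": mx,
                "S3": my,
                "S4": props["F"],
                "S5": props["C_T"],
                "S6": props["C1"],
                "S7": props["C2"],
                "S8": props["C3"],
                "S9": float(isopleth(ud, full_level).size),
                "S10": float(isopleth(ud, core_level).size),
            }
        )
    summary = SpaceUseSummary(cow_id=cow_id, days_used=len(rows))
    if rows:
        daily = pd.DataFrame(rows)
        for col in daily.columns:
            setattr(summary, col, float(daily[col].mean(skipna=True)))
    return summary


def features_table(summaries: list[SpaceUseSummary]) -> pd.DataFrame:
    """Assemble per-cow summaries into the canonical feature table."""
    df = pd.DataFrame([s.as_dict() for s in summaries])
    cols = ["cow_id", *MEASURES, "days_used"]
    return df[cols]


def daily_uds_for_cow(
    day_parts: list[DayPart], grid: GridSpec, *, clamp_max_y: float | None = 30.0
) -> list[UtilityDistribution]:
    """Build one UD per day part (empty parts yield flagged-empty UDs)."""
    return [build_ud(p.trajectory, grid, clamp_max_y=clamp_max_y) for p in day_parts]
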