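"""Trajectory I/O, smoothing, cleaning and daily partitioning.

The preparation order is fixed: smooth -> clean -> split_by_day. Smoothing
runs on the raw stream; cleaning then drops milking-window samples and
samples outside the upper barn; splitting partitions by local calendar day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BarnGeometry

#: canonical column order for location files
LOCATION_COLUMNS = ("cow_id", "timestamp", "x", "y")


class FormatError(ValueError):
    """A location file does not expose the required columns."""


@dataclass
class Trajectory:
    """Timestamped (x, y) stream for one animal.

    ``df`` has columns timestamp (datetime64), x, y; timestamps strictly
    increasing. ``exclusions`` counts samples dropped at each stage, keyed
    by reason.
    """

    cow_id: str
    df: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if len(self.df) > 1:
            dt = self.df["timestamp"].diff().dropna()
            if (dt <= pd.Timedelta(0)).any():
                raise ValueError(f"{self.cow_id}: timestamps not strictly increasing")
        for c in ("x", "y"):
            if len(self.df) and not np.isfinite(self.df[c].to_numpy(float)).all():
                raise ValueError(f"{self.cow_id}: non-finite {c} coordinate")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())


def sma_window_from_duration(duration_s: float, rate_hz: float) -> int:
    """Number of samples spanned by a moving-average window of given duration."""
    if rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    return int(round(duration_s * rate_hz))


def nominal_sample_count(rate_hz: float, n_days: int) -> int:
    """Theoretical maximum number of samples for continuous 24 h recording."""
    if rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    return int(round(rate_hz * 86400)) * n_days


def read_locations(
    path,
    *,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
) -> list[Trajectory]:
    """Read a delimited location file into one Trajectory per animal.

    ``column_map`` maps the canonical names (cow_id, timestamp, x, y) onto
    the file's actual header names. Rows with unparseable coordinates or
    timestamps are dropped and counted under ``exclusions['unparseable']``;
    duplicate timestamps collapse to the last record.
    """
    colmap = {c: c for c in LOCATION_COLUMNS}
    if column_map:
        colmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty location file: {path}", stacklevel=2)
        return []
    missing = [k for k, v in colmap.items() if v not in raw.columns]
    if missing:
        raise FormatError(
            f"missing required column(s): {', '.join(colmap[m] for m in missing)}"
        )
    df = pd.DataFrame(
        {
            "cow_id": raw[colmap["cow_id"]].astype(str),
            "timestamp": pd.to_datetime(raw[colmap["timestamp"]], errors="coerce"),
            "x": pd.to_numeric(raw[colmap["x"]], errors="coerce"),
            "y": pd.to_numeric(raw[colmap["y"]], errors="coerce"),
        }
    )
    bad = df[["timestamp", "x", "y"]].isna().any(axis=1)
    n_bad_total = int(bad.sum())
    df = df[~bad]

    out: list[Trajectory] = []
    for cow_id, grp in df.groupby("cow_id", sort=True):
        g = (
            grp.sort_values("timestamp", kind="stable")
            .drop_duplicates("timestamp", keep="last")
            .drop(columns="cow_id")
            .reset_index(drop=True)
        )
        excl = {"unparseable": n_bad_total} if n_bad_total else {}
        out.append(Trajectory(cow_id=str(cow_id), df=g, exclusions=dict(excl)))
    return out


def write_locations(trajectories, path, *, float_format: str = "%.4f") -> None:
    """Write trajectories to the canonical delimited location format."""
    frames = []
    for t in trajectories:
        d = t.df.copy()
        d.insert(0, "cow_id", t.cow_id)
        frames.append(d)
    all_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(LOCATION_COLUMNS))
    )
    all_df.to_csv(path, index=False, float_format=float_format)


def smooth_sma(traj: Trajectory, window: int = 15) -> Trajectory:
    """Centred simple moving average over ``window`` samples per coordinate.

    At the stream edges the window truncates to the available samples, so
    the stream length is unchanged. The window must be odd so the centring
    is well defined; window=1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("SMA window must be odd and >= 1")
    df = traj.df.copy()
    if len(df) and window > 1:
        for c in ("x", "y"):
            # centred window truncating to the available samples at the edges
            df[c] = df[c].rolling(window, center=True, min_periods=1).mean()
    return Trajectory(traj.cow_id, df, dict(traj.exclusions), smoothed=True)


def clean(traj: Trajectory, geometry: BarnGeometry) -> Trajectory:
    """Drop milking-window samples and samples outside the upper barn.

    Exclusion counts are recorded under ``milking`` and ``out_of_barn``;
    the operation is idempotent.
    """
    df = traj.df
    excl = dict(traj.exclusions)
    if len(df):
        ts = df["timestamp"]
        sod = (
            ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second + ts.dt.microsecond / 1e6
        ).to_numpy(float)
        milking = np.zeros(len(df), dtype=bool)
        for w in geometry.milking:
            milking |= (sod >= w.start_s) & (sod < w.end_s)
        x = df["x"].to_numpy(float)
        y = df["y"].to_numpy(float)
        b = geometry.barn
        out = ~((x >= b.xmin) & (x <= b.xmax) & (y >= b.ymin) & (y <= b.ymax))
        out &= ~milking  # count each dropped sample under one reason only
        excl["milking"] = excl.get("milking", 0) + int(milking.sum())
        excl["out_of_barn"] = excl.get("out_of_barn", 0) + int(out.sum())
        df = df[~(milking | out)]
    else:
        excl.setdefault("milking", 0)
        excl.setdefault("out_of_barn", 0)
    return Trajectory(traj.cow_id, df.reset_index(drop=True), excl, traj.smoothed)


@dataclass
class DayPart:
    """One calendar day of a trajectory; empty days are kept and flagged."""

    day_index: int
    date: pd.Timestamp
    trajectory: Trajectory

    @property
    def empty(self) -> bool:
        return len(self.trajectory) == 0


def split_by_day(traj: Trajectory) -> list[DayPart]:
    """Partition a (cleaned) trajectory by local calendar date.

    Every date between the first and last observed date is represented;
    days with no samples appear as empty, flagged parts.
    """
    if len(traj) == 0:
        return []
    dates = traj.df["timestamp"].dt.normalize()
    first, last = dates.iloc[0], dates.iloc[-1]
    all_days = pd.date_range(first, last, freq="D")
    by_date = {d: g for d, g in traj.df.groupby(dates, sort=True)}
    parts = []
    for i, d in enumerate(all_days):
        g = by_date.get(d, traj.df.iloc[0:0])
        parts.append(
            DayPart(
                day_index=i,
                date=d,
                trajectory=Trajectory(
                    traj.cow_id, g.reset_index(drop=True), {}, traj.smoothed
                ),
            )
        )
    return parts


def prepare(
    traj: Trajectory,
    geometry: BarnGeometry,
    *,
    window: int = 15,
    smooth_first: bool = True,
) -> list[DayPart]:
    """Full preparation: smooth, clean, split by day (default order)."""
    if smooth_first:
        return split_by_day(clean(smooth_sma(traj, window), geometry))
    return split_by_day(smooth_sma(clean(traj, geometry), window))
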