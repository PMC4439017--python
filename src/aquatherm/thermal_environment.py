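"""Operative-temperature profiles of stratified water columns.

Depth-stratified datalogger records (temperature at every 5 cm of the
column, every 30 min) are assembled into a rectangular depth x time grid
per tank.  The grid is the operative-temperature (T_e) profile: the null
distribution of body temperatures a non-thermoregulating animal would
attain, and the environmental side of every thermoregulatory index.

Depths are centimetres below the surface (0 = surface, positive down).
Times are real timestamps; interpolation is bilinear (linear in depth and
in time), so evaluating at an exact grid node returns the logged value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptyInputError,
    FormatError,
    GapError,
    GridMismatchError,
    OutOfRangeError,
)

LOGGER_COLUMNS = ("tank_id", "depth_cm", "timestamp", "temp_C")


@dataclass(frozen=True)
class TeProfile:
    """Rectangular depth x time grid of water temperatures for one tank.

    Attributes
    ----------
    tank_id : str
        Identifier of the tank the loggers sat in.
    depths : numpy.ndarray
        Strictly increasing depth grid, cm below surface.
    times : pandas.DatetimeIndex
        Strictly increasing logger timestamps.
    grid : numpy.ndarray
        Temperatures in deg C, shape ``(len(depths), len(times))``, no NaNs.
    """

    tank_id: str
    depths: np.ndarray
    times: pd.DatetimeIndex
    grid: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.depths) <= 0):
            raise GridMismatchError("depths must be strictly increasing")
        if (self.times[1:] <= self.times[:-1]).any():
            raise GridMismatchError("times must be strictly increasing")
        if self.grid.shape != (len(self.depths), len(self.times)):
            raise GridMismatchError(
                f"grid shape {self.grid.shape} does not match "
                f"{len(self.depths)} depths x {len(self.times)} times"
            )
        if not np.all(np.isfinite(self.grid)):
            raise GapError("profile grid contains non-finite cells")

    @property
    def date(self) -> pd.Timestamp:
        """Calendar date of the first reading (midnight-normalised)."""
        return self.times[0].normalize()

    def _hours(self) -> np.ndarray:
        return (self.times - self.times[0]) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class ColumnSummary:
    """Water-column statistics at one instant: mean/min/max T_e over depths."""

    hour: float
    mean_Te: float
    min_Te: float
    max_Te: float

    def __post_init__(self):
        if not (self.min_Te <= self.mean_Te <= self.max_Te):
            raise ValueError("require min_Te <= mean_Te <= max_Te")


@dataclass(frozen=True)
class ConsistencyCheck:
    """Result of the inter-tank agreement check."""

    max_abs_diff_C: float
    exceeds: bool
    threshold_C: float = 1.0


def load_te_readings(path) -> pd.DataFrame:
    """Read a logger CSV into a readings table.

    Expected header: ``tank_id,depth_cm,timestamp,temp_C`` with ISO-8601
    timestamps.  Lines starting with ``#`` are treated as comments (the
    synthetic generator writes its seed there).

    Returns a DataFrame with one reading per row and parsed dtypes.

    Raises
    ------
    FormatError
        If a required column is missing or a field cannot be parsed.
    EmptyInputError
        If the file holds no data rows.
    DuplicateRecordError
        If the same (tank_id, depth_cm, timestamp) key appears twice.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data rows in {path}") from None
    missing = [c for c in LOGGER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"logger CSV missing column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df["depth_cm"] = df["depth_cm"].astype(int)
        df["temp_C"] = df["temp_C"].astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable field in {path}: {exc}") from exc
    df["tank_id"] = df["tank_id"].astype(str)
    key = ["tank_id", "depth_cm", "timestamp"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        keys = df.loc[dup, key].drop_duplicates().to_records(index=False)
        raise DuplicateRecordError(f"duplicated logger keys: {list(keys)[:10]}")
    return df[list(LOGGER_COLUMNS)]


def build_profile(readings: pd.DataFrame, tank_id: str) -> TeProfile:
    """Assemble one tank's readings into a complete :class:`TeProfile`.

    The depth and time grids are the sorted unique values seen for the
    tank.  A single interior missing timestep at a depth is filled by
    linear interpolation in time; a missing boundary cell takes the
    nearest value at that depth.  Two or more consecutive missing
    timesteps are a :class:`~aquatherm.errors.GapError`.
    """
    sub = readings[readings["tank_id"].astype(str) == str(tank_id)]
    if sub.empty:
        raise EmptyInputError(f"no readings for tank {tank_id!r}")
    wide = sub.pivot_table(
        index="depth_cm", columns="timestamp", values="temp_C", aggfunc="first"
    )
    grid = wide.to_numpy(dtype=float)
    depths = wide.index.to_numpy(dtype=float)
    times = pd.DatetimeIndex(wide.columns)
    t = (times - times[0]) / pd.Timedelta(hours=1)
    for i, depth in enumerate(depths):
        row = grid[i]
        nan = np.isnan(row)
        if not nan.any():
            continue
        # reject runs of >1 consecutive missing timesteps
        run = 0
        for j, is_nan in enumerate(nan):
            run = run + 1 if is_nan else 0
            if run > 1:
                raise GapError(
                    f"tank {tank_id!r}, depth {depth:g} cm: >1 consecutive "
                    f"missing reading around {times[j]}"
                )
        if nan.all():
            raise GapError(f"tank {tank_id!r}, depth {depth:g} cm: no readings")
        # np.interp holds boundary gaps at the nearest value and fills
        # interior single gaps linearly in time
        grid[i] = np.interp(t, np.asarray(t)[~nan], row[~nan])
    return TeProfile(tank_id=str(tank_id), depths=depths, times=times, grid=grid)


def _time_weights(profile: TeProfile, when: pd.Timestamp) -> tuple[int, int, float]:
    """Bracketing time indices and interpolation weight for ``when``."""
    t = np.asarray(profile._hours())
    x = (pd.Timestamp(when) - profile.times[0]) / pd.Timedelta(hours=1)
    if x < t[0] or x > t[-1]:
        raise OutOfRangeError(
            f"time {when} outside profile span "
            f"[{profile.times[0]}, {profile.times[-1]}]"
        )
    j = int(np.searchsorted(t, x, side="right")) - 1
    j = min(j, len(t) - 2)
    w = (x - t[j]) / (t[j + 1] - t[j])
    return j, j + 1, float(w)


def column_at(profile: TeProfile, when) -> np.ndarray:
    """Temperatures over the whole depth grid at one instant (time-linear)."""
    j0, j1, w = _time_weights(profile, when)
    return (1.0 - w) * profile.grid[:, j0] + w * profile.grid[:, j1]


def te_at(profile: TeProfile, depth_cm: float, when) -> float:
    """Operative temperature at an arbitrary depth and time.

    Bilinear interpolation on the logger grid; exact grid nodes are
    returned unchanged.  Raises :class:`~aquatherm.errors.OutOfRangeError`
    outside the profile span.
    """
    d = float(depth_cm)
    if d < profile.depths[0] or d > profile.depths[-1]:
        raise OutOfRangeError(
            f"depth {d:g} cm outside [{profile.depths[0]:g}, {profile.depths[-1]:g}]"
        )
    col = column_at(profile, when)
    return float(np.interp(d, profile.depths, col))


def hourly_column_stats(
    profile: TeProfile, hours: Iterable[float], date=None
) -> list[ColumnSummary]:
    """Column mean/min/max at each clock hour.

    ``date`` defaults to the profile's first calendar date; pass it
    explicitly for multi-day records.  An empty ``hours`` yields an empty
    list; an hour outside the profile span raises
    :class:`~aquatherm.errors.OutOfRangeError`.
    """
    base = profile.date if date is None else pd.Timestamp(date).normalize()
    out = []
    for h in hours:
        when = base + pd.Timedelta(hours=float(h))
        col = column_at(profile, when)
        out.append(
            ColumnSummary(
                hour=float(h),
                mean_Te=float(col.mean()),
                min_Te=float(col.min()),
                max_Te=float(col.max()),
            )
        )
    return out


def check_inter_tank_consistency(
    profiles: Sequence[TeProfile], threshold_C: float = 1.0
) -> ConsistencyCheck:
    """Largest cell-wise spread (max minus min) across tanks.

    All profiles must share the depth and time grid.  The flag is set when
    any cell's spread exceeds ``threshold_C`` (default 1 deg C, the level
    below which a few logger tanks are taken to represent all tanks).
    """
    if len(profiles) < 2:
        raise GridMismatchError("need at least two profiles to compare")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.depths, ref.depths) or not p.times.equals(ref.times):
            raise GridMismatchError(
                f"profile {p.tank_id!r} grid differs from {ref.tank_id!r}"
            )
    stack = np.stack([p.grid for p in profiles])
    spread = stack.max(axis=0) - stack.min(axis=0)
    worst = float(spread.max())
    return ConsistencyCheck(
        max_abs_diff_C=worst, exceeds=worst > threshold_C, threshold_C=threshold_C
    )
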