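"""Gridded monthly climate normals and their weekly disaggregation.

Climate input is a long-format CSV of per-cell monthly normals (minimum and
maximum temperature, precipitation total, optional relative humidity at
09:00 and 15:00).  The suitability engine runs on a weekly time step, so
each cell's twelve monthly values are disaggregated to 52 weeks: a daily
series is built by linear interpolation between mid-month anchors on a
fixed 365-day calendar and averaged (temperatures) or summed
(precipitation, via daily rates) into consecutive 7-day bins, the 52nd bin
covering the final 8 days.  Interpolation is exact for constant fields and
conserves annual precipitation up to the interpolation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateDataError",
    "MonthlyNormals",
    "GridCell",
    "ClimateGrid",
    "WeeklySeries",
    "read_climate_csv",
    "write_climate_csv",
    "monthly_to_weekly",
    "write_ei_csv",
    "read_ei_csv",
]

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
_MONTH_START = np.concatenate([[0.0], np.cumsum(MONTH_LENGTHS)[:-1]])
#: Mid-month anchor positions (continuous day-of-year, 365-day calendar).
MONTH_MID = _MONTH_START + MONTH_LENGTHS / 2.0
#: Centers of the 365 days.
_DAY_CENTERS = np.arange(365, dtype=float) + 0.5


class ClimateDataError(ValueError):
    """Raised for malformed or inconsistent climate input."""


def normalize_longitude(lon: float) -> float:
    """Map a longitude into [-180, 180)."""
    return ((lon + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class MonthlyNormals:
    """Twelve monthly climate normals for one cell.

    ``tmin``/``tmax`` in degC, ``precip`` in mm per month; ``rh09``/``rh15``
    are percent relative humidity and may be absent (parsed and preserved
    but unused by the default engine).
    """

    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    rh09: np.ndarray | None = None
    rh15: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "precip"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (12,):
                raise ClimateDataError(f"{name} must have 12 monthly values, got shape {arr.shape}")
            if np.isnan(arr).any():
                raise ClimateDataError(f"{name} contains missing values")
        if np.any(self.tmin > self.tmax):
            bad = int(np.argmax(self.tmin > self.tmax)) + 1
            raise ClimateDataError(f"tmin > tmax in month {bad}")
        if np.any(self.precip < 0):
            raise ClimateDataError("precipitation must be non-negative")
        for name in ("rh09", "rh15"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                object.__setattr__(self, name, arr)
                if arr.shape != (12,):
                    raise ClimateDataError(f"{name} must have 12 monthly values")
                if np.any((arr < 0) | (arr > 100)):
                    raise ClimateDataError(f"{name} must lie in [0, 100]")

    @property
    def tavg(self) -> np.ndarray:
        return (self.tmin + self.tmax) / 2.0


@dataclass(frozen=True)
class GridCell:
    """A grid cell: coordinates of the cell center plus its normals."""

    cell_id: str
    lat: float
    lon: float
    normals: MonthlyNormals

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ClimateDataError(f"cell {self.cell_id!r}: latitude {self.lat} out of [-90, 90]")
        object.__setattr__(self, "lon", normalize_longitude(float(self.lon)))


@dataclass
class ClimateGrid:
    """A collection of grid cells, ordered by cell_id."""

    cells: list[GridCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ClimateDataError(f"duplicate cell ids: {dupes}")
        self.cells = sorted(self.cells, key=lambda c: c.cell_id)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[GridCell]:
        return iter(self.cells)

    def __getitem__(self, cell_id: str) -> GridCell:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]


@dataclass(frozen=True)
class WeeklySeries:
    """52 weekly values: mean/min/max temperature (degC) and precipitation (mm/week)."""

    tavg: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tavg", "tmin", "tmax", "precip"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (52,):
                raise ClimateDataError(f"{name} must have 52 weekly values")
        if np.any(self.tmin > self.tavg + 1e-9) or np.any(self.tavg > self.tmax + 1e-9):
            raise ClimateDataError("weekly series must satisfy tmin <= tavg <= tmax")
        if np.any(self.precip < 0):
            raise ClimateDataError("weekly precipitation must be non-negative")


def _daily_from_monthly(values: Sequence[float]) -> np.ndarray:
    """365 daily values by periodic linear interpolation between mid-month anchors."""
    v = np.asarray(values, dtype=float)
    x = np.concatenate([[MONTH_MID[-1] - 365.0], MONTH_MID, [MONTH_MID[0] + 365.0]])
    y = np.concatenate([[v[-1]], v, [v[0]]])
    return np.interp(_DAY_CENTERS, x, y)


def _weekly_means(daily: np.ndarray) -> np.ndarray:
    out = np.empty(52)
    out[:51] = daily[:357].reshape(51, 7).mean(axis=1)
    out[51] = daily[357:].mean()
    return out


def _weekly_sums(daily: np.ndarray) -> np.ndarray:
    out = np.empty(52)
    out[:51] = daily[:357].reshape(51, 7).sum(axis=1)
    out[51] = daily[357:].sum()
    return out


def monthly_to_weekly(normals: MonthlyNormals) -> WeeklySeries:
    """Disaggregate monthly normals to a 52-week series.

    Temperatures: daily linear interpolation between mid-month anchors,
    averaged per week.  Precipitation: monthly totals converted to daily
    rates (total / month length), interpolated the same way and summed per
    week, which conserves the annual total up to the interpolation scheme.
    """
    tmin_d = _daily_from_monthly(normals.tmin)
    tmax_d = _daily_from_monthly(normals.tmax)
    rate_d = _daily_from_monthly(normals.precip / MONTH_LENGTHS)
    tmin_w = _weekly_means(tmin_d)
    tmax_w = _weekly_means(tmax_d)
    precip_w = np.maximum(_weekly_sums(rate_d), 0.0)
    return WeeklySeries(
        tavg=(tmin_w + tmax_w) / 2.0, tmin=tmin_w, tmax=tmax_w, precip=precip_w
    )


_REQUIRED_COLUMNS = ("cell_id", "lat", "lon", "month", "tmin", "tmax", "precip")


def read_climate_csv(path: str | Path) -> ClimateGrid:
    """Read a long-format climate CSV (12 rows per cell, one per month).

    Required columns: cell_id, lat, lon, month (1-12), tmin, tmax, precip;
    optional: rh09, rh15.  Row order is irrelevant.  Lines starting with
    '#' are treated as comments.
    """
    df = pd.read_csv(path, comment="#", dtype={"cell_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ClimateDataError(f"{path}: missing required columns {missing}")
    has_rh = (
        all(c in df.columns for c in ("rh09", "rh15"))
        and not df[["rh09", "rh15"]].isna().all().all()
    )
    cells: list[GridCell] = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        months = sorted(sub["month"].astype(int))
        if months != list(range(1, 13)):
            raise ClimateDataError(
                f"{path}: cell {cell_id!r} has months {months}, expected 1..12"
            )
        sub = sub.sort_values("month")
        lat = float(sub["lat"].iloc[0])
        lon = float(sub["lon"].iloc[0])
        bad = sub[sub["tmin"] > sub["tmax"]]
        if not bad.empty:
            m = int(bad["month"].iloc[0])
            raise ClimateDataError(f"{path}: cell {cell_id!r} month {m}: tmin > tmax")
        normals = MonthlyNormals(
            tmin=sub["tmin"].to_numpy(float),
            tmax=sub["tmax"].to_numpy(float),
            precip=sub["precip"].to_numpy(float),
            rh09=sub["rh09"].to_numpy(float) if has_rh else None,
            rh15=sub["rh15"].to_numpy(float) if has_rh else None,
        )
        cells.append(GridCell(cell_id=str(cell_id), lat=lat, lon=lon, normals=normals))
    return ClimateGrid(cells)


def write_climate_csv(
    grid: ClimateGrid, path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    """Write a grid back to the long-format climate CSV dialect."""
    rows = []
    has_rh = any(c.normals.rh09 is not None for c in grid)
    for c in grid:
        for m in range(12):
            row = {
                "cell_id": c.cell_id,
                "lat": c.lat,
                "lon": c.lon,
                "month": m + 1,
                "tmin": c.normals.tmin[m],
                "tmax": c.normals.tmax[m],
                "precip": c.normals.precip[m],
            }
            if has_rh:
                row["rh09"] = c.normals.rh09[m] if c.normals.rh09 is not None else np.nan
                row["rh15"] = c.normals.rh15[m] if c.normals.rh15 is not None else np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


_EI_COLUMNS = ("cell_id", "lat", "lon", "gi_a", "cs", "hs", "ds", "ws", "ei", "class")


def write_ei_csv(results, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write per-cell suitability results (cell_id ascending)."""
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    rows = [
        {
            "cell_id": r.cell_id,
            "lat": r.lat,
            "lon": r.lon,
            "gi_a": r.gi_a,
            "cs": r.cs,
            "hs": r.hs,
            "ds": r.ds,
            "ws": r.ws,
            "ei": r.ei,
            "class": r.suitability,
        }
        for r in sorted(results, key=lambda r: r.cell_id)
    ]
    df = pd.DataFrame(rows, columns=list(_EI_COLUMNS))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_ei_csv(path: str | Path):
    """Read a per-cell suitability CSV written by :func:`write_ei_csv`."""
    from .engine import CellResult  # local import to avoid a cycle

    df = pd.read_csv(path, comment="#", dtype={"cell_id": str})
    missing = [c for c in _EI_COLUMNS if c not in df.columns]
    if missing:
        raise ClimateDataError(f"{path}: missing columns {missing}")
    return [
        CellResult(
            cell_id=str(row["cell_id"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            gi_a=float(row["gi_a"]),
            cs=float(row["cs"]),
            hs=float(row["hs"]),
            ds=float(row["ds"]),
            ws=float(row["ws"]),
            ei=float(row["ei"]),
            suitability=str(row["class"]),
        )
        for _, row in df.iterrows()
    ]
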