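"""Synthetic climate grids, future scenarios, and occurrence records.

The generator emulates the structure of a global gridded climatology that
the analysis assumes: a latitudinal temperature gradient away from a warm
equator, a seasonal cycle whose amplitude grows with latitude and whose
phase flips between hemispheres, a fixed diurnal (tmax - tmin) range, and
a zonal precipitation field with an arid subtropical band and a
summer-peaking wet season.  The world is zonally symmetric by default
(longitude enters only through opt-in noise), which makes the resulting
suitability pattern — a temperate band bracketed by heat/dry-limited low
latitudes and cold-limited high latitudes — predictable and testable.

Future scenarios apply a uniform (optionally latitude-dependent) warming
offset and a precipitation multiplier, with per-cell noise standing in for
the internal variability that distinguishes one climate model from
another.  Occurrences are sampled from a suitability surface with
probability proportional to EI**gamma, then contaminated with the defects
a raw biodiversity-database export exhibits: blanked coordinates, exact
duplicates, and dense clusters that exercise spatial thinning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_grid import ClimateGrid, GridCell, MonthlyNormals, WeeklySeries, MONTH_LENGTHS
from .engine import CellResult, potential_evapotranspiration
from .occurrences import EARTH_RADIUS_KM, OccurrenceRecord
from .params import SpeciesParameters, brassica_napus_parameters

__all__ = [
    "ClimateGenConfig",
    "ScenarioGenConfig",
    "generate_climate",
    "generate_future",
    "generate_occurrences",
    "fixture_weekly",
    "fixture_cell",
]

_MONTHS = np.arange(1, 13, dtype=float)
_KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


@dataclass(frozen=True)
class ClimateGenConfig:
    """Configuration of the synthetic climatology.

    Defaults describe a smooth, zonally symmetric world: annual-mean
    temperature 27 degC at the equator falling 0.55 degC per degree of
    latitude; seasonal amplitude 2 + 0.25*|lat| degC peaking in local
    summer; diurnal range 8 degC; 80 mm/month precipitation with a x0.2
    arid belt at 12-28 deg latitude and a moderate summer wet season.
    """

    n_lat: int = 20
    n_lon: int = 8
    lat_range: tuple[float, float] = (-60.0, 60.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    t_equator: float = 27.0
    lapse: float = 0.55
    seasonal_amp0: float = 2.0
    seasonal_amp_slope: float = 0.25
    diurnal_range: float = 8.0
    precip_base: float = 80.0
    arid_band: tuple[float, float] = (12.0, 28.0)
    arid_factor: float = 0.2
    wet_season_phase: int = 0
    wet_season_amp: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be positive")
        if self.seasonal_amp0 < 0 or self.seasonal_amp_slope < 0:
            raise ValueError("seasonal amplitudes must be non-negative")
        if not (0 <= self.wet_season_amp <= 1):
            raise ValueError("wet_season_amp must lie in [0, 1]")
        lo, hi = self.lat_range
        if not (-90.0 <= lo < hi <= 90.0):
            raise ValueError(f"invalid lat_range {self.lat_range}")


@dataclass(frozen=True)
class ScenarioGenConfig:
    """A synthetic future forcing: warming offset + precipitation scaling."""

    warming: float = 2.0
    warming_lat_slope: float = 0.0
    precip_scale: float = 1.0
    model_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.precip_scale <= 0:
            raise ValueError("precip_scale must be positive")


def _cell_centers(lo: float, hi: float, n: int) -> np.ndarray:
    step = (hi - lo) / n
    return lo + step * (np.arange(n) + 0.5)


def _summer_peak_month(lat: float) -> float:
    # mid-July in the northern hemisphere, mid-January in the southern
    return 7.0 if lat >= 0 else 1.0


def _monthly_normals(lat: float, cfg: ClimateGenConfig, rng: np.random.Generator) -> MonthlyNormals:
    mean = cfg.t_equator - cfg.lapse * abs(lat)
    amp = cfg.seasonal_amp0 + cfg.seasonal_amp_slope * abs(lat)
    peak = _summer_peak_month(lat)
    tavg = mean + amp * np.cos(2 * np.pi * (_MONTHS - peak) / 12.0)
    if cfg.noise_sd > 0:
        tavg = tavg + rng.normal(0.0, cfg.noise_sd, 12)
    tmin = tavg - cfg.diurnal_range / 2.0
    tmax = tavg + cfg.diurnal_range / 2.0

    mult = cfg.arid_factor if cfg.arid_band[0] <= abs(lat) <= cfg.arid_band[1] else 1.0
    wet_peak = _summer_peak_month(lat) + cfg.wet_season_phase
    seasonal = 1.0 + cfg.wet_season_amp * np.cos(2 * np.pi * (_MONTHS - wet_peak) / 12.0)
    precip = np.maximum(cfg.precip_base * mult * seasonal, 0.0)
    return MonthlyNormals(tmin=tmin, tmax=tmax, precip=precip)


def generate_climate(cfg: ClimateGenConfig = ClimateGenConfig()) -> ClimateGrid:
    """Generate a synthetic climate grid, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    lats = _cell_centers(*cfg.lat_range, cfg.n_lat)
    lons = _cell_centers(*cfg.lon_range, cfg.n_lon)
    cells = []
    for i, lat in enumerate(lats):
        for j, lon in enumerate(lons):
            cells.append(
                GridCell(
                    cell_id=f"c{i:03d}_{j:03d}",
                    lat=float(lat),
                    lon=float(lon),
                    normals=_monthly_normals(float(lat), cfg, rng),
                )
            )
    return ClimateGrid(cells)


def generate_future(grid: ClimateGrid, cfg: ScenarioGenConfig) -> ClimateGrid:
    """Apply a synthetic future forcing to every cell of a grid.

    Temperatures shift by warming + warming_lat_slope*|lat| plus seeded
    per-cell noise; precipitation is scaled.  Two different seeds stand in
    for two climate models when building agreement maps.
    """
    rng = np.random.default_rng(cfg.seed)
    cells = []
    for cell in grid:
        offset = cfg.warming + cfg.warming_lat_slope * abs(cell.lat)
        if cfg.model_noise_sd > 0:
            offset += rng.normal(0.0, cfg.model_noise_sd)
        n = cell.normals
        cells.append(
            GridCell(
                cell_id=cell.cell_id,
                lat=cell.lat,
                lon=cell.lon,
                normals=MonthlyNormals(
                    tmin=n.tmin + offset,
                    tmax=n.tmax + offset,
                    precip=n.precip * cfg.precip_scale,
                    rh09=n.rh09,
                    rh15=n.rh15,
                ),
            )
        )
    return ClimateGrid(cells)


def _grid_spacing(values: np.ndarray) -> float:
    u = np.unique(values)
    return float(np.median(np.diff(u))) if u.size > 1 else 1.0


def generate_occurrences(
    results: list[CellResult],
    n: int,
    gamma: float = 4.0,
    frac_missing: float = 0.0,
    frac_duplicate: float = 0.0,
    frac_cluster: float = 0.0,
    cluster_radius_km: float = 20.0,
    seed: int = 0,
) -> list[OccurrenceRecord]:
    """Sample contaminated occurrence records from a suitability surface.

    Cells with EI > 0 are sampled with probability proportional to
    EI**gamma (gamma=0: uniform over EI > 0 cells) and each point is
    jittered uniformly within its cell.  Contamination then emulates a raw
    export: each base record loses its coordinates with probability
    *frac_missing*; round(n*frac_duplicate) exact coordinate duplicates
    and round(n*frac_cluster) near-by cluster points (within
    *cluster_radius_km* of a parent record) are appended.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    rng = np.random.default_rng(seed)
    ei = np.array([r.ei for r in results])
    positive = np.flatnonzero(ei > 0)
    if n > 0 and positive.size == 0:
        raise ValueError("cannot sample occurrences: all cells have EI = 0")
    weights = ei[positive] ** gamma
    weights = weights / weights.sum()
    lats = np.array([r.lat for r in results])
    lons = np.array([r.lon for r in results])
    dlat = _grid_spacing(lats)
    dlon = _grid_spacing(lons)

    records: list[OccurrenceRecord] = []
    counter = 0

    def new_record(lat: float | None, lon: float | None) -> OccurrenceRecord:
        nonlocal counter
        counter += 1
        return OccurrenceRecord(
            record_id=f"occ-{counter:06d}", lon=lon, lat=lat, source="synthetic"
        )

    choices = rng.choice(positive, size=n, p=weights)
    for idx in choices:
        lat = float(lats[idx] + rng.uniform(-dlat / 2, dlat / 2))
        lon = float(lons[idx] + rng.uniform(-dlon / 2, dlon / 2))
        if rng.random() < frac_missing:
            records.append(new_record(None, None))
        else:
            records.append(new_record(np.clip(lat, -90.0, 90.0), lon))

    with_coords = [r for r in records if r.has_coordinates]
    if with_coords:
        for _ in range(round(n * frac_duplicate)):
            parent = with_coords[rng.integers(len(with_coords))]
            records.append(new_record(parent.lat, parent.lon))
        for _ in range(round(n * frac_cluster)):
            parent = with_coords[rng.integers(len(with_coords))]
            bearing = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0, cluster_radius_km)
            dlat_km = dist * np.cos(bearing) / _KM_PER_DEG
            coslat = max(np.cos(np.radians(parent.lat)), 1e-6)
            dlon_km = dist * np.sin(bearing) / (_KM_PER_DEG * coslat)
            records.append(
                new_record(
                    float(np.clip(parent.lat + dlat_km, -90.0, 90.0)),
                    float(parent.lon + dlon_km),
                )
            )
    return records


_PROFILES = ("optimal", "cold", "hot", "dry", "wet")


def _optimal_precip_weekly(p: SpeciesParameters) -> float:
    # precipitation exactly balancing PET keeps the bucket at sm_init
    return float(potential_evapotranspiration(16.0, p))


def fixture_weekly(profile: str, p: SpeciesParameters | None = None) -> WeeklySeries:
    """Hand-built 52-week fixtures keyed to the packaged parameter set.

    optimal: tavg 16, tmin 10, tmax 22 all year, precipitation balancing
    PET so soil moisture holds at 0.5 (EI = 100); cold: 12 weeks with
    tmin = -20; hot: 12 weeks with tmax = 35; dry: zero precipitation;
    wet: precipitation at 10x PET.
    """
    p = brassica_napus_parameters() if p is None else p
    if profile not in _PROFILES:
        raise ValueError(f"unknown fixture profile {profile!r}; choose from {_PROFILES}")
    tavg = np.full(52, 16.0)
    tmin = np.full(52, 10.0)
    tmax = np.full(52, 22.0)
    precip = np.full(52, _optimal_precip_weekly(p))
    if profile == "cold":
        tmin[:12] = -20.0
    elif profile == "hot":
        tmax[:12] = 35.0
    elif profile == "dry":
        precip[:] = 0.0
    elif profile == "wet":
        precip[:] = 10.0 * _optimal_precip_weekly(p)
    return WeeklySeries(tavg=tavg, tmin=tmin, tmax=tmax, precip=precip)


def fixture_cell(
    profile: str, p: SpeciesParameters | None = None, cell_id: str | None = None
) -> GridCell:
    """Single-cell monthly-normal fixtures mirroring :func:`fixture_weekly`.

    Monthly fields are flat, so the weekly disaggregation is exact:
    optimal reaches EI = 100 under the packaged parameters; cold (deep
    frost year-round), hot and dry are driven to EI = 0 by their
    respective stress.
    """
    p = brassica_napus_parameters() if p is None else p
    if profile not in _PROFILES:
        raise ValueError(f"unknown fixture profile {profile!r}; choose from {_PROFILES}")
    # balance annual precipitation against annual PET exactly, so the
    # bucket cycles around sm_init instead of drifting on the 8-day week 52
    daily_opt = 52.0 * _optimal_precip_weekly(p) / 365.0
    tmin, tmax, daily_rate = 10.0, 22.0, daily_opt
    if profile == "cold":
        tmin, tmax = -25.0, -15.0
    elif profile == "hot":
        tmin, tmax = 27.0, 35.0
    elif profile == "dry":
        daily_rate = 0.0
    elif profile == "wet":
        daily_rate = 10.0 * daily_opt
    return GridCell(
        cell_id=cell_id or f"fixture_{profile}",
        lat=0.0,
        lon=0.0,
        normals=MonthlyNormals(
            tmin=np.full(12, tmin),
            tmax=np.full(12, tmax),
            precip=daily_rate * MONTH_LENGTHS,
        ),
    )
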