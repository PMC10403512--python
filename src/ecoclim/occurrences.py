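"""Occurrence-record cleaning and model validation against an EI grid.

Raw occurrence exports (GBIF/EPPO/CABI style) typically contain rows with
missing coordinates, exact duplicates, and dense clusters from uneven
sampling effort.  The cleaning pipeline applies, in order: removal of
records without usable coordinates, coordinate deduplication (equality at
4-decimal rounding, about 11 m), and greedy great-circle thinning so that
no two retained records lie within a given radius (50 km by default).
Retained records can then be overlaid on a suitability grid to report the
share of records per suitability class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .climate_grid import normalize_longitude

__all__ = [
    "EARTH_RADIUS_KM",
    "OccurrenceRecord",
    "CleaningReport",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "haversine_km",
    "drop_missing_coordinates",
    "deduplicate",
    "spatial_thin",
    "clean_pipeline",
    "split_fit_validation",
    "overlay_validation",
    "share_percentages",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class OccurrenceRecord:
    """One occurrence record; coordinates may be absent (None)."""

    record_id: str
    lon: float | None
    lat: float | None
    source: str = ""

    def __post_init__(self) -> None:
        if self.lon is not None and self.lat is not None:
            if -90.0 <= self.lat <= 90.0:
                object.__setattr__(self, "lon", normalize_longitude(float(self.lon)))

    @property
    def has_coordinates(self) -> bool:
        return (
            self.lon is not None
            and self.lat is not None
            and -90.0 <= self.lat <= 90.0
        )


@dataclass(frozen=True)
class CleaningReport:
    """Stage-by-stage record counts; retained = initial minus all removals."""

    n_initial: int
    n_removed_no_coords: int
    n_removed_duplicates: int
    n_removed_thinning: int
    n_retained: int

    def __post_init__(self) -> None:
        counts = (
            self.n_initial,
            self.n_removed_no_coords,
            self.n_removed_duplicates,
            self.n_removed_thinning,
            self.n_retained,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"cleaning counts must be non-negative: {counts}")
        expected = (
            self.n_initial
            - self.n_removed_no_coords
            - self.n_removed_duplicates
            - self.n_removed_thinning
        )
        if self.n_retained != expected:
            raise ValueError(
                f"cleaning counts inconsistent: retained {self.n_retained} != {expected}"
            )

    @classmethod
    def from_removals(
        cls, n_initial: int, no_coords: int, duplicates: int, thinning: int
    ) -> "CleaningReport":
        """Build a report from the initial count and the three removal counts."""
        return cls(
            n_initial=n_initial,
            n_removed_no_coords=no_coords,
            n_removed_duplicates=duplicates,
            n_removed_thinning=thinning,
            n_retained=n_initial - no_coords - duplicates - thinning,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_initial": self.n_initial,
            "n_removed_no_coords": self.n_removed_no_coords,
            "n_removed_duplicates": self.n_removed_duplicates,
            "n_removed_thinning": self.n_removed_thinning,
            "n_retained": self.n_retained,
        }


def read_occurrences_csv(path: str | Path) -> list[OccurrenceRecord]:
    """Read an occurrence CSV (record_id, longitude, latitude, source)."""
    df = pd.read_csv(path, comment="#", dtype={"record_id": str, "source": str})
    required = ("record_id", "longitude", "latitude", "source")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        lon = None if pd.isna(row.longitude) else float(row.longitude)
        lat = None if pd.isna(row.latitude) else float(row.latitude)
        source = "" if pd.isna(row.source) else str(row.source)
        records.append(
            OccurrenceRecord(record_id=str(row.record_id), lon=lon, lat=lat, source=source)
        )
    return records


def write_occurrences_csv(
    records: Iterable[OccurrenceRecord], path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    df = pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "longitude": r.lon,
                "latitude": r.lat,
                "source": r.source,
            }
            for r in records
        ],
        columns=["record_id", "longitude", "latitude", "source"],
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (haversine, Earth radius 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def _sort_key(r: OccurrenceRecord) -> tuple[str, str]:
    return (r.source, r.record_id)


def drop_missing_coordinates(
    records: Sequence[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], int]:
    """Keep records with both coordinates present and in range."""
    kept = [r for r in records if r.has_coordinates]
    return kept, len(records) - len(kept)


def deduplicate(
    records: Sequence[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], int]:
    """Collapse records sharing coordinates at 4-decimal rounding (~11 m).

    Within each coordinate group the first record by (source, record_id)
    order is kept.
    """
    seen: dict[tuple[float, float], OccurrenceRecord] = {}
    for r in sorted(records, key=_sort_key):
        key = (round(r.lat, 4), round(r.lon, 4))
        seen.setdefault(key, r)
    kept = sorted(seen.values(), key=_sort_key)
    return kept, len(records) - len(kept)


def spatial_thin(
    records: Sequence[OccurrenceRecord], radius_km: float = 50.0
) -> tuple[list[OccurrenceRecord], int]:
    """Greedy sequential thinning to a minimum pairwise distance.

    Records are visited in (source, record_id) order; one is kept iff it
    lies at least *radius_km* (great-circle) from every previously kept
    record, so all pairwise distances in the kept set are >= radius_km.
    Exact maximal-subset thinning is NP-hard; the greedy rule is
    deterministic and reproducible.
    """
    if radius_km <= 0:
        raise ValueError(f"thinning radius must be positive, got {radius_km}")
    ordered = sorted(records, key=_sort_key)
    kept: list[OccurrenceRecord] = []
    kept_lat = np.empty(len(ordered))
    kept_lon = np.empty(len(ordered))
    for r in ordered:
        n = len(kept)
        if n == 0 or np.all(
            haversine_km(kept_lat[:n], kept_lon[:n], r.lat, r.lon) >= radius_km
        ):
            kept_lat[n] = r.lat
            kept_lon[n] = r.lon
            kept.append(r)
    return kept, len(ordered) - len(kept)


def clean_pipeline(
    records: Sequence[OccurrenceRecord], radius_km: float = 50.0
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Missing-coordinate removal, deduplication, then spatial thinning."""
    with_coords, n_no_coords = drop_missing_coordinates(records)
    unique, n_dupes = deduplicate(with_coords)
    thinned, n_thinned = spatial_thin(unique, radius_km=radius_km)
    report = CleaningReport.from_removals(
        len(records), n_no_coords, n_dupes, n_thinned
    )
    return thinned, report


def split_fit_validation(
    records: Sequence[OccurrenceRecord],
    validation_region: tuple[float, float, float, float],
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Partition records by a validation bounding box.

    *validation_region* is (lon_min, lat_min, lon_max, lat_max); records
    inside (inclusive) form the validation set, the rest the fit set.  An
    empty validation set triggers a warning, not an error.
    """
    lon_min, lat_min, lon_max, lat_max = validation_region
    fit, val = [], []
    for r in records:
        inside = (
            r.has_coordinates
            and lon_min <= r.lon <= lon_max
            and lat_min <= r.lat <= lat_max
        )
        (val if inside else fit).append(r)
    if not val:
        warnings.warn("validation region contains no records", stacklevel=2)
    return fit, val


def _infer_max_distance_km(lats: np.ndarray, lons: np.ndarray) -> float:
    """One cell diagonal, inferred from the median coordinate spacing."""

    def spacing(vals: np.ndarray) -> float:
        u = np.unique(vals)
        return float(np.median(np.diff(u))) if u.size > 1 else 1.0

    dlat = spacing(lats)
    dlon = spacing(lons)
    # diagonal at the least favorable (highest) latitude of the grid
    coslat = max(np.cos(np.radians(np.abs(lats).max())), 1e-6)
    km_per_deg = EARTH_RADIUS_KM * np.pi / 180.0
    return float(km_per_deg * np.hypot(dlat, dlon * coslat))


def overlay_validation(
    records: Sequence[OccurrenceRecord],
    results,
    max_distance_km: float | None = None,
) -> dict[str, float]:
    """Percentage of records per suitability class of their nearest cell.

    Each record is assigned to the nearest cell center (great circle, ties
    broken by lowest cell_id) and rejected if farther than one cell
    diagonal (inferred from the grid spacing unless given).  Percentages
    are over assigned records and sum to 100.
    """
    results = sorted(results, key=lambda r: r.cell_id)
    records = [r for r in records if r.has_coordinates]
    if not results or not records:
        raise ValueError("overlay requires non-empty records and results")
    lats = np.array([r.lat for r in results])
    lons = np.array([r.lon for r in results])
    classes = [r.suitability for r in results]
    if max_distance_km is None:
        max_distance_km = _infer_max_distance_km(lats, lons)
    counts = {"unsuitable": 0, "suitable": 0, "high": 0}
    n_assigned = 0
    for rec in records:
        d = haversine_km(lats, lons, rec.lat, rec.lon)
        i = int(np.argmin(d))  # argmin returns the first (lowest cell_id) on ties
        if d[i] <= max_distance_km:
            counts[classes[i]] += 1
            n_assigned += 1
    if n_assigned == 0:
        raise ValueError("no occurrence record lies within reach of any grid cell")
    return {k: 100.0 * v / n_assigned for k, v in counts.items()}


def share_percentages(counts: Mapping[str, int]) -> dict[str, int]:
    """Integer-rounded percentage share of each group in a count table."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: round(100.0 * v / total) for k, v in counts.items()}
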