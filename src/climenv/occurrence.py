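"""Occurrence data assembly: presences, transect absences, pseudo-absences.

The model-fitting currency is a *feature table*: one row per labelled point
with the five bioclimatic covariates extracted from a climate grid and a
binary response (presence = 1, absence or pseudo-absence = 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyTableError,
    InfeasibleSamplingError,
    SchemaError,
)
from .grids import ClimateGrid

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: Columns of a feature table that are not model covariates.
META_COLUMNS = ("lon", "lat", "label", "source", "response")

LABELS = ("presence", "absence", "pseudo_absence")
SOURCES = ("sighting", "nest", "transect_midpoint", "random_background")

# label <-> source pairings that must hold for non-presence records
_LABEL_SOURCE = {"absence": "transect_midpoint", "pseudo_absence": "random_background"}


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude point in degrees (WGS84-style coordinates)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ConfigurationError(f"lon {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ConfigurationError(f"lat {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class OccurrenceRecord:
    point: GeoPoint
    label: str
    source: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise SchemaError(f"unknown label {self.label!r}")
        if self.source not in SOURCES:
            raise SchemaError(f"unknown source {self.source!r}")
        expected = _LABEL_SOURCE.get(self.label)
        if expected is not None and self.source != expected:
            raise SchemaError(
                f"label {self.label!r} requires source {expected!r}, got {self.source!r}"
            )
        if self.label == "presence" and self.source not in ("sighting", "nest"):
            raise SchemaError("presence records must come from sightings or nests")


@dataclass(frozen=True)
class TransectRecord:
    """A walked straight-line transect with a detection outcome."""

    start: GeoPoint
    end: GeoPoint
    detected: bool


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km (haversine, Earth radius 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geodesic_midpoint(a: GeoPoint, b: GeoPoint) -> GeoPoint:
    """Midpoint of the great-circle segment between two points."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    x1, y1, z1 = (math.cos(la1) * math.cos(lo1), math.cos(la1) * math.sin(lo1),
                  math.sin(la1))
    x2, y2, z2 = (math.cos(la2) * math.cos(lo2), math.cos(la2) * math.sin(lo2),
                  math.sin(la2))
    x, y, z = (x1 + x2) / 2, (y1 + y2) / 2, (z1 + z2) / 2
    hyp = math.hypot(x, y)
    if hyp == 0 and z == 0:  # antipodal: midpoint undefined
        raise ConfigurationError("midpoint of antipodal points is undefined")
    return GeoPoint(lon=math.degrees(math.atan2(y, x)),
                    lat=math.degrees(math.atan2(z, hyp)))


def transect_absence_midpoints(
    transects: Iterable[TransectRecord],
) -> list[OccurrenceRecord]:
    """One absence record at the midpoint of every transect without a detection.

    Transects on which the species was detected contribute nothing (their
    detections are normally already in the presence set).
    """
    out = []
    for t in transects:
        if t.detected:
            continue
        mid = geodesic_midpoint(t.start, t.end)
        out.append(OccurrenceRecord(mid, label="absence", source="transect_midpoint"))
    return out


def sample_pseudo_absences(
    region: tuple[float, float, float, float],
    presences: Sequence[GeoPoint],
    n: int,
    min_dist_km: float,
    seed: int,
    max_attempts_factor: int = 1000,
) -> list[OccurrenceRecord]:
    """Uniform background points at least `min_dist_km` from every presence.

    `region` is (lon_min, lon_max, lat_min, lat_max); sampling is uniform in
    coordinates (rejection sampling against the presence exclusion buffers).
    Raises InfeasibleSamplingError if the proposal budget
    (``max_attempts_factor * n``) is exhausted, e.g. when the buffers cover
    the whole region.
    """
    lon_min, lon_max, lat_min, lat_max = region
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ConfigurationError("pseudo-absence region is degenerate")
    if min_dist_km < 0:
        raise ConfigurationError("min_dist_km must be >= 0")
    if n == 0:
        return []

    rng = np.random.default_rng(seed)
    p_lon = np.array([p.lon for p in presences])
    p_lat = np.array([p.lat for p in presences])

    kept_lon: list[np.ndarray] = []
    kept_lat: list[np.ndarray] = []
    n_kept = 0
    budget = max_attempts_factor * n
    spent = 0
    while n_kept < n:
        batch = min(max(n - n_kept, 1024), budget - spent)
        if batch <= 0:
            raise InfeasibleSamplingError(
                f"placed {n_kept}/{n} pseudo-absences in {budget} proposals; "
                "exclusion buffers may cover the region"
            )
        lon = rng.uniform(lon_min, lon_max, batch)
        lat = rng.uniform(lat_min, lat_max, batch)
        spent += batch
        if len(p_lon) and min_dist_km > 0:
            d = haversine_km(lon[:, None], lat[:, None], p_lon[None, :], p_lat[None, :])
            ok = d.min(axis=1) >= min_dist_km
        else:
            ok = np.ones(batch, dtype=bool)
        kept_lon.append(lon[ok])
        kept_lat.append(lat[ok])
        n_kept += int(ok.sum())

    lon = np.concatenate(kept_lon)[:n]
    lat = np.concatenate(kept_lat)[:n]
    return [
        OccurrenceRecord(GeoPoint(lo, la), "pseudo_absence", "random_background")
        for lo, la in zip(lon, lat)
    ]


def _as_records(
    points: Sequence, label: str, source: str
) -> list[OccurrenceRecord]:
    out = []
    for p in points:
        if isinstance(p, OccurrenceRecord):
            out.append(p)
        else:
            out.append(OccurrenceRecord(p, label, source))
    return out


def assemble_training_set(
    presences: Sequence,
    transect_absences: Sequence[OccurrenceRecord],
    pseudo_absences: Sequence[OccurrenceRecord],
    grid: ClimateGrid,
) -> pd.DataFrame:
    """Build the feature table: covariates per point plus a binary response.

    Covariates are taken from the grid cell containing each point (no
    interpolation; edge ties go to the north-east cell). Points outside the
    grid are dropped with a logged count. Row order is presences, transect
    absences, pseudo-absences.
    """
    records = (
        _as_records(presences, "presence", "sighting")
        + _as_records(transect_absences, "absence", "transect_midpoint")
        + _as_records(pseudo_absences, "pseudo_absence", "random_background")
    )
    if not records:
        raise EmptyTableError("no input records")
    lon = np.array([r.point.lon for r in records])
    lat = np.array([r.point.lat for r in records])
    covs, inside = grid.extract(lon, lat)

    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("assemble_training_set: dropped %d point(s) outside the grid",
                    n_dropped)
    if n_dropped == len(records):
        raise EmptyTableError("every input point falls outside the grid")

    table = pd.DataFrame(
        {
            "lon": lon,
            "lat": lat,
            "label": [r.label for r in records],
            "source": [r.source for r in records],
            "response": [1 if r.label == "presence" else 0 for r in records],
        }
    )
    table = pd.concat([table, covs], axis=1)[np.asarray(inside)]
    return table.reset_index(drop=True)


def covariate_columns(table: pd.DataFrame) -> list[str]:
    """The covariate columns of a feature table (everything non-meta)."""
    return [c for c in table.columns if c not in META_COLUMNS]


# -- CSV I/O -----------------------------------------------------------------

def records_to_frame(records: Sequence[OccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lon": [r.point.lon for r in records],
            "lat": [r.point.lat for r in records],
            "label": [r.label for r in records],
            "source": [r.source for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[OccurrenceRecord]:
    return [
        OccurrenceRecord(GeoPoint(row.lon, row.lat), row.label, row.source)
        for row in frame.itertuples()
    ]


def write_records_csv(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[OccurrenceRecord]:
    return frame_to_records(pd.read_csv(path))


def transects_to_frame(transects: Sequence[TransectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lon1": [t.start.lon for t in transects],
            "lat1": [t.start.lat for t in transects],
            "lon2": [t.end.lon for t in transects],
            "lat2": [t.end.lat for t in transects],
            "detected": [t.detected for t in transects],
        }
    )


def frame_to_transects(frame: pd.DataFrame) -> list[TransectRecord]:
    return [
        TransectRecord(GeoPoint(r.lon1, r.lat1), GeoPoint(r.lon2, r.lat2),
                       bool(r.detected))
        for r in frame.itertuples()
    ]


def write_transects_csv(transects: Sequence[TransectRecord], path: str | Path) -> None:
    transects_to_frame(transects).to_csv(path, index=False)


def read_transects_csv(path: str | Path) -> list[TransectRecord]:
    return frame_to_transects(pd.read_csv(path))
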