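"""Synthetic study world: climate grids, occupancy truth, occurrences, futures.

The generator emulates the statistical structure the analysis assumes for a
threshold-limited range: a cool, dry core region inside a larger, hotter and
wetter-in-the-dry-season background. Maximum temperature of the warmest month
rises with distance from the core and dry-season precipitation does likewise,
so true occupancy — a product of two declining logistics in those bands — is
high only near the core. The remaining three bands are spatially smooth
nuisance fields carrying no occupancy signal.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import ConfigurationError, SchemaError, UnsampleableError
from .grids import BAND_NAMES, ClimateGrid, GridGeometry, ScenarioSpec, require_bands
from .occurrence import GeoPoint, TransectRecord

#: Default per-band noise standard deviations (band units).
DEFAULT_NOISE_SD: dict[str, float] = {
    "bio_maxtemp": 0.5,
    "bio_tseason": 40.0,
    "bio_trange": 0.4,
    "bio_pwet": 12.0,
    "bio_pdry": 10.0,
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Parameters of the synthetic study region.

    The default extent is the pseudo-absence region used for model building
    (1.86-6.87 N, 33.17-43.67 E) at 0.05 degree resolution; the cool-dry core
    sits near the species' core range. Occupancy declines through a logistic
    of width `temp_softness` around `temp_threshold` (degC) and one of width
    `precip_softness` around `precip_threshold` (mm of dry-season rain).
    """

    extent: tuple[float, float, float, float] = (33.17, 43.67, 1.86, 6.87)
    resolution: float = 0.05
    core_center: tuple[float, float] = (38.2, 4.75)
    temp_threshold: float = 33.0
    temp_softness: float = 1.0
    precip_threshold: float = 60.0
    precip_softness: float = 5.0
    core_temp: float = 28.0
    temp_gradient: float = 3.0  # degC per degree of distance from the core
    # the dry pole is displaced from the thermal core and its gradient is
    # anisotropic, so the two governing bands are distinct constraints rather
    # than one collinear signal; the occupied zone is their intersection
    precip_center: tuple[float, float] = (36.9, 5.6)
    precip_anisotropy: tuple[float, float] = (0.7, 1.4)  # lon/lat stretch
    core_precip: float = 25.0
    precip_gradient: float = 25.0  # mm per degree of distance from the dry pole
    field_smoothing_scale: float = 5.0  # cells (Gaussian sigma)
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    n_presence: int = 500
    n_transects: int = 255
    transect_length_km: float = 1.0
    detection_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ConfigurationError("extent is degenerate (min must be < max)")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.temp_softness <= 0 or self.precip_softness <= 0:
            raise ConfigurationError("threshold softness parameters must be positive")
        if not (0 < self.detection_prob <= 1):
            raise ConfigurationError("detection_prob must be in (0, 1]")
        if self.n_presence < 0 or self.n_transects < 0:
            raise ConfigurationError("sample counts must be non-negative")

    @property
    def geometry(self) -> GridGeometry:
        lon_min, lon_max, lat_min, lat_max = self.extent
        return GridGeometry.from_extent(lon_min, lon_max, lat_min, lat_max,
                                        self.resolution)


@dataclass
class OccupancySurface:
    """True per-cell probability of occurrence; geometry matches its source grid."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.geometry.shape:
            raise SchemaError("occupancy values do not match the grid geometry")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise SchemaError("occupancy values must lie in [0, 1]")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float, sd: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to standard deviation `sd`."""
    if sd == 0:
        return np.zeros(shape)
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    s = z.std()
    if s > 0:
        z *= sd / s
    return z


def generate_climate_grid(config: SyntheticWorldConfig) -> ClimateGrid:
    """Five-band synthetic climate stack for current conditions.

    bio_maxtemp increases radially away from the thermal core; bio_pdry
    increases (anisotropically) away from the displaced dry pole; both carry
    smoothed noise. The remaining three bands are smooth nuisance fields
    (mild directional gradients plus smoothed noise).
    """
    geom = config.geometry
    rng = np.random.default_rng(config.seed)
    lon, lat = geom.center_mesh()
    clon, clat = config.core_center
    # distance from the core in degrees, longitude scaled by cos(latitude)
    d = np.hypot((lon - clon) * math.cos(math.radians(clat)), lat - clat)
    plon, plat = config.precip_center
    ax, ay = config.precip_anisotropy
    dp = np.hypot(ax * (lon - plon) * math.cos(math.radians(plat)),
                  ay * (lat - plat))
    sigma = config.field_smoothing_scale
    sd = {**DEFAULT_NOISE_SD, **dict(config.noise_sd)}

    bands = {
        "bio_maxtemp": config.core_temp + config.temp_gradient * d
        + _smooth_noise(rng, geom.shape, sigma, sd["bio_maxtemp"]),
        "bio_tseason": 1500.0 + 30.0 * (lon - geom.lon_min)
        + _smooth_noise(rng, geom.shape, sigma, sd["bio_tseason"]),
        "bio_trange": 18.0 + 0.4 * (lat - geom.lat_min)
        + _smooth_noise(rng, geom.shape, sigma, sd["bio_trange"]),
        "bio_pwet": 320.0 - 10.0 * (lat - geom.lat_min)
        + _smooth_noise(rng, geom.shape, sigma, sd["bio_pwet"]),
        "bio_pdry": np.maximum(
            0.0,
            config.core_precip + config.precip_gradient * dp
            + _smooth_noise(rng, geom.shape, sigma, sd["bio_pdry"]),
        ),
    }
    assert tuple(bands) == BAND_NAMES
    return ClimateGrid(geom, bands, ScenarioSpec.current())


def true_occupancy(grid: ClimateGrid, config: SyntheticWorldConfig) -> OccupancySurface:
    """Product-of-logistics occupancy: soft upper thresholds on heat and dry-season rain.

    p = logistic((T0 - T)/sT) * logistic((P0 - P)/sP), so p -> 0 wherever
    maximum temperature or dry-season precipitation is far above its
    threshold, and p is non-increasing in both governing bands.
    """
    require_bands(grid, ("bio_maxtemp", "bio_pdry"))
    t = grid.band("bio_maxtemp")
    p = grid.band("bio_pdry")
    occ = expit((config.temp_threshold - t) / config.temp_softness) * expit(
        (config.precip_threshold - p) / config.precip_softness
    )
    return OccupancySurface(grid.geometry, occ)


def sample_presences(
    surface: OccupancySurface, n: int, seed: int
) -> list[GeoPoint]:
    """Presence points drawn with probability proportional to cell occupancy.

    Points are jittered uniformly within their cell so they do not stack on
    cell centres.
    """
    if n == 0:
        return []
    w = surface.values.ravel().astype(float)
    total = w.sum()
    if total <= 0:
        raise UnsampleableError("occupancy surface is identically zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(w.size, size=n, p=w / total)
    rows, cols = np.unravel_index(idx, surface.geometry.shape)
    r = surface.geometry.resolution
    lon = surface.geometry.lon_min + (cols + rng.random(n)) * r
    lat = surface.geometry.lat_min + (rows + rng.random(n)) * r
    return [GeoPoint(lo, la) for lo, la in zip(lon, lat)]


def _occupancy_at(surface: OccupancySurface, lon: np.ndarray,
                  lat: np.ndarray) -> np.ndarray:
    rows, cols, inside = surface.geometry.cell_index(lon, lat)
    rows = np.clip(rows, 0, surface.geometry.n_rows - 1)
    cols = np.clip(cols, 0, surface.geometry.n_cols - 1)
    return surface.values[rows, cols]


def simulate_transects(
    surface: OccupancySurface,
    n_transects: int,
    length_km: float,
    detection_prob: float,
    seed: int,
) -> list[TransectRecord]:
    """Walked straight transects with Bernoulli detection.

    Start points are stratified-random over a regular macro-grid covering the
    extent (so some transects fall well outside the occupied core); each
    transect is one straight segment of `length_km` at a random bearing, and
    the detection flag is Bernoulli(detection_prob x mean occupancy along the
    transect).
    """
    if n_transects <= 0:
        raise ConfigurationError("n_transects must be positive")
    geom = surface.geometry
    width_km = (geom.lon_max - geom.lon_min) * 111.32 * math.cos(
        math.radians((geom.lat_min + geom.lat_max) / 2)
    )
    height_km = (geom.lat_max - geom.lat_min) * 111.32
    if length_km > min(width_km, height_km):
        raise ConfigurationError("transect length exceeds the grid extent")

    rng = np.random.default_rng(seed)
    # macro-grid with roughly square blocks, at least n_transects of them
    aspect = (geom.lon_max - geom.lon_min) / (geom.lat_max - geom.lat_min)
    nby = max(1, int(math.sqrt(n_transects / aspect)))
    nbx = max(1, math.ceil(n_transects / nby))
    block_w = (geom.lon_max - geom.lon_min) / nbx
    block_h = (geom.lat_max - geom.lat_min) / nby

    out: list[TransectRecord] = []
    for i in range(n_transects):
        bx, by = (i % (nbx * nby)) % nbx, (i % (nbx * nby)) // nbx
        lon0 = geom.lon_min + (bx + rng.random()) * block_w
        lat0 = geom.lat_min + (by + rng.random()) * block_h
        theta = rng.uniform(0, 2 * math.pi)
        for _ in range(2):  # flip bearing if the endpoint leaves the extent
            dlat = length_km / 111.32 * math.sin(theta)
            dlon = length_km / (111.32 * math.cos(math.radians(lat0))) * math.cos(theta)
            lon1, lat1 = lon0 + dlon, lat0 + dlat
            if (geom.lon_min <= lon1 <= geom.lon_max
                    and geom.lat_min <= lat1 <= geom.lat_max):
                break
            theta += math.pi
        ts = np.linspace(0.0, 1.0, 11)
        occ = _occupancy_at(surface, lon0 + ts * (lon1 - lon0),
                            lat0 + ts * (lat1 - lat0)).mean()
        detected = bool(rng.random() < detection_prob * occ)
        out.append(TransectRecord(GeoPoint(lon0, lat0), GeoPoint(lon1, lat1), detected))
    return out


def generate_future_grid(
    current: ClimateGrid,
    gcm_delta: Mapping[str, float],
    scenario: ScenarioSpec,
) -> ClimateGrid:
    """Future climate stack: band-wise additive offsets to the current grid.

    `gcm_delta` must supply an offset (zero allowed) for every band of the
    input. Geometry is unchanged; the output carries the scenario metadata.
    """
    missing = [b for b in current.bands if b not in gcm_delta]
    if missing:
        raise SchemaError(f"gcm_delta missing offsets for band(s): {missing}")
    bands = {name: arr + float(gcm_delta[name]) for name, arr in current.bands.items()}
    return ClimateGrid(current.geometry, bands, scenario)


# -- stock GCM delta sets ------------------------------------------------------

#: Six synthetic GCM labels standing in for a multi-model ensemble.
DEFAULT_GCM_IDS = ("GCM-A", "GCM-B", "GCM-C", "GCM-D", "GCM-E", "GCM-F")

# Regional mean warming (degC over current) by RCP and horizon year; values
# bracket the IPCC-range global means with modest tropical amplification.
_MEAN_WARMING = {
    (2.6, 2050): 1.2, (4.5, 2050): 1.6, (6.0, 2050): 1.8, (8.5, 2050): 2.2,
    (2.6, 2070): 1.3, (4.5, 2070): 2.1, (6.0, 2070): 2.6, (8.5, 2070): 3.6,
}
# Across-GCM spread: offsets of each model from the RCP mean (degC).
_GCM_SPREAD = (-0.75, -0.45, -0.15, 0.15, 0.45, 0.75)
# Dry-season precipitation change (mm) per RCP/year: little systematic change,
# mild wetting at higher forcing (warming, not rainfall, drives the declines).
_PDRY_DELTA = {
    (2.6, 2050): 0.0, (4.5, 2050): 1.0, (6.0, 2050): 1.0, (8.5, 2050): 2.0,
    (2.6, 2070): 1.0, (4.5, 2070): 2.0, (6.0, 2070): 3.0, (8.5, 2070): 4.0,
}
# Per-GCM precipitation disagreement (mm).
_GCM_PDRY_SPREAD = (-4.0, 3.0, -2.0, 1.0, 4.0, -1.0)


def default_gcm_deltas(
    rcp: float, year: int, gcm_ids: Sequence[str] = DEFAULT_GCM_IDS
) -> dict[str, dict[str, float]]:
    """Stock additive climate deltas per GCM for one RCP/year scenario.

    Warming is applied to all three temperature bands; dry-season
    precipitation shifts by the RCP trend plus a per-GCM disagreement term;
    wet-season precipitation is left unchanged.
    """
    key = (float(rcp), int(year))
    if key not in _MEAN_WARMING:
        raise ConfigurationError(f"no stock deltas for rcp={rcp}, year={year}")
    warm = _MEAN_WARMING[key]
    pdry = _PDRY_DELTA[key]
    out = {}
    for i, gcm in enumerate(gcm_ids):
        dt = warm + _GCM_SPREAD[i % len(_GCM_SPREAD)]
        dp = pdry + _GCM_PDRY_SPREAD[i % len(_GCM_PDRY_SPREAD)]
        out[gcm] = {
            "bio_maxtemp": dt,
            "bio_tseason": 20.0 * dt,
            "bio_trange": 0.2 * dt,
            "bio_pwet": 0.0,
            "bio_pdry": dp,
        }
    return out
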