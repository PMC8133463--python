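"""Gridded climate data: geometry, the five-band climate stack, and text raster I/O.

Grids are regular lon/lat rasters. Band arrays are stored with row index
increasing northward (row 0 is the southernmost row); the ESRI ASCII writer
flips to the format's top-down order. Each grid carries scenario metadata
(current conditions, or a GCM x RCP x year future).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

#: The five bioclimatic covariates, in canonical order: maximum temperature of
#: the warmest month (degC), temperature seasonality, annual temperature range
#: (degC), precipitation of the wettest quarter (mm), precipitation of the
#: driest quarter (mm).
BAND_NAMES: tuple[str, ...] = (
    "bio_maxtemp",
    "bio_tseason",
    "bio_trange",
    "bio_pwet",
    "bio_pdry",
)

#: Kilometres per degree of latitude (and of longitude at the equator).
KM_PER_DEGREE = 111.32

VALID_RCPS = (2.6, 4.5, 6.0, 8.5)
VALID_YEARS = (2050, 2070)


@dataclass(frozen=True)
class ScenarioSpec:
    """Identifies the climate scenario a grid represents.

    ``gcm``, ``rcp`` and ``year`` are set only for future scenarios; the
    distinguished current-conditions scenario has all three unset.
    """

    gcm: str | None = None
    rcp: float | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        future_fields = (self.gcm, self.rcp, self.year)
        if any(f is not None for f in future_fields) and any(
            f is None for f in future_fields
        ):
            raise ConfigurationError(
                "scenario must set gcm, rcp and year together (or none of them)"
            )
        if self.rcp is not None and self.rcp not in VALID_RCPS:
            raise ConfigurationError(f"rcp must be one of {VALID_RCPS}, got {self.rcp}")
        if self.year is not None and self.year not in VALID_YEARS:
            raise ConfigurationError(
                f"year must be one of {VALID_YEARS}, got {self.year}"
            )

    @property
    def is_current(self) -> bool:
        return self.gcm is None

    @classmethod
    def current(cls) -> "ScenarioSpec":
        return cls()

    def label(self) -> str:
        if self.is_current:
            return "current"
        return f"{self.gcm}_rcp{self.rcp}_{self.year}"


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid: west/south origin, square cells of `resolution` degrees."""

    lon_min: float
    lat_min: float
    resolution: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigurationError("grid must have at least one cell")

    @classmethod
    def from_extent(
        cls, lon_min: float, lon_max: float, lat_min: float, lat_max: float,
        resolution: float,
    ) -> "GridGeometry":
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ConfigurationError("extent is degenerate (min must be < max)")
        if resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        # ceil so the grid always covers the requested extent
        n_cols = max(1, math.ceil((lon_max - lon_min) / resolution - 1e-9))
        n_rows = max(1, math.ceil((lat_max - lat_min) / resolution - 1e-9))
        return cls(lon_min, lat_min, resolution, n_cols, n_rows)

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.resolution

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) cell-center arrays, each of shape (n_rows, n_cols)."""
        return np.meshgrid(self.lon_centers, self.lat_centers)

    def cell_index(
        self, lon: np.ndarray, lat: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) of the containing cell.

        Points exactly on a cell edge belong to the cell to the north-east
        (the floor convention). Returns (rows, cols, inside) where ``inside``
        flags points within the grid extent.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        cols = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        rows = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        inside = (cols >= 0) & (cols < self.n_cols) & (rows >= 0) & (rows < self.n_rows)
        return rows, cols, inside

    def cell_area_km2(self) -> np.ndarray:
        """Per-row cell area (km^2): cosine-latitude rectangle approximation."""
        side = self.resolution * KM_PER_DEGREE
        return side * side * np.cos(np.radians(self.lat_centers))


@dataclass
class ClimateGrid:
    """A multi-band climate raster plus scenario metadata."""

    geometry: GridGeometry
    bands: dict[str, np.ndarray]
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec.current)

    def __post_init__(self) -> None:
        for name, arr in self.bands.items():
            if arr.shape != self.geometry.shape:
                raise SchemaError(
                    f"band {name!r} has shape {arr.shape}, "
                    f"expected {self.geometry.shape}"
                )

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise SchemaError(f"grid has no band {name!r}") from None

    def extract(self, lon: np.ndarray, lat: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
        """Band values of the cell containing each point.

        Returns (frame, inside): one row per input point (off-grid rows are
        NaN) and the boolean inside-extent mask.
        """
        rows, cols, inside = self.geometry.cell_index(lon, lat)
        out = {}
        r = np.where(inside, rows, 0)
        c = np.where(inside, cols, 0)
        for name, arr in self.bands.items():
            vals = arr[r, c].astype(float)
            vals[~inside] = np.nan
            out[name] = vals
        return pd.DataFrame(out), inside

    def as_table(self) -> pd.DataFrame:
        """All cells as a flat table of band values (row-major, south to north)."""
        return pd.DataFrame({k: v.ravel() for k, v in self.bands.items()})

    def with_scenario(self, scenario: ScenarioSpec) -> "ClimateGrid":
        return replace(self, scenario=scenario)

    # -- text raster I/O ---------------------------------------------------

    def write_dir(self, path: str | Path) -> Path:
        """Write one ESRI ASCII raster per band plus a JSON metadata sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.bands.items():
            write_ascii_raster(path / f"{name}.asc", self.geometry, arr)
        meta = {
            "bands": list(self.bands),
            "scenario": {
                "gcm": self.scenario.gcm,
                "rcp": self.scenario.rcp,
                "year": self.scenario.year,
            },
        }
        (path / "grid.json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def read_dir(cls, path: str | Path) -> "ClimateGrid":
        path = Path(path)
        meta_file = path / "grid.json"
        if not meta_file.exists():
            raise SchemaError(f"{path} is not a grid directory (grid.json missing)")
        meta = json.loads(meta_file.read_text())
        geometry = None
        bands: dict[str, np.ndarray] = {}
        for name in meta["bands"]:
            geom, arr = read_ascii_raster(path / f"{name}.asc")
            if geometry is None:
                geometry = geom
            elif geom != geometry:
                raise SchemaError(f"band {name!r} geometry differs from the stack")
            bands[name] = arr
        s = meta["scenario"]
        scenario = ScenarioSpec(gcm=s["gcm"], rcp=s["rcp"], year=s["year"])
        assert geometry is not None
        return cls(geometry, bands, scenario)


def write_ascii_raster(
    path: str | Path, geometry: GridGeometry, values: np.ndarray,
    nodata: float = -9999.0,
) -> None:
    """Write a single band as an ESRI ASCII grid (text)."""
    arr = np.array(values, dtype=float)
    arr[~np.isfinite(arr)] = nodata
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.lon_min!r}\n"
        f"yllcorner {geometry.lat_min!r}\n"
        f"cellsize {geometry.resolution!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # .asc stores rows north-to-south
        np.savetxt(fh, arr[::-1], fmt="%.10g")


def read_ascii_raster(path: str | Path) -> tuple[GridGeometry, np.ndarray]:
    """Read an ESRI ASCII grid back into (geometry, south-up array)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)[::-1].copy()
    nodata = header.get("nodata_value", -9999.0)
    arr[arr == nodata] = np.nan
    geometry = GridGeometry(
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        resolution=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    if arr.shape != geometry.shape:
        raise SchemaError(f"{path}: data shape {arr.shape} != header {geometry.shape}")
    return geometry, arr


def iter_band_pairs(grids: list[ClimateGrid]) -> Iterator[tuple[str, np.ndarray]]:
    for g in grids:
        for name, arr in g.bands.items():
            yield name, arr


def require_bands(grid: ClimateGrid, names: Mapping[str, str] | tuple[str, ...]) -> None:
    missing = [n for n in names if n not in grid.bands]
    if missing:
        raise SchemaError(f"grid is missing required band(s): {missing}")
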