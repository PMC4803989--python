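"""Readers/writers and coordinate conventions for the exposure pipeline.

All coordinates are WGS84 longitude/latitude in decimal degrees; all
distances are great-circle kilometres (haversine, Earth radius
6371.0088 km).  Rasters are exchanged as ESRI ASCII grids — a plain-text
format that round-trips bit-exactly and needs no binary dependency.
Grids are cell-centre addressed: row 0 is the *southern* row internally,
and cell (r, c) has centre (lon0 + c*cell, lat0 + r*cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

#: GPWv3-style 2.5 arc-minute cell size, in decimal degrees.
DEFAULT_CELL_SIZE = 2.5 / 60.0


@dataclass(frozen=True)
class StationRecord:
    """One monitor: location plus its long-term mean O3 concentration (ppb)."""

    station_id: str
    lon: float
    lat: float
    conc: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(
                f"station {self.station_id!r}: lon {self.lon} outside [-180, 180]"
            )
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(
                f"station {self.station_id!r}: lat {self.lat} outside [-90, 90]"
            )
        if self.conc < 0:
            raise ValueError(
                f"station {self.station_id!r}: negative concentration {self.conc}"
            )


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat raster geometry, addressed by cell centres.

    ``lon0``/``lat0`` are the centre of the lower-left (south-west) cell.
    """

    lon0: float
    lat0: float
    cell_size: float
    n_lon: int
    n_lat: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("n_lon and n_lat must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.lon0 + col * self.cell_size, self.lat0 + row * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lons, lats) arrays of shape (n_lat, n_lon)."""
        lons = self.lon0 + np.arange(self.n_lon) * self.cell_size
        lats = self.lat0 + np.arange(self.n_lat) * self.cell_size
        return np.meshgrid(lons, lats)


@dataclass
class ExposureGrid:
    """Raster of concentrations (ppb) with a validity mask (True = inside study area)."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spec.shape:
            raise ValueError("mask shape mismatch")
        inside = self.values[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("non-finite values on unmasked cells")


@dataclass
class RegionMap:
    """Integer region code per cell plus a code → name mapping.

    Must share the exposure grid's :class:`GridSpec` exactly; resampling is
    out of scope.
    """

    spec: GridSpec
    codes: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.spec.shape:
            raise ValueError("region codes shape mismatch")

    @property
    def region_names(self) -> list[str]:
        return list(self.names.values())

    def cells_of(self, region: str) -> np.ndarray:
        """Boolean raster selecting the named region's cells."""
        for code, name in self.names.items():
            if name == region:
                return self.codes == code
        raise KeyError(f"region {region!r} not in map (have {self.region_names})")


@dataclass(frozen=True)
class RegionBurden:
    """Per-region population >=25 and DALY burden totals."""

    region: str
    pop25: float
    total_dalys: float
    copd_dalys: float
    copd_male: float
    copd_female: float

    def __post_init__(self) -> None:
        for name in ("pop25", "total_dalys", "copd_dalys", "copd_male", "copd_female"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.region}: {name} must be >= 0")
        if self.copd_dalys > self.total_dalys:
            raise ValueError(f"{self.region}: COPD DALYs exceed total DALYs")
        if abs(self.copd_male + self.copd_female - self.copd_dalys) > 1.0:
            raise ValueError(
                f"{self.region}: male+female COPD DALYs differ from total by >1"
            )


# ---------------------------------------------------------------------------
# distance


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance between two (lon, lat) points in kilometres."""
    lon1, lat1 = math.radians(a[0]), math.radians(a[1])
    lon2, lat2 = math.radians(b[0]), math.radians(b[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def haversine_matrix(
    lons1: np.ndarray, lats1: np.ndarray, lons2: np.ndarray, lats2: np.ndarray
) -> np.ndarray:
    """Pairwise great-circle distances (km), shape (len(1), len(2))."""
    lam1 = np.radians(np.asarray(lons1, float))[:, None]
    phi1 = np.radians(np.asarray(lats1, float))[:, None]
    lam2 = np.radians(np.asarray(lons2, float))[None, :]
    phi2 = np.radians(np.asarray(lats2, float))[None, :]
    h = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


# ---------------------------------------------------------------------------
# station table


def read_stations(path) -> list[StationRecord]:
    """Read a delimited station table (station_id, lon, lat, conc)."""
    df = pd.read_csv(path)
    required = {"station_id", "lon", "lat", "conc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station table missing columns: {sorted(missing)}")
    dupes = df["station_id"].astype(str)[df["station_id"].astype(str).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate station_id: {dupes.iloc[0]!r}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                StationRecord(
                    station_id=str(row["station_id"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    conc=float(row["conc"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"station table row {i}: {exc}") from exc
    return records


def write_stations(stations: list[StationRecord], path) -> None:
    pd.DataFrame(
        [
            {"station_id": s.station_id, "lon": s.lon, "lat": s.lat, "conc": s.conc}
            for s in stations
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid

_ESRI_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
_NODATA_DEFAULT = -9999.0


def read_grid(path) -> ExposureGrid:
    """Read an ESRI ASCII grid; NODATA cells become masked.

    The header's corner coordinates are converted to cell-centre addressing
    (centre = corner + cellsize/2).
    """
    with open(path) as fh:
        header: dict[str, float] = {}
        line = fh.readline()
        while line:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ESRI_KEYS + ("nodata_value",):
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError as exc:
                    raise ValueError(f"ESRI ASCII header: bad value for {parts[0]!r}") from exc
                line = fh.readline()
            else:
                break
        for key in _ESRI_KEYS:
            if key not in header:
                raise ValueError(f"ESRI ASCII header missing {key!r}")
        nodata = header.get("nodata_value", _NODATA_DEFAULT)
        body = line + fh.read()
    data = np.loadtxt(body.splitlines(), dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid body shape {data.shape} != ({nrows}, {ncols})")
    cell = header["cellsize"]
    spec = GridSpec(
        lon0=header["xllcorner"] + cell / 2,
        lat0=header["yllcorner"] + cell / 2,
        cell_size=cell,
        n_lon=ncols,
        n_lat=nrows,
    )
    data = data[::-1]  # file stores north-up; internal row 0 is south
    mask = data != nodata
    values = np.where(mask, data, np.nan)
    return ExposureGrid(spec=spec, values=values, mask=mask)


def write_grid(grid: ExposureGrid, path, significant_digits: int = 6) -> None:
    """Write an ESRI ASCII grid (north-up), NODATA = -9999."""
    spec = grid.spec
    out = np.where(grid.mask, grid.values, _NODATA_DEFAULT)[::-1]
    fmt = f"%.{significant_digits}g"
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_lon}\n")
        fh.write(f"nrows {spec.n_lat}\n")
        fh.write(f"xllcorner {spec.lon0 - spec.cell_size / 2!r}\n")
        fh.write(f"yllcorner {spec.lat0 - spec.cell_size / 2!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA_DEFAULT:g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# region map + burden table


def read_region_map(grid_path, names_path) -> RegionMap:
    """Region map = ESRI ASCII grid of integer codes + sidecar CSV (code, region_name)."""
    grid = read_grid(grid_path)
    names_df = pd.read_csv(names_path)
    names = {int(r["code"]): str(r["region_name"]) for _, r in names_df.iterrows()}
    codes = np.where(grid.mask, grid.values, -1).astype(int)
    present = set(np.unique(codes[grid.mask]).tolist())
    unknown = present - set(names)
    if unknown:
        raise ValueError(f"region codes {sorted(unknown)} missing from sidecar table")
    return RegionMap(spec=grid.spec, codes=codes, names=names)


def write_region_map(regions: RegionMap, grid_path, names_path) -> None:
    grid = ExposureGrid(
        spec=regions.spec,
        values=regions.codes.astype(float),
        mask=regions.codes >= 0,
    )
    write_grid(grid, grid_path)
    pd.DataFrame(
        [{"code": c, "region_name": n} for c, n in sorted(regions.names.items())]
    ).to_csv(names_path, index=False)


BURDEN_COLUMNS = ["region", "pop25", "total_dalys", "copd_dalys", "copd_male", "copd_female"]


def read_burden_table(path) -> list[RegionBurden]:
    df = pd.read_csv(path)
    missing = set(BURDEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"burden table missing columns: {sorted(missing)}")
    return [
        RegionBurden(
            region=str(r["region"]),
            pop25=float(r["pop25"]),
            total_dalys=float(r["total_dalys"]),
            copd_dalys=float(r["copd_dalys"]),
            copd_male=float(r["copd_male"]),
            copd_female=float(r["copd_female"]),
        )
        for _, r in df.iterrows()
    ]


def write_burden_table(burdens: list[RegionBurden], path) -> None:
    pd.DataFrame(
        [{c: getattr(b, c) for c in BURDEN_COLUMNS} for b in burdens]
    ).to_csv(path, index=False)
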