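"""Raster and occurrence I/O for gridded climate analyses.

All layers live on a single geographic (lon/lat) grid.  Row 0 is the
northernmost row; cells are half-open, so a point lying exactly on a shared
edge belongs to the cell to its south-east.  Supported raster formats are
ESRI ASCII grid (``.asc``) and single-band GeoTIFF (``.tif``/``.tiff``)
with ``ModelPixelScale``/``ModelTiepoint`` georeferencing tags.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIABLES = ("tmax", "tmin", "prec")

SEASONS = ("breeding", "winter", "migratory", "excluded")

#: Default month -> season labelling.  Breeding records are compiled from
#: late spring through mid summer, winter from December to February; April
#: and September-November are migratory transit months, and March/August are
#: transitional months that cannot be assigned with confidence.
DEFAULT_SEASON_OF_MONTH: dict[int, str] = {
    1: "winter",
    2: "winter",
    3: "excluded",
    4: "migratory",
    5: "breeding",
    6: "breeding",
    7: "breeding",
    8: "excluded",
    9: "migratory",
    10: "migratory",
    11: "migratory",
    12: "winter",
}

#: Months whose layers enter each season's model.  The breeding model uses
#: May-June only (the months of peak breeding suitability), even though
#: July records carry the breeding label.
SEASON_MODEL_MONTHS: dict[str, tuple[int, ...]] = {
    "breeding": (5, 6),
    "winter": (12, 1, 2),
    "migratory": (4, 9, 10, 11),
}

MIGRATORY_MONTHS = (4, 9, 10, 11)

# GeoTIFF tag codes for georeferencing and nodata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_FILENAME_RE = re.compile(r"(tmax|tmin|prec)[_-](\d{1,2})")


@dataclass(frozen=True)
class GridSpec:
    """Georeferenced grid: ``(x_origin, y_origin)`` is the outer corner of
    the top-left cell, rows run north to south."""

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = -9999.0
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid edges."""
        return (
            self.x_origin,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin - self.n_rows * self.cell_size,
            self.y_origin,
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the cell containing the point, or None outside the
        grid.  Half-open cells: a point on a shared edge falls in the cell
        to its south-east."""
        col = math.floor((lon - self.x_origin) / self.cell_size)
        row = math.floor((self.y_origin - lat) / self.cell_size)
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class Layer:
    """One gridded climate variable for one month.

    ``values`` stores the raster with ``grid.nodata`` marking missing cells;
    temperatures are in degrees C, precipitation in mm.
    """

    grid: GridSpec
    variable: str | None
    month: int | None
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.variable == "prec":
            data = self.values[~self.nodata_mask]
            if data.size and (data < 0).any():
                raise ValueError("precipitation must be non-negative where not nodata")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isclose(self.values, self.grid.nodata) | np.isnan(self.values)

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out


class ClimateStack:
    """Monthly climate layers keyed by ``(variable, month)``.

    All layers must share one grid, and every month present must carry all
    three variables (tmax, tmin, prec).
    """

    def __init__(self, layers: Iterable[Layer]):
        self._layers: dict[tuple[str, int], Layer] = {}
        for layer in layers:
            if layer.variable is None or layer.month is None:
                raise ValueError("stack layers need both variable and month set")
            key = (layer.variable, layer.month)
            if key in self._layers:
                raise ValueError(f"duplicate layer {key}")
            self._layers[key] = layer
        if not self._layers:
            raise ValueError("empty climate stack")
        grids = [l.grid for l in self._layers.values()]
        for g in grids[1:]:
            if not grids[0].approx_equal(g):
                raise ValueError("all layers in a stack must share one grid")
        for month in self.months:
            for var in VARIABLES:
                if (var, month) not in self._layers:
                    raise ValueError(f"month {month} missing variable {var}")

    @property
    def grid(self) -> GridSpec:
        return next(iter(self._layers.values())).grid

    @property
    def months(self) -> tuple[int, ...]:
        return tuple(sorted({m for _, m in self._layers}))

    def get(self, variable: str, month: int) -> Layer:
        return self._layers[(variable, month)]

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._layers

    def season_mean(self, variable: str, months: Sequence[int]) -> np.ndarray:
        """Mean of a variable over the given months, NaN where any month is
        nodata."""
        stacked = np.stack([self.get(variable, m).masked() for m in months])
        return stacked.mean(axis=0)

    def env_grid(self, months: Sequence[int]) -> np.ndarray:
        """(n_rows, n_cols, 3) array of season-mean tmax/tmin/prec, NaN at
        nodata."""
        return np.stack([self.season_mean(v, months) for v in VARIABLES], axis=-1)


@dataclass(frozen=True)
class OccurrenceRecord:
    id: str
    lon: float
    lat: float
    month: int
    season: str | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")


@dataclass
class OccurrenceSet:
    records: list[OccurrenceRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset_season(self, season: str) -> "OccurrenceSet":
        return OccurrenceSet(
            [r for r in self.records if r.season == season],
            provenance=f"{self.provenance} [season={season}]",
        )

    def subset_month(self, month: int) -> "OccurrenceSet":
        return OccurrenceSet(
            [r for r in self.records if r.month == month],
            provenance=f"{self.provenance} [month={month}]",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "lon": [r.lon for r in self.records],
                "lat": [r.lat for r in self.records],
                "month": [r.month for r in self.records],
                "season": [r.season for r in self.records],
            }
        )


@dataclass
class EnvMatrix:
    """Dense environmental matrix: one row per record or cell, one column
    per climate variable; never contains nodata."""

    values: np.ndarray
    columns: tuple[str, ...]
    row_keys: list

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if len(self.row_keys) != self.values.shape[0]:
            raise ValueError("row_keys length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("EnvMatrix must not contain nodata/NaN entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Raster I/O


def _parse_variable_month(path: Path) -> tuple[str | None, int | None]:
    m = _FILENAME_RE.search(path.stem)
    if m:
        return m.group(1), int(m.group(2))
    return None, None


def read_raster(path: str | Path) -> Layer:
    """Read a single-band raster (ESRI ASCII grid or GeoTIFF) into a Layer.

    Variable and month are parsed from filenames like ``tmax_05.asc`` when
    present.  Missing georeferencing raises a ValueError naming the field.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        grid, values = _read_ascii(path)
    elif suffix in (".tif", ".tiff"):
        grid, values = _read_geotiff(path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    variable, month = _parse_variable_month(path)
    return Layer(grid=grid, variable=variable, month=month, values=values)


def write_raster(layer: Layer, path: str | Path) -> Path:
    """Write a Layer as ESRI ASCII grid or GeoTIFF, by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_ascii(layer, path)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(layer, path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    return path


def _read_ascii(path: Path) -> tuple[GridSpec, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not re.match(r"^[A-Za-z_]+$", parts[0]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(0)
        values = np.loadtxt(fh, skiprows=len(header), dtype=np.float64, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field '{key}'")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cell / 2
    else:
        raise ValueError(f"ASCII grid {path} missing header field 'xllcorner'")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cell / 2
    else:
        raise ValueError(f"ASCII grid {path} missing header field 'yllcorner'")
    nodata = header.get("nodata_value", -9999.0)
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"ASCII grid {path}: data shape {values.shape} does not match header"
        )
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=x0,
        y_origin=yll + n_rows * cell,
        cell_size=cell,
        nodata=nodata,
    )
    return grid, values


def _write_ascii(layer: Layer, path: Path) -> None:
    g = layer.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_origin!r}\n")
        fh.write(f"yllcorner {(g.y_origin - g.n_rows * g.cell_size)!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {g.nodata!r}\n")
        for row in layer.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path) -> tuple[GridSpec, np.ndarray]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        tags = {tag.code: tag.value for tag in page.tags.values()}
    if values.ndim != 2:
        raise ValueError(f"GeoTIFF {path} must be single-band")
    if _TAG_MODEL_PIXEL_SCALE not in tags:
        raise ValueError(f"GeoTIFF {path} missing georeferencing: ModelPixelScaleTag")
    if _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"GeoTIFF {path} missing georeferencing: ModelTiepointTag")
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    tie = tags[_TAG_MODEL_TIEPOINT]
    # raster point (i, j, k) maps to model point (x, y, z)
    i, j, _k, x, y, _z = tie[:6]
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
    grid = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        x_origin=x - i * sx,
        y_origin=y + j * sy,
        cell_size=sx,
        nodata=nodata,
    )
    if not np.isclose(sx, sy):
        raise ValueError(f"GeoTIFF {path}: non-square pixels not supported")
    return grid, values


def _write_geotiff(layer: Layer, path: Path) -> None:
    import tifffile

    g = layer.grid
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_origin, g.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(g.nodata)),
    ]
    tifffile.imwrite(str(path), layer.values, extratags=extratags)


def load_stack(
    directory: str | Path,
    months: Iterable[int] | None = None,
    pattern: str = "{var}_{month:02d}",
    fmt: str = "asc",
) -> ClimateStack:
    """Load a ClimateStack from a directory of per-variable, per-month
    rasters named e.g. ``tmax_05.asc``."""
    directory = Path(directory)
    layers = []
    months = list(months) if months is not None else list(range(1, 13))
    for month in months:
        for var in VARIABLES:
            path = directory / f"{pattern.format(var=var, month=month)}.{fmt}"
            if not path.exists():
                raise FileNotFoundError(path)
            layer = read_raster(path)
            layer.variable, layer.month = var, month
            layers.append(layer)
    return ClimateStack(layers)


def write_stack(
    stack: ClimateStack,
    directory: str | Path,
    pattern: str = "{var}_{month:02d}",
    fmt: str = "asc",
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for month in stack.months:
        for var in VARIABLES:
            write_raster(
                stack.get(var, month),
                directory / f"{pattern.format(var=var, month=month)}.{fmt}",
            )
    return directory


# ---------------------------------------------------------------------------
# Occurrence I/O and cleaning


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read occurrences from CSV with columns id, lon, lat and one of month
    or date (ISO-8601); an optional season column is preserved."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for req in ("id", "lon", "lat"):
        if req not in cols:
            raise ValueError(f"occurrence CSV missing required column '{req}'")
    if "month" in cols:
        months = df[cols["month"]].astype(int)
    elif "date" in cols:
        months = pd.to_datetime(df[cols["date"]]).dt.month
    else:
        raise ValueError("occurrence CSV needs a 'month' or 'date' column")
    seasons = df[cols["season"]] if "season" in cols else [None] * len(df)
    records = [
        OccurrenceRecord(
            id=str(i), lon=float(lo), lat=float(la), month=int(m),
            season=(None if s is None or (isinstance(s, float) and np.isnan(s)) else str(s)),
        )
        for i, lo, la, m, s in zip(
            df[cols["id"]], df[cols["lon"]], df[cols["lat"]], months, seasons
        )
    ]
    return OccurrenceSet(records, provenance=str(path))


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> Path:
    occ.to_frame().to_csv(path, index=False)
    return Path(path)


def assign_season(
    occ: OccurrenceSet, season_map: Mapping[int, str] | None = None
) -> OccurrenceSet:
    """Label every record with its season from a month -> season map.

    The default map assigns May-July to breeding, December-February to
    winter, April and September-November to the migratory period, and marks
    March and August as excluded transitional months.
    """
    season_map = dict(season_map) if season_map is not None else DEFAULT_SEASON_OF_MONTH
    records = []
    for r in occ.records:
        if r.month not in season_map:
            raise ValueError(f"record {r.id}: month {r.month} not in season map")
        records.append(replace(r, season=season_map[r.month]))
    return OccurrenceSet(records, provenance=occ.provenance)


def dedup_occurrences(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Keep at most one record per (grid cell, season), retaining the
    earliest record in input order.

    Records outside the grid extent are dropped with a warning rather than
    raising, since curated datasets routinely contain strays.
    """
    seen: set[tuple[int, int, str | None]] = set()
    kept: list[OccurrenceRecord] = []
    n_dup = n_outside = 0
    for r in occ.records:
        cell = grid.cell_of(r.lon, r.lat)
        if cell is None:
            n_outside += 1
            continue
        key = (cell[0], cell[1], r.season)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        kept.append(r)
    if n_outside:
        warnings.warn(
            f"dedup_occurrences: dropped {n_outside} record(s) outside the grid extent",
            stacklevel=2,
        )
    if n_dup:
        logger.info("dedup_occurrences: removed %d duplicate record(s)", n_dup)
    return OccurrenceSet(kept, provenance=occ.provenance)


def _resolve_months(selector: int | str | Iterable[int]) -> list[int]:
    if isinstance(selector, int):
        return [selector]
    if isinstance(selector, str):
        if selector not in SEASON_MODEL_MONTHS:
            raise ValueError(f"unknown season selector '{selector}'")
        return list(SEASON_MODEL_MONTHS[selector])
    return list(selector)


def extract_env(
    stack: ClimateStack,
    occ: OccurrenceSet,
    month_or_season: int | str | Iterable[int],
) -> EnvMatrix:
    """Climate values at the occurrence points.

    The selector is a month, an iterable of months, or a season name; for
    multi-month selectors each variable is averaged over the months.
    Records on nodata cells (or outside the grid) are dropped with a logged
    count.
    """
    months = _resolve_months(month_or_season)
    for m in months:
        if ("tmax", m) not in stack:
            raise ValueError(f"month {m} not present in stack")
    env = stack.env_grid(months)
    rows, keys = [], []
    n_dropped = 0
    for r in occ.records:
        cell = stack.grid.cell_of(r.lon, r.lat)
        if cell is None:
            n_dropped += 1
            continue
        vals = env[cell[0], cell[1]]
        if np.isnan(vals).any():
            n_dropped += 1
            continue
        rows.append(vals)
        keys.append(r.id)
    if n_dropped:
        warnings.warn(
            f"extract_env: dropped {n_dropped} record(s) on nodata or outside grid",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("extract_env: no records left after nodata filtering")
    return EnvMatrix(np.array(rows), VARIABLES, keys)


def cells_env(
    stack: ClimateStack,
    month_or_season: int | str | Iterable[int],
    mask: np.ndarray | None = None,
) -> EnvMatrix:
    """Season-mean climate for every non-nodata cell (optionally restricted
    to a boolean mask), keyed by flat cell index."""
    months = _resolve_months(month_or_season)
    env = stack.env_grid(months)
    valid = ~np.isnan(env).any(axis=-1)
    if mask is not None:
        valid &= mask.astype(bool)
    idx = np.flatnonzero(valid.ravel())
    if idx.size == 0:
        raise ValueError("cells_env: no valid cells selected")
    flat = env.reshape(-1, len(VARIABLES))
    return EnvMatrix(flat[idx], VARIABLES, idx.tolist())
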