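"""Internal structure of a modeled niche via distance to the centroid.

Climate variables over the modeled-presence cells are Z-standardized
(mean 0, sd 1, sample convention), so the niche centroid is the zero
vector.  Each cell's distance to the centroid (DC) is the Euclidean norm of
its standardized climate row; the DC raster is then classified into
optimal / suboptimal / marginal zones by ascending cutoffs.

The sum-of-squares under the distance is square-rooted: DC is a genuine
Euclidean metric, which the zone monotonicity properties require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geodata import ClimateStack, EnvMatrix, GridSpec, OccurrenceSet, _resolve_months
from .rulesets import SuitabilityMap

ZONE_LABELS = {1: "optimal", 2: "suboptimal", 3: "marginal"}

#: Default DC breakpoints between optimal/suboptimal and suboptimal/marginal
#: zones.  Zone cutoffs are data-derived in any given study; these defaults
#: make classification total by placing the breaks at the midpoints of the
#: conventional band gaps (optimal up to ~1.51, suboptimal to ~2.9,
#: marginal beyond).
DEFAULT_CUTOFFS = (1.515, 2.95)


@dataclass
class Standardization:
    """Per-variable mean and sample (n-1) standard deviation over the
    modeled-presence cells."""

    means: np.ndarray
    sds: np.ndarray
    columns: tuple[str, ...]
    ddof: int = 1

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        if (self.sds <= 0).any():
            raise ValueError("standard deviations must be > 0")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=np.float64) - self.means) / self.sds


@dataclass
class NicheStructure:
    standardization: Standardization
    dc: np.ndarray            # raster of distances, NaN outside the modeled area
    zones: np.ndarray         # integer raster 1/2/3, 0 outside
    cutoffs: tuple[float, float]
    grid: GridSpec


@dataclass
class ZoneAssignment:
    ids: list[str]
    dc: np.ndarray
    zones: np.ndarray  # integer codes

    @property
    def counts(self) -> dict[str, int]:
        return {
            label: int((self.zones == code).sum())
            for code, label in ZONE_LABELS.items()
        }


def standardize_env(cells: EnvMatrix, ddof: int = 1) -> tuple[Standardization, np.ndarray]:
    """Z-standardize each variable over the given cells.

    Returns the standardization parameters and the standardized matrix; by
    construction every column of the output has mean 0 and sd 1, so the
    niche centroid is the zero vector.  Constant variables are dropped with
    a warning.
    """
    if cells.n < 2:
        raise ValueError("need at least 2 cells to standardize")
    X = cells.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    keep = sds > 0
    if not keep.all():
        dropped = [c for c, k in zip(cells.columns, keep) if not k]
        warnings.warn(f"standardize_env: dropping constant variable(s) {dropped}",
                      stacklevel=2)
    cols = tuple(c for c, k in zip(cells.columns, keep) if k)
    if not cols:
        raise ValueError("all variables constant")
    std = Standardization(means[keep], sds[keep], cols, ddof)
    return std, std.transform(X[:, keep])


def centroid_distance(z_matrix: np.ndarray) -> np.ndarray:
    """Euclidean distance of each standardized row to the niche centroid
    (the origin): DC_i = sqrt(sum_j z_ij^2)."""
    z = np.atleast_2d(np.asarray(z_matrix, dtype=np.float64))
    return np.sqrt((z ** 2).sum(axis=1))


def classify_zones(
    dc: np.ndarray, cutoffs: Sequence[float] = DEFAULT_CUTOFFS
) -> np.ndarray:
    """Classify DC values into zones 1=optimal, 2=suboptimal, 3=marginal
    using contiguous bins [0, b1], (b1, b2], (b2, inf)."""
    b1, b2 = cutoffs
    if not 0 <= b1 < b2:
        raise ValueError("cutoffs must be ascending and non-negative")
    dc = np.asarray(dc, dtype=np.float64)
    if (dc < 0).any():
        raise ValueError("DC values must be non-negative")
    zones = np.full(dc.shape, 3, dtype=np.int8)
    zones[dc <= b2] = 2
    zones[dc <= b1] = 1
    return zones


def build_structure(
    stack: ClimateStack,
    suitability: SuitabilityMap,
    months: int | str | Sequence[int],
    cutoffs: Sequence[float] | str = DEFAULT_CUTOFFS,
) -> NicheStructure:
    """DC and zone rasters over the cells the model predicts present.

    ``cutoffs="auto"`` splits the observed DC range into three equal-width
    bins instead of using the default breakpoints.
    """
    months = _resolve_months(months)
    env = stack.env_grid(months)
    mask = suitability.binary & ~np.isnan(env).any(axis=-1)
    idx = np.flatnonzero(mask.ravel())
    if idx.size < 2:
        raise ValueError("fewer than 2 modeled-presence cells")
    flat = env.reshape(-1, env.shape[-1])
    from .geodata import VARIABLES

    cells = EnvMatrix(flat[idx], VARIABLES, idx.tolist())
    std, z = standardize_env(cells)
    dc_vals = centroid_distance(z)
    if isinstance(cutoffs, str):
        if cutoffs != "auto":
            raise ValueError(f"unknown cutoff mode '{cutoffs}'")
        lo, hi = float(dc_vals.min()), float(dc_vals.max())
        width = (hi - lo) / 3 or 1.0
        cut = (lo + width, lo + 2 * width)
    else:
        cut = (float(cutoffs[0]), float(cutoffs[1]))
    dc_raster = np.full(flat.shape[0], np.nan)
    dc_raster[idx] = dc_vals
    zone_raster = np.zeros(flat.shape[0], dtype=np.int8)
    zone_raster[idx] = classify_zones(dc_vals, cut)
    grid = stack.grid
    return NicheStructure(std, dc_raster.reshape(grid.shape),
                          zone_raster.reshape(grid.shape), cut, grid)


def classify_records(
    occ: OccurrenceSet,
    structure: NicheStructure,
    stack: ClimateStack,
    months: int | str | Sequence[int] | None = None,
) -> ZoneAssignment:
    """Locate records within a season's niche structure.

    Each record's climate (its own month's layers by default, or the
    season-mean over ``months``) is standardized with the SEASON's
    standardization, DC computed, zone assigned.  Records outside the
    modeled climate envelope still classify — they simply get a large DC.
    Records on nodata cells are excluded with a warning.
    """
    from .geodata import VARIABLES

    std = structure.standardization
    col_idx = [VARIABLES.index(c) for c in std.columns]
    rows, ids = [], []
    n_dropped = 0
    env_cache: dict[tuple[int, ...], np.ndarray] = {}
    for r in occ.records:
        sel = tuple([r.month] if months is None else _resolve_months(months))
        cell = stack.grid.cell_of(r.lon, r.lat)
        if cell is None:
            n_dropped += 1
            continue
        if sel not in env_cache:
            env_cache[sel] = stack.env_grid(list(sel))
        env = env_cache[sel][cell[0], cell[1]]
        if np.isnan(env).any():
            n_dropped += 1
            continue
        rows.append(env[col_idx])
        ids.append(r.id)
    if n_dropped:
        warnings.warn(
            f"classify_records: excluded {n_dropped} record(s) on nodata or "
            "outside the grid", stacklevel=2,
        )
    if not rows:
        return ZoneAssignment([], np.empty(0), np.empty(0, dtype=np.int8))
    z = std.transform(np.array(rows))
    dc = centroid_distance(z)
    zones = classify_zones(dc, structure.cutoffs)
    return ZoneAssignment(ids, dc, zones)
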