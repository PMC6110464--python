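"""Synthetic climate stacks and occurrences with known niche structure.

The generator stands in for field data: monthly climate surfaces are built
from a latitudinal gradient plus a seasonal cycle and smooth spatial noise,
and occurrences are drawn from a diagonal-Gaussian suitability surface in
climate space.  Because the ground-truth centroids, spreads and separations
are known, every downstream stage (model fit, structure, breadth,
similarity) can be checked for parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .geodata import (
    VARIABLES,
    ClimateStack,
    GridSpec,
    Layer,
    OccurrenceRecord,
    OccurrenceSet,
)

logger = logging.getLogger(__name__)

#: Records per season/month mirroring a realistic curated dataset for a
#: grassland migrant: 246 breeding, 83 winter, and 28/20/33/15 for
#: April/September/October/November.
DEFAULT_RECORD_COUNTS = {
    "breeding": 246,
    "winter": 83,
    "migratory": {4: 28, 9: 20, 10: 33, 11: 15},
}


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic monthly climate surfaces.

    tmax(month, row) = tmax_base + tmax_gradient*row
                       + seasonal_amplitude*cos(2*pi*(month-7)/12) + noise
    tmin = tmax minus a diurnal range with its own longitudinal gradient and
    texture; precipitation has its own gradients, amplitude and phase and is
    clipped at zero.
    """

    tmax_base: float = 10.0          # deg C at the northern edge, annual mean
    tmax_gradient: float = 0.25      # deg C per row going south (warms southward)
    seasonal_amplitude: float = 8.0  # deg C, half peak-to-trough of the cycle
    diurnal_offset: float = 10.0     # mean tmax - tmin, deg C
    diurnal_lon_gradient: float = 0.03  # deg C per column (continentality)
    diurnal_noise_sd: float = 0.5    # deg C spatial texture of the offset
    prec_base: float = 140.0         # mm at the north-west corner
    prec_gradient: float = -0.8      # mm per row going south (drier southward)
    prec_lon_gradient: float = 1.2   # mm per column going east (wetter eastward)
    prec_amplitude: float = 10.0     # mm seasonal half-range
    prec_phase_month: int = 7        # wettest month
    noise_sd: float = 1.0            # deg C amplitude of smooth noise
    prec_noise_sd: float = 4.0       # mm amplitude of smooth noise
    noise_smoothing: float = 6.0     # gaussian-filter sigma in cells


@dataclass(frozen=True)
class NicheSpec:
    """Ground-truth Gaussian niche: centroid and per-variable spread in
    climate units, with the season label and record count to draw."""

    centroid: tuple[float, float, float]
    spread: tuple[float, float, float]
    season: str
    n_records: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spread):
            raise ValueError("spreads must be > 0")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


@dataclass
class Scenario:
    stack: ClimateStack
    niches: list[NicheSpec]
    seed: int
    kind: str = "custom"
    season_months: dict = field(default_factory=dict)
    #: month -> NicheSpec for the per-month migratory draws
    migratory: dict[int, NicheSpec] = field(default_factory=dict)

    def niche(self, season: str) -> NicheSpec:
        for n in self.niches:
            if n.season == season:
                return n
        raise KeyError(season)


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma <= 0:
        return noise
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def make_climate_stack(
    grid: GridSpec,
    params: ClimateParams = ClimateParams(),
    seed: int = 0,
    months: Iterable[int] = range(1, 13),
) -> ClimateStack:
    """Build monthly tmax/tmin/prec layers on ``grid``.

    The same seed always yields a bit-identical stack.  The smooth noise
    field is drawn once per variable and held fixed across months so that
    season means inherit the same spatial texture.
    """
    rng = np.random.default_rng(seed)
    shape = grid.shape
    rows = np.arange(grid.n_rows, dtype=np.float64)[:, None] * np.ones((1, grid.n_cols))
    cols = np.ones((grid.n_rows, 1)) * np.arange(grid.n_cols, dtype=np.float64)[None, :]
    noise_t = _smooth_field(shape, params.noise_smoothing, rng) * params.noise_sd
    noise_p = _smooth_field(shape, params.noise_smoothing, rng) * params.prec_noise_sd
    # the diurnal range gets its own spatial structure so tmin is not a
    # constant shift of tmax (which would make the variables collinear)
    diurnal = (params.diurnal_offset
               + params.diurnal_lon_gradient * cols
               + _smooth_field(shape, params.noise_smoothing, rng) * params.diurnal_noise_sd)

    layers = []
    n_clipped = 0
    for m in months:
        cyc_t = params.seasonal_amplitude * np.cos(2 * np.pi * (m - 7) / 12.0)
        cyc_p = params.prec_amplitude * np.cos(
            2 * np.pi * (m - params.prec_phase_month) / 12.0
        )
        tmax = params.tmax_base + params.tmax_gradient * rows + cyc_t + noise_t
        tmin = tmax - diurnal
        prec = (params.prec_base + params.prec_gradient * rows
                + params.prec_lon_gradient * cols + cyc_p + noise_p)
        neg = prec < 0
        if neg.any():
            n_clipped += int(neg.sum())
            prec = np.where(neg, 0.0, prec)
        layers.append(Layer(grid, "tmax", m, tmax))
        layers.append(Layer(grid, "tmin", m, tmin))
        layers.append(Layer(grid, "prec", m, prec))
    if n_clipped:
        logger.info("make_climate_stack: clipped %d negative precipitation cells", n_clipped)
    return ClimateStack(layers)


def suitability(
    stack: ClimateStack, spec: NicheSpec, months: Sequence[int]
) -> np.ndarray:
    """Gaussian suitability s(cell) = exp(-0.5 * sum_v ((x_v - c_v)/sd_v)^2)
    on the season-mean climate; NaN at nodata."""
    env = stack.env_grid(months)
    c = np.asarray(spec.centroid, dtype=np.float64)
    s = np.asarray(spec.spread, dtype=np.float64)
    z2 = (((env - c) / s) ** 2).sum(axis=-1)
    return np.exp(-0.5 * z2)


def sample_occurrences(
    stack: ClimateStack,
    spec: NicheSpec,
    months: Sequence[int],
    seed: int,
    id_prefix: str | None = None,
) -> OccurrenceSet:
    """Draw ``spec.n_records`` cells without replacement with probability
    proportional to Gaussian suitability on the season-mean climate; one
    record per cell with its month drawn uniformly from ``months``."""
    months = list(months)
    if not months:
        raise ValueError("months must be non-empty")
    rng = np.random.default_rng(seed)
    s = suitability(stack, spec, months)
    flat = np.nan_to_num(s.ravel(), nan=0.0)
    n_positive = int((flat > 0).sum())
    if n_positive < spec.n_records:
        raise ValueError(
            f"only {n_positive} cells with positive suitability for "
            f"{spec.n_records} requested records"
        )
    p = flat / flat.sum()
    cells = rng.choice(flat.size, size=spec.n_records, replace=False, p=p)
    record_months = rng.choice(np.asarray(months), size=spec.n_records, replace=True)
    grid = stack.grid
    prefix = id_prefix if id_prefix is not None else spec.season
    records = []
    for i, (cell, m) in enumerate(zip(cells, record_months)):
        row, col = divmod(int(cell), grid.n_cols)
        lon, lat = grid.cell_center(row, col)
        records.append(
            OccurrenceRecord(
                id=f"{prefix}_{i:04d}", lon=lon, lat=lat,
                month=int(m), season=spec.season,
            )
        )
    return OccurrenceSet(records, provenance=f"synthetic[{prefix}, seed={seed}]")


DEFAULT_GRID = GridSpec(
    n_rows=120, n_cols=120, x_origin=-110.0, y_origin=50.0, cell_size=0.0416
)

_SEASON_MONTHS = {"breeding": (5, 6), "winter": (12, 1, 2)}


def _season_envelope(stack: ClimateStack, months: Sequence[int]) -> np.ndarray:
    env = stack.env_grid(months).reshape(-1, len(VARIABLES))
    return env[~np.isnan(env).any(axis=1)]


def make_scenario(
    kind: str = "follower",
    seed: int = 0,
    delta: float = 0.0,
    grid: GridSpec = DEFAULT_GRID,
    params: ClimateParams = ClimateParams(),
    spread: tuple[float, float, float] = (1.5, 1.5, 6.0),
    record_counts: dict | None = None,
    niches: list[NicheSpec] | None = None,
) -> Scenario:
    """Assemble a full study scenario with known ground truth.

    ``follower``: breeding and winter niches share one climate centroid.
    ``switcher``: the two centroids sit ``delta`` standardized units apart
    (distance measured in units of the per-variable spread, split evenly
    across variables).  Migratory niches sit halfway between the two
    seasonal centroids.  ``custom`` takes explicit ``niches``.
    """
    stack = make_climate_stack(grid, params, seed=seed)
    counts = record_counts or DEFAULT_RECORD_COUNTS
    if kind == "custom":
        if niches is None:
            raise ValueError("custom scenario needs explicit niches")
        return Scenario(stack, list(niches), seed, kind, dict(_SEASON_MONTHS))
    if kind == "follower":
        delta = 0.0
    elif kind != "switcher":
        raise ValueError(f"unknown scenario kind '{kind}'")

    # Anchor the shared/midpoint centroid where both seasons realize the
    # climate: the midpoint of the intersection of the two seasons' ranges.
    env_b = _season_envelope(stack, _SEASON_MONTHS["breeding"])
    env_w = _season_envelope(stack, _SEASON_MONTHS["winter"])
    lo = np.maximum(env_b.min(axis=0), env_w.min(axis=0))
    hi = np.minimum(env_b.max(axis=0), env_w.max(axis=0))
    if (lo >= hi).any():
        raise ValueError(
            "seasonal climate ranges do not overlap; increase the latitudinal "
            "gradient or reduce the seasonal amplitude"
        )
    sd = np.asarray(spread, dtype=np.float64)
    mid0 = (lo + hi) / 2.0
    # Anchor the centroid on climates the grid actually realizes: average of
    # the nearest realized breeding and winter cell climates (spread metric).
    def _nearest(env: np.ndarray, target: np.ndarray) -> np.ndarray:
        d2 = (((env - target) / sd) ** 2).sum(axis=1)
        return env[int(np.argmin(d2))]

    mid = (_nearest(env_b, mid0) + _nearest(env_w, mid0)) / 2.0
    # The switcher offset runs along the realized climate gradient (the
    # direction latitude sweeps through climate space), so a separation of
    # `delta` standardized (Mahalanobis) units is actually attainable on
    # the grid.
    grad = np.array([params.tmax_gradient, params.tmax_gradient, params.prec_gradient])
    u = grad / sd
    unit = u / np.linalg.norm(u)
    offset = (delta / 2.0) * unit * sd
    centroid_b = tuple(mid + offset)
    centroid_w = tuple(mid - offset)
    niche_list = [
        NicheSpec(centroid_b, tuple(sd), "breeding", counts["breeding"]),
        NicheSpec(centroid_w, tuple(sd), "winter", counts["winter"]),
    ]
    # Migratory birds transit between the two seasonal niches; their
    # ground-truth centroid is the midpoint of the seasonal centroids.
    migratory = {
        int(month): NicheSpec(tuple(mid), tuple(sd), "migratory", n)
        for month, n in counts["migratory"].items()
    }
    niche_list.extend(migratory.values())
    return Scenario(stack, niche_list, seed, kind, dict(_SEASON_MONTHS), migratory)


def scenario_occurrences(scenario: Scenario, seed: int | None = None) -> OccurrenceSet:
    """Sample the full occurrence set of a scenario: one draw per seasonal
    niche plus one per migratory month, deterministic under the seed."""
    seed = scenario.seed if seed is None else seed
    records: list[OccurrenceRecord] = []
    sub = 0
    for season in ("breeding", "winter"):
        spec = scenario.niche(season)
        occ = sample_occurrences(
            scenario.stack, spec, list(scenario.season_months[season]),
            seed=(seed * 1000 + 17 * sub) % (2**31 - 1), id_prefix=season,
        )
        records.extend(occ.records)
        sub += 1
    for month in sorted(scenario.migratory):
        spec = scenario.migratory[month]
        occ = sample_occurrences(
            scenario.stack, spec, [month],
            seed=(seed * 1000 + 17 * sub) % (2**31 - 1), id_prefix=f"mig{month:02d}",
        )
        records.extend(occ.records)
        sub += 1
    return OccurrenceSet(records, provenance=f"scenario[{scenario.kind}, seed={seed}]")
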