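"""End-to-end seasonal niche analysis from a single configuration.

The pipeline assigns seasons and deduplicates records, fits a best-subsets
rule-set ensemble per season (80/20 calibration split), evaluates with
partial ROC, projects the seasonal models onto each other and onto the
migratory months (directional geographic overlap, NA where a projection
predicts no area), characterizes niche structure and locates records in
its zones, measures polar-coordinate breadth and hull overlap, runs the
PCA-env similarity test in both directions, and assembles monthly climate
profiles.  One global seed deterministically derives per-stage seeds so any
stage can be rerun in isolation; reruns of one config are bit-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geodata
from .geodata import (
    MIGRATORY_MONTHS,
    SEASON_MODEL_MONTHS,
    VARIABLES,
    ClimateStack,
    EnvMatrix,
    OccurrenceSet,
    cells_env,
    dedup_occurrences,
    extract_env,
)
from . import synth
from .rulesets import (
    GAParams,
    NicheEnsemble,
    SuitabilityMap,
    fit_rule_model,
    geographic_overlap,
    predict,
    select_best_subset,
    split_calibration,
)
from .evaluation import partial_roc
from .structure import build_structure, classify_records, DEFAULT_CUTOFFS
from .breadth import (
    PolarLattice,
    alpha_hull,
    breadth_overlap,
    minmax_scaling,
    polar_coordinates,
)
from .similarity import build_pca_env, similarity_test

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed and a
    stage name."""
    h = zlib.crc32(stage.encode("utf8"))
    return int((h ^ (global_seed * 2654435761)) % (2**31 - 1))


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every stage reads its settings from
    here and the config is serialized into the summary."""

    # data source: synthetic scenario (default) or files
    scenario_kind: str = "follower"        # follower | switcher | files
    delta: float = 0.0                     # centroid separation, standardized units
    grid_size: int = 120
    rasters_dir: str | None = None
    occurrences_csv: str | None = None
    record_counts: dict | None = None
    # season definition
    season_map: dict | None = None
    # model settings
    n_replicates: int = 100
    k_best: int = 10
    omission_max: float = 0.10
    consensus: int | None = None           # default: majority of k_best
    calibration_fraction: float = 0.8
    background_size: int = 10_000
    region_buffer_fraction: float = 0.10   # bbox buffer around season records
    ga: GAParams = field(default_factory=GAParams)
    # evaluation
    E: float = 0.05
    n_boot: int = 1000
    # structure
    cutoffs: tuple[float, float] | str = DEFAULT_CUTOFFS
    # breadth
    breadth_lattice: int = 100
    alpha: float | None = None
    # similarity
    similarity_resolution: int = 100
    similarity_reps: int = 100
    bandwidth: float | None = None
    # global
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("cutoffs"), tuple):
            d["cutoffs"] = list(d["cutoffs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAParams(**d["ga"])
        if isinstance(d.get("cutoffs"), list):
            d["cutoffs"] = tuple(d["cutoffs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class ClimateProfile:
    """Five-number per-variable summary of climate at a selection of
    records or cells."""

    table: pd.DataFrame  # variable, min, q25, median, q75, max
    source: str

    def to_dict(self) -> dict:
        return {"source": self.source,
                "table": self.table.round(6).to_dict(orient="records")}


def climate_profile(
    stack: ClimateStack,
    selector: OccurrenceSet | np.ndarray | SuitabilityMap,
    months: int | str | Sequence[int],
    source: str = "",
) -> ClimateProfile:
    """Five-number summary (min, quartiles, median, max) of each climate
    variable over records or selected cells, computed on non-nodata values
    only."""
    if isinstance(selector, OccurrenceSet):
        env = extract_env(stack, selector, months)
    else:
        mask = selector.binary if isinstance(selector, SuitabilityMap) else selector
        env = cells_env(stack, months, mask=mask)
    rows = []
    for j, var in enumerate(env.columns):
        v = env.values[:, j]
        q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append({"variable": var, "min": q[0], "q25": q[1],
                     "median": q[2], "q75": q[3], "max": q[4]})
    return ClimateProfile(pd.DataFrame(rows), source)


def _region_mask(grid, occ: OccurrenceSet, buffer_fraction: float) -> np.ndarray:
    """Boolean cell mask of a buffered bounding box around the records —
    the modeling/calibration region for commission and background."""
    lons = np.array([r.lon for r in occ.records])
    lats = np.array([r.lat for r in occ.records])
    bx = (lons.max() - lons.min()) * buffer_fraction + grid.cell_size
    by = (lats.max() - lats.min()) * buffer_fraction + grid.cell_size
    lo_x, hi_x = lons.min() - bx, lons.max() + bx
    lo_y, hi_y = lats.min() - by, lats.max() + by
    cols = np.arange(grid.n_cols)
    rows = np.arange(grid.n_rows)
    cx = grid.x_origin + (cols + 0.5) * grid.cell_size
    cy = grid.y_origin - (rows + 0.5) * grid.cell_size
    in_x = (cx >= lo_x) & (cx <= hi_x)
    in_y = (cy >= lo_y) & (cy <= hi_y)
    return in_y[:, None] & in_x[None, :]


def _sample_background(region: EnvMatrix, size: int, seed: int) -> EnvMatrix:
    if region.n <= size:
        return region
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(region.n, size=size, replace=False))
    return EnvMatrix(region.values[idx], region.columns,
                     [region.row_keys[i] for i in idx])


def fit_season(
    stack: ClimateStack,
    occ_train: OccurrenceSet,
    region_cells: EnvMatrix,
    config: RunConfig,
    season: str,
) -> NicheEnsemble:
    """Fit R replicate rule-set models for one season and select the best
    subset by the omission/commission protocol."""
    months = SEASON_MODEL_MONTHS[season]
    presence = extract_env(stack, occ_train, months)
    # calibration background samples the whole accessible landscape so the
    # GA sees unsuitable climates; commission uses the tighter region
    background = _sample_background(
        cells_env(stack, months), config.background_size,
        stage_seed(config.seed, f"background:{season}"),
    )
    replicates = []
    for r in range(config.n_replicates):
        replicates.append(
            fit_rule_model(
                presence, background, config.ga,
                seed=stage_seed(config.seed, f"fit:{season}:{r}"),
            )
        )
    return select_best_subset(
        replicates, region_cells, config.omission_max, config.k_best
    )


def _num(x):
    if x is None:
        return None
    return round(float(x), 9)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full seasonal workflow and return (and optionally write)
    a machine-readable summary.  Deterministic under ``config.seed``."""
    summary: dict = {"config": config.to_dict()}

    # --- inputs -----------------------------------------------------------
    if config.scenario_kind == "files":
        if not config.rasters_dir or not config.occurrences_csv:
            raise ValueError("files scenario needs rasters_dir and occurrences_csv")
        stack = geodata.load_stack(config.rasters_dir)
        occ = geodata.read_occurrences(config.occurrences_csv)
        if any(r.season is None for r in occ.records):
            occ = geodata.assign_season(occ, config.season_map)
    else:
        scenario = synth.make_scenario(
            kind=config.scenario_kind,
            seed=stage_seed(config.seed, "scenario"),
            delta=config.delta,
            grid=synth.GridSpec(
                n_rows=config.grid_size, n_cols=config.grid_size,
                x_origin=-110.0, y_origin=50.0, cell_size=0.0416,
            ),
            record_counts=config.record_counts,
        )
        stack = scenario.stack
        occ = synth.scenario_occurrences(scenario)
    occ = dedup_occurrences(occ, stack.grid)
    summary["n_records"] = {
        s: len(occ.subset_season(s)) for s in ("breeding", "winter", "migratory")
    }

    # --- per-season models ------------------------------------------------
    seasons = ("breeding", "winter")
    ensembles: dict[str, NicheEnsemble] = {}
    maps: dict[str, SuitabilityMap] = {}
    structures = {}
    region_cells: dict[str, EnvMatrix] = {}
    season_summaries: dict[str, dict] = {}
    for season in seasons:
        occ_s = occ.subset_season(season)
        months = SEASON_MODEL_MONTHS[season]
        train, test = split_calibration(
            occ_s, config.calibration_fraction,
            seed=stage_seed(config.seed, f"split:{season}"),
        )
        mask = _region_mask(stack.grid, occ_s, config.region_buffer_fraction)
        region = cells_env(stack, months, mask=mask)
        region_cells[season] = region
        ensemble = fit_season(stack, train, region, config, season)
        ensembles[season] = ensemble
        smap = predict(ensemble, stack, months, consensus=config.consensus)
        maps[season] = smap
        roc = partial_roc(
            smap, test, E=config.E, n_boot=config.n_boot,
            seed=stage_seed(config.seed, f"roc:{season}"),
        )
        structure = build_structure(stack, smap, months, config.cutoffs)
        structures[season] = structure
        zones_own = classify_records(occ_s, structure, stack)
        season_summaries[season] = {
            "n_train": len(train),
            "n_test": len(test),
            "ensemble_omission": [_num(m.omission) for m in ensemble.members],
            "partial_roc": {k: _num(v) if isinstance(v, float) else v
                            for k, v in roc.to_dict().items()},
            "predicted_cells": int(smap.binary.sum()),
            "zone_counts_own_records": zones_own.counts,
        }
    summary["seasons"] = season_summaries

    # --- inter-prediction and migratory projections -----------------------
    proj: dict[tuple[str, object], SuitabilityMap] = {}
    for season in seasons:
        other = "winter" if season == "breeding" else "breeding"
        proj[(season, other)] = predict(
            ensembles[season], stack, SEASON_MODEL_MONTHS[other],
            consensus=config.consensus,
        )
        for month in MIGRATORY_MONTHS:
            proj[(season, month)] = predict(
                ensembles[season], stack, month, consensus=config.consensus,
            )
    inter = {}
    for season in seasons:
        other = "winter" if season == "breeding" else "breeding"
        ov = geographic_overlap(proj[(season, other)], maps[other])
        inter[f"{season}_onto_{other}"] = {
            "projection_to_resident_pct": _num(ov["a_to_b"]),
            "resident_to_projection_pct": _num(ov["b_to_a"]),
            "cells_projection": ov["cells_a"],
            "cells_resident": ov["cells_b"],
        }
    summary["inter_prediction"] = inter

    # --- directional overlap table for migratory months (geographic) ------
    table_rows = []
    for season in seasons:
        for month in MIGRATORY_MONTHS:
            ov = geographic_overlap(maps[season], proj[(season, month)])
            table_rows.append({
                "season": season,
                "month": int(month),
                "season_to_month_pct": _num(ov["a_to_b"]),
                "month_to_season_pct": _num(ov["b_to_a"]),
            })
    summary["migration_overlap_table"] = table_rows

    # --- niche breadth in polar coordinates -------------------------------
    env_b = cells_env(stack, SEASON_MODEL_MONTHS["breeding"], mask=maps["breeding"].binary)
    env_w = cells_env(stack, SEASON_MODEL_MONTHS["winter"], mask=maps["winter"].binary)
    scaling = minmax_scaling(env_b, env_w)
    cloud_b = polar_coordinates(env_b, scaling=scaling)
    cloud_w = polar_coordinates(env_w, scaling=scaling)
    hull_b = alpha_hull(cloud_b, alpha=config.alpha)
    hull_w = alpha_hull(cloud_w, alpha=config.alpha)
    lattice = PolarLattice.over(
        [hull_b.boundary, hull_w.boundary],
        config.breadth_lattice, config.breadth_lattice,
    )
    ov = breadth_overlap(hull_b, hull_w, lattice)
    summary["breadth"] = {
        "breeding_area": _num(hull_b.area),
        "winter_area": _num(hull_w.area),
        "breeding_pixels": ov["pixels_a"],
        "winter_pixels": ov["pixels_b"],
        "breeding_to_winter_pct": _num(ov["a_to_b"]),
        "winter_to_breeding_pct": _num(ov["b_to_a"]),
        "alpha": [_num(hull_b.alpha), _num(hull_w.alpha)],
    }

    # --- PCA-env similarity test, both directions -------------------------
    space = build_pca_env(
        region_cells["breeding"], region_cells["winter"],
        resolution=config.similarity_resolution,
    )
    occ_env_b = extract_env(stack, occ.subset_season("breeding"),
                            SEASON_MODEL_MONTHS["breeding"])
    occ_env_w = extract_env(stack, occ.subset_season("winter"),
                            SEASON_MODEL_MONTHS["winter"])
    sim = {}
    for direction in ("a_vs_b", "b_vs_a"):
        res = similarity_test(
            occ_env_b, occ_env_w, space,
            n_reps=config.similarity_reps, direction=direction,
            seed=stage_seed(config.seed, f"similarity:{direction}"),
            bandwidth=config.bandwidth,
        )
        label = ("breeding_vs_winter" if direction == "a_vs_b"
                 else "winter_vs_breeding")
        sim[label] = {
            "d_observed": _num(res.d_observed),
            "p_value": _num(res.p_value),
            "n_reps": res.n_reps,
            "null_d_median": _num(float(np.median(res.null_d))),
        }
    sim["explained_variance"] = [_num(v) for v in space.explained_variance_ratio]
    summary["similarity"] = sim

    # --- migratory records in the seasonal niche structures ----------------
    occ_mig = occ.subset_season("migratory")
    mig = {}
    for season in seasons:
        za = classify_records(occ_mig, structures[season], stack)
        counts = za.counts
        n_cls = max(sum(counts.values()), 1)
        mig[f"{season}_structure"] = {
            "zone_counts": counts,
            "suboptimal_marginal_fraction": _num(
                (counts["suboptimal"] + counts["marginal"]) / n_cls
            ),
            "mean_dc": _num(float(za.dc.mean())) if za.dc.size else None,
        }
    summary["migratory_zones"] = mig

    # --- climate profiles --------------------------------------------------
    profiles = []
    for month in MIGRATORY_MONTHS:
        occ_m = occ.subset_month(month)
        if len(occ_m):
            profiles.append(climate_profile(stack, occ_m, month,
                                            source=f"records_month_{month:02d}").to_dict())
        for season in seasons:
            pm = proj[(season, month)]
            if pm.binary.any():
                profiles.append(
                    climate_profile(stack, pm, month,
                                    source=f"projection_{season}_month_{month:02d}").to_dict()
                )
    for season in seasons:
        profiles.append(
            climate_profile(stack, maps[season], SEASON_MODEL_MONTHS[season],
                            source=f"model_{season}").to_dict()
        )
    summary["climate_profiles"] = profiles

    # --- artifacts ---------------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for season in seasons:
            ensembles[season].save(outdir / f"ensemble_{season}.json")
            _write_map(maps[season], stack, outdir / f"agreement_{season}.asc")
        geodata.write_occurrences(occ, outdir / "occurrences_clean.csv")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
    return summary


def _write_map(smap: SuitabilityMap, stack: ClimateStack, path: Path) -> None:
    values = np.where(np.isnan(smap.agreement), smap.grid.nodata, smap.agreement)
    geodata.write_raster(
        geodata.Layer(smap.grid, None, None, values), path
    )


def summary_json(summary: dict) -> str:
    """Canonical JSON text of a pipeline summary (stable key order)."""
    return json.dumps(summary, indent=1, sort_keys=True)
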