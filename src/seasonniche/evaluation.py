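"""Partial-ROC evaluation of suitability maps.

The curve plots sensitivity (1 - omission on test records) against the
proportion of the modeling region predicted present, one point per distinct
suitability threshold.  The analysis is restricted to the high-sensitivity
region (sensitivity >= 1 - E) and summarized as the AUC ratio: model area
over chance-line area, both by trapezoid.  Ratios near 1 indicate
chance-level performance; values up to 2 indicate performance better than
random with low omission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geodata import ClimateStack, OccurrenceSet
from .rulesets import SuitabilityMap


@dataclass
class PartialROCResult:
    auc_ratio: float
    p_value: float
    n_bootstrap: int
    E: float
    bootstrap_ratios: np.ndarray = field(repr=False)
    n_test: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.auc_ratio <= 2 + 1e-9:
            raise ValueError(f"auc_ratio out of [0, 2]: {self.auc_ratio}")

    def to_dict(self) -> dict:
        return {
            "auc_ratio": float(self.auc_ratio),
            "p_value": float(self.p_value),
            "n_bootstrap": int(self.n_bootstrap),
            "E": float(self.E),
            "n_test": int(self.n_test),
        }


def _region_curve_x(region_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending thresholds over distinct region values and the matching
    proportion-of-area coordinates, with a (0, 0) starting point."""
    thresholds = np.unique(region_vals)[::-1]
    sr = np.sort(region_vals)
    x = np.empty(thresholds.size + 1)
    x[0] = 0.0  # threshold above the maximum
    x[1:] = (sr.size - np.searchsorted(sr, thresholds, side="left")) / sr.size
    return thresholds, x


def _sensitivity(test_vals: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Sensitivity (1 - omission) of the test set at each threshold,
    prefixed with the (0, 0) starting point."""
    st = np.sort(test_vals)
    y = np.empty(thresholds.size + 1)
    y[0] = 0.0
    y[1:] = (st.size - np.searchsorted(st, thresholds, side="left")) / st.size
    return y


def _roc_points(test_vals: np.ndarray, region_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Curve points (proportion of area predicted, sensitivity), one per
    distinct threshold over the region's suitability values, ordered by
    increasing area; includes the (0, 0) endpoint."""
    thresholds, x = _region_curve_x(region_vals)
    return x, _sensitivity(test_vals, thresholds)


def _ratio_from_curve(x: np.ndarray, y: np.ndarray, E: float) -> float:
    """AUC ratio over the restricted region sensitivity >= 1 - E, with the
    boundary crossing interpolated linearly."""
    s_min = 1.0 - E
    keep = y >= s_min
    if not keep.any():
        raise ValueError("no curve points reach the required sensitivity")
    first = int(np.argmax(keep))  # points are ordered by increasing x and y
    xs, ys = x[keep], y[keep]
    if first > 0 and y[first] > s_min:
        # interpolate the crossing between the last failing and first passing point
        x0, y0, x1, y1 = x[first - 1], y[first - 1], x[first], y[first]
        if y1 > y0:
            xc = x0 + (s_min - y0) * (x1 - x0) / (y1 - y0)
            xs = np.concatenate([[xc], xs])
            ys = np.concatenate([[s_min], ys])
    auc_model = float(np.trapezoid(ys, xs))
    auc_chance = float(np.trapezoid(xs, xs))  # area under the 1:1 line
    if auc_chance <= 0:
        raise ValueError("chance area is zero over the restricted region; ratio undefined")
    return auc_model / auc_chance


def partial_roc(
    suitability: SuitabilityMap,
    test: OccurrenceSet,
    stack: ClimateStack | None = None,
    E: float = 0.05,
    n_boot: int = 1000,
    boot_fraction: float = 0.5,
    seed: int = 0,
) -> PartialROCResult:
    """Partial-ROC AUC ratio of a suitability map against held-out records.

    Test records are located on the agreement raster; records on nodata are
    dropped.  ``p_value`` is the fraction of bootstrap ratios <= 1 (the
    chance level), from ``n_boot`` resamples of ``boot_fraction`` of the
    test points with replacement.  A map with constant suitability over the
    region coincides with the chance line and scores exactly 1.
    """
    del stack  # records are located directly on the agreement raster
    agreement = suitability.agreement
    grid = suitability.grid
    region_vals = agreement[~np.isnan(agreement)].ravel()
    test_vals = []
    for r in test.records:
        cell = grid.cell_of(r.lon, r.lat)
        if cell is None:
            continue
        v = agreement[cell]
        if not np.isnan(v):
            test_vals.append(float(v))
    test_vals = np.asarray(test_vals)
    if test_vals.size < 5:
        raise ValueError("need at least 5 test records on valid cells")
    if np.unique(region_vals).size < 2:
        # degenerate chance case: the curve IS the 1:1 line
        ratios = np.ones(n_boot)
        return PartialROCResult(1.0, float((ratios <= 1).mean()), n_boot, E,
                                ratios, test_vals.size)
    thresholds, x = _region_curve_x(region_vals)
    ratio = _ratio_from_curve(x, _sensitivity(test_vals, thresholds), E)

    rng = np.random.default_rng(seed)
    m = int(np.ceil(boot_fraction * test_vals.size))
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sample = rng.choice(test_vals, size=m, replace=True)
        ratios[b] = _ratio_from_curve(x, _sensitivity(sample, thresholds), E)
    p_value = float((ratios <= 1.0).mean())
    return PartialROCResult(float(ratio), p_value, n_boot, E, ratios, test_vals.size)
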