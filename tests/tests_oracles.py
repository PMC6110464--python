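"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_auc_ratio(test_vals, region_vals, E):
    """Trapezoid partial-ROC oracle: explicit loop over every distinct
    threshold, explicit area sums, same high-sensitivity restriction."""
    thresholds = sorted(set(np.asarray(region_vals).tolist()), reverse=True)
    pts = [(0.0, 0.0)]
    for t in thresholds:
        x = sum(1 for v in region_vals if v >= t) / len(region_vals)
        y = sum(1 for v in test_vals if v >= t) / len(test_vals)
        pts.append((x, y))
    s_min = 1.0 - E
    kept = [(x, y) for x, y in pts if y >= s_min]
    first_idx = next(i for i, (_, y) in enumerate(pts) if y >= s_min)
    if first_idx > 0:
        x0, y0 = pts[first_idx - 1]
        x1, y1 = pts[first_idx]
        if y1 > s_min and y1 > y0:
            xc = x0 + (s_min - y0) * (x1 - x0) / (y1 - y0)
            kept = [(xc, s_min)] + kept
    area_model = 0.0
    area_chance = 0.0
    for (x0, y0), (x1, y1) in zip(kept[:-1], kept[1:]):
        area_model += (x1 - x0) * (y0 + y1) / 2
        area_chance += (x1 - x0) * (x0 + x1) / 2
    return area_model / area_chance
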