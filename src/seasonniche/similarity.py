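"""Niche similarity in a two-axis PCA climate space.

The comparison space is a PCA calibrated on the pooled, standardized
environmental backgrounds of both groups.  Occurrences and backgrounds are
kernel-density smoothed on a shared R x R lattice of PCA scores; occupancy
is the occurrence density corrected by environmental availability (o/e),
rescaled to sum to one.  Overlap between two occupancy grids is Schoener's
D = 1 - 0.5 * sum|z1 - z2|, and the similarity test compares the observed D
to a null built by re-drawing the focal group's records from the pooled
records of both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .geodata import EnvMatrix

#: availability below this fraction of the peak counts as unavailable
_AVAILABILITY_EPS = 1e-6


@dataclass
class PcaEnvSpace:
    mean: np.ndarray
    sd: np.ndarray
    components: np.ndarray          # (2, p), orthonormal rows
    explained_variance_ratio: np.ndarray
    columns: tuple[str, ...]
    xedges: np.ndarray
    yedges: np.ndarray
    bg_scores_a: np.ndarray = field(repr=False, default=None)
    bg_scores_b: np.ndarray = field(repr=False, default=None)

    @property
    def resolution(self) -> int:
        return self.xedges.size - 1

    def score(self, values: np.ndarray) -> np.ndarray:
        """Project climate rows onto the two principal axes."""
        z = (np.atleast_2d(values) - self.mean) / self.sd
        return z @ self.components.T

    def score_env(self, env: EnvMatrix) -> np.ndarray:
        if env.columns != self.columns:
            raise ValueError("column mismatch with the PCA space")
        return self.score(env.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = (self.xedges[:-1] + self.xedges[1:]) / 2
        cy = (self.yedges[:-1] + self.yedges[1:]) / 2
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return gx, gy


@dataclass
class OccupancyGrid:
    z: np.ndarray             # (R, R), >= 0, sums to 1
    bandwidth: float
    n_occ: int

    def __post_init__(self) -> None:
        if (self.z < 0).any():
            raise ValueError("occupancy must be non-negative")
        if abs(self.z.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy must sum to 1")


@dataclass
class SimilarityResult:
    d_observed: float
    null_d: np.ndarray
    p_value: float
    direction: str
    n_reps: int
    seed: int
    bandwidth: float | None = None

    def to_dict(self) -> dict:
        return {
            "d_observed": float(self.d_observed),
            "p_value": float(self.p_value),
            "direction": self.direction,
            "n_reps": int(self.n_reps),
            "seed": int(self.seed),
            "null_d": [float(v) for v in self.null_d],
        }


def build_pca_env(
    background_a: EnvMatrix,
    background_b: EnvMatrix,
    resolution: int = 100,
    margin: float = 0.05,
) -> PcaEnvSpace:
    """Two-axis PCA of the pooled, standardized backgrounds, with an R x R
    score lattice spanning all background scores plus a margin."""
    if background_a.columns != background_b.columns:
        raise ValueError("backgrounds must share columns")
    pooled = np.vstack([background_a.values, background_b.values])
    if pooled.shape[0] < 10:
        raise ValueError("pooled backgrounds need at least 10 rows")
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("constant variable in pooled background")
    z = (pooled - mean) / sd
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(z)
    components = pca.components_.copy()
    # deterministic sign: the largest-magnitude loading of each axis is positive
    for i in range(2):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    scores = z @ components.T
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    pad = (hi - lo) * margin
    pad[pad == 0] = 1e-6
    xedges = np.linspace(lo[0] - pad[0], hi[0] + pad[0], resolution + 1)
    yedges = np.linspace(lo[1] - pad[1], hi[1] + pad[1], resolution + 1)
    space = PcaEnvSpace(
        mean, sd, components, pca.explained_variance_ratio_.copy(),
        background_a.columns, xedges, yedges,
    )
    na = background_a.values.shape[0]
    space.bg_scores_a = scores[:na]
    space.bg_scores_b = scores[na:]
    return space


#: KDE cost is linear in the number of support points; availability
#: backgrounds larger than this are subsampled (deterministically)
_MAX_KDE_POINTS = 4000


def _kde_on_grid(scores: np.ndarray, space: PcaEnvSpace, bandwidth) -> np.ndarray:
    gx, gy = space.cell_centers()
    if scores.shape[0] > _MAX_KDE_POINTS:
        idx = np.sort(np.random.default_rng(834_001).choice(
            scores.shape[0], size=_MAX_KDE_POINTS, replace=False))
        scores = scores[idx]
    pts = scores.T
    try:
        kde = gaussian_kde(pts, bw_method=bandwidth)
    except np.linalg.LinAlgError:
        # degenerate (e.g. collinear) scores: fall back to jittered points
        jitter = 1e-9 * np.random.default_rng(0).standard_normal(pts.shape)
        kde = gaussian_kde(pts + jitter, bw_method=bandwidth)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    return dens, float(kde.factor)


def availability_grid(background_scores: np.ndarray, space: PcaEnvSpace) -> np.ndarray:
    """Kernel density of the environmental background on the score lattice
    (Silverman bandwidth); precompute it when building many occupancy grids
    against one background."""
    e, _ = _kde_on_grid(np.atleast_2d(background_scores), space, "silverman")
    return e


def occupancy_grid(
    occ_scores: np.ndarray,
    background_scores: np.ndarray,
    space: PcaEnvSpace,
    bandwidth: float | str | None = None,
    availability: np.ndarray | None = None,
) -> OccupancyGrid:
    """Availability-corrected occurrence density on the PCA lattice.

    z(cell) = o(cell) / e(cell) where the background density e is
    non-negligible, else 0, rescaled to sum to 1.  The occurrence bandwidth
    defaults to Silverman's rule on the occurrence scores; the availability
    surface e is always smoothed with its own Silverman bandwidth so that a
    narrow occurrence bandwidth cannot punch holes in it.
    """
    occ_scores = np.atleast_2d(occ_scores)
    if occ_scores.shape[0] < 3:
        raise ValueError("need at least 3 occurrence scores")
    bw = "silverman" if bandwidth is None else bandwidth
    o, factor = _kde_on_grid(occ_scores, space, bw)
    if availability is not None:
        e = availability
    else:
        e, _ = _kde_on_grid(np.atleast_2d(background_scores), space, "silverman")
    avail = e > e.max() * _AVAILABILITY_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(avail, o / np.where(avail, e, 1.0), 0.0)
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy grid is identically zero")
    return OccupancyGrid(z / total, factor, occ_scores.shape[0])


def schoener_d(z1: OccupancyGrid | np.ndarray, z2: OccupancyGrid | np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |z1 - z2| over the shared lattice;
    0 = complete differentiation, 1 = complete similarity."""
    a = z1.z if isinstance(z1, OccupancyGrid) else np.asarray(z1, dtype=np.float64)
    b = z2.z if isinstance(z2, OccupancyGrid) else np.asarray(z2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("occupancy grids must share one shape")
    d = 1.0 - 0.5 * float(np.abs(a - b).sum())
    return min(max(d, 0.0), 1.0)


def similarity_test(
    occ_a: EnvMatrix,
    occ_b: EnvMatrix,
    space: PcaEnvSpace,
    n_reps: int = 100,
    direction: str = "a_vs_b",
    seed: int = 0,
    bandwidth: float | str | None = None,
) -> SimilarityResult:
    """Randomization similarity test on Schoener's D.

    The focal group's records are replaced, ``n_reps`` times, by an
    equal-size draw from the pooled records of both groups and D is
    recomputed against the other group's fixed occupancy; the one-sided
    p-value (add-one convention) is the probability of a null D at least as
    large as the observed D, i.e. small p means the two groups are more
    similar than random relabelling would produce.
    """
    if direction not in ("a_vs_b", "b_vs_a"):
        raise ValueError("direction must be a_vs_b or b_vs_a")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scores_a = space.score_env(occ_a)
    scores_b = space.score_env(occ_b)
    avail_a = availability_grid(space.bg_scores_a, space)
    avail_b = availability_grid(space.bg_scores_b, space)
    grid_a = occupancy_grid(scores_a, space.bg_scores_a, space, bandwidth,
                            availability=avail_a)
    grid_b = occupancy_grid(scores_b, space.bg_scores_b, space, bandwidth,
                            availability=avail_b)
    d_obs = schoener_d(grid_a, grid_b)

    focal_scores, fixed_grid, focal_bg, focal_avail = (
        (scores_a, grid_b, space.bg_scores_a, avail_a)
        if direction == "a_vs_b"
        else (scores_b, grid_a, space.bg_scores_b, avail_b)
    )
    pooled = np.vstack([scores_a, scores_b])
    n_focal = focal_scores.shape[0]
    if pooled.shape[0] < n_focal:
        raise ValueError("pooled records smaller than the focal sample size")
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for i in range(n_reps):
        draw = pooled[rng.choice(pooled.shape[0], size=n_focal, replace=False)]
        grid_null = occupancy_grid(draw, focal_bg, space, bandwidth,
                                   availability=focal_avail)
        null[i] = schoener_d(grid_null, fixed_grid)
    p = (1.0 + float((null >= d_obs).sum())) / (n_reps + 1.0)
    return SimilarityResult(d_obs, null, p, direction, n_reps, seed,
                            grid_a.bandwidth)
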