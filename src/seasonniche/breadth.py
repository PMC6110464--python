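"""Niche breadth in a 2-D polar-coordinate climate space.

Each climate variable is treated as a force vector at a fixed angle; a
cell's (X, Y) position is the equilibrium point (vector sum) of its
min-max-scaled variable values.  The occupied climate area of a stage is
delimited by the alpha-hull of its point cloud (the convex hull in the
large-alpha limit), its area is the niche breadth, and directional overlap
between stages is measured as the percentage of coinciding cells after
rasterizing both hulls onto a shared lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union
import shapely

from .geodata import EnvMatrix


def default_angles(columns: Sequence[str]) -> dict[str, float]:
    """Evenly spaced angles on [0, 2*pi) in the given variable order."""
    n = len(columns)
    return {c: 2 * np.pi * i / n for i, c in enumerate(columns)}


def minmax_scaling(*envs: EnvMatrix) -> dict[str, tuple[float, float]]:
    """Per-variable (min, max) over the union of the given matrices, so
    stages being compared share one polar space."""
    if not envs:
        raise ValueError("need at least one EnvMatrix")
    cols = envs[0].columns
    pooled = np.vstack([e.values for e in envs])
    return {c: (float(pooled[:, j].min()), float(pooled[:, j].max()))
            for j, c in enumerate(cols)}


@dataclass
class PolarCloud:
    points: np.ndarray  # (n, 2)
    angle_map: dict[str, float]
    scaling: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        angles = list(self.angle_map.values())
        if len(set(np.round(angles, 12))) != len(angles):
            raise ValueError("angles must be distinct per variable")


@dataclass
class BreadthPolygon:
    boundary: object          # shapely geometry (possibly multi-part)
    alpha: float
    area: float
    pixel_area: int | None = None


def polar_coordinates(
    env: EnvMatrix,
    angle_map: Mapping[str, float] | None = None,
    scaling: Mapping[str, tuple[float, float]] | None = None,
) -> PolarCloud:
    """Project climate rows to 2-D: X = sum_v x_v cos(theta_v),
    Y = sum_v x_v sin(theta_v), after min-max scaling each variable.

    Pass a shared ``scaling`` (from :func:`minmax_scaling` over all compared
    stages) so that stages live in one space; otherwise scaling is computed
    from ``env`` alone.
    """
    if len(env.columns) < 1:
        raise ValueError("need at least one variable")
    angle_map = dict(angle_map) if angle_map else default_angles(env.columns)
    scaling = dict(scaling) if scaling else minmax_scaling(env)
    X = np.zeros(env.n)
    Y = np.zeros(env.n)
    for j, c in enumerate(env.columns):
        lo, hi = scaling[c]
        span = hi - lo
        x = (env.values[:, j] - lo) / span if span > 0 else np.zeros(env.n)
        theta = angle_map[c]
        X += x * np.cos(theta)
        Y += x * np.sin(theta)
    return PolarCloud(np.column_stack([X, Y]), angle_map, scaling)


def _triangle_circumradius(pts: np.ndarray) -> float:
    a = np.linalg.norm(pts[1] - pts[0])
    b = np.linalg.norm(pts[2] - pts[1])
    c = np.linalg.norm(pts[0] - pts[2])
    u, v = pts[1] - pts[0], pts[2] - pts[0]
    area2 = abs(u[0] * v[1] - u[1] * v[0])  # 2 * area
    if area2 <= 0:
        return np.inf
    return a * b * c / (2 * area2)


def alpha_hull(cloud: PolarCloud, alpha: float | None = None) -> BreadthPolygon:
    """Alpha-shape of the polar points: the union of Delaunay triangles
    whose circumradius is at most ``alpha``.

    As alpha grows the hull converges to the convex hull; small alpha
    carves concavities.  Default alpha is six times the median
    nearest-neighbor distance of the cloud — large enough that a connected
    cloud yields one coherent polygon, small enough to carve real
    concavities.  Degenerate (collinear) clouds yield a zero-area polygon
    with a warning.
    """
    pts = np.unique(cloud.points, axis=0)
    if alpha is None:
        if pts.shape[0] >= 2:
            d, _ = cKDTree(pts).query(pts, k=2)
            alpha = 6.0 * float(np.median(d[:, 1]))
        else:
            alpha = 1.0
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if pts.shape[0] < 3:
        warnings.warn("alpha_hull: fewer than 3 distinct points; zero-area result",
                      stacklevel=2)
        return BreadthPolygon(MultiPoint(pts).convex_hull, alpha, 0.0)
    try:
        tri = Delaunay(pts)
    except QhullError:
        warnings.warn("alpha_hull: degenerate (collinear) cloud; zero-area result",
                      stacklevel=2)
        return BreadthPolygon(MultiPoint(pts).convex_hull, alpha, 0.0)
    triangles = []
    for simplex in tri.simplices:
        tpts = pts[simplex]
        if _triangle_circumradius(tpts) <= alpha:
            triangles.append(Polygon(tpts))
    if not triangles:
        warnings.warn("alpha_hull: alpha too small, empty hull", stacklevel=2)
        return BreadthPolygon(Polygon(), alpha, 0.0)
    geom = unary_union(triangles)
    return BreadthPolygon(geom, float(alpha), float(geom.area))


@dataclass(frozen=True)
class PolarLattice:
    """Fixed evaluation lattice over polar space used to count occupied
    cells (breadth in 'pixels') and overlap."""

    xmin: float
    ymin: float
    dx: float
    dy: float
    nx: int
    ny: int

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.xmin + (np.arange(self.nx) + 0.5) * self.dx
        cy = self.ymin + (np.arange(self.ny) + 0.5) * self.dy
        gx, gy = np.meshgrid(cx, cy)
        return gx.ravel(), gy.ravel()

    @classmethod
    def over(cls, geoms: Sequence[object], nx: int = 100, ny: int = 100,
             margin: float = 0.02) -> "PolarLattice":
        bounds = np.array([g.bounds for g in geoms if not g.is_empty])
        if bounds.size == 0:
            raise ValueError("cannot build a lattice over empty geometries")
        xmin, ymin = bounds[:, 0].min(), bounds[:, 1].min()
        xmax, ymax = bounds[:, 2].max(), bounds[:, 3].max()
        mx = (xmax - xmin) * margin or 1e-9
        my = (ymax - ymin) * margin or 1e-9
        return cls(xmin - mx, ymin - my,
                   (xmax - xmin + 2 * mx) / nx, (ymax - ymin + 2 * my) / ny,
                   nx, ny)


def rasterize(polygon: BreadthPolygon, lattice: PolarLattice) -> np.ndarray:
    """Boolean occupancy of lattice cells whose center lies inside the
    polygon (boundary-inclusive)."""
    gx, gy = lattice.centers()
    if polygon.boundary.is_empty:
        return np.zeros(gx.size, dtype=bool)
    inside = shapely.contains_xy(polygon.boundary, gx, gy)
    on_edge = shapely.intersects_xy(polygon.boundary, gx, gy)
    return inside | on_edge


def breadth_overlap(
    a: BreadthPolygon,
    b: BreadthPolygon,
    lattice: PolarLattice | None = None,
    nx: int = 100,
    ny: int = 100,
) -> dict:
    """Directional percent overlap of two breadth polygons on a shared
    lattice: overlap(a->b) = 100 * |cells(a) AND cells(b)| / |cells(a)|.

    Also records each polygon's occupied-cell count (breadth in pixels).
    """
    if lattice is None:
        lattice = PolarLattice.over([a.boundary, b.boundary], nx, ny)
    cells_a = rasterize(a, lattice)
    cells_b = rasterize(b, lattice)
    na, nb = int(cells_a.sum()), int(cells_b.sum())
    if na == 0 or nb == 0:
        raise ValueError("empty rasterization of a breadth polygon")
    inter = int((cells_a & cells_b).sum())
    a.pixel_area = na
    b.pixel_area = nb
    return {
        "a_to_b": 100.0 * inter / na,
        "b_to_a": 100.0 * inter / nb,
        "pixels_a": na,
        "pixels_b": nb,
        "pixels_intersection": inter,
    }
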