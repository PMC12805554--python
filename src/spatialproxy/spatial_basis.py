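"""Per-city areal spline bases.

A city's spatial surface is represented by tensor-product cubic B-splines
evaluated on a regular grid of points spanning the city's minimum bounding
rectangle, then averaged over the grid points falling inside each region
polygon.  The basis count is ``L = floor(r * N)`` for ``N`` regions and a
ratio ``r`` in [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math

import numpy as np
from scipy.interpolate import BSpline
from shapely import contains_xy, intersects_xy
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

log = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 100


@dataclasses.dataclass
class BasisMatrix:
    """Region-integrated basis values for one city (``N x L``)."""

    city_id: object
    L: int
    B: np.ndarray
    ratio: float
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape[1] != self.L:
            raise ValueError("B column count does not match L")
        if self.L > 0 and np.any(np.all(self.B == 0, axis=1)):
            raise ValueError("basis matrix has an all-zero row")


def grid_points(polygons, resolution: int = DEFAULT_RESOLUTION):
    """Regular ``resolution x resolution`` grid over the bounding rectangle.

    Returns ``(points, bounds)`` where ``points`` is ``(resolution**2, 2)``
    (x varying fastest) and ``bounds = (xmin, ymin, xmax, ymax)`` of the
    union of the city's polygons.  Corners are included, so the spacing is
    ``extent / (resolution - 1)`` per axis.
    """
    union = unary_union(list(polygons))
    xmin, ymin, xmax, ymax = union.bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate (zero-area) bounding rectangle")
    xs = np.linspace(xmin, xmax, resolution)
    ys = np.linspace(ymin, ymax, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts, (xmin, ymin, xmax, ymax)


class TensorCubicBasis:
    """Tensor-product clamped cubic B-spline basis on a rectangle.

    For a target count ``L >= 2`` the per-axis basis size is
    ``m = max(4, ceil(sqrt(L)))`` with ``m - 3`` equally spaced knot
    intervals; the first ``L`` of the ``m**2`` tensor functions are kept in
    row-major (x-major) order.  When ``L`` is a perfect square ``m**2`` the
    full tensor is used and forms a partition of unity.  ``L = 1`` is the
    degenerate constant basis.
    """

    def __init__(self, bounds, L: int):
        if L < 1:
            raise ValueError("L must be >= 1")
        self.bounds = tuple(map(float, bounds))
        self.L = int(L)
        if L == 1:
            self.m = 1
            return
        self.m = max(4, math.ceil(math.sqrt(L)))
        xmin, ymin, xmax, ymax = self.bounds
        self._tx = self._knots(xmin, xmax, self.m)
        self._ty = self._knots(ymin, ymax, self.m)

    @staticmethod
    def _knots(a: float, b: float, m: int) -> np.ndarray:
        breaks = np.linspace(a, b, m - 2)
        return np.concatenate([[a] * 3, breaks, [b] * 3])

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.L == 1:
            return np.ones((pts.shape[0], 1))
        xmin, ymin, xmax, ymax = self.bounds
        x = np.clip(pts[:, 0], xmin, xmax)
        y = np.clip(pts[:, 1], ymin, ymax)
        bx = BSpline.design_matrix(x, self._tx, 3).toarray()
        by = BSpline.design_matrix(y, self._ty, 3).toarray()
        full = np.einsum("ni,nj->nij", bx, by).reshape(pts.shape[0], self.m * self.m)
        return full[:, : self.L]


def cubic_basis_values(points: np.ndarray, L: int, bounds=None) -> np.ndarray:
    """Evaluate the tensor cubic basis at grid points (``n_points x L``)."""
    pts = np.asarray(points, dtype=float)
    if bounds is None:
        bounds = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    return TensorCubicBasis(bounds, L)(pts)


def assign_points(points: np.ndarray, polygons) -> np.ndarray:
    """Assign each point to at most one region (index, or -1 if outside).

    Pass 1 uses strict interior containment, which for tiled polygons acts
    as a half-open rule (shared edges belong to no interior).  Pass 2
    assigns remaining boundary points to the first region whose closed
    polygon touches them, so tilings cover every point exactly once and no
    point is double counted.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    owner = np.full(pts.shape[0], -1, dtype=int)
    for j, poly in enumerate(polygons):
        xmin, ymin, xmax, ymax = poly.bounds
        cand = (owner < 0) & (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        if not cand.any():
            continue
        idx = np.flatnonzero(cand)
        inside = contains_xy(poly, x[idx], y[idx])
        owner[idx[inside]] = j
    left = np.flatnonzero(owner < 0)
    if left.size:
        for j, poly in enumerate(polygons):
            if left.size == 0:
                break
            touch = intersects_xy(poly, x[left], y[left])
            owner[left[touch]] = j
            left = left[~touch]
    return owner


def integrate_over_regions(basis_at_points: np.ndarray, points: np.ndarray,
                           region_polygons, basis: TensorCubicBasis | None = None) -> np.ndarray:
    """Average basis values over the grid points inside each region.

    Regions containing no grid point fall back to the basis value at the
    polygon's representative interior point (logged); without a ``basis``
    evaluator that fallback is impossible and an error names the region.
    """
    vals = np.asarray(basis_at_points, dtype=float)
    owner = assign_points(points, region_polygons)
    nreg = len(region_polygons)
    B = np.zeros((nreg, vals.shape[1]))
    for j in range(nreg):
        mask = owner == j
        if mask.any():
            B[j] = vals[mask].mean(axis=0)
        else:
            if basis is None:
                raise ValueError(f"region {j} contains no grid points and no basis "
                                 "evaluator was supplied for fallback")
            log.warning("region %d contains no grid points; using representative point", j)
            rp = region_polygons[j].representative_point()
            B[j] = basis(np.array([[rp.x, rp.y]]))[0]
    return B


def basis_count(n_regions: int, ratio: float) -> int:
    """``L = floor(r * N)``, with ``L >= 1`` enforced for any positive r."""
    if not 0 <= ratio <= 1:
        raise ValueError("ratio must be in [0, 1]")
    L = math.floor(ratio * n_regions)
    if ratio > 0:
        L = max(L, 1)
    return L


def make_basis(table, city_id, r: float, resolution: int = DEFAULT_RESOLUTION) -> BasisMatrix:
    """Build the region-integrated basis matrix for one city at ratio ``r``."""
    polygons = table.city_polygons(city_id)
    L = basis_count(len(polygons), r)
    if L == 0:
        return BasisMatrix(city_id, 0, np.zeros((len(polygons), 0)), r, resolution)
    pts, bounds = grid_points(polygons, resolution)
    basis = TensorCubicBasis(bounds, L)
    vals = basis(pts)
    B = integrate_over_regions(vals, pts, polygons, basis=basis)
    return BasisMatrix(city_id, L, B, r, resolution)


def make_bases(table, r: float, resolution: int = DEFAULT_RESOLUTION) -> dict:
    """Basis matrices for every city in the table, keyed by city id."""
    return {c: make_basis(table, c, r, resolution) for c in table.cities}


def save_bases(bases: dict, path) -> None:
    """Write basis matrices to a JSON file keyed by city id."""
    payload = {
        str(c): {
            "city_id": c if not isinstance(c, (np.integer, np.floating)) else c.item(),
            "L": int(b.L),
            "ratio": float(b.ratio),
            "resolution": int(b.resolution),
            "B": b.B.tolist(),
        }
        for c, b in bases.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_bases(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for entry in payload.values():
        c = entry["city_id"]
        out[c] = BasisMatrix(c, entry["L"], np.asarray(entry["B"], dtype=float),
                             entry["ratio"], entry["resolution"])
    return out
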