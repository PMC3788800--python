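"""Grid-algebra primitives shared by the four migratory-concentration models.

The modeling framework scores every raster cell with a migratory importance
score (MIS): base *factors* valued in [0, 1] (0 = no importance, 1 = high
importance) are multiplied by *modifiers* in [0, 2] (0 removes a factor, 1
leaves it unchanged, 2 doubles it), each modified factor is normalized back
to [0, 1], the normalized terms are combined as a weighted sum, and the sum
is normalized once more so the final surface spans [0, 1].

This module provides the grid container and every geometric / map-algebra
sub-procedure those models share: feature rasterization, focal density,
distance decay, buffering with value carry-over, minimum-rectangle
orientation, topographic position, aspect-versus-wind updraft matching,
normalization, weighted combination and quantile classification.

Conventions: coordinates are projected meters; grids use an upper-left
origin with row-major cells (row 0 is the northern edge); all distances are
Euclidean in the projection plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Grid",
    "FactorLayer",
    "ModifierLayer",
    "QuantileClassGrid",
    "rasterize_valued_features",
    "focal_point_density",
    "density_to_importance",
    "inverse_distance_decay",
    "buffer_carry_value",
    "min_rect_northness",
    "topographic_position",
    "standardized_tpi",
    "aspect_from_elevation",
    "classify_aspect",
    "updraft_factor",
    "apply_modifiers",
    "normalize01",
    "combine_mis",
    "quantile_classify",
]

NODATA = -9999.0

#: compass categories used for aspect and prevailing wind, clockwise from north
COMPASS_8 = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

#: sentinel aspect value for flat cells (no defined downslope direction)
FLAT_ASPECT = -1.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class Grid:
    """A single-band raster: values, NoData mask, cell size and origin.

    ``mask`` is True where the cell holds no data. ``origin`` is the
    projected (x, y) of the grid's upper-left corner.
    """

    values: np.ndarray
    mask: np.ndarray = None
    cell_size: float = 90.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("unmasked grid values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """A new grid sharing this grid's geometry."""
        return Grid(
            np.asarray(values, dtype=float),
            self.mask.copy() if mask is None else mask,
            self.cell_size,
            self.origin,
        )

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates of every cell, each shaped like values."""
        nrow, ncol = self.shape
        cs = self.cell_size
        xs = self.origin[0] + (np.arange(ncol) + 0.5) * cs
        ys = self.origin[1] - (np.arange(nrow) + 0.5) * cs
        return np.broadcast_to(xs, (nrow, ncol)).copy(), np.broadcast_to(
            ys[:, None], (nrow, ncol)
        ).copy()

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing projected points (x, y)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Values at point locations; NaN outside the extent or on NoData."""
        row, col = self.cell_index(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        nrow, ncol = self.shape
        ok = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
        rr, cc = row[ok], col[ok]
        vals = self.values[rr, cc].astype(float)
        vals[self.mask[rr, cc]] = np.nan
        out[ok] = vals
        return out


def _check_geometry(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise ValueError("grids do not share shape, cell size and origin")


@dataclass
class FactorLayer:
    """A base importance layer; unmasked values must lie in [0, 1]."""

    grid: Grid
    name: str = "factor"

    def __post_init__(self) -> None:
        v = self.grid.values[~self.grid.mask]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError(f"factor '{self.name}' has values outside [0, 1]")


@dataclass
class ModifierLayer:
    """A multiplicative adjustment layer; unmasked values must lie in [0, 2]."""

    grid: Grid
    name: str = "modifier"

    def __post_init__(self) -> None:
        v = self.grid.values[~self.grid.mask]
        if v.size and (v.min() < -1e-9 or v.max() > 2 + 1e-9):
            raise ValueError(f"modifier '{self.name}' has values outside [0, 2]")


@dataclass
class QuantileClassGrid:
    """Integer bin ranks 1..k_effective plus the break values that define them."""

    classes: Grid
    breaks: np.ndarray
    k_effective: int = field(default=0)

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        if self.breaks.size > 1 and not np.all(np.diff(self.breaks) > 0):
            raise ValueError("breaks must be strictly increasing")
        if not self.k_effective:
            self.k_effective = len(self.breaks) + 1


# ---------------------------------------------------------------------------
# feature rasterization and distance operators


def _window(template: Grid, bounds, pad: float = 0.0):
    """Row/col slice of the cells whose squares may touch padded bounds."""
    minx, miny, maxx, maxy = bounds
    x0, y0 = template.origin
    cs = template.cell_size
    nrow, ncol = template.shape
    c0 = max(int(math.floor((minx - pad - x0) / cs)), 0)
    c1 = min(int(math.floor((maxx + pad - x0) / cs)) + 1, ncol)
    r0 = max(int(math.floor((y0 - (maxy + pad)) / cs)), 0)
    r1 = min(int(math.floor((y0 - (miny - pad)) / cs)) + 1, nrow)
    return r0, r1, c0, c1


def _cell_boxes(template: Grid, r0, r1, c0, c1):
    x0, y0 = template.origin
    cs = template.cell_size
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xmin = x0 + cols * cs
    ymax = y0 - rows * cs
    xm, ym = np.meshgrid(xmin, ymax)
    return shapely.box(xm.ravel(), (ym - cs).ravel(), (xm + cs).ravel(), ym.ravel())


def rasterize_valued_features(
    features: Iterable[tuple[BaseGeometry, float]], template: Grid
) -> Grid:
    """Burn valued geometries onto the template grid, max-combining overlaps.

    A cell takes the maximum value among the features whose geometry
    intersects the cell's square; cells touched by no feature are 0.
    An empty feature set yields an all-zero grid.
    """
    out = np.zeros(template.shape, dtype=float)
    for geom, value in features:
        if geom is None or geom.is_empty or value <= 0:
            continue
        r0, r1, c0, c1 = _window(template, geom.bounds)
        if r0 >= r1 or c0 >= c1:
            continue
        boxes = _cell_boxes(template, r0, r1, c0, c1)
        hits = shapely.intersects(boxes, geom).reshape(r1 - r0, c1 - c0)
        win = out[r0:r1, c0:c1]
        win[hits] = np.maximum(win[hits], value)
    return template.with_values(out)


def focal_point_density(
    points_xy: np.ndarray, template: Grid, radius: float = 5000.0
) -> Grid:
    """Points per km² within a circular window around every cell center.

    ``points_xy`` is an (n, 2) array of projected coordinates (typically
    polygon representative points, e.g. wetland centroids).
    """
    if radius < template.cell_size:
        raise ValueError("density radius must be at least one cell")
    points_xy = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    area_km2 = math.pi * (radius / 1000.0) ** 2
    if len(points_xy) == 0:
        return template.with_values(np.zeros(template.shape))
    tree = cKDTree(points_xy)
    xs, ys = template.cell_centers()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    counts = tree.query_ball_point(centers, r=radius, return_length=True)
    return template.with_values(counts.reshape(template.shape) / area_km2)


def density_to_importance(
    density: Grid,
    anchors: tuple[float, float] = (2.0, 28.0),
    values: tuple[float, float] = (0.25, 1.0),
    name: str = "wetland_density",
) -> FactorLayer:
    """Linear importance ramp on a density surface.

    Below ``anchors[0]`` (2/km²) the factor is 0; importance rises linearly
    from ``values[0]`` (0.25) at the lower anchor to ``values[1]`` (1.0) at
    the upper anchor (28/km²) and clamps there above it.
    """
    d = density.values
    if np.any(d[~density.mask] < 0):
        raise ValueError("density must be non-negative")
    lo, hi = anchors
    v0, v1 = values
    ramp = v0 + (d - lo) / (hi - lo) * (v1 - v0)
    out = np.where(d < lo, 0.0, np.minimum(ramp, v1))
    return FactorLayer(density.with_values(out), name)


def inverse_distance_decay(valued: Grid, max_dist: float = 500.0) -> Grid:
    """Spread source values outward with an inverse-distance-squared decay.

    Source cells (value > 0) keep their value. A cell at Euclidean distance
    d (0 < d ≤ max_dist) from its nearest source cell receives
    v·min(1, (cell_size/d)²) where v is that source's value; cells farther
    than ``max_dist`` receive 0.
    """
    src = (valued.values > 0) & ~valued.mask
    if not src.any():
        return valued.with_values(np.zeros(valued.shape))
    dist, (ri, ci) = ndimage.distance_transform_edt(
        ~src, sampling=valued.cell_size, return_indices=True
    )
    nearest = valued.values[ri, ci]
    with np.errstate(divide="ignore"):
        decay = np.minimum(1.0, (valued.cell_size / dist) ** 2)
    out = np.where(dist == 0, valued.values, np.where(dist <= max_dist, nearest * decay, 0.0))
    out[valued.mask] = valued.values[valued.mask]
    return valued.with_values(out)


def buffer_carry_value(
    features: Iterable[tuple[BaseGeometry, float]],
    dist: float,
    template: Grid,
) -> Grid:
    """Carry each feature's value to every cell within ``dist`` of it.

    Overlapping buffers take the maximum value; the distance is measured
    from the cell center to the feature geometry.
    """
    if dist <= 0:
        raise ValueError("buffer distance must be positive")
    out = np.zeros(template.shape, dtype=float)
    for geom, value in features:
        if geom is None or geom.is_empty or value <= 0:
            continue
        r0, r1, c0, c1 = _window(template, geom.bounds, pad=dist + template.cell_size)
        if r0 >= r1 or c0 >= c1:
            continue
        xs, ys = template.cell_centers()
        px = xs[r0:r1, c0:c1].ravel()
        py = ys[r0:r1, c0:c1].ravel()
        d = shapely.distance(shapely.points(px, py), geom).reshape(r1 - r0, c1 - c0)
        win = out[r0:r1, c0:c1]
        near = d <= dist
        win[near] = np.maximum(win[near], value)
    return template.with_values(out)


# ---------------------------------------------------------------------------
# orientation


def min_rect_northness(geometry: BaseGeometry) -> float:
    """North–south alignment of a geometry's minimum-area rectangle, in [1, 2].

    The minimum-area bounding rectangle is drawn around the geometry; with
    θ ∈ [0°, 180°) the azimuth of its long axis and δ = min(θ, 180° − θ) the
    deviation from north, the northness index is 2 − δ/90: 2 for a due
    north–south feature, 1 for due east–west, linear in between.
    """
    coords = shapely.get_coordinates(geometry)
    if len(np.unique(coords, axis=0)) < 2:
        raise ValueError("geometry must have at least two distinct vertices")
    rect = shapely.oriented_envelope(geometry)
    rc = shapely.get_coordinates(rect)
    if len(rc) >= 4:
        e1 = rc[1] - rc[0]
        e2 = rc[2] - rc[1]
        axis = e1 if np.hypot(*e1) >= np.hypot(*e2) else e2
    else:  # degenerate (collinear input): the envelope is the segment itself
        axis = rc[-1] - rc[0]
    theta = math.degrees(math.atan2(axis[0], axis[1])) % 180.0
    delta = min(theta, 180.0 - theta)
    return 2.0 - delta / 90.0


# ---------------------------------------------------------------------------
# terrain


def _disk(radius_cells: int) -> np.ndarray:
    r = int(radius_cells)
    yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx <= r * r).astype(float)


def standardized_tpi(elevation: Grid, radius_cells: int) -> Grid:
    """Topographic position index in a circular window, in SD units.

    TPI = elevation − mean(elevation within the window); the surface is
    standardized by its own standard deviation over unmasked cells, so +1
    means one SD more locally elevated than the window average.
    """
    k = _disk(radius_cells)
    if k.shape[0] > min(elevation.shape):
        raise ValueError("TPI window larger than grid")
    valid = (~elevation.mask).astype(float)
    filled = np.where(elevation.mask, 0.0, elevation.values)
    counts = fftconvolve(valid, k, mode="same")
    sums = fftconvolve(filled, k, mode="same")
    mean = sums / np.maximum(counts, 1e-12)
    tpi = np.where(elevation.mask, 0.0, elevation.values - mean)
    # suppress FFT round-off so a featureless surface standardizes to zero
    scale = max(1.0, float(np.abs(elevation.values[~elevation.mask]).max(initial=0.0)))
    tpi[np.abs(tpi) < 1e-8 * scale] = 0.0
    sd = tpi[~elevation.mask].std()
    if sd > 1e-12:
        tpi = tpi / sd
    return elevation.with_values(tpi)


def topographic_position(
    elevation: Grid,
    windows: Sequence[int] = (20, 50),
    threshold: float = 1.0,
    name: str = "topography",
) -> FactorLayer:
    """Ridge-like landform factor from multi-scale topographic position.

    A cell is flagged high-importance (1) when its standardized TPI exceeds
    ``threshold`` in any of the circular windows (radii in cells); all other
    cells are 0. The default two windows capture both narrow hogbacks and
    broad ridge systems.
    """
    flag = np.zeros(elevation.shape, dtype=bool)
    for w in windows:
        flag |= standardized_tpi(elevation, w).values > threshold
    out = np.where(elevation.mask, 0.0, flag.astype(float))
    return FactorLayer(elevation.with_values(out), name)


def aspect_from_elevation(elevation: Grid) -> Grid:
    """Downslope azimuth in degrees clockwise from north; flat cells get −1."""
    grow, gcol = np.gradient(elevation.values, elevation.cell_size)
    # grow is d(elev)/d(row): rows increase southward, so northward slope = -grow
    east, north = -gcol, grow
    az = (np.degrees(np.arctan2(east, north))) % 360.0
    flat = np.hypot(east, north) < 1e-9
    az[flat] = FLAT_ASPECT
    return elevation.with_values(az)


def classify_aspect(aspect: Grid) -> np.ndarray:
    """8-category compass class of an aspect grid; −1 marks flat cells."""
    az = aspect.values
    cls = np.floor(((az + 22.5) % 360.0) / 45.0).astype(int)
    cls[az == FLAT_ASPECT] = -1
    return cls


def updraft_factor(aspect: Grid, wind_category: Grid, name: str = "updrafts") -> FactorLayer:
    """Slope-aspect versus prevailing-wind agreement factor.

    Aspect is classified into the same 8 compass categories as the wind
    grid. Matching categories score 1 (strong deflection updrafts),
    circularly adjacent categories 0.75, everything else 0; flat cells 0.
    """
    _check_geometry(aspect, wind_category)
    wind = wind_category.values
    wv = wind[~wind_category.mask]
    if wv.size and (np.any(wv < 0) | np.any(wv > 7) | np.any(wv != np.round(wv))):
        raise ValueError("wind categories must be integers 0..7")
    acls = classify_aspect(aspect)
    diff = np.mod(acls - wind.astype(int), 8)
    out = np.where(diff == 0, 1.0, np.where((diff == 1) | (diff == 7), 0.75, 0.0))
    out[acls < 0] = 0.0
    out[aspect.mask | wind_category.mask] = 0.0
    return FactorLayer(aspect.with_values(out), name)


# ---------------------------------------------------------------------------
# model algebra


def apply_modifiers(factor: FactorLayer, modifiers: Sequence[ModifierLayer]) -> Grid:
    """Cellwise product of a factor with its modifiers (pre-normalization).

    A modifier of 0 removes the factor at that cell, 1 leaves it unchanged,
    2 doubles it; the product can therefore exceed 1 and is normalized later.
    """
    grid = factor.grid
    out = grid.values.copy()
    for m in modifiers:
        _check_geometry(grid, m.grid)
        out = out * m.grid.values
    return grid.with_values(out)


def normalize01(grid: Grid) -> Grid:
    """Divide by the maximum unmasked value; an all-zero grid stays all zero."""
    v = grid.values[~grid.mask]
    if v.size and v.min() < 0:
        raise ValueError("normalize01 requires non-negative values")
    top = v.max() if v.size else 0.0
    if top <= 0:
        return grid.with_values(np.zeros(grid.shape))
    return grid.with_values(grid.values / top)


def combine_mis(
    terms: Sequence[tuple[Grid, float]], mask: np.ndarray | None = None
) -> Grid:
    """Weighted sum of normalized term grids, renormalized to [0, 1].

    This is the additive combination at the heart of the migratory
    importance score: MIS = normalize01(Σᵢ wᵢ·termᵢ). Because of the final
    normalization the result is invariant to a common positive scaling of
    all weights.
    """
    if not terms:
        raise ValueError("combine_mis requires at least one term")
    first = terms[0][0]
    total = np.zeros(first.shape, dtype=float)
    for grid, weight in terms:
        if weight <= 0:
            raise ValueError("term weights must be positive")
        _check_geometry(first, grid)
        total = total + weight * grid.values
    out_mask = first.mask.copy()
    for grid, _ in terms:
        out_mask |= grid.mask
    if mask is not None:
        out_mask |= np.asarray(mask, dtype=bool)
    total[out_mask] = 0.0
    return normalize01(Grid(total, out_mask, first.cell_size, first.origin))


def quantile_classify(grid: Grid, k: int = 5) -> QuantileClassGrid:
    """Classify a grid into k bins of (approximately) equal cell counts.

    Breaks sit at the 1/k … (k−1)/k empirical quantiles of the unmasked
    values. Duplicate breaks caused by heavy ties (e.g. a large mass of
    zeros) are merged, reducing ``k_effective``; a value equal to a break
    falls in the lower bin, so tied masses land in a single bin.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    vals = grid.values[~grid.mask]
    if vals.size < k:
        raise ValueError("fewer unmasked cells than bins")
    breaks = np.quantile(vals, np.arange(1, k) / k)
    breaks = np.unique(breaks)
    breaks = breaks[breaks < vals.max()]  # a break at the maximum would empty the top bin
    classes = np.searchsorted(breaks, grid.values, side="left") + 1
    classes = classes.astype(float)
    classes[grid.mask] = 0
    return QuantileClassGrid(grid.with_values(classes), breaks, len(breaks) + 1)
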