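"""Synthetic landscape, occurrence and wind-potential generators.

The generators emulate the structure of the real inputs the migration
models assume — a mountain/basin elevation surface with oriented ridges, a
branching stream network with orders 0–7, clustered wetlands spanning the
<5 / 5–15 / >15 ha size classes, a categorical land-cover field including
prairie and riparian classes, 0–1 probability surfaces, an 8-category
prevailing-wind grid, a flyway mask, occurrence points with a known
relationship to a concentration surface, and a ridge-associated wind
development potential surface — so every downstream stage is testable
without any external GIS download.

Everything is reproducible from the seed; identical parameters and seed
produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .engine import Grid, aspect_from_elevation, normalize01, standardized_tpi
from .layers import CropClass, LandCover, LayerStack, StreamFeature, WetlandFeature

__all__ = [
    "LandscapeParams",
    "generate_landscape",
    "generate_occurrences",
    "generate_wind_potential",
    "synthetic_migration_windows",
]


@dataclass
class LandscapeParams:
    """Knobs of the synthetic landscape; defaults give a 150×150 cell
    (13.5×13.5 km at 90 m) landscape exercising every model input."""

    extent_cells: tuple[int, int] = (150, 150)
    cell_size: float = 90.0
    seed: int = 0
    n_ridges: int = 6
    ridge_orientation_mix: float = 0.7
    n_stream_trunks: int = 4
    wetland_cluster_count: int = 5
    wetlands_per_cluster: int = 220
    wetland_area_range: tuple[float, float] = (0.5, 40.0)
    elevation_range: tuple[float, float] = (1500.0, 3200.0)
    flyway_split_col: int | None = None
    crop_fraction: float = 0.08

    def __post_init__(self) -> None:
        rows, cols = self.extent_cells
        if rows <= 0 or cols <= 0:
            raise ValueError("extent_cells must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        for frac in (self.ridge_orientation_mix, self.crop_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if not self.wetland_area_range[0] < self.wetland_area_range[1]:
            raise ValueError("wetland_area_range must be (min, max) with min < max")
        if not self.elevation_range[0] < self.elevation_range[1]:
            raise ValueError("elevation_range must be (min, max) with min < max")
        if self.flyway_split_col is None:
            self.flyway_split_col = cols // 2


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially correlated noise rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (f - lo) / (hi - lo)


def _elevation(params: LandscapeParams, rng: np.random.Generator) -> np.ndarray:
    rows, cols = params.extent_cells
    yy, xx = np.mgrid[0:rows, 0:cols]
    xn = xx / max(cols - 1, 1)
    yn = yy / max(rows - 1, 1)
    # westward mountains sloping into eastern basins, as in a basin-and-range setting
    surface = 0.45 * (1.0 - xn) + 0.1 * yn
    n_ns = int(round(params.ridge_orientation_mix * params.n_ridges))
    for i in range(params.n_ridges):
        ns = i < n_ns
        azimuth = math.radians((0.0 if ns else 90.0) + rng.uniform(-15, 15))
        cx = rng.uniform(0.1, 0.9) * cols
        cy = rng.uniform(0.1, 0.9) * rows
        length = rng.uniform(0.25, 0.7) * min(rows, cols)
        width = rng.uniform(2.0, 5.0)
        amp = rng.uniform(0.35, 0.8)
        # distance along/across the ridge axis (axis azimuth measured from north)
        dx = xx - cx
        dy = cy - yy  # +y is north
        along = dx * math.sin(azimuth) + dy * math.cos(azimuth)
        across = dx * math.cos(azimuth) - dy * math.sin(azimuth)
        surface = surface + amp * np.exp(
            -0.5 * (along / (length / 2.0)) ** 2 - 0.5 * (across / width) ** 2
        )
    surface = surface + 0.05 * _smooth_field(rng, (rows, cols), sigma=3.0)
    lo, hi = params.elevation_range
    surface = (surface - surface.min()) / (surface.max() - surface.min())
    return lo + surface * (hi - lo)


def _walk_line(
    rng: np.random.Generator,
    start: tuple[float, float],
    heading_deg: float,
    length: float,
    step: float,
    jitter_deg: float = 18.0,
) -> LineString:
    """A jittered polyline of roughly the requested length and heading."""
    pts = [start]
    heading = math.radians(heading_deg)
    n = max(int(length / step), 2)
    for _ in range(n):
        heading += math.radians(rng.uniform(-jitter_deg, jitter_deg))
        x = pts[-1][0] + step * math.sin(heading)
        y = pts[-1][1] + step * math.cos(heading)
        pts.append((x, y))
    return LineString(pts)


def _streams(params: LandscapeParams, rng: np.random.Generator, template: Grid) -> list[StreamFeature]:
    rows, cols = params.extent_cells
    cs = params.cell_size
    width = cols * cs
    height = rows * cs
    x0, y0 = template.origin
    streams: list[StreamFeature] = []
    n_ns = int(round(params.ridge_orientation_mix * params.n_stream_trunks))
    for i in range(params.n_stream_trunks):
        ns = i < n_ns
        if ns:
            start = (x0 + rng.uniform(0.15, 0.85) * width, y0)
            heading = 180.0 + rng.uniform(-10, 10)  # flowing south
        else:
            start = (x0, y0 - rng.uniform(0.15, 0.85) * height)
            heading = 90.0 + rng.uniform(-10, 10)  # flowing east
        trunk = _walk_line(rng, start, heading, 1.1 * max(width, height), step=5 * cs)
        order = 7 if i == 0 else int(rng.integers(5, 7))
        streams.append(
            StreamFeature(trunk, order=order, perennial=True, large_river=(order == 7))
        )
        # tributaries: order decreases with branching depth
        frontier = [(trunk, order, heading)]
        for _depth in range(2):
            next_frontier = []
            for parent, porder, pheading in frontier:
                for _ in range(int(rng.integers(1, 4))):
                    t = rng.uniform(0.2, 0.9)
                    anchor = parent.interpolate(t, normalized=True)
                    side = rng.choice([-1.0, 1.0])
                    heading2 = pheading + side * rng.uniform(50, 110)
                    length2 = rng.uniform(0.1, 0.3) * max(width, height)
                    branch = _walk_line(rng, (anchor.x, anchor.y), heading2, length2, step=4 * cs)
                    border = max(porder - int(rng.integers(1, 4)), 0)
                    perennial = bool(border >= 3 or rng.random() < 0.35)
                    streams.append(StreamFeature(branch, order=border, perennial=perennial))
                    next_frontier.append((branch, border, heading2))
            frontier = next_frontier
    return streams


def _wetlands(params: LandscapeParams, rng: np.random.Generator, template: Grid) -> list[WetlandFeature]:
    rows, cols = params.extent_cells
    cs = params.cell_size
    x0, y0 = template.origin
    wetlands: list[WetlandFeature] = []
    lo, hi = params.wetland_area_range
    for _ in range(params.wetland_cluster_count):
        ccx = x0 + rng.uniform(0.1, 0.9) * cols * cs
        ccy = y0 - rng.uniform(0.1, 0.9) * rows * cs
        # cluster spread varies so focal density spans both sides of the
        # 2 wetlands/km^2 ramp threshold within one landscape
        sigma = rng.uniform(800.0, 2200.0)
        for _ in range(params.wetlands_per_cluster):
            wx = ccx + rng.normal(scale=sigma)
            wy = ccy + rng.normal(scale=sigma)
            area_ha = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            radius = math.sqrt(area_ha * 1e4 / math.pi)
            geom = Point(wx, wy).buffer(radius, quad_segs=4)
            kind = "lacustrine" if area_ha > 15 else "palustrine"
            wetlands.append(WetlandFeature(geom, area_ha=area_ha, kind=kind))
    return wetlands


def _near_streams_mask(
    streams: list[StreamFeature], template: Grid, dist: float, min_order: int = 2
) -> np.ndarray:
    from .engine import buffer_carry_value

    feats = [(s.geometry, 1.0) for s in streams if s.order >= min_order]
    if not feats:
        return np.zeros(template.shape, dtype=bool)
    return buffer_carry_value(feats, dist, template).values > 0


def generate_landscape(params: LandscapeParams) -> LayerStack:
    """Generate a complete input landscape from the parameter set.

    The elevation surface is a sloped plane plus anisotropic Gaussian
    ridges with the requested orientation mix; streams, wetland clusters,
    land cover, probability indices, the wind-category grid, crops and the
    flyway mask are derived around it. Reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.extent_cells
    cs = params.cell_size
    template = Grid(np.zeros((rows, cols)), cell_size=cs, origin=(0.0, rows * cs))

    elevation = template.with_values(_elevation(params, rng))
    aspect = aspect_from_elevation(elevation)
    streams = _streams(params, rng, template)
    wetlands = _wetlands(params, rng, template)

    riparian_zone = _near_streams_mask(
        [s for s in streams if s.perennial], template, dist=2.5 * cs
    )

    # categorical land cover from a correlated field, riparian classes along streams
    base = _smooth_field(rng, (rows, cols), sigma=6.0)
    land_cover = np.select(
        [base < 0.3, base < 0.55, base < 0.8],
        [LandCover.SHORT_MIXED_GRASS, LandCover.MEDIUM_TALL_GRASS, LandCover.ARID_SHRUB],
        default=LandCover.CONIFER_FOREST,
    ).astype(float)
    rip = _smooth_field(rng, (rows, cols), sigma=4.0)
    rip_class = np.select(
        [rip < 0.25, rip < 0.5, rip < 0.75],
        [LandCover.GRASS_RIPARIAN, LandCover.SHRUB_RIPARIAN, LandCover.RIPARIAN_WOODLAND_SHRUBLAND],
        default=LandCover.FOREST_RIPARIAN,
    )
    land_cover[riparian_zone] = rip_class[riparian_zone]

    bare = np.clip(
        0.7 * _smooth_field(rng, (rows, cols), sigma=5.0)
        + 0.3 * np.isin(land_cover, (LandCover.SHORT_MIXED_GRASS, LandCover.ARID_SHRUB)),
        0.0,
        1.0,
    )
    low_elev = elevation.values < np.quantile(elevation.values, 0.6)
    cottonwood = np.clip(
        0.45 * _smooth_field(rng, (rows, cols), sigma=5.0) + 0.55 * (riparian_zone & low_elev),
        0.0,
        1.0,
    )
    willow = np.clip(
        0.45 * _smooth_field(rng, (rows, cols), sigma=5.0) + 0.55 * riparian_zone, 0.0, 1.0
    )
    prairie_dog = np.clip(
        0.5 * _smooth_field(rng, (rows, cols), sigma=7.0)
        + 0.5 * (land_cover == LandCover.SHORT_MIXED_GRASS),
        0.0,
        1.0,
    )

    # prevailing wind: a dominant regional direction with coherent local shifts
    dominant = int(rng.integers(0, 8))
    shift = np.round(2.0 * (_smooth_field(rng, (rows, cols), sigma=10.0) - 0.5) * 2.0)
    wind_cat = np.mod(dominant + shift, 8).astype(float)

    # crops occupy the lowest, flattest fraction of the landscape
    crops = np.zeros((rows, cols))
    if params.crop_fraction > 0:
        suit = (1.0 - (elevation.values - elevation.values.min())
                / (np.ptp(elevation.values) + 1e-12))
        suit = 0.6 * suit + 0.4 * _smooth_field(rng, (rows, cols), sigma=6.0)
        cut = np.quantile(suit, 1.0 - params.crop_fraction)
        cropped = suit >= cut
        split = _smooth_field(rng, (rows, cols), sigma=5.0) > 0.5
        crops[cropped & split] = CropClass.GRAIN
        crops[cropped & ~split] = CropClass.HAY_PASTURE_NONGRAIN

    flyway = np.zeros((rows, cols))
    flyway[:, params.flyway_split_col :] = 1.0

    stack = LayerStack(
        grids={
            "elevation": elevation,
            "aspect": aspect,
            "land_cover": template.with_values(land_cover),
            "bare_ground": template.with_values(bare),
            "cottonwood": template.with_values(cottonwood),
            "willow": template.with_values(willow),
            "prairie_dog": template.with_values(prairie_dog),
            "wind_direction_category": template.with_values(wind_cat),
            "crops": template.with_values(crops),
            "flyway_mask": template.with_values(flyway),
        },
        streams=streams,
        wetlands=wetlands,
    )
    stack.validate()
    return stack


def synthetic_migration_windows(n_species: int, seed: int = 0) -> pd.DataFrame:
    """A synthetic (species, start, end) migration-window table.

    Windows are arbitrary spring spans; they exist so the date filter of the
    validation chain is exercisable, mirroring how real windows are species
    metadata supplied as data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_species):
        start_doy = int(rng.integers(60, 110))  # early March to mid April
        length = int(rng.integers(30, 75))
        start = pd.Timestamp("2001-01-01") + pd.Timedelta(days=start_doy - 1)
        end = start + pd.Timedelta(days=length)
        rows.append(
            {
                "species": f"sp{i + 1:02d}",
                "start_mmdd": start.strftime("%m-%d"),
                "end_mmdd": end.strftime("%m-%d"),
            }
        )
    return pd.DataFrame(rows)


def generate_occurrences(
    mis: Grid,
    n: int,
    bias: float = 2.0,
    n_species: int = 5,
    seed: int = 0,
    windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sample occurrence points preferentially from high-concentration cells.

    Cells are drawn with probability proportional to ``mis**bias`` (bias = 0
    is uniform over unmasked cells); points are jittered uniformly within
    their cell, assigned round-robin to ``n_species`` species, and given
    randomized positional-accuracy and quality-rank fields so the validation
    filters have something to do.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if bias < 0:
        raise ValueError("bias must be non-negative")
    rng = np.random.default_rng(seed)
    unmasked = ~mis.mask
    vals = np.clip(mis.values, 0.0, None)
    if bias == 0:
        weights = unmasked.astype(float)
    else:
        weights = np.where(unmasked, vals**bias, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot sample: mis**bias is zero everywhere")
    flat_idx = rng.choice(weights.size, size=n, p=(weights / total).ravel())
    row, col = np.unravel_index(flat_idx, mis.shape)
    cs = mis.cell_size
    x = mis.origin[0] + (col + rng.uniform(0, 1, n)) * cs
    y = mis.origin[1] - (row + rng.uniform(0, 1, n)) * cs
    species = np.array([f"sp{(i % n_species) + 1:02d}" for i in range(n)])
    if windows is None:
        windows = synthetic_migration_windows(n_species, seed=seed)
    win = windows.set_index("species")
    dates = []
    year = 2010
    for sp in species:
        start = pd.Timestamp(f"{year}-{win.loc[sp, 'start_mmdd']}")
        end = pd.Timestamp(f"{year}-{win.loc[sp, 'end_mmdd']}")
        span = max((end - start).days, 1)
        dates.append((start + pd.Timedelta(days=int(rng.integers(0, span)))).strftime("%Y-%m-%d"))
    accuracy = np.round(rng.lognormal(mean=4.5, sigma=1.0, size=n), 1)  # median ~90 m
    quality = rng.integers(1, 6, size=n)  # 5 = best quality
    return pd.DataFrame(
        {
            "species": species,
            "x": x,
            "y": y,
            "date": dates,
            "accuracy_m": accuracy,
            "quality_rank": quality,
        }
    )


def generate_wind_potential(
    stack: LayerStack, ridge_weight: float = 0.6, seed: int = 0
) -> Grid:
    """A wind-development-potential surface in [0, 1].

    The surface mixes a ridge-association component (squashed standardized
    topographic position) with an eastward regional gradient, plus a little
    correlated noise — emulating the spatial character of a fitted
    development-potential model without fitting one.
    """
    if not 0 <= ridge_weight <= 1:
        raise ValueError("ridge_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    elevation = stack["elevation"]
    rows, cols = elevation.shape
    radius = max(3, min(20, min(rows, cols) // 4))
    tpi = standardized_tpi(elevation, radius).values
    tpi01 = 1.0 / (1.0 + np.exp(-2.0 * tpi))  # squash SD units into (0, 1)
    east = np.broadcast_to(np.linspace(0.0, 1.0, cols), (rows, cols))
    noise = _smooth_field(rng, (rows, cols), sigma=4.0)
    raw = 0.85 * (ridge_weight * tpi01 + (1.0 - ridge_weight) * east) + 0.15 * noise
    raw = raw - raw.min()
    return normalize01(elevation.with_values(raw))
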