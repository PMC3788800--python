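"""Landscape layer containers: the grid stack plus stream and wetland features.

A :class:`LayerStack` holds every input layer the four group models consume:
continuous grids (elevation, aspect, probability indices), categorical grids
(land cover, crops, prevailing wind category, flyway mask) and the two vector
feature sets (streams with order/perenniality attributes, wetland polygons
with size class attributes). All grids in a stack share shape, cell size,
origin and NoData mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .engine import Grid

__all__ = [
    "StreamFeature",
    "WetlandFeature",
    "LayerStack",
    "GRID_NAMES",
    "LandCover",
    "CropClass",
]


class LandCover:
    """Integer codes for the categorical land-cover grid."""

    OTHER = 0
    SHORT_MIXED_GRASS = 1      # short-grass or mixed-grass prairie
    MEDIUM_TALL_GRASS = 2      # medium or tall grasslands
    ARID_SHRUB = 3             # arid shrublands
    FOREST_RIPARIAN = 4
    RIPARIAN_WOODLAND_SHRUBLAND = 5
    SHRUB_RIPARIAN = 6
    GRASS_RIPARIAN = 7
    CONIFER_FOREST = 8

    ALL = tuple(range(9))
    RIPARIAN = (FOREST_RIPARIAN, RIPARIAN_WOODLAND_SHRUBLAND, SHRUB_RIPARIAN, GRASS_RIPARIAN)


class CropClass:
    """Integer codes for the cultivated-crops grid."""

    NONE = 0
    GRAIN = 1
    HAY_PASTURE_NONGRAIN = 2

    ALL = (NONE, GRAIN, HAY_PASTURE_NONGRAIN)


#: grid layers every complete stack provides
GRID_NAMES = (
    "elevation",
    "aspect",
    "land_cover",
    "bare_ground",
    "cottonwood",
    "willow",
    "prairie_dog",
    "wind_direction_category",
    "crops",
    "flyway_mask",
)

_PROBABILITY_GRIDS = ("bare_ground", "cottonwood", "willow", "prairie_dog")


@dataclass
class StreamFeature:
    """A stream polyline with the attributes the models consume."""

    geometry: LineString
    order: int
    perennial: bool = False
    large_river: bool = False

    def __post_init__(self) -> None:
        if not 0 <= int(self.order) <= 7:
            raise ValueError("stream order must be in 0..7")


@dataclass
class WetlandFeature:
    """A wetland polygon; ``area_ha`` is the attribute the size factor reads."""

    geometry: Polygon
    area_ha: float
    kind: str = "palustrine"

    def __post_init__(self) -> None:
        if self.area_ha < 0:
            raise ValueError("wetland area must be non-negative")
        if self.kind not in ("lacustrine", "palustrine"):
            raise ValueError("wetland kind must be 'lacustrine' or 'palustrine'")

    @property
    def representative_point(self) -> tuple[float, float]:
        c = self.geometry.centroid
        return (c.x, c.y)


@dataclass
class LayerStack:
    """Named grids plus stream and wetland features for one landscape."""

    grids: dict[str, Grid]
    streams: list[StreamFeature] = field(default_factory=list)
    wetlands: list[WetlandFeature] = field(default_factory=list)

    def __getitem__(self, name: str) -> Grid:
        try:
            return self.grids[name]
        except KeyError:
            raise KeyError(
                f"layer '{name}' missing from stack (have: {sorted(self.grids)})"
            ) from None

    @property
    def template(self) -> Grid:
        return next(iter(self.grids.values()))

    def validate(self) -> None:
        """Raise if any stack invariant is violated."""
        if not self.grids:
            raise ValueError("stack has no grids")
        tmpl = self.template
        for name, g in self.grids.items():
            if not tmpl.same_geometry(g):
                raise ValueError(f"grid '{name}' does not share the stack geometry")
            if not np.array_equal(tmpl.mask, g.mask):
                raise ValueError(f"grid '{name}' does not share the stack NoData mask")
        for name in _PROBABILITY_GRIDS:
            if name in self.grids:
                v = self.grids[name].values[~self.grids[name].mask]
                if v.size and (v.min() < 0 or v.max() > 1):
                    raise ValueError(f"probability grid '{name}' outside [0, 1]")
        if "wind_direction_category" in self.grids:
            g = self.grids["wind_direction_category"]
            v = g.values[~g.mask]
            if v.size and (np.any(v < 0) or np.any(v > 7) or np.any(v != np.round(v))):
                raise ValueError("wind_direction_category must hold integers 0..7")
        for s in self.streams:
            if not 0 <= s.order <= 7:
                raise ValueError("stream order must be in 0..7")

    def wetland_points(self) -> np.ndarray:
        """(n, 2) representative points of all wetlands (for focal density)."""
        if not self.wetlands:
            return np.empty((0, 2))
        return np.array([w.representative_point for w in self.wetlands])
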