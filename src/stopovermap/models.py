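"""The four bird-group migratory concentration models.

Each model is a :class:`GroupModelSpec`: an ordered list of terms, where a
term pairs a base factor (streams, wetland density, topography, …) with the
modifiers that scale it (elevation, river proximity, orientation, …) and a
positive weight. Evaluating a spec against a :class:`~stopovermap.layers.LayerStack`
builds each factor from the landscape layers, multiplies it by its
modifiers, normalizes the product to [0, 1], sums the weighted normalized
terms and normalizes the sum — yielding a migratory importance score (MIS)
surface in [0, 1].

The four canned specs encode the published expert parameterizations:

* wetland birds (spring): streams + 3×(wetland density·elev·river·flyway)
  + wetland size·elev·river·flyway + forage·river + take-off/approach buffer
* riparian birds (spring): 2×(streams·orientation·cottonwood·willow·
  structural diversity) + wetland density·elev·river
* raptors (fall): topography·orientation + updrafts + thermal formation
  + streams·orientation·cottonwood
* sparse grassland birds (spring): land cover·bare ground + prairie dogs

Every numeric threshold in the factor/modifier tables lives in
:class:`ModelConfig` so a run can override any table value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage import measure

from . import engine
from .engine import FactorLayer, Grid, ModifierLayer
from .layers import CropClass, LandCover, LayerStack

__all__ = [
    "Term",
    "GroupModelSpec",
    "MISRaster",
    "ModelConfig",
    "GROUPS",
    "canned_spec",
    "prepare_factor",
    "prepare_modifier",
    "run_model",
    "ModelContext",
]

GROUPS = ("wetland", "riparian", "raptor", "sparse_grassland")


@dataclass
class ModelConfig:
    """Every table-derived threshold of the four models, overridable per run."""

    # elevation modifier (meters -> multiplier)
    elevation_breaks: tuple[float, float] = (2438.0, 2743.0)
    elevation_values: tuple[float, float, float] = (1.0, 0.5, 0.1)
    # proximity-to-river modifier (km -> multiplier), streams of order >= 3
    proximity_breaks_km: tuple[float, float] = (5.0, 10.0)
    proximity_values: tuple[float, float, float] = (2.0, 1.5, 1.0)
    proximity_min_order: int = 3
    flyway_value: float = 1.25
    # wetland density factor
    density_radius_m: float = 5000.0
    density_anchors: tuple[float, float] = (2.0, 28.0)
    density_ramp: tuple[float, float] = (0.25, 1.0)
    # wetland size factor (ha breaks -> values below/between/above)
    wetland_size_breaks_ha: tuple[float, float] = (5.0, 15.0)
    wetland_size_values: tuple[float, float, float] = (0.0, 0.5, 1.0)
    # stream factor values
    stream_value_large: float = 1.0
    stream_value_mid: float = 0.5       # orders 3-4
    stream_value_low: float = 0.25      # order 2 (wetland model)
    riparian_perennial_value: float = 1.0
    riparian_intermittent_value: float = 0.25
    # distance operators
    decay_max_dist_m: float = 500.0
    buffer_dist_m: float = 1000.0
    # topographic position factor
    tpi_windows: tuple[int, int] = (20, 50)
    tpi_threshold: float = 1.0
    # land-cover factor values (grassland model)
    landcover_values: dict = field(
        default_factory=lambda: {
            LandCover.SHORT_MIXED_GRASS: 1.0,
            LandCover.MEDIUM_TALL_GRASS: 0.5,
            LandCover.ARID_SHRUB: 0.25,
        }
    )
    # forage factor values (wetland model)
    forage_values: dict = field(
        default_factory=lambda: {CropClass.GRAIN: 1.0, CropClass.HAY_PASTURE_NONGRAIN: 0.5}
    )
    # riparian structural diversity modifier
    structural_values: dict = field(
        default_factory=lambda: {
            LandCover.FOREST_RIPARIAN: 2.0,
            LandCover.RIPARIAN_WOODLAND_SHRUBLAND: 1.5,
            LandCover.SHRUB_RIPARIAN: 1.25,
            LandCover.GRASS_RIPARIAN: 1.0,
        }
    )

    def override(self, **kwargs) -> "ModelConfig":
        valid = {f.name for f in fields(self)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(valid)}")
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Term:
    """One summand of the model: factor × modifiers × weight."""

    factor_id: str
    modifier_ids: tuple[str, ...] = ()
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("term weight must be positive")
        object.__setattr__(self, "modifier_ids", tuple(self.modifier_ids))


@dataclass(frozen=True)
class GroupModelSpec:
    group: str
    season: str
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a model needs at least one term")
        object.__setattr__(self, "terms", tuple(self.terms))


@dataclass
class MISRaster:
    """A migratory importance surface plus the spec that produced it."""

    grid: Grid
    spec: GroupModelSpec | None = None


# display names used in sensitivity reports (and nothing else)
FACTOR_NAMES = {
    "streams_wetland": "Streams",
    "streams_riparian": "Streams",
    "streams_raptor": "Streams",
    "wetland_density": "Wetland density",
    "wetland_size": "Wetland size",
    "forage": "Forage availability",
    "takeoff_buffer": "Take-off/approach buffer",
    "topography": "Topography",
    "updrafts": "Updrafts",
    "thermals": "Thermal formation",
    "land_cover": "Land cover",
    "prairie_dog": "Prairie dog occurrence",
}

MODIFIER_NAMES = {
    "elevation": "elevation",
    "river_proximity": "river proximity",
    "flyway": "flyway location",
    "stream_orientation": "orientation",
    "topo_orientation": "orientation",
    "cottonwood": "cottonwood abundance",
    "willow": "willow abundance",
    "structural_diversity": "structural diversity",
    "bare_ground": "bare ground",
}


def canned_spec(group: str) -> GroupModelSpec:
    """The published expert parameterization for one of the four groups."""
    if group == "wetland":
        return GroupModelSpec(
            "wetland",
            "spring",
            (
                Term("streams_wetland", (), 1.0),
                Term("wetland_density", ("elevation", "river_proximity", "flyway"), 3.0),
                Term("wetland_size", ("elevation", "river_proximity", "flyway"), 1.0),
                Term("forage", ("river_proximity",), 1.0),
                Term("takeoff_buffer", (), 1.0),
            ),
        )
    if group == "riparian":
        return GroupModelSpec(
            "riparian",
            "spring",
            (
                Term(
                    "streams_riparian",
                    ("stream_orientation", "cottonwood", "willow", "structural_diversity"),
                    2.0,
                ),
                Term("wetland_density", ("elevation", "river_proximity"), 1.0),
            ),
        )
    if group == "raptor":
        return GroupModelSpec(
            "raptor",
            "fall",
            (
                Term("topography", ("topo_orientation",), 1.0),
                Term("updrafts", (), 1.0),
                Term("thermals", (), 1.0),
                Term("streams_raptor", ("stream_orientation", "cottonwood"), 1.0),
            ),
        )
    if group == "sparse_grassland":
        return GroupModelSpec(
            "sparse_grassland",
            "spring",
            (
                Term("land_cover", ("bare_ground",), 1.0),
                Term("prairie_dog", (), 1.0),
            ),
        )
    raise ValueError(f"unknown group '{group}'; expected one of {GROUPS}")


# ---------------------------------------------------------------------------
# factor builders


def _wetland_stream_value(s, cfg: ModelConfig) -> float:
    if s.large_river:
        return cfg.stream_value_large
    if s.order in (3, 4):
        return cfg.stream_value_mid
    if s.order == 2:
        return cfg.stream_value_low
    return 0.0


def _raptor_stream_value(s, cfg: ModelConfig) -> float:
    if s.large_river:
        return cfg.stream_value_large
    if s.order in (3, 4):
        return cfg.stream_value_mid
    return 0.0


def _riparian_stream_value(s, cfg: ModelConfig) -> float:
    if 2 <= s.order <= 7:
        return cfg.riparian_perennial_value if s.perennial else cfg.riparian_intermittent_value
    return 0.0


def _wetland_size_value(area_ha: float, cfg: ModelConfig) -> float:
    lo, hi = cfg.wetland_size_breaks_ha
    below, mid, above = cfg.wetland_size_values
    if area_ha < lo:
        return below
    if area_ha <= hi:
        return mid
    return above


def _map_codes(grid: Grid, mapping: dict, default: float) -> np.ndarray:
    out = np.full(grid.shape, default, dtype=float)
    for code, value in mapping.items():
        out[grid.values == code] = value
    return out


def _build_streams_wetland(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    feats = [(s.geometry, _wetland_stream_value(s, cfg)) for s in stack.streams]
    return FactorLayer(engine.rasterize_valued_features(feats, stack.template), "streams")


def _build_streams_riparian(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    feats = [(s.geometry, _riparian_stream_value(s, cfg)) for s in stack.streams]
    burned = engine.rasterize_valued_features(feats, stack.template)
    return FactorLayer(engine.inverse_distance_decay(burned, cfg.decay_max_dist_m), "streams")


def _build_streams_raptor(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    feats = [(s.geometry, _raptor_stream_value(s, cfg)) for s in stack.streams]
    burned = engine.rasterize_valued_features(feats, stack.template)
    return FactorLayer(engine.inverse_distance_decay(burned, cfg.decay_max_dist_m), "streams")


def _build_wetland_density(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    # every wetland counts here, including the <5 ha ones the size factor zeroes
    density = engine.focal_point_density(
        stack.wetland_points(), stack.template, cfg.density_radius_m
    )
    return engine.density_to_importance(density, cfg.density_anchors, cfg.density_ramp)


def _build_wetland_size(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    feats = [(w.geometry, _wetland_size_value(w.area_ha, cfg)) for w in stack.wetlands]
    return FactorLayer(engine.rasterize_valued_features(feats, stack.template), "wetland_size")


def _build_forage(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    out = _map_codes(stack["crops"], cfg.forage_values, 0.0)
    return FactorLayer(stack.template.with_values(out), "forage")


def _build_takeoff_buffer(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    feats = [
        (s.geometry, _wetland_stream_value(s, cfg)) for s in stack.streams
    ] + [(w.geometry, _wetland_size_value(w.area_ha, cfg)) for w in stack.wetlands]
    grid = engine.buffer_carry_value(
        [(g, v) for g, v in feats if v > 0], cfg.buffer_dist_m, stack.template
    )
    return FactorLayer(grid, "takeoff_buffer")


def _build_topography(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    return engine.topographic_position(
        stack["elevation"], cfg.tpi_windows, cfg.tpi_threshold
    )


def _build_updrafts(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    return engine.updraft_factor(stack["aspect"], stack["wind_direction_category"])


def _build_thermals(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    # bare-ground index, with cultivated croplands added as thermal sources
    bare = np.clip(stack["bare_ground"].values, 0.0, 1.0)
    out = np.where(stack["crops"].values > 0, 1.0, bare)
    return FactorLayer(stack.template.with_values(out), "thermals")


def _build_land_cover(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    out = _map_codes(stack["land_cover"], cfg.landcover_values, 0.0)
    return FactorLayer(stack.template.with_values(out), "land_cover")


def _build_prairie_dog(stack: LayerStack, cfg: ModelConfig) -> FactorLayer:
    out = np.clip(stack["prairie_dog"].values, 0.0, 1.0)
    return FactorLayer(stack.template.with_values(out), "prairie_dog")


# ---------------------------------------------------------------------------
# modifier builders


def _build_elevation_mod(stack: LayerStack, cfg: ModelConfig) -> ModifierLayer:
    lo, hi = cfg.elevation_breaks
    v_low, v_mid, v_high = cfg.elevation_values
    e = stack["elevation"].values
    out = np.select([e < lo, e < hi], [v_low, v_mid], default=v_high)
    return ModifierLayer(stack.template.with_values(out), "elevation")


def _build_river_proximity(stack: LayerStack, cfg: ModelConfig) -> ModifierLayer:
    feats = [(s.geometry, 1.0) for s in stack.streams if s.order >= cfg.proximity_min_order]
    burned = engine.rasterize_valued_features(feats, stack.template)
    src = burned.values > 0
    if src.any():
        dist = ndimage.distance_transform_edt(~src, sampling=stack.template.cell_size)
    else:
        dist = np.full(stack.template.shape, np.inf)
    lo, hi = (b * 1000.0 for b in cfg.proximity_breaks_km)
    near, mid, far = cfg.proximity_values
    out = np.select([dist < lo, dist < hi], [near, mid], default=far)
    return ModifierLayer(stack.template.with_values(out), "river_proximity")


def _build_flyway(stack: LayerStack, cfg: ModelConfig) -> ModifierLayer:
    out = np.where(stack["flyway_mask"].values > 0, cfg.flyway_value, 1.0)
    return ModifierLayer(stack.template.with_values(out), "flyway")


def _build_stream_orientation(stack: LayerStack, cfg: ModelConfig) -> ModifierLayer:
    """Per-stream northness carried along each stream footprint.

    Each stream polyline (order ≥ 2, the orders any model values) gets one
    northness value from its minimum-area rectangle; the value is burned
    along the line and extended to the decay reach of the stream factors;
    everywhere else the modifier is neutral (1).
    """
    template = stack.template
    feats = []
    for s in stack.streams:
        if s.order >= 2:
            try:
                feats.append((s.geometry, engine.min_rect_northness(s.geometry)))
            except ValueError:
                continue
    burned = engine.rasterize_valued_features(feats, template)
    src = burned.values > 0
    out = np.ones(template.shape)
    if src.any():
        dist, (ri, ci) = ndimage.distance_transform_edt(
            ~src, sampling=template.cell_size, return_indices=True
        )
        reach = dist <= cfg.decay_max_dist_m
        out[reach] = burned.values[ri, ci][reach]
    return ModifierLayer(template.with_values(out), "stream_orientation")


def _build_topo_orientation(stack: LayerStack, cfg: ModelConfig) -> ModifierLayer:
    """Northness of each ridge feature (connected component of the
    topographic-position factor), applied over the component's footprint."""
    template = stack.template
    topo = _build_topography(stack, cfg).grid.values > 0
    out = np.ones(template.shape)
    labels = measure.label(topo, connectivity=2)
    xs, ys = template.cell_centers()
    for region in measure.regionprops(labels):
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        pts = MultiPoint(list(zip(xs[rr, cc], ys[rr, cc])))
        try:
            northness = engine.min_rect_northness(pts)
        except ValueError:  # single-cell ridge fragment: no axis, stay neutral
            continue
        out[rr, cc] = northness
    return ModifierLayer(template.with_values(out), "topo_orientation")


def _index_modifier(stack: LayerStack, layer: str, name: str) -> ModifierLayer:
    # a 0-1 likelihood index mapped linearly onto the 1-2 modifier range
    out = 1.0 + np.clip(stack[layer].values, 0.0, 1.0)
    return ModifierLayer(stack.template.with_values(out), name)


def _build_structural_diversity(stack: LayerStack, cfg: ModelConfig) -> ModifierLayer:
    out = _map_codes(stack["land_cover"], cfg.structural_values, 1.0)
    return ModifierLayer(stack.template.with_values(out), "structural_diversity")


FACTOR_BUILDERS: dict[str, Callable[[LayerStack, ModelConfig], FactorLayer]] = {
    "streams_wetland": _build_streams_wetland,
    "streams_riparian": _build_streams_riparian,
    "streams_raptor": _build_streams_raptor,
    "wetland_density": _build_wetland_density,
    "wetland_size": _build_wetland_size,
    "forage": _build_forage,
    "takeoff_buffer": _build_takeoff_buffer,
    "topography": _build_topography,
    "updrafts": _build_updrafts,
    "thermals": _build_thermals,
    "land_cover": _build_land_cover,
    "prairie_dog": _build_prairie_dog,
}

MODIFIER_BUILDERS: dict[str, Callable[[LayerStack, ModelConfig], ModifierLayer]] = {
    "elevation": _build_elevation_mod,
    "river_proximity": _build_river_proximity,
    "flyway": _build_flyway,
    "stream_orientation": _build_stream_orientation,
    "topo_orientation": _build_topo_orientation,
    "cottonwood": lambda s, c: _index_modifier(s, "cottonwood", "cottonwood"),
    "willow": lambda s, c: _index_modifier(s, "willow", "willow"),
    "bare_ground": lambda s, c: _index_modifier(s, "bare_ground", "bare_ground"),
    "structural_diversity": _build_structural_diversity,
}


def prepare_factor(
    factor_id: str, stack: LayerStack, config: ModelConfig | None = None
) -> FactorLayer:
    """Build one named factor layer from the landscape stack."""
    if factor_id not in FACTOR_BUILDERS:
        raise ValueError(f"unknown factor '{factor_id}'; known: {sorted(FACTOR_BUILDERS)}")
    return FACTOR_BUILDERS[factor_id](stack, config or ModelConfig())


def prepare_modifier(
    modifier_id: str, stack: LayerStack, config: ModelConfig | None = None
) -> ModifierLayer:
    """Build one named modifier layer from the landscape stack."""
    if modifier_id not in MODIFIER_BUILDERS:
        raise ValueError(f"unknown modifier '{modifier_id}'; known: {sorted(MODIFIER_BUILDERS)}")
    return MODIFIER_BUILDERS[modifier_id](stack, config or ModelConfig())


class ModelContext:
    """Caches factor and modifier layers for one (stack, config) pair.

    Sensitivity analysis evaluates tens of partial models against the same
    landscape; with the layers memoized each partial evaluation reduces to
    cheap array products and sums.
    """

    def __init__(self, stack: LayerStack, config: ModelConfig | None = None) -> None:
        self.stack = stack
        self.config = config or ModelConfig()
        self._factors: dict[str, FactorLayer] = {}
        self._modifiers: dict[str, ModifierLayer] = {}

    def factor(self, factor_id: str) -> FactorLayer:
        if factor_id not in self._factors:
            self._factors[factor_id] = prepare_factor(factor_id, self.stack, self.config)
        return self._factors[factor_id]

    def modifier(self, modifier_id: str) -> ModifierLayer:
        if modifier_id not in self._modifiers:
            self._modifiers[modifier_id] = prepare_modifier(modifier_id, self.stack, self.config)
        return self._modifiers[modifier_id]

    def evaluate(self, spec: GroupModelSpec) -> MISRaster:
        terms = []
        for term in spec.terms:
            factor = self.factor(term.factor_id)
            modified = engine.apply_modifiers(
                factor, [self.modifier(m) for m in term.modifier_ids]
            )
            terms.append((engine.normalize01(modified), term.weight))
        mis = engine.combine_mis(terms, mask=self.stack.template.mask)
        return MISRaster(mis, spec)


def run_model(
    spec: GroupModelSpec, stack: LayerStack, config: ModelConfig | None = None
) -> MISRaster:
    """Evaluate a group model spec against a landscape stack."""
    return ModelContext(stack, config).evaluate(spec)
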