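"""Readers/writers and run configuration.

Grids are stored as single-band ESRI ASCII grids (.asc, NoData −9999), a
plain-text raster format with cell size and origin in the header; stream
and wetland features as GeoJSON FeatureCollections; occurrence records and
report tables as CSV. All round trips are lossless to float32 precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .engine import NODATA, Grid
from .layers import LayerStack, StreamFeature, WetlandFeature
from .models import GROUPS, ModelConfig
from .synthetic import LandscapeParams

__all__ = [
    "read_raster",
    "write_raster",
    "write_stack",
    "read_stack",
    "write_occurrences",
    "read_occurrences",
    "RunConfig",
    "load_config",
]

log = logging.getLogger(__name__)


def write_raster(grid: Grid, path: str | Path, fmt: str = "%.7g") -> None:
    """Write a grid as an ESRI ASCII raster (NoData −9999)."""
    path = Path(path)
    nrow, ncol = grid.shape
    vals = np.where(grid.mask, NODATA, grid.values)
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1] - nrow * grid.cell_size:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_raster(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster back into a Grid."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            try:
                key, value = line.split()
                header[key.lower()] = float(value)
            except ValueError as exc:
                raise ValueError(f"malformed ASCII grid header in {path}: {line!r}") from exc
        values = np.loadtxt(fh, ndmin=2)
    nrow, ncol = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrow, ncol):
        raise ValueError(f"{path}: data shape {values.shape} does not match header")
    nodata = header.get("nodata_value", NODATA)
    mask = values == nodata
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrow * cs)
    values = np.where(mask, 0.0, values)
    return Grid(values, mask, cs, origin)


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _write_streams(streams: list[StreamFeature], path: Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(s.geometry),
            "properties": {
                "order": int(s.order),
                "perennial": bool(s.perennial),
                "large_river": bool(s.large_river),
            },
        }
        for s in streams
    ]
    path.write_text(json.dumps(_feature_collection(feats)))


def _write_wetlands(wetlands: list[WetlandFeature], path: Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(w.geometry),
            "properties": {"area_ha": float(w.area_ha), "kind": w.kind},
        }
        for w in wetlands
    ]
    path.write_text(json.dumps(_feature_collection(feats)))


def write_stack(stack: LayerStack, out_dir: str | Path) -> None:
    """Write a landscape stack to a directory: one .asc per grid plus
    streams.geojson and wetlands.geojson."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.grids.items():
        write_raster(grid, out / f"{name}.asc")
    _write_streams(stack.streams, out / "streams.geojson")
    _write_wetlands(stack.wetlands, out / "wetlands.geojson")


def read_stack(in_dir: str | Path) -> LayerStack:
    """Read a landscape stack written by :func:`write_stack`."""
    src = Path(in_dir)
    grids = {p.stem: read_raster(p) for p in sorted(src.glob("*.asc"))}
    if not grids:
        raise ValueError(f"no .asc grids found in {src}")
    streams: list[StreamFeature] = []
    spath = src / "streams.geojson"
    if spath.exists():
        for feat in json.loads(spath.read_text())["features"]:
            props = feat.get("properties", {})
            streams.append(
                StreamFeature(
                    shape(feat["geometry"]),
                    order=int(props.get("order", 0)),
                    perennial=bool(props.get("perennial", False)),
                    large_river=bool(props.get("large_river", False)),
                )
            )
    wetlands: list[WetlandFeature] = []
    wpath = src / "wetlands.geojson"
    if wpath.exists():
        for feat in json.loads(wpath.read_text())["features"]:
            props = feat.get("properties", {})
            wetlands.append(
                WetlandFeature(
                    shape(feat["geometry"]),
                    area_ha=float(props.get("area_ha", 0.0)),
                    kind=props.get("kind", "palustrine"),
                )
            )
    stack = LayerStack(grids=grids, streams=streams, wetlands=wetlands)
    stack.validate()
    return stack


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    landscape: LandscapeParams = dataclasses.field(default_factory=LandscapeParams)
    groups: tuple[str, ...] = GROUPS
    bins: int = 10
    seed: int = 0
    n_occurrences: int = 600
    occurrence_bias: float = 2.0
    n_species: int = 5
    ridge_weight: float = 0.6
    thresholds: ModelConfig = dataclasses.field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}; valid: {GROUPS}")
        if self.bins < 2:
            raise ValueError("bins must be at least 2")


_TOP_KEYS = {
    "landscape",
    "groups",
    "bins",
    "seed",
    "n_occurrences",
    "occurrence_bias",
    "n_species",
    "ridge_weight",
    "thresholds",
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; every omitted key keeps its default
    (the published table values for all model thresholds). Overrides of
    table values are logged so a run stays auditable."""
    if path is None:
        return RunConfig()
    try:
        data = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(_TOP_KEYS)}")
    kwargs = dict(data)
    if "landscape" in kwargs:
        ls = kwargs["landscape"]
        valid = {f.name for f in dataclasses.fields(LandscapeParams)}
        unknown = set(ls) - valid
        if unknown:
            raise ValueError(
                f"unknown landscape keys {sorted(unknown)}; valid: {sorted(valid)}"
            )
        for key in ("extent_cells", "wetland_area_range", "elevation_range"):
            if key in ls:
                ls[key] = tuple(ls[key])
        kwargs["landscape"] = LandscapeParams(**ls)
    if "groups" in kwargs:
        kwargs["groups"] = tuple(kwargs["groups"])
    if "thresholds" in kwargs:
        overrides = kwargs["thresholds"]
        for key, value in overrides.items():
            log.info("table-value override: %s = %r", key, value)
        overrides = {
            k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
        }
        kwargs["thresholds"] = ModelConfig().override(**overrides)
    return RunConfig(**kwargs)
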