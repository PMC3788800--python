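"""Exposure of migratory concentration areas to wind-development potential.

Both the concentration surface and the wind-potential surface are quantile
recoded to the ordinal values {0, 0.25, 0.5, 0.75, 1} (1 = top 20% of the
data) so the two models become comparable; their cellwise product is the
exposure surface, classified into five named levels. Uncertainty is
propagated by recomputing exposure for every drop-one partial model and
taking the per-cell standard deviation. The headline overlap statistics
intersect the top-two-quantile masks of migration and wind potential:

    A = 100·|mig ∩ wind| / |mig|   (percent of migration area exposed)
    B = 100·|mig ∩ wind| / |wind|  (percent of wind area carrying migrants)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Grid, quantile_classify

__all__ = [
    "ExposureReport",
    "EXPOSURE_CLASSES",
    "RECODE_VALUES",
    "quantile_recode",
    "exposure_product",
    "exposure_class",
    "exposure_sd",
    "top2_mask",
    "overlap_percentages",
    "cumulative_mask",
    "mean_ci",
    "exposure_report",
]

RECODE_VALUES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: products attainable from two recoded grids
ATTAINABLE_PRODUCTS = tuple(sorted({a * b for a in RECODE_VALUES for b in RECODE_VALUES}))

#: class code -> (label, lower bound, upper bound); half-open cover of [0, 1]
#: regularizing the printed thresholds very high (>0.75), high (0.56-0.75),
#: moderate (0.26-0.559), low (0.1-0.259), very low (<0.1)
EXPOSURE_CLASSES = {
    1: ("very_low", 0.0, 0.1),
    2: ("low", 0.1, 0.26),
    3: ("moderate", 0.26, 0.56),
    4: ("high", 0.56, 0.75),
    5: ("very_high", 0.75, 1.0),
}


@dataclass
class ExposureReport:
    exposure_grid: Grid
    class_grid: Grid
    sd_grid: Grid | None
    overlap_rows: pd.DataFrame


def quantile_recode(grid: Grid, k: int = 5) -> Grid:
    """Map a continuous surface onto {0, 0.25, 0.5, 0.75, 1} by quantiles.

    A cell's recoded value is (number of quantile breaks strictly below the
    cell value)/(k−1), so with distinct breaks the five classes get exactly
    {0, 0.25, 0.5, 0.75, 1} with 1 for the highest 20% of the data. Heavy
    ties (e.g. a zero mass spanning several quantiles) collapse low classes
    onto 0 while the surviving upper classes keep their quantile values —
    the tied mass stays "very low" and the top quantile stays 1. A surface
    with a single distinct value cannot be recoded and raises.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    vals = grid.values[~grid.mask]
    if vals.size < k:
        raise ValueError("fewer unmasked cells than bins")
    breaks = np.quantile(vals, np.arange(1, k) / k)
    if vals.min() == vals.max():
        raise ValueError("degenerate surface: all unmasked values identical")
    out = np.searchsorted(breaks, grid.values, side="left") / (k - 1.0)
    out[grid.mask] = 0.0
    return grid.with_values(out)


def _check_recoded(grid: Grid, name: str) -> None:
    v = grid.values[~grid.mask]
    ok = np.isclose(v[:, None], np.array(RECODE_VALUES)[None, :]).any(axis=1)
    if not ok.all():
        raise ValueError(f"{name} holds values outside the recode set {RECODE_VALUES}")


def exposure_product(wind_q: Grid, mig_q: Grid) -> Grid:
    """Cellwise product of two recoded surfaces (symmetric in its arguments)."""
    if not wind_q.same_geometry(mig_q):
        raise ValueError("grids do not share geometry")
    _check_recoded(wind_q, "wind grid")
    _check_recoded(mig_q, "migration grid")
    mask = wind_q.mask | mig_q.mask
    out = wind_q.values * mig_q.values
    out[mask] = 0.0
    return Grid(out, mask, wind_q.cell_size, wind_q.origin)


def exposure_class(exposure: Grid) -> Grid:
    """Classify an exposure surface into codes 1..5 (very_low..very_high)."""
    v = exposure.values[~exposure.mask]
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("exposure values must lie in [0, 1]")
    e = exposure.values
    out = np.select(
        [e < 0.1, e < 0.26, e < 0.56, e <= 0.75],
        [1, 2, 3, 4],
        default=5,
    ).astype(float)
    out[exposure.mask] = 0
    return exposure.with_values(out)


def exposure_sd(exposures: list[Grid]) -> Grid:
    """Per-cell population standard deviation across exposure surfaces."""
    if len(exposures) < 2:
        raise ValueError("at least two exposure grids are required")
    first = exposures[0]
    for g in exposures[1:]:
        if not first.same_geometry(g):
            raise ValueError("exposure grids do not share geometry")
    sd = np.stack([g.values for g in exposures]).std(axis=0)
    mask = np.logical_or.reduce([g.mask for g in exposures])
    sd[mask] = 0.0
    return Grid(sd, mask, first.cell_size, first.origin)


def top2_mask(recoded: Grid) -> Grid:
    """Binary mask of the top two quantile classes (recoded value ≥ 0.75)."""
    out = (recoded.values >= 0.75).astype(float)
    out[recoded.mask] = 0.0
    return recoded.with_values(out)


def overlap_percentages(mig_mask: Grid, wind_mask: Grid) -> tuple[float, float]:
    """(percent of migration area overlapped, percent of wind area overlapped)."""
    if not mig_mask.same_geometry(wind_mask):
        raise ValueError("masks do not share geometry")
    valid = ~mig_mask.mask & ~wind_mask.mask
    m = mig_mask.values > 0
    w = wind_mask.values > 0
    n_m = int(np.sum(m & valid))
    n_w = int(np.sum(w & valid))
    if n_m == 0 or n_w == 0:
        raise ValueError("empty migration or wind mask; overlap percentage undefined")
    n_i = int(np.sum(m & w & valid))
    return 100.0 * n_i / n_m, 100.0 * n_i / n_w


def cumulative_mask(masks: list[Grid]) -> Grid:
    """Cellwise union of binary masks (cross-group concentration footprint)."""
    if not masks:
        raise ValueError("at least one mask is required")
    first = masks[0]
    out = np.zeros(first.shape, dtype=float)
    for g in masks:
        if not first.same_geometry(g):
            raise ValueError("masks do not share geometry")
        out = np.maximum(out, (g.values > 0).astype(float))
    return first.with_values(out)


def mean_ci(values: list[float]) -> tuple[float, float, float]:
    """Mean and normal-approximation 95% confidence interval."""
    if len(values) < 2:
        raise ValueError("at least two values are required")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    half = 1.96 * float(arr.std(ddof=1)) / math.sqrt(len(arr))
    return mean, mean - half, mean + half


def exposure_report(
    group: str,
    full_mis: Grid,
    partial_mis: list[Grid],
    wind: Grid,
) -> ExposureReport:
    """Full exposure analysis of one bird group against a wind surface.

    Recodes the wind surface once and the full plus every partial
    concentration surface, multiplies, classifies the full-model exposure,
    computes the SD surface across all model versions, and tabulates the
    top-two-quantile overlap percentages for the full model together with
    their mean and 95% CI across the full and partial models.
    """
    wind_q = quantile_recode(wind)
    wind_top = top2_mask(wind_q)
    all_mis = [full_mis] + list(partial_mis)
    exposures = []
    pct_a, pct_b = [], []
    for i, mis in enumerate(all_mis):
        try:
            mis_q = quantile_recode(mis)
        except ValueError:
            if i == 0:
                raise
            # a collapsed partial model (constant surface) carries no
            # quantile structure; it cannot contribute an exposure surface
            continue
        exposures.append(exposure_product(wind_q, mis_q))
        a, b = overlap_percentages(top2_mask(mis_q), wind_top)
        pct_a.append(a)
        pct_b.append(b)
    sd_grid = exposure_sd(exposures) if len(exposures) >= 2 else None
    row = {
        "group": group,
        "pct_of_migration_area": pct_a[0],
        "pct_of_wind_area": pct_b[0],
    }
    if len(pct_a) >= 2:
        for prefix, series in (("migration", pct_a), ("wind", pct_b)):
            mean, lo, hi = mean_ci(series)
            row[f"{prefix}_mean"] = mean
            row[f"{prefix}_ci_low"] = lo
            row[f"{prefix}_ci_high"] = hi
    return ExposureReport(
        exposure_grid=exposures[0],
        class_grid=exposure_class(exposures[0]),
        sd_grid=sd_grid,
        overlap_rows=pd.DataFrame([row]),
    )
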