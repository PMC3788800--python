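"""Leave-one-out sensitivity and uncertainty analysis of a group model.

Each factor, each modifier and each non-unit weight is dropped from the
model one at a time; every resulting partial model is compared with the full
model in three ways:

* per-cell percent difference 100·|full − partial|/full, summarized by its
  mean and standard deviation over cells where the full model is positive;
* classification accuracy: both surfaces are classified into 5-quantiles
  and the percentage of cells landing in the same class is reported;
* an uncertainty surface: the per-cell mean of the percent-difference
  grids across all partial models.

Cells where the full model is zero are excluded from percent-difference
statistics (the ratio is undefined there) and no cap is applied to large
per-cell percent differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import Grid, quantile_classify
from .layers import LayerStack
from .models import (
    FACTOR_NAMES,
    MODIFIER_NAMES,
    GroupModelSpec,
    MISRaster,
    ModelConfig,
    ModelContext,
    Term,
)

__all__ = [
    "SensitivityReport",
    "enumerate_partials",
    "percent_difference_stats",
    "classification_accuracy",
    "uncertainty_surface",
    "run_sensitivity",
]


@dataclass
class SensitivityReport:
    """Per-partial summary rows plus the mean percent-difference surface."""

    rows: pd.DataFrame  # dropped_label, mean_pct_diff, sd_pct_diff, classification_accuracy_pct
    uncertainty_grid: Grid
    partials: list[MISRaster]
    full: MISRaster


def enumerate_partials(spec: GroupModelSpec) -> list[tuple[str, GroupModelSpec]]:
    """All drop-one-term variants of a model spec.

    One partial per factor (the whole term removed), one per modifier
    (that modifier removed from its term) and one per non-unit weight (the
    weight reset to 1). Labels name the dropped piece, e.g. "Wetland
    density: elevation" or "Weight for wetland density".
    """
    partials: list[tuple[str, GroupModelSpec]] = []
    terms = list(spec.terms)
    for i, term in enumerate(terms):
        fname = FACTOR_NAMES.get(term.factor_id, term.factor_id)
        if len(terms) > 1:
            remaining = tuple(t for j, t in enumerate(terms) if j != i)
            partials.append((fname, replace(spec, terms=remaining)))
        for mod in term.modifier_ids:
            mname = MODIFIER_NAMES.get(mod, mod)
            new_term = Term(
                term.factor_id,
                tuple(m for m in term.modifier_ids if m != mod),
                term.weight,
            )
            new_terms = tuple(new_term if j == i else t for j, t in enumerate(terms))
            partials.append((f"{fname}: {mname}", replace(spec, terms=new_terms)))
    for i, term in enumerate(terms):
        if term.weight != 1.0:
            fname = FACTOR_NAMES.get(term.factor_id, term.factor_id)
            new_term = Term(term.factor_id, term.modifier_ids, 1.0)
            new_terms = tuple(new_term if j == i else t for j, t in enumerate(terms))
            partials.append((f"Weight for {fname.lower()}", replace(spec, terms=new_terms)))
    return partials


def percent_difference_stats(
    full: MISRaster, partial: MISRaster
) -> tuple[Grid, float, float]:
    """Per-cell percent difference plus its mean and SD over full > 0 cells."""
    fg, pg = full.grid, partial.grid
    if not fg.same_geometry(pg):
        raise ValueError("full and partial grids do not share geometry")
    valid = ~fg.mask & (fg.values > 0)
    if not valid.any():
        raise ValueError("full model is zero everywhere; percent difference undefined")
    pct = np.zeros(fg.shape)
    pct[valid] = 100.0 * np.abs(fg.values[valid] - pg.values[valid]) / fg.values[valid]
    grid = Grid(pct, ~valid, fg.cell_size, fg.origin)
    return grid, float(pct[valid].mean()), float(pct[valid].std())


def classification_accuracy(full: MISRaster, partial: MISRaster, k: int = 5) -> float:
    """Percent of cells classed in the same quantile bin by both surfaces.

    Both rasters are quantile-classified independently; the accuracy is the
    diagonal mass of the k×k cross-tabulation as a percentage of all
    unmasked cells.
    """
    fg, pg = full.grid, partial.grid
    if not fg.same_geometry(pg):
        raise ValueError("full and partial grids do not share geometry")
    fc = quantile_classify(fg, k).classes.values
    pc = quantile_classify(pg, k).classes.values
    valid = ~fg.mask & ~pg.mask
    return float(100.0 * np.mean(fc[valid] == pc[valid]))


def uncertainty_surface(full: MISRaster, partials: list[MISRaster]) -> Grid:
    """Per-cell mean percent difference across all partial models."""
    if not partials:
        raise ValueError("at least one partial model is required")
    grids = [percent_difference_stats(full, p)[0] for p in partials]
    stackv = np.stack([g.values for g in grids])
    mean = stackv.mean(axis=0)
    return Grid(mean, grids[0].mask.copy(), full.grid.cell_size, full.grid.origin)


def run_sensitivity(
    spec: GroupModelSpec,
    stack: LayerStack,
    config: ModelConfig | None = None,
    k: int = 5,
    context: ModelContext | None = None,
) -> SensitivityReport:
    """Evaluate every drop-one partial of ``spec`` and summarize the changes."""
    ctx = context or ModelContext(stack, config)
    full = ctx.evaluate(spec)
    rows = []
    partial_rasters = []
    for label, pspec in enumerate_partials(spec):
        partial = ctx.evaluate(pspec)
        partial_rasters.append(partial)
        _, mean, sd = percent_difference_stats(full, partial)
        acc = classification_accuracy(full, partial, k)
        rows.append(
            {
                "dropped_label": label,
                "mean_pct_diff": mean,
                "sd_pct_diff": sd,
                "classification_accuracy_pct": acc,
            }
        )
    return SensitivityReport(
        rows=pd.DataFrame(rows),
        uncertainty_grid=uncertainty_surface(full, partial_rasters),
        partials=partial_rasters,
        full=full,
    )
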