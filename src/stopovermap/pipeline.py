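"""End-to-end orchestration: generate → model → validate → sensitivity → exposure.

A single seeded generator drives every stage through per-stage sub-seeds,
so a run is reproducible end to end and no stage consumes unseeded
randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from .engine import Grid
from .exposure import cumulative_mask, exposure_report, overlap_percentages, quantile_recode, top2_mask
from .models import ModelContext, canned_spec
from .sensitivity import run_sensitivity
from .synthetic import generate_landscape, generate_occurrences, generate_wind_potential
from .validation import (
    boyce,
    filter_by_accuracy,
    stratified_subsample,
    thin_min_distance,
)

__all__ = ["run_pipeline", "stage_seeds"]

log = logging.getLogger(__name__)

_STAGES = ("landscape", "occurrences", "subsample", "wind", "boyce")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage sub-seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def run_pipeline(config: "smio.RunConfig", out_dir: str | Path) -> dict:
    """Run every requested stage and write all artifacts under ``out_dir``.

    Per group: the MIS raster, a validation report (filter chain + Boyce
    index), the sensitivity table and uncertainty surface, and the exposure
    surfaces and overlap table; plus the landscape stack, the wind-potential
    surface and a cross-group cumulative overlap summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "groups": {}}

    landscape_params = config.landscape
    if landscape_params.seed == 0 and config.seed != 0:
        landscape_params = dataclasses.replace(landscape_params, seed=seeds["landscape"])
    log.info("generating landscape (seed %d)", landscape_params.seed)
    stack = generate_landscape(landscape_params)
    smio.write_stack(stack, out / "landscape")

    wind = generate_wind_potential(stack, config.ridge_weight, seed=seeds["wind"])
    smio.write_raster(wind, out / "wind_potential.asc")
    wind_top = top2_mask(quantile_recode(wind))

    ctx = ModelContext(stack, config.thresholds)
    mig_tops: list[Grid] = []
    for gi, group in enumerate(config.groups):
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        spec = canned_spec(group)
        log.info("evaluating %s model", group)
        mis = ctx.evaluate(spec)
        smio.write_raster(mis.grid, gdir / "mis.asc")

        occ = generate_occurrences(
            mis.grid,
            n=config.n_occurrences,
            bias=config.occurrence_bias,
            n_species=config.n_species,
            seed=seeds["occurrences"] + gi,
        )
        smio.write_occurrences(occ, gdir / "occurrences.csv")
        filtered = filter_by_accuracy(occ)
        thinned = thin_min_distance(filtered)
        points = stratified_subsample(thinned, seed=seeds["subsample"] + gi)
        bres = boyce(mis.grid, points, k=config.bins, seed=seeds["boyce"] + gi)
        bres.bins.to_csv(gdir / "boyce_bins.csv", index=False)

        sens = run_sensitivity(spec, stack, context=ctx)
        sens.rows.to_csv(gdir / "sensitivity.csv", index=False)
        smio.write_raster(sens.uncertainty_grid, gdir / "uncertainty.asc")

        exp = exposure_report(
            group, mis.grid, [p.grid for p in sens.partials], wind
        )
        smio.write_raster(exp.exposure_grid, gdir / "exposure.asc")
        smio.write_raster(exp.class_grid, gdir / "exposure_class.asc", fmt="%d")
        if exp.sd_grid is not None:
            smio.write_raster(exp.sd_grid, gdir / "exposure_sd.asc")
        exp.overlap_rows.to_csv(gdir / "overlap.csv", index=False)

        mig_tops.append(top2_mask(quantile_recode(mis.grid)))
        report["groups"][group] = {
            "n_validation_points": int(len(points)),
            "boyce_rho": bres.rho,
            "boyce_p": bres.p_value,
            "boyce_bins_effective": bres.k_effective,
            "sensitivity": sens.rows.to_dict(orient="records"),
            "overlap": exp.overlap_rows.iloc[0].to_dict(),
        }

    if mig_tops:
        combined = cumulative_mask(mig_tops)
        smio.write_raster(combined, out / "cumulative_top2.asc", fmt="%d")
        a, b = overlap_percentages(combined, wind_top)
        report["combined_overlap"] = {
            "pct_of_migration_area": a,
            "pct_of_wind_area": b,
        }
    wind_frac = float(np.mean(wind_top.values[~wind_top.mask] > 0))
    report["wind_top2_area_fraction_pct"] = 100.0 * wind_frac

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
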