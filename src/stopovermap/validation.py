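"""Presence-only validation of concentration surfaces.

The chain mirrors how opportunistic occurrence records are prepared before
computing a Boyce index against a model surface:

1. date-window filter (species-specific migration windows, supplied as data)
2. positional-accuracy / quality filter (default: error ≤ 400 m)
3. 800-m minimum-distance thinning, preferring better-quality records
4. stratified subsampling (up to 10 points per species)
5. the Boyce index on point-balanced bins with midpoint thresholds

The Boyce index is the Spearman rank correlation between each bin's rank and
its area-adjusted frequency (fraction of validation points in the bin divided
by the fraction of study-area cells in the bin). It ranges from −1 (counter
prediction) to 1 (perfect positive prediction), with values near 0 meaning
the model is no better than random. Because every step is rank-based, the
index is invariant under strictly increasing transforms of the surface.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import Grid

__all__ = [
    "BoyceResult",
    "ExpertRating",
    "filter_by_window",
    "filter_by_accuracy",
    "thin_min_distance",
    "stratified_subsample",
    "boyce",
    "expert_weighted_score",
]

log = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ("species", "x", "y", "date", "accuracy_m", "quality_rank")

MODEL_RATINGS = (-1.0, -0.5, 0.0, 0.5, 1.0)
EXPERTISE_RATINGS = (1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass(frozen=True)
class ExpertRating:
    """One reviewer's Likert model rating and self-rated expertise."""

    model_rating: float
    expertise: float

    def __post_init__(self) -> None:
        if self.model_rating not in MODEL_RATINGS:
            raise ValueError(f"model_rating must be one of {MODEL_RATINGS}")
        if self.expertise not in EXPERTISE_RATINGS:
            raise ValueError(f"expertise must be one of {EXPERTISE_RATINGS}")


@dataclass
class BoyceResult:
    """Per-bin observed/expected ratios plus the rank correlation."""

    bins: pd.DataFrame  # rank, score_lo, score_hi, point_fraction, area_fraction, ratio
    rho: float
    p_value: float
    k_effective: int
    thresholds: np.ndarray


def filter_by_window(records: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Keep records dated inside their species' migration window.

    ``windows`` has columns species, start_mmdd, end_mmdd; windows wrapping
    the new year are honored. Species absent from the table are dropped.
    """
    if records.empty:
        return records.copy()
    win = windows.set_index("species")
    mmdd = pd.to_datetime(records["date"]).dt.strftime("%m-%d")
    keep = np.zeros(len(records), dtype=bool)
    for i, (sp, d) in enumerate(zip(records["species"], mmdd)):
        if sp not in win.index:
            continue
        start, end = win.loc[sp, "start_mmdd"], win.loc[sp, "end_mmdd"]
        keep[i] = (start <= d <= end) if start <= end else (d >= start or d <= end)
    return records.loc[keep].reset_index(drop=True)


def filter_by_accuracy(
    records: pd.DataFrame, max_error: float = 400.0, keep_worse_than: bool = False
) -> pd.DataFrame:
    """Drop records of poor positional accuracy (error > ``max_error``).

    ``keep_worse_than=True`` inverts the threshold direction (retaining only
    records with error ≥ ``max_error``); the default reading — drop records
    whose positional error exceeds the threshold — is the ecologically
    sensible one, and the direction is exposed so the choice is explicit.
    """
    if records.empty:
        return records.copy()
    err = records["accuracy_m"].to_numpy(dtype=float)
    keep = err >= max_error if keep_worse_than else err <= max_error
    return records.loc[keep].reset_index(drop=True)


def thin_min_distance(records: pd.DataFrame, min_dist: float = 800.0) -> pd.DataFrame:
    """Greedy spatial thinning preferring better-quality records.

    Records are visited in descending ``quality_rank`` order (stable within
    ties); a record is kept iff no already-kept record lies closer than
    ``min_dist``. The result is idempotent: thinning twice changes nothing.
    """
    if records.empty:
        return records.copy()
    order = np.argsort(-records["quality_rank"].to_numpy(), kind="stable")
    xs = records["x"].to_numpy(dtype=float)
    ys = records["y"].to_numpy(dtype=float)
    kept: list[int] = []
    for i in order:
        d2min = min(
            ((xs[i] - xs[j]) ** 2 + (ys[i] - ys[j]) ** 2 for j in kept), default=math.inf
        )
        if d2min >= min_dist**2:
            kept.append(i)
    return records.iloc[sorted(kept)].reset_index(drop=True)


def stratified_subsample(
    records: pd.DataFrame,
    per_species_cap: int = 10,
    target_min: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly select up to ``per_species_cap`` records per species.

    Balances the contribution of individual species so the validation
    statistic is not dominated by data-rich species. Warns (via logging)
    when fewer than ``target_min`` records remain in total.
    """
    if records.empty:
        return records.copy()
    rng = np.random.default_rng(seed)
    picks: list[np.ndarray] = []
    for _, group in records.groupby("species", sort=True):
        idx = group.index.to_numpy()
        if len(idx) > per_species_cap:
            idx = rng.choice(idx, size=per_species_cap, replace=False)
        picks.append(idx)
    chosen = np.sort(np.concatenate(picks))
    out = records.loc[chosen].reset_index(drop=True)
    if len(out) < target_min:
        log.warning(
            "only %d validation points after subsampling (target at least %d)",
            len(out),
            target_min,
        )
    return out


def _spearman_p(ranks: np.ndarray, values: np.ndarray, rho: float, seed: int) -> float:
    """One-sided (positive-association) permutation p-value for Spearman rho.

    Exact enumeration up to 8 bins; seeded Monte-Carlo (10,000 permutations)
    above that, where full enumeration would be disproportionate.
    """
    k = len(ranks)
    vr = stats.rankdata(values)
    if k <= 8:
        perms = np.array(list(itertools.permutations(range(1, k + 1))), dtype=float)
    else:
        rng = np.random.default_rng(seed)
        perms = np.tile(np.arange(1.0, k + 1), (10000, 1))
        perms = rng.permuted(perms, axis=1)
    pc = perms - perms.mean(axis=1, keepdims=True)
    vc = vr - vr.mean()
    denom = np.sqrt((pc**2).sum(axis=1) * (vc**2).sum())
    rhos = (pc @ vc) / np.where(denom == 0, np.inf, denom)
    return float(np.mean(rhos >= rho - 1e-12))


def boyce(
    mis: Grid,
    points: pd.DataFrame,
    k: int = 10,
    p_method: str = "permutation",
    seed: int = 0,
) -> BoyceResult:
    """Boyce index of a concentration surface against occurrence points.

    Points are ranked by their surface score and split into ``k`` nearly
    equal groups; bin thresholds are the midpoints of the scores straddling
    each split. Duplicate thresholds (score ties across a split) are merged,
    reducing ``k_effective`` — exactly the situation that arises when a large
    share of cells scores zero. Bins with zero study-area share are merged
    into their lower neighbor. ``p_method='none'`` skips the permutation
    p-value (useful in simulation loops).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    scores = mis.sample(points["x"].to_numpy(float), points["y"].to_numpy(float))
    scores = scores[~np.isnan(scores)]
    if scores.size < k:
        raise ValueError(f"need at least k={k} points with valid scores, got {scores.size}")
    scores.sort()
    groups = np.array_split(scores, k)
    thresholds = np.array(
        [(g1[-1] + g2[0]) / 2.0 for g1, g2 in zip(groups[:-1], groups[1:])]
    )
    thresholds = np.unique(thresholds)
    cell_vals = mis.values[~mis.mask]

    def _tabulate(thr: np.ndarray):
        # bin i covers (thr[i-1], thr[i]]; scores equal to a threshold fall low
        pt_bin = np.searchsorted(thr, scores, side="left")
        cell_bin = np.searchsorted(thr, cell_vals, side="left")
        nbins = len(thr) + 1
        pt_frac = np.bincount(pt_bin, minlength=nbins) / scores.size
        area_frac = np.bincount(cell_bin, minlength=nbins) / cell_vals.size
        return pt_frac, area_frac

    pt_frac, area_frac = _tabulate(thresholds)
    while len(thresholds) > 0 and np.any(area_frac == 0):
        empty = int(np.argmax(area_frac == 0))
        drop = max(empty - 1, 0)  # merge an area-empty bin into its lower neighbor
        thresholds = np.delete(thresholds, drop)
        pt_frac, area_frac = _tabulate(thresholds)
    k_eff = len(thresholds) + 1
    if k_eff < 2:
        raise ValueError("fewer than two usable bins; surface is degenerate")

    ratio = pt_frac / area_frac
    ranks = np.arange(1, k_eff + 1, dtype=float)
    vr = stats.rankdata(ratio)
    if len(np.unique(vr)) == len(vr):
        # untied ratios: the classical formula is exact (integer differences),
        # so a perfect ranking yields exactly +/-1
        d = vr - ranks
        rho = float(1.0 - 6.0 * np.sum(d * d) / (k_eff * (k_eff**2 - 1)))
    else:
        rho = float(stats.spearmanr(ranks, ratio).statistic)
    if p_method == "none":
        p = float("nan")
    elif p_method == "permutation":
        p = _spearman_p(ranks, ratio, rho, seed)
    else:
        raise ValueError("p_method must be 'permutation' or 'none'")

    lo_edges = np.concatenate([[float(cell_vals.min())], thresholds])
    hi_edges = np.concatenate([thresholds, [float(cell_vals.max())]])
    bins = pd.DataFrame(
        {
            "rank": ranks.astype(int),
            "score_lo": lo_edges,
            "score_hi": hi_edges,
            "point_fraction": pt_frac,
            "area_fraction": area_frac,
            "ratio": ratio,
        }
    )
    return BoyceResult(bins, rho, p, k_eff, thresholds)


def expert_weighted_score(ratings: list[ExpertRating]) -> float:
    """Expertise-weighted mean model rating, in [−2, 2].

    Each reviewer's model rating is multiplied by their expertise level and
    the products are averaged; scores below zero indicate a poor model,
    above zero a good one.
    """
    if not ratings:
        raise ValueError("at least one rating is required")
    return float(np.mean([r.model_rating * r.expertise for r in ratings]))
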