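"""Seasonal-ecotype classification and aggregation of periodic taxa.

A periodic taxon is assigned a peak season from its *measured* (never
interpolated) relative abundances: observations are pooled by the season of
their calendar month, the four season means are compared, and the argmax
wins.  Monthly climatologies (January-December calendar means) and
group-by-season depth profiles summarise how seasonal ecotypes partition the
annual cycle through the water column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AbundanceTable, Season, SEASON_ORDER, season_of_month
from .timegrid import MonthlySeries

__all__ = [
    "SeasonalProfile",
    "EcotypeDepthProfile",
    "monthly_climatology",
    "peak_season",
    "aggregate_seasonal_ecotypes",
    "seasonal_ecotype_report",
]


@dataclass
class SeasonalProfile:
    """Per-taxon, per-depth calendar summary of measured abundances."""

    taxon_id: str
    depth_m: float
    monthly_mean: np.ndarray  # 12 calendar-month means, NaN if unobserved
    season_mean: np.ndarray  # winter, spring, summer, fall
    peak_season: Season | None  # None = unclassifiable (an empty season)
    tie: bool = False


@dataclass
class EcotypeDepthProfile:
    """Aggregate abundance of one group's pASVs by peak season at one depth."""

    group: str
    depth_m: float
    fraction_by_peak_season: dict[Season, float]


def _measured(series: MonthlySeries) -> tuple[np.ndarray, np.ndarray]:
    """(slot indices, values) of measured observations only."""
    sel = series.observed_mask & np.isfinite(series.values)
    return np.where(sel)[0], series.values[sel]


def monthly_climatology(series: MonthlySeries) -> np.ndarray:
    """Calendar-month means (Jan..Dec) of measured values across years.

    Months never observed are NaN.  Warns when fewer than 8 distinct
    calendar months carry observations.
    """
    slots, vals = _measured(series)
    if slots.size == 0:
        raise ValueError("series has no measured values")
    months = np.array([series.calendar_month(int(t)) for t in slots])
    out = np.full(12, np.nan)
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            out[m - 1] = vals[sel].mean()
    covered = np.count_nonzero(np.isfinite(out))
    if covered < 8:
        warnings.warn(
            f"climatology covers only {covered} calendar months", stacklevel=2
        )
    return out


def peak_season(series: MonthlySeries) -> tuple[Season | None, np.ndarray, bool]:
    """Season-averaged measured abundances and the peak season.

    Every measured observation counts once (years are not reweighted).  A
    season with no observations makes the taxon unclassifiable (peak None).
    Exact ties go to the earliest season in winter-spring-summer-fall order,
    flagged.
    """
    slots, vals = _measured(series)
    if slots.size == 0:
        raise ValueError("series has no measured values")
    seasons = np.array([
        SEASON_ORDER.index(season_of_month(series.calendar_month(int(t))))
        for t in slots
    ])
    means = np.full(4, np.nan)
    for k in range(4):
        sel = seasons == k
        if sel.any():
            means[k] = vals[sel].mean()
    if np.any(np.isnan(means)):
        return None, means, False
    best = int(np.argmax(means))  # argmax takes the first maximum: winter-first
    tie = bool(np.count_nonzero(means == means[best]) > 1)
    return SEASON_ORDER[best], means, tie


def aggregate_seasonal_ecotypes(
    table: AbundanceTable,
    profiles: list[SeasonalProfile],
    depth_m: float,
    group_labels: dict[str, str] | None = None,
) -> list[EcotypeDepthProfile]:
    """Time-averaged summed abundance of each group's pASVs by peak season.

    For every (group, season) the relative abundances of the group's taxa
    peaking in that season are summed within each measured sample at the
    depth, then averaged over samples.  Taxa without a label fall into the
    ``"all"`` group when no labels are supplied, else ``"unlabeled"``.
    """
    if table.mode != "relative":
        raise ValueError("aggregation requires a relative-mode table")
    sub = table.restrict_depth(depth_m)
    default_group = "all" if group_labels is None else "unlabeled"
    group_labels = group_labels or {}
    by_group: dict[str, dict[Season, list[str]]] = {}
    for prof in profiles:
        if prof.depth_m != depth_m or prof.peak_season is None:
            continue
        g = group_labels.get(prof.taxon_id, default_group)
        by_group.setdefault(g, {s: [] for s in SEASON_ORDER})
        by_group[g][prof.peak_season].append(prof.taxon_id)
    taxon_row = {t: i for i, t in enumerate(sub.taxa)}
    out = []
    for g in sorted(by_group):
        fractions: dict[Season, float] = {}
        for s in SEASON_ORDER:
            rows = [taxon_row[t] for t in by_group[g][s]]
            if rows:
                fractions[s] = float(sub.values[rows].sum(axis=0).mean())
            else:
                fractions[s] = 0.0
        out.append(EcotypeDepthProfile(group=g, depth_m=depth_m, fraction_by_peak_season=fractions))
    return out


def build_seasonal_profile(
    series: MonthlySeries, taxon_id: str, depth_m: float
) -> SeasonalProfile:
    """Climatology + peak season for one measured series."""
    clim = monthly_climatology(series)
    peak, means, tie = peak_season(series)
    return SeasonalProfile(
        taxon_id=taxon_id,
        depth_m=depth_m,
        monthly_mean=clim,
        season_mean=means,
        peak_season=peak,
        tie=tie,
    )


def seasonal_ecotype_report(
    profiles: list[SeasonalProfile],
    depth_profiles: list[EcotypeDepthProfile],
) -> dict[str, pd.DataFrame]:
    """Tidy long-format report frames.

    Returns ``pasv_profiles`` (taxon x calendar month climatologies),
    ``season_fractions_by_depth`` (per-taxon season means and peak), and
    ``group_depth_profiles`` (group x season x depth aggregate fractions).
    All frames are deterministically ordered, so a rerun with the same
    inputs is byte-identical on disk.
    """
    clim_rows = []
    season_rows = []
    for p in sorted(profiles, key=lambda p: (p.depth_m, p.taxon_id)):
        for m in range(12):
            clim_rows.append({
                "taxon_id": p.taxon_id,
                "depth_m": p.depth_m,
                "month": m + 1,
                "mean_relative_abundance": p.monthly_mean[m],
            })
        season_rows.append({
            "taxon_id": p.taxon_id,
            "depth_m": p.depth_m,
            **{f"{s.value}_mean": p.season_mean[k] for k, s in enumerate(SEASON_ORDER)},
            "peak_season": p.peak_season.value if p.peak_season else "unclassifiable",
            "tie": p.tie,
        })
    group_rows = []
    for gp in sorted(depth_profiles, key=lambda g: (g.depth_m, g.group)):
        for s in SEASON_ORDER:
            group_rows.append({
                "group": gp.group,
                "depth_m": gp.depth_m,
                "peak_season": s.value,
                "fraction": gp.fraction_by_peak_season[s],
            })
    return {
        "pasv_profiles": pd.DataFrame(
            clim_rows,
            columns=["taxon_id", "depth_m", "month", "mean_relative_abundance"],
        ),
        "season_fractions_by_depth": pd.DataFrame(
            season_rows,
            columns=["taxon_id", "depth_m", "winter_mean", "spring_mean",
                     "summer_mean", "fall_mean", "peak_season", "tie"],
        ),
        "group_depth_profiles": pd.DataFrame(
            group_rows, columns=["group", "depth_m", "peak_season", "fraction"]
        ),
    }
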