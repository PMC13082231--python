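"""Per-taxon periodicity screening: the pASV set and its depth profile.

Each taxon's relative-abundance series at one depth is gridded, interpolated
and passed through the umbrella rhythm scan; taxa whose adjusted p falls at
or below alpha are the periodic ASVs (pASVs).  Interpolated values are used
only inside the test — every abundance fraction, climatology and season mean
downstream is computed from measured values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import AbundanceTable, Season
from .ecotypes import build_seasonal_profile, SeasonalProfile
from .timegrid import build_monthly_series, interpolate_linear

__all__ = ["PASVRecord", "SkipRecord", "detect_pasvs", "pasv_fraction_by_depth"]


@dataclass
class PASVRecord:
    """One taxon that passed the annual-periodicity test at one depth."""

    taxon_id: str
    depth_m: float
    statistic: float
    p_adjusted: float
    peak_month: int
    peak_season: Season | None
    rise_length: int
    mean_relative_abundance: float
    n_observed: int


@dataclass
class SkipRecord:
    """A taxon that could not be tested, with the reason."""

    taxon_id: str
    depth_m: float
    reason: str


def detect_pasvs(
    table: AbundanceTable,
    depth_m: float,
    alpha: float = 0.05,
    period: int = 12,
    origin: tuple[int, int] | None = None,
    method: str = "normal",
    seed: int = 0,
    n_perm: int = 1000,
    bh_across_taxa: bool = False,
) -> tuple[list[PASVRecord], list[SkipRecord], list[SeasonalProfile]]:
    """Screen every taxon at one depth for annual periodicity.

    Returns (pASV records with p_adjusted <= alpha, skip log, seasonal
    profiles of the pASVs).  Constant series (including all-zero taxa) and
    taxa observed in fewer than ``period`` distinct months are skipped with
    a reason, never silently dropped.  ``bh_across_taxa`` additionally
    Benjamini-Hochberg-corrects the per-series p-values across taxa before
    applying the cutoff (off by default: the cutoff is per taxon).
    """
    if table.mode != "relative":
        raise ValueError("pASV detection requires a relative-mode table")
    sub = table.restrict_depth(depth_m)
    import warnings as _warnings

    from .rhythm import rain_test

    skips: list[SkipRecord] = []
    tested: list[tuple[str, object, object]] = []  # taxon, result, measured series
    for i, taxon in enumerate(sub.taxa):
        pairs = list(zip(sub.samples, sub.values[i].astype(float)))
        series = build_monthly_series(pairs, origin=origin, depth_m=depth_m, taxon_id=taxon)
        if series.n_observed < period:
            skips.append(SkipRecord(taxon, depth_m, "insufficient_months"))
            continue
        obs = series.observed_values()
        if obs.max() == obs.min():
            skips.append(SkipRecord(taxon, depth_m, "constant"))
            continue
        filled = interpolate_linear(series)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = rain_test(
                filled, period=period, method=method, alpha=alpha,
                n_perm=n_perm, seed=seed,
            )
        tested.append((taxon, res, series))

    pvals = np.array([res.p_adjusted for _, res, _ in tested])
    if bh_across_taxa and len(pvals):
        pvals = multipletests(pvals, method="fdr_bh")[1]

    records: list[PASVRecord] = []
    profiles: list[SeasonalProfile] = []
    for (taxon, res, series), p in zip(tested, pvals):
        if p > alpha:
            continue
        prof = build_seasonal_profile(series, taxon, depth_m)
        profiles.append(prof)
        records.append(PASVRecord(
            taxon_id=taxon,
            depth_m=depth_m,
            statistic=res.statistic,
            p_adjusted=float(p),
            peak_month=res.peak_month,
            peak_season=prof.peak_season,
            rise_length=res.best_envelope.rise_length,
            mean_relative_abundance=float(series.observed_values().mean()),
            n_observed=res.n_observed,
        ))
    return records, skips, profiles


def pasv_fraction_by_depth(
    table: AbundanceTable,
    records: list[PASVRecord],
    n_tested_by_depth: dict[float, int] | None = None,
) -> dict[float, dict[str, float]]:
    """Per-depth summary of how much of the community is periodic.

    ``abundance_fraction`` is the time average, over measured samples at the
    depth, of the summed relative abundance of that depth's pASVs;
    ``count_fraction`` divides the pASV count by the number of taxa tested
    (all taxa in the table unless ``n_tested_by_depth`` says otherwise).
    """
    if table.mode != "relative":
        raise ValueError("fractions require a relative-mode table")
    by_depth: dict[float, list[str]] = {}
    for r in records:
        by_depth.setdefault(r.depth_m, []).append(r.taxon_id)
    out: dict[float, dict[str, float]] = {}
    for depth in table.depths():
        sub = table.restrict_depth(depth)
        taxa = by_depth.get(depth, [])
        rows = [sub.taxa.index(t) for t in taxa]
        if rows:
            fraction = float(sub.values[rows].sum(axis=0).mean())
        else:
            fraction = 0.0
        n_tested = (n_tested_by_depth or {}).get(depth, len(table.taxa))
        out[depth] = {
            "abundance_fraction": fraction,
            "count": float(len(taxa)),
            "count_fraction": len(taxa) / n_tested if n_tested else 0.0,
        }
    return out


def records_frame(records: list[PASVRecord]) -> pd.DataFrame:
    """pASV records as a tidy frame (deterministic row order)."""
    rows = [{
        "taxon_id": r.taxon_id,
        "depth_m": r.depth_m,
        "statistic": r.statistic,
        "p_adjusted": r.p_adjusted,
        "peak_month": r.peak_month,
        "peak_season": r.peak_season.value if r.peak_season else "unclassifiable",
        "rise_length": r.rise_length,
        "mean_relative_abundance": r.mean_relative_abundance,
        "n_observed": r.n_observed,
    } for r in sorted(records, key=lambda r: (r.depth_m, r.taxon_id))]
    return pd.DataFrame(rows, columns=[
        "taxon_id", "depth_m", "statistic", "p_adjusted", "peak_month",
        "peak_season", "rise_length", "mean_relative_abundance", "n_observed",
    ])
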