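"""Whole-community periodicity: Bray-Curtis time-lag structure and diversity.

Annual recurrence of a community shows up as dips in the mean pairwise
Bray-Curtis dissimilarity at time lags that are multiples of 12 months.  The
lag-binned mean dissimilarity series is itself tested for 12-month rhythm
with the same umbrella rank scan used for single taxa, as are per-depth
richness and Shannon-diversity series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AbundanceTable
from .rhythm import RhythmResult, rain_test
from .timegrid import MonthlySeries, build_monthly_series, interpolate_linear, month_index

__all__ = [
    "LagSeries",
    "bray_curtis",
    "dissimilarity_by_lag",
    "community_rhythm",
    "richness",
    "shannon",
    "diversity_periodicity",
]


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class LagSeries:
    """Mean pairwise dissimilarity per month lag at one depth."""

    depth_m: float
    lags: np.ndarray
    mean_dissimilarity: np.ndarray
    n_pairs_per_lag: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.mean_dissimilarity = np.asarray(self.mean_dissimilarity, dtype=float)
        self.n_pairs_per_lag = np.asarray(self.n_pairs_per_lag, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any((self.mean_dissimilarity < 0) | (self.mean_dissimilarity > 1)):
            raise ValueError("mean dissimilarities must lie in [0, 1]")


def _monthly_community(
    table: AbundanceTable, origin: tuple[int, int] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse same-month duplicate samples by averaging their relative-
    abundance profiles; returns (month indices, taxa x months matrix)."""
    if origin is None:
        origin = min((s.year, s.month) for s in table.samples)
    idx = np.array([month_index(s.year, s.month, origin) for s in table.samples])
    months = np.unique(idx)
    profiles = np.column_stack([
        table.values[:, idx == m].mean(axis=1) for m in months
    ])
    return months, profiles


def dissimilarity_by_lag(
    table: AbundanceTable,
    depth_m: float | None = None,
    origin: tuple[int, int] | None = None,
) -> LagSeries:
    """Group pairwise Bray-Curtis dissimilarities by unsigned month lag.

    Same-month duplicates are averaged first, so a lag is a whole number of
    months; lag-0 pairs are excluded.  Requires >= 3 samples at the depth and
    a relative-mode table.
    """
    if table.mode != "relative":
        raise ValueError("community analysis requires a relative-mode table")
    sub = table if depth_m is None else table.restrict_depth(depth_m)
    if depth_m is None:
        depths = sub.depths()
        if len(depths) != 1:
            raise ValueError("table spans multiple depths; pass depth_m")
        depth_m = depths[0]
    if len(sub.samples) < 3:
        raise ValueError(f"need >= 3 samples at depth {depth_m} m")
    months, profiles = _monthly_community(sub, origin)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(len(months)):
        for j in range(i + 1, len(months)):
            lag = int(abs(months[j] - months[i]))
            d = bray_curtis(profiles[:, i], profiles[:, j])
            sums[lag] = sums.get(lag, 0.0) + d
            counts[lag] = counts.get(lag, 0) + 1
    lags = sorted(sums)
    return LagSeries(
        depth_m=depth_m,
        lags=np.array(lags),
        mean_dissimilarity=np.array([sums[l] / counts[l] for l in lags]),
        n_pairs_per_lag=np.array([counts[l] for l in lags]),
    )


def community_rhythm(
    lag_series: LagSeries, period: int = 12, **rain_kwargs
) -> RhythmResult:
    """Rhythm test of mean dissimilarity on the integer lag axis.

    Lags without pairs are linearly interpolated first; a periodic community
    produces dissimilarity minima every ``period`` lags.
    """
    if len(lag_series.lags) < period:
        raise ValueError(
            f"need >= {period} lag bins, have {len(lag_series.lags)}"
        )
    lo, hi = int(lag_series.lags.min()), int(lag_series.lags.max())
    values = np.full(hi - lo + 1, np.nan)
    values[lag_series.lags - lo] = lag_series.mean_dissimilarity
    mask = np.isfinite(values)
    series = MonthlySeries(
        values=values, observed_mask=mask, origin=None, depth_m=lag_series.depth_m
    )
    series = interpolate_linear(series)
    return rain_test(series, period=period, **rain_kwargs)


def richness(column: np.ndarray) -> int:
    """Number of taxa with strictly positive abundance."""
    column = np.asarray(column, dtype=float)
    if np.any(column < 0):
        raise ValueError("abundances must be nonnegative")
    return int(np.count_nonzero(column > 0))


def shannon(column: np.ndarray, tol: float = 1e-6) -> float:
    """Shannon index H = -sum p ln p (nats) of a relative-abundance vector."""
    p = np.asarray(column, dtype=float)
    if np.any(p < 0):
        raise ValueError("relative abundances must be nonnegative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"relative abundances must sum to 1 (got {p.sum():.6g})")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def diversity_periodicity(
    table: AbundanceTable,
    depth_m: float,
    metric: str = "richness",
    origin: tuple[int, int] | None = None,
    **rain_kwargs,
) -> RhythmResult:
    """Rhythm test of a per-depth diversity series (richness or Shannon)."""
    sub = table.restrict_depth(depth_m)
    if metric == "richness":
        vals = [richness(sub.values[:, j]) for j in range(len(sub.samples))]
    elif metric == "shannon":
        if sub.mode != "relative":
            raise ValueError("shannon requires a relative-mode table")
        vals = [shannon(sub.values[:, j]) for j in range(len(sub.samples))]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    series = build_monthly_series(
        list(zip(sub.samples, map(float, vals))), origin=origin, depth_m=depth_m
    )
    series = interpolate_linear(series)
    return rain_test(series, **rain_kwargs)
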