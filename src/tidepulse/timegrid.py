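"""Monthly time grid: map irregular cruise samples onto integer month slots.

Cruises visit approximately monthly but skip months and occasionally sample
twice in one calendar month.  The rhythm test needs one value per integer
month, so samples are gridded (duplicates within a month averaged), interior
gaps are filled by linear interpolation, and an observed/interpolated mask is
kept so later season/climatology summaries can use measured values only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Sample

__all__ = ["MonthlySeries", "month_index", "build_monthly_series", "interpolate_linear"]


@dataclass
class MonthlySeries:
    """One value per integer month slot, with missing encoded as NaN.

    ``observed_mask[t]`` is True only for slots holding a measured value
    (possibly the mean of same-month duplicates); interpolated slots carry a
    finite value but remain False in the mask.  ``origin`` is the (year,
    month) of slot 0, or None for non-calendar axes (e.g. a lag axis).
    """

    values: np.ndarray
    observed_mask: np.ndarray
    origin: tuple[int, int] | None = None
    depth_m: float | None = None
    taxon_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask lengths differ")
        if np.any(np.isnan(self.values[self.observed_mask])):
            raise ValueError("observed slots must hold finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def calendar_month(self, t: int) -> int:
        """Calendar month (1-12) of slot ``t``; requires a calendar origin."""
        if self.origin is None:
            raise ValueError("series has no calendar origin")
        return (self.origin[1] - 1 + t) % 12 + 1

    def observed_values(self) -> np.ndarray:
        return self.values[self.observed_mask]


def month_index(year: int, month: int, origin: tuple[int, int]) -> int:
    """Integer month offset of (year, month) from the grid origin."""
    return 12 * (year - origin[0]) + (month - origin[1])


def build_monthly_series(
    samples: list[tuple[Sample, float]],
    origin: tuple[int, int] | None = None,
    depth_m: float | None = None,
    taxon_id: str | None = None,
) -> MonthlySeries:
    """Grid (sample, value) pairs onto the monthly axis.

    All samples must share one depth.  Months with multiple samples hold the
    arithmetic mean; unvisited months are missing.  The grid spans from the
    origin (default: the earliest observed month) to the latest observed
    month; samples predating an explicit origin are an error.
    """
    if not samples:
        raise ValueError("no samples to grid")
    depths = {s.depth_m for s, _ in samples}
    if len(depths) > 1:
        raise ValueError(f"samples span multiple depths: {sorted(depths)}")
    if depth_m is None:
        depth_m = samples[0][0].depth_m
    if origin is None:
        origin = min((s.year, s.month) for s, _ in samples)
    idx = [month_index(s.year, s.month, origin) for s, _ in samples]
    if min(idx) < 0:
        raise ValueError("sample predates the grid origin")
    n = max(idx) + 1
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for t, (_, v) in zip(idx, samples):
        sums[t] += v
        counts[t] += 1
    values = np.full(n, np.nan)
    mask = counts > 0
    values[mask] = sums[mask] / counts[mask]
    return MonthlySeries(
        values=values, observed_mask=mask, origin=origin,
        depth_m=depth_m, taxon_id=taxon_id,
    )


def interpolate_linear(series: MonthlySeries) -> MonthlySeries:
    """Fill interior missing slots by linear interpolation.

    Each missing slot strictly between two finite slots gets the straight-line
    value of its nearest finite neighbors; leading/trailing gaps are left
    missing (no extrapolation).  The observed mask is unchanged, so filled
    slots are identifiable as interpolated.
    """
    have = np.where(np.isfinite(series.values))[0]
    if have.size < 2:
        raise ValueError("need at least 2 finite points to interpolate")
    values = series.values.copy()
    lo, hi = have[0], have[-1]
    interior = np.arange(lo, hi + 1)
    gaps = interior[np.isnan(values[interior])]
    if gaps.size:
        values[gaps] = np.interp(gaps, have, series.values[have])
    return replace(series, values=values, observed_mask=series.observed_mask.copy())
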