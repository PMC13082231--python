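"""Nonparametric annual-rhythm detection by umbrella rank statistics.

A monthly series is folded into ``period`` phase groups (slot index mod
period).  For each candidate rhythm *envelope* — a peak phase plus a rise
length, covering symmetric and asymmetric waveforms — an umbrella statistic
sums Mann-Whitney U counts over all group pairs that the envelope orders:
concordant pairs on the rising arm (earlier phase below later) and on the
falling arm (earlier phase above later), ties counted 1/2.  One-sided
p-values against the exchangeable permutation null are computed per envelope
(exact enumeration, seeded Monte Carlo, or a normal approximation with the
exact permutation mean and variance of S), then Benjamini-Hochberg adjusted across
envelopes; the series-level p is the minimum adjusted value.

This is the peak-known umbrella test of Mack & Wolfe (1981) scanned over all
peaks and shapes, which is the construction behind nonparametric rhythm
screens of omics time series.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .timegrid import MonthlySeries

__all__ = [
    "Envelope",
    "RhythmResult",
    "enumerate_envelopes",
    "phase_groups",
    "umbrella_statistic",
    "envelope_pvalue",
    "rain_test",
    "EXACT_MAX_N",
]

EXACT_MAX_N = 9  # full permutation enumeration caps at 9! = 362880 layouts
_EPS = 1e-9


@dataclass(frozen=True)
class Envelope:
    """One candidate rhythm shape: peak phase and rise length (months)."""

    period: int
    peak_phase: int
    rise_length: int

    def __post_init__(self) -> None:
        if self.period < 3:
            raise ValueError("period must be >= 3")
        if not 0 <= self.peak_phase < self.period:
            raise ValueError("peak_phase must be in 0..period-1")
        if not 1 <= self.rise_length <= self.period - 1:
            raise ValueError("rise_length must be in 1..period-1")

    @property
    def trough_phase(self) -> int:
        return (self.peak_phase - self.rise_length) % self.period

    @property
    def asymmetry(self) -> float:
        """|rise - fall| / period; 0 for the symmetric (cosine-like) shape."""
        return abs(self.rise_length - self.period / 2) / self.period


@dataclass
class RhythmResult:
    """Outcome of the rhythm scan on one series."""

    statistic: float
    p_adjusted: float
    best_envelope: Envelope
    p_raw_best: float
    peak_month: int | None
    n_observed: int
    method: str
    per_envelope_p: np.ndarray | None = None


def enumerate_envelopes(
    period: int, peak_border: tuple[float, float] = (0.0, 1.0)
) -> list[Envelope]:
    """All envelopes whose rise fraction r/period lies strictly inside
    ``peak_border``, in deterministic phase-major order."""
    lo, hi = peak_border
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid peak_border {peak_border}")
    out = [
        Envelope(period=period, peak_phase=phase, rise_length=r)
        for phase in range(period)
        for r in range(1, period)
        if lo < r / period < hi
    ]
    if not out:
        raise ValueError(f"peak_border {peak_border} admits no envelope at period {period}")
    return out


def phase_groups(series: MonthlySeries, period: int) -> list[np.ndarray]:
    """Fold a (typically interpolated) series into phase groups.

    Group k collects the finite values at slots t with t mod period == k;
    slots still missing after interpolation contribute nothing.
    """
    finite = np.isfinite(series.values)
    groups = []
    for k in range(period):
        sel = finite & (np.arange(len(series)) % period == k)
        groups.append(series.values[sel])
    return groups


# ---------------------------------------------------------------------------
# Envelope geometry
# ---------------------------------------------------------------------------

def _envelope_mask(period: int, peak_phase: int, rise_length: int) -> np.ndarray:
    """0/1 matrix M with M[a, b] = 1 iff the envelope predicts values in
    phase group a below values in phase group b.

    Phases are rotated so the trough comes first; rising-arm pairs (i < j <=
    r) count U(g_i < g_j), falling-arm pairs (r <= i < j) count U(g_i > g_j),
    i.e. U(g_j < g_i).  The trough group anchors only the rising arm.
    """
    q = (peak_phase - rise_length) % period
    order = [(q + i) % period for i in range(period)]
    M = np.zeros((period, period))
    r = rise_length
    for i in range(r + 1):
        for j in range(i + 1, r + 1):
            M[order[i], order[j]] = 1.0
    for i in range(r, period):
        for j in range(i + 1, period):
            M[order[j], order[i]] = 1.0
    return M


@lru_cache(maxsize=16)
def _envelope_tensor(
    period: int, peak_border: tuple[float, float]
) -> tuple[tuple[Envelope, ...], np.ndarray]:
    envs = enumerate_envelopes(period, peak_border)
    M = np.stack([
        _envelope_mask(period, e.peak_phase, e.rise_length) for e in envs
    ])
    return tuple(envs), M


def _value_moments(x: np.ndarray) -> tuple:
    """Sums over the value comparison matrix needed for exact null moments.

    With b_uv = 1[x_u < x_v] + 1/2[x_u = x_v] (diagonal zeroed), returns the
    pair/triple/quadruple sums of b over distinct value indices.  These fully
    encode the tie structure of the data.
    """
    B = _comparison_matrix(x)
    np.fill_diagonal(B, 0.0)
    rowB = B.sum(axis=1)
    colB = B.sum(axis=0)
    T = B.sum()
    S2 = (B * B).sum()
    Srev = (B * B.T).sum()
    V1 = (rowB * rowB).sum() - S2
    V2 = (colB * colB).sum() - S2
    V3 = (rowB * colB).sum() - Srev
    Vd = T * T - (S2 + Srev + V1 + V2 + 2.0 * V3)
    return len(x), S2, Srev, V1, V2, V3, Vd


def _exact_moments(
    x: np.ndarray, sizes: np.ndarray, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact permutation-null mean and variance of S for every envelope.

    S is a quadratic permutation statistic S = sum_{s!=t} w_st b(pi_s, pi_t)
    with position weights w_st = M[group_s, group_t]; its second moment
    decomposes over the overlap pattern of position pairs (identical, shared
    source, shared target, chained, disjoint), each matched with the
    corresponding comparison-matrix sum.  Exact for arbitrary ties, which
    keeps the envelope ranking deterministic even on heavily tied series.
    """
    N, S2, Srev, V1, V2, V3, Vd = _value_moments(x)
    n = sizes.astype(float)
    r = np.einsum("eab,b->ea", M, n)  # per-envelope row weight by group
    c = np.einsum("eab,a->eb", M, n)
    W = np.einsum("ea,a->e", r, n)
    A1 = np.einsum("ea,a->e", r * r, n) - W
    A2 = np.einsum("eb,b->e", c * c, n) - W
    A3 = np.einsum("ea,a->e", r * c, n)
    D = W * W - (W + A1 + A2 + 2.0 * A3)
    mean = W / 2.0
    p2 = N * (N - 1.0)
    p3 = p2 * (N - 2.0)
    p4 = p3 * (N - 3.0)
    second = W * S2 / p2 + (A1 * V1 + A2 * V2 + 2.0 * A3 * V3) / p3
    if N >= 4:
        second = second + D * Vd / p4
    var = np.maximum(second - mean * mean, 0.0)
    return mean, var


@lru_cache(maxsize=4096)
def _layout_moments(
    period: int, peak_border: tuple[float, float], sizes: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-null mean and variance of S per envelope (no-ties case).

    Closed-form Mack-Wolfe peak-known moments for arbitrary group sizes;
    the mean n_pairs/2 also holds under the 1/2 tie convention.
    """
    envs, _ = _envelope_tensor(period, peak_border)
    n = np.asarray(sizes, dtype=float)
    means = np.empty(len(envs))
    variances = np.empty(len(envs))
    for i, env in enumerate(envs):
        q = env.trough_phase
        s = n[(q + np.arange(period)) % period]
        r = env.rise_length
        N1 = s[: r + 1].sum()
        N2 = s[r:].sum()
        npk = s[r]
        N = s.sum()
        n_pairs = (N1 * N1 + N2 * N2 - (s * s).sum() - npk * npk) / 2.0
        var = (
            2.0 * (N1**3 + N2**3)
            + 3.0 * (N1 * N1 + N2 * N2)
            - (s * s * (2.0 * s + 3.0)).sum()
            - npk * npk * (2.0 * npk + 3.0)
            + 12.0 * npk * N1 * N2
            - 12.0 * npk * npk * N
        ) / 72.0
        means[i] = n_pairs / 2.0
        variances[i] = max(var, 0.0)
    return means, variances


# ---------------------------------------------------------------------------
# Statistic
# ---------------------------------------------------------------------------

def _comparison_matrix(x: np.ndarray) -> np.ndarray:
    """C[s, t] = 1 if x_s < x_t, 1/2 if tied, 0 otherwise."""
    return (x[:, None] < x[None, :]) + 0.5 * (x[:, None] == x[None, :])


def _group_matrix(labels: np.ndarray, period: int) -> np.ndarray:
    G = np.zeros((period, len(labels)))
    G[labels, np.arange(len(labels))] = 1.0
    return G


def umbrella_statistic(
    groups: list[np.ndarray], envelope: Envelope
) -> tuple[float, int]:
    """Summed Mann-Whitney statistic S and the cross-group pair count.

    S counts concordant pairs over both arms of the envelope (ties 1/2);
    pairs involving empty phase groups simply do not exist.
    """
    period = envelope.period
    if len(groups) != period:
        raise ValueError(f"expected {period} phase groups, got {len(groups)}")
    M = _envelope_mask(period, envelope.peak_phase, envelope.rise_length)
    S = 0.0
    n_pairs = 0
    for a in range(period):
        ga = np.asarray(groups[a], dtype=float)
        if ga.size == 0:
            continue
        for b in range(period):
            if M[a, b] == 0.0:
                continue
            gb = np.asarray(groups[b], dtype=float)
            if gb.size == 0:
                continue
            lt = np.count_nonzero(ga[:, None] < gb[None, :])
            eq = np.count_nonzero(ga[:, None] == gb[None, :])
            S += lt + 0.5 * eq
            n_pairs += ga.size * gb.size
    if n_pairs == 0:
        raise ValueError("no cross-group pairs: statistic undefined")
    return float(S), int(n_pairs)


# ---------------------------------------------------------------------------
# Null distributions
# ---------------------------------------------------------------------------

def _perm_statistics(
    x: np.ndarray,
    labels: np.ndarray,
    period: int,
    M: np.ndarray,
    perms: np.ndarray,
    chunk: int = 200,
) -> np.ndarray:
    """S for each permuted value assignment, for every envelope in M.

    ``perms`` has one row of value indices per permutation; envelopes share
    each permutation, which preserves their joint dependence.
    """
    G = _group_matrix(labels, period)
    out = np.empty((len(perms), M.shape[0]))
    for start in range(0, len(perms), chunk):
        X = x[perms[start : start + chunk]]
        C = (X[:, :, None] < X[:, None, :]) + 0.5 * (X[:, :, None] == X[:, None, :])
        U = np.einsum("as,bst,ct->bac", G, C, G)
        out[start : start + chunk] = np.einsum("eac,bac->be", M, U)
    return out


def _random_permutations(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    """n_perm independent uniform permutations of range(n), drawn in one call."""
    return rng.permuted(np.tile(np.arange(n, dtype=np.intp), (n_perm, 1)), axis=1)


def _all_permutations(x: np.ndarray) -> np.ndarray:
    n = len(x)
    if n > EXACT_MAX_N:
        raise ValueError(
            f"exact enumeration limited to N <= {EXACT_MAX_N} values (got {n}); "
            "use method='montecarlo'"
        )
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _normal_tail(S: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """One-sided upper tail with continuity correction; degenerate nulls
    (zero variance) give p = 1 whenever S does not exceed its mean."""
    S = np.atleast_1d(np.asarray(S, dtype=float))
    mean = np.broadcast_to(mean, S.shape)
    var = np.broadcast_to(var, S.shape)
    p = np.ones_like(S)
    ok = var > 0
    p[ok] = norm.sf((S[ok] - mean[ok] - 0.5) / np.sqrt(var[ok]))
    degenerate = ~ok & (S > mean + _EPS)
    p[degenerate] = 0.0
    return np.clip(p, np.finfo(float).tiny, 1.0)


def envelope_pvalue(
    S: float,
    groups: list[np.ndarray],
    envelope: Envelope,
    method: str = "normal",
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """One-sided p = Pr(S* >= S) under random reassignment of the observed
    values to the same group-size layout.

    ``exact`` fully enumerates assignments (total N <= 9); ``montecarlo``
    uses seeded resampling with the add-one correction; ``normal`` uses the
    Gaussian tail with the exact permutation moments of S (valid under any
    tie structure) and a continuity correction.
    """
    period = envelope.period
    x = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    labels = np.concatenate([
        np.full(len(g), k, dtype=np.intp) for k, g in enumerate(groups)
    ])
    M = _envelope_mask(period, envelope.peak_phase, envelope.rise_length)[None]
    if method == "exact":
        perms = _all_permutations(x)
        S_null = _perm_statistics(x, labels, period, M, perms)[:, 0]
        return float(np.mean(S_null >= S - _EPS))
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        perms = _random_permutations(rng, n_perm, len(x))
        S_null = _perm_statistics(x, labels, period, M, perms)[:, 0]
        return float((1 + np.count_nonzero(S_null >= S - _EPS)) / (1 + n_perm))
    if method == "normal":
        sizes = np.array([len(g) for g in groups])
        mean, var = _exact_moments(x, sizes, M)
        return float(_normal_tail(np.array([S]), mean, var)[0])
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------

def rain_test(
    series: MonthlySeries,
    period: int = 12,
    peak_border: tuple[float, float] = (0.0, 1.0),
    method: str = "normal",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    keep_per_envelope: bool = False,
) -> RhythmResult:
    """Scan every envelope, BH-adjust across envelopes, report the minimum.

    The series should be interpolated first; at least one full period of
    finite values is required and two are recommended.  ``seed`` drives the
    Monte Carlo / tie-calibration permutations, making every run reproducible.
    The best envelope minimizes the raw p, ties broken by earliest peak
    phase, then most symmetric shape.
    """
    finite = np.isfinite(series.values)
    n_obs = int(finite.sum())
    if n_obs < period:
        raise ValueError(f"need >= {period} finite values, have {n_obs}")
    if n_obs < 2 * period:
        warnings.warn(
            f"only {n_obs} finite values (< 2 periods); rhythm test is weak",
            stacklevel=2,
        )
    x = series.values[finite]
    labels = (np.where(finite)[0] % period).astype(np.intp)
    envs, M = _envelope_tensor(period, tuple(peak_border))
    G = _group_matrix(labels, period)
    sizes = G.sum(axis=1)
    U = G @ _comparison_matrix(x) @ G.T
    S_all = np.einsum("eab,ab->e", M, U)

    constant = x.max() == x.min()
    if constant:
        p_raw = np.ones(len(envs))
    elif method == "exact":
        perms = _all_permutations(x)
        S_null = _perm_statistics(x, labels, period, M, perms)
        p_raw = np.mean(S_null >= S_all[None] - _EPS, axis=0)
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        perms = _random_permutations(rng, n_perm, len(x))
        S_null = _perm_statistics(x, labels, period, M, perms)
        hits = np.count_nonzero(S_null >= S_all[None] - _EPS, axis=0)
        p_raw = (1.0 + hits) / (1.0 + n_perm)
    elif method == "normal":
        means, variances = _exact_moments(x, sizes, M)
        p_raw = _normal_tail(S_all, means, variances)
    else:
        raise ValueError(f"unknown method {method!r}")

    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    order = np.lexsort((
        [e.asymmetry for e in envs],
        [e.peak_phase for e in envs],
        p_raw,
    ))
    best_i = int(order[0])
    best = envs[best_i]
    peak_month = None
    if series.origin is not None and period == 12:
        peak_month = (series.origin[1] - 1 + best.peak_phase) % 12 + 1
    return RhythmResult(
        statistic=float(S_all[best_i]),
        p_adjusted=float(p_adj.min()),
        best_envelope=best,
        p_raw_best=float(p_raw[best_i]),
        peak_month=peak_month,
        n_observed=n_obs,
        method=method,
        per_envelope_p=p_raw if keep_per_envelope else None,
    )
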