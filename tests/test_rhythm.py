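import itertools

import numpy as np
import pytest

from tidepulse.rhythm import (
    EXACT_MAX_N,
    Envelope,
    enumerate_envelopes,
    envelope_pvalue,
    phase_groups,
    rain_test,
    umbrella_statistic,
)
from tidepulse.rhythm import _envelope_mask, _comparison_matrix
from tidepulse.timegrid import MonthlySeries


# --- independent oracles (pure-python pair enumeration) --------------------

def oracle_umbrella(groups, envelope):
    """Exhaustive pair counting straight from the definition: rotate so the
    trough is first, count concordant pairs on the rising then falling arm,
    ties as 1/2."""
    period, r = envelope.period, envelope.rise_length
    q = (envelope.peak_phase - r) % period
    order = [(q + i) % period for i in range(period)]
    S, n = 0.0, 0
    for i in range(period):
        for j in range(i + 1, period):
            if j <= r:
                lo, hi = order[i], order[j]  # expect group lo < group hi
            elif i >= r:
                lo, hi = order[j], order[i]  # falling: later phase is lower
            else:
                continue
            for a in groups[lo]:
                for b in groups[hi]:
                    S += 1.0 if a < b else (0.5 if a == b else 0.0)
                    n += 1
    return S, n


def oracle_exact_p(groups, envelope, S_obs):
    """Full enumeration of value-to-layout assignments."""
    values = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    total, hits = 0, 0
    for perm in itertools.permutations(values):
        regrouped, pos = [], 0
        for k in sizes:
            regrouped.append(list(perm[pos:pos + k]))
            pos += k
        S, _ = oracle_umbrella(regrouped, envelope)
        total += 1
        hits += S >= S_obs - 1e-9
    return hits / total


def random_groups(rng, period, max_per_group=3, allow_empty=False):
    lo = 0 if allow_empty else 1
    return [
        rng.integers(0, 10, size=rng.integers(lo, max_per_group + 1)).astype(float)
        for _ in range(period)
    ]


# --- envelope enumeration ---------------------------------------------------

class TestEnumerateEnvelopes:
    def test_full_border_counts(self):
        assert len(enumerate_envelopes(12, (0.0, 1.0))) == 132
        assert len(enumerate_envelopes(4, (0.0, 1.0))) == 12

    def test_narrow_border_keeps_only_symmetric(self):
        envs = enumerate_envelopes(12, (0.49, 0.51))
        assert len(envs) == 12
        assert all(e.rise_length == 6 for e in envs)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            enumerate_envelopes(12, (0.0, 1 / 24))

    def test_deterministic_phase_major_order(self):
        envs = enumerate_envelopes(4, (0.0, 1.0))
        assert [(e.peak_phase, e.rise_length) for e in envs[:4]] == [
            (0, 1), (0, 2), (0, 3), (1, 1)
        ]


class TestPhaseGroups:
    def _series(self, n, missing=()):
        v = np.arange(n, dtype=float)
        mask = np.ones(n, bool)
        for t in missing:
            v[t] = np.nan
            mask[t] = False
        return MonthlySeries(values=v, observed_mask=mask)

    def test_two_full_years(self):
        groups = phase_groups(self._series(24), 12)
        assert [len(g) for g in groups] == [2] * 12

    def test_thirteen_months(self):
        groups = phase_groups(self._series(13), 12)
        assert [len(g) for g in groups] == [2] + [1] * 11

    def test_uninterpolable_missing_slot_shrinks_its_group(self):
        groups = phase_groups(self._series(13, missing=[5]), 12)
        assert len(groups[5]) == 0


# --- statistic --------------------------------------------------------------

class TestUmbrellaStatistic:
    def test_period4_worked_example(self):
        groups = [np.array([v]) for v in [1.0, 2.0, 3.0, 2.0]]
        env = Envelope(period=4, peak_phase=2, rise_length=2)
        S, n = umbrella_statistic(groups, env)
        assert (S, n) == (4.0, 4)

    def test_constant_series_gives_half_pairs(self):
        groups = [np.full(2, 3.0) for _ in range(6)]
        for env in enumerate_envelopes(6, (0.0, 1.0))[::5]:
            S, n = umbrella_statistic(groups, env)
            assert S == pytest.approx(n / 2)

    def test_perfect_anti_rhythm_scores_zero(self):
        # values fall where the envelope rises and rise where it falls
        env = Envelope(period=6, peak_phase=3, rise_length=3)
        values_by_phase = [5.0, 4.0, 3.0, 2.0, 3.5, 4.5]  # trough at the peak
        groups = [np.array([v]) for v in values_by_phase]
        S, _ = umbrella_statistic(groups, env)
        assert S == 0.0

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(100):
            period = int(rng.integers(3, 7))
            groups = random_groups(rng, period, allow_empty=True)
            envs = enumerate_envelopes(period, (0.0, 1.0))
            env = envs[rng.integers(len(envs))]
            expected_S, expected_n = oracle_umbrella(groups, env)
            if expected_n == 0:
                with pytest.raises(ValueError):
                    umbrella_statistic(groups, env)
                continue
            S, n = umbrella_statistic(groups, env)
            assert S == pytest.approx(expected_S, abs=1e-12)
            assert n == expected_n

    def test_forward_plus_reversed_equals_pair_count(self, rng):
        # exchanging rising and falling arms flips every predicted
        # inequality, so the two statistics tile all cross-group pairs
        for _ in range(30):
            period = int(rng.integers(3, 8))
            groups = random_groups(rng, period)
            envs = enumerate_envelopes(period, (0.0, 1.0))
            env = envs[rng.integers(len(envs))]
            M = _envelope_mask(period, env.peak_phase, env.rise_length)
            x = np.concatenate(groups)
            labels = np.concatenate([
                np.full(len(g), k) for k, g in enumerate(groups)
            ]).astype(int)
            G = np.zeros((period, len(x)))
            G[labels, np.arange(len(x))] = 1.0
            U = G @ _comparison_matrix(x) @ G.T
            sizes = np.array([len(g) for g in groups], dtype=float)
            n_pairs = np.einsum("ab,a,b->", M, sizes, sizes)
            assert (M * U).sum() + (M.T * U).sum() == pytest.approx(n_pairs)


# --- null distributions -----------------------------------------------------

class TestEnvelopePvalue:
    def test_exact_matches_brute_force_enumeration(self, rng):
        for _ in range(12):
            period = int(rng.integers(3, 5))
            groups = random_groups(rng, period, max_per_group=2)
            if sum(len(g) for g in groups) > 7:
                continue
            envs = enumerate_envelopes(period, (0.0, 1.0))
            env = envs[rng.integers(len(envs))]
            S, _ = umbrella_statistic(groups, env)
            p = envelope_pvalue(S, groups, env, method="exact")
            assert p == pytest.approx(oracle_exact_p(groups, env, S), abs=1e-12)

    def test_period4_worked_example_exact(self):
        groups = [np.array([v]) for v in [1.0, 2.0, 3.0, 2.0]]
        env = Envelope(period=4, peak_phase=2, rise_length=2)
        S, _ = umbrella_statistic(groups, env)
        p = envelope_pvalue(S, groups, env, method="exact")
        assert p == pytest.approx(oracle_exact_p(groups, env, S), abs=1e-12)

    def test_montecarlo_within_binomial_error_of_exact(self, rng):
        groups = [rng.uniform(size=2) for _ in range(4)]
        env = Envelope(period=4, peak_phase=1, rise_length=2)
        S, _ = umbrella_statistic(groups, env)
        p_exact = envelope_pvalue(S, groups, env, method="exact")
        n_perm = 20000
        p_mc = envelope_pvalue(S, groups, env, method="montecarlo",
                               n_perm=n_perm, seed=7)
        bound = 3 * np.sqrt(p_exact * (1 - p_exact) / n_perm) + 2 / n_perm
        assert abs(p_mc - p_exact) <= bound

    def test_exact_refuses_large_n(self, rng):
        groups = [rng.uniform(size=2) for _ in range(6)]
        env = Envelope(period=6, peak_phase=2, rise_length=3)
        with pytest.raises(ValueError, match="montecarlo"):
            envelope_pvalue(5.0, groups, env, method="exact")
        assert sum(len(g) for g in groups) > EXACT_MAX_N

    @pytest.mark.parametrize("method", ["exact", "montecarlo", "normal"])
    def test_constant_series_p_is_one(self, method):
        groups = [np.full(2, 1.0) for _ in range(4)]
        env = Envelope(period=4, peak_phase=2, rise_length=2)
        S, n = umbrella_statistic(groups, env)
        assert envelope_pvalue(S, groups, env, method=method, seed=3) == 1.0

    def test_normal_close_to_exact_on_moderate_instance(self, rng):
        groups = [rng.uniform(size=2) for _ in range(4)]
        env = Envelope(period=4, peak_phase=0, rise_length=2)
        S, _ = umbrella_statistic(groups, env)
        p_exact = envelope_pvalue(S, groups, env, method="exact")
        p_norm = envelope_pvalue(S, groups, env, method="normal")
        assert abs(p_norm - p_exact) < 0.05


# --- full scan --------------------------------------------------------------

def cosine_series(n_months=102, peak_month=7, origin=(2014, 11), noise_sd=0.0,
                  rng=None):
    t = np.arange(n_months)
    cal = (origin[1] - 1 + t) % 12 + 1
    v = np.cos(2 * np.pi * (cal - peak_month) / 12.0)
    if noise_sd and rng is not None:
        v = v + rng.normal(0, noise_sd, n_months)
    return MonthlySeries(values=v, observed_mask=np.ones(n_months, bool),
                         origin=origin)


class TestRainTest:
    @pytest.mark.parametrize("peak_month", [1, 4, 7, 12])
    def test_noiseless_cosine_recovers_peak(self, peak_month):
        res = rain_test(cosine_series(peak_month=peak_month))
        assert res.p_adjusted <= 0.001
        assert res.peak_month == peak_month
        # any rise length is fully concordant for a unimodal cosine, so the
        # winning shape need not be symmetric; the peak itself must be exact

    def test_rank_invariance_under_monotone_transforms(self, rng):
        series = cosine_series(noise_sd=1.0, rng=rng)
        base = rain_test(series)
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2, np.arctan):
            other = MonthlySeries(values=f(series.values),
                                  observed_mask=series.observed_mask,
                                  origin=series.origin)
            res = rain_test(other)
            assert res.p_adjusted == base.p_adjusted
            assert res.statistic == base.statistic
            assert res.best_envelope == base.best_envelope

    def test_montecarlo_rank_invariance_with_fixed_seed(self, rng):
        series = cosine_series(n_months=30, noise_sd=1.0, rng=rng)
        a = rain_test(series, method="montecarlo", n_perm=500, seed=11)
        b = MonthlySeries(values=np.exp(series.values),
                          observed_mask=series.observed_mask,
                          origin=series.origin)
        res_b = rain_test(b, method="montecarlo", n_perm=500, seed=11)
        assert res_b.p_adjusted == a.p_adjusted

    def test_too_few_observations_error(self):
        s = MonthlySeries(values=np.ones(8), observed_mask=np.ones(8, bool))
        with pytest.raises(ValueError, match=">= 12"):
            rain_test(s)

    def test_short_series_warns(self, rng):
        v = rng.uniform(size=16)
        s = MonthlySeries(values=v, observed_mask=np.ones(16, bool))
        with pytest.warns(UserWarning, match="2 periods"):
            rain_test(s)

    def test_constant_series_p_one(self):
        s = MonthlySeries(values=np.ones(36), observed_mask=np.ones(36, bool),
                          origin=(2014, 11))
        res = rain_test(s)
        assert res.p_adjusted == 1.0

    def test_normal_agrees_with_montecarlo_full_scan(self, rng):
        series = cosine_series(n_months=48, peak_month=3, noise_sd=2.0, rng=rng)
        a = rain_test(series, method="normal", keep_per_envelope=True)
        b = rain_test(series, method="montecarlo", n_perm=4000, seed=5,
                      keep_per_envelope=True)
        mid = (a.per_envelope_p > 0.02) & (a.per_envelope_p < 0.6)
        assert np.all(np.abs(a.per_envelope_p[mid] - b.per_envelope_p[mid]) < 0.04)

    def test_reruns_are_identical(self, rng):
        series = cosine_series(noise_sd=0.5, rng=rng)
        a = rain_test(series)
        b = rain_test(series)
        assert (a.statistic, a.p_adjusted, a.best_envelope) == \
               (b.statistic, b.p_adjusted, b.best_envelope)
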