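"""PAVA and the AR(1) online active-set solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import isotonic_oracle, qp_oracle_lasso
from spikedeconv.ar1 import (OnlineOasisAR1, Pool, add_spike_split,
                             construct_solution, l0_deconvolve, merge_pools,
                             oasis_ar1, oasis_ar1_limited_lag, pava,
                             smin_lag_schedule)
from spikedeconv.core import estimate_noise_psd


class TestPava:
    def test_monotone_input_unchanged(self):
        assert np.allclose(pava([1, 2, 3]), [1, 2, 3])

    def test_violation_averaged(self):
        assert np.allclose(pava([2, 1]), [1.5, 1.5])

    def test_matches_projection_oracle(self, rng):
        for _ in range(5):
            y = rng.normal(size=12)
            x = pava(y)
            assert np.all(np.diff(x) >= -1e-12)
            assert np.allclose(x, isotonic_oracle(y), atol=1e-8)


class TestMerge:
    def test_gamma_one_reduces_to_averaging(self):
        m = merge_pools(Pool(2.0, 1.0, 0, 1), Pool(0.0, 1.0, 1, 1), 1.0)
        assert m == Pool(1.0, 2.0, 0, 2)

    def test_hand_evaluated_weighted_merge(self):
        m = merge_pools(Pool(1.0, 1.0, 4, 1), Pool(0.5, 1.0, 5, 1), 0.95)
        assert np.isclose(m.v, (1 + 0.95 * 0.5) / (1 + 0.9025))
        assert np.isclose(m.w, 1.9025)
        assert m.l == 2 and m.t == 4

    def test_merge_equals_direct_recomputation(self, rng):
        # the O(1) merge reproduces the closed-form weighted average over
        # the concatenated data (the induction behind the algorithm)
        g = 0.9
        y = rng.normal(size=10) + 1
        d = g ** np.arange(10)
        pools = [Pool(float(y[t]), 1.0, t, 1) for t in range(10)]
        merged = pools[0]
        for p in pools[1:]:
            merged = merge_pools(merged, p, g)
            l = merged.l
            expect = (y[:l] @ d[:l]) / (d[:l] @ d[:l])
            assert np.isclose(merged.v, expect, rtol=1e-12)

    def test_non_adjacent_rejected(self):
        with pytest.raises(ValueError):
            merge_pools(Pool(1, 1, 0, 1), Pool(1, 1, 5, 1), 0.9)


class TestOasisAr1:
    def test_feasible_input_unchanged(self):
        c, s, _ = oasis_ar1([1, 0.5, 0.25], 0.5)
        assert np.allclose(c, [1, 0.5, 0.25])
        assert np.allclose(s, [1, 0, 0])

    def test_hand_evaluated_merge(self):
        c, s, _ = oasis_ar1([1.0, 0.0], 0.5)
        assert np.allclose(c, [0.8, 0.4])
        assert np.allclose(s, [0.8, 0.0])

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            oasis_ar1([1.0, np.nan], 0.9)
        with pytest.raises(ValueError):
            oasis_ar1([1.0], 1.2)
        with pytest.raises(ValueError):
            oasis_ar1([1.0], 0.9, lam=1.0, s_min=0.5)

    @pytest.mark.parametrize("trial", range(10))
    def test_exactness_vs_qp_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        T = int(rng.integers(50, 300))
        g = rng.uniform(0.5, 0.99)
        lam = rng.uniform(0.0, 5.0)
        spikes = rng.exponential(size=T) * (rng.random(T) < 0.05)
        y = np.convolve(spikes, g ** np.arange(T))[:T] + rng.normal(0, 0.3, T)
        c, s, _ = oasis_ar1(y, g, lam=lam)
        orac = qp_oracle_lasso(y, (g,), lam)
        assert orac.status == "optimal"
        obj = 0.5 * np.sum((c - y) ** 2) + lam * s.sum()
        assert obj <= orac.objective * (1 + 1e-8) + 1e-10
        assert np.max(np.abs(c - orac.c)) < 1e-6

    def test_pava_reduction(self, rng):
        for _ in range(20):
            y = rng.normal(size=100)
            _, _, part = oasis_ar1(y, 1.0, zero_floor=False)
            c, _ = construct_solution(part, clip=False)
            assert np.allclose(c, pava(y), atol=1e-10)

    def test_constraints_satisfied_at_convergence(self, ar1_traces):
        for tr in ar1_traces[:2]:
            _, _, part = oasis_ar1(tr.y, 0.95, lam=2.0)
            for i in range(part.z - 1):
                assert part.v[i + 1] >= 0.95 ** part.l[i] * part.v[i] - 1e-10

    def test_negative_pool_clipped(self):
        c, s, _ = oasis_ar1([-1.0, -0.5, -0.25], 0.5)
        assert np.all(c == 0) and np.all(s == 0)

    def test_merge_count_soft_bound(self, ar1_traces):
        for tr in ar1_traces[:2]:
            *_, merges = oasis_ar1(tr.y, 0.95, lam=1.0, count_merges=True)
            assert len(merges) == tr.spec.T
            assert max(merges) <= 10

    def test_deconvolved_nonnegative_at_pool_starts(self, ar1_traces):
        for tr in ar1_traces:
            _, s, part = oasis_ar1(tr.y, 0.95, lam=1.5)
            assert np.all(s[part.t[1:]] >= -1e-12)

    @given(smin=st.floats(0.1, 1.0))
    @settings(max_examples=10, deadline=None)
    def test_hard_threshold_spikes_exceed_smin(self, smin, ar1_traces):
        _, s, part = oasis_ar1(ar1_traces[0].y, 0.95, s_min=smin)
        spikes = s[np.asarray(part.t[1:])]
        assert np.all(spikes[spikes > 0] >= smin - 1e-9)


class TestSpikeSplit:
    @staticmethod
    def _single_pool(y, g):
        from spikedeconv.ar1 import PoolPartition, pool_value
        v, w = pool_value(np.asarray(y, float), g, 0, len(y))
        return PoolPartition([v], [w], [0], [len(y)], g, np.zeros(len(y)))

    def test_split_values_match_closed_form(self):
        y = np.array([1.0, 0.7, 0.9, 0.5])
        part = self._single_pool(y, 0.95)
        part = add_spike_split(part, 2, y, 0.95)
        d = 0.95 ** np.arange(2)
        assert np.isclose(part.v[0], (y[:2] @ d) / (d @ d))
        assert np.isclose(part.v[1], (y[2:] @ d) / (d @ d))
        assert part.l == [2, 2]

    def test_split_reduces_rss(self, ar1_traces):
        y = ar1_traces[0].y[:200]
        part = self._single_pool(y, 0.95)
        for t_s in [50, 120, 80]:
            before = part.rss(y)
            add_spike_split(part, t_s, y, 0.95)
            assert part.rss(y) <= before + 1e-9

    def test_split_at_boundary_rejected(self):
        part = self._single_pool(np.ones(10), 0.9)
        part = add_spike_split(part, 5, np.ones(10), 0.9)
        with pytest.raises(ValueError):
            add_spike_split(part, 5, np.ones(10), 0.9)


class TestL0:
    def test_single_spike_recovered(self):
        g = 0.9
        y = np.convolve(np.eye(1, 80, 30).ravel(), g ** np.arange(80))[:80]
        c, s, smin, _ = l0_deconvolve(y, g, sigma=1e-3, s_l1=y * 0 + (np.arange(80) == 30))
        assert np.flatnonzero(s > 1e-6).tolist() == [30]

    def test_rss_descends_and_meets_constraint(self, ar1_traces):
        tr = ar1_traces[0]
        sigma = estimate_noise_psd(tr.y, frame_rate=30.0)
        from spikedeconv.tuning import tune_constrained
        st = tune_constrained(tr.y, gamma=0.95, sigma=sigma)
        c, s, smin, part = l0_deconvolve(tr.y, 0.95, sigma, s_l1=st.s)
        rss = np.sum((c - tr.y) ** 2)
        assert rss <= sigma ** 2 * tr.spec.T * (1 + 1e-9)
        # far sparser than the l1 solution
        assert (s > 0).sum() < (st.s > 0).sum()


class TestOnline:
    def test_unlimited_lag_equals_batch(self, ar1_traces):
        y = ar1_traces[0].y[:500]
        for lam, smin in [(2.0, 0.0), (0.0, 0.5)]:
            cb, sb, _ = oasis_ar1(y, 0.95, lam=lam, s_min=smin)
            co, so = oasis_ar1_limited_lag(y, 0.95, lam=lam, s_min=smin,
                                           lag=600)
            assert np.allclose(cb, co, atol=1e-10)
            assert np.allclose(sb, so, atol=1e-10)

    def test_committed_outputs_immutable(self, ar1_traces):
        y = ar1_traces[0].y[:300]
        est = OnlineOasisAR1(g=0.95, lam=1.0, lag=5)
        snapshots = []
        for t, y_t in enumerate(y):
            est.update(y_t)
            if t == 150:
                snapshots = (list(est.c), list(est.s))
        assert est.c[:len(snapshots[0])] == snapshots[0]
        assert est.s[:len(snapshots[1])] == snapshots[1]

    def test_smin_schedule_endpoints(self):
        assert np.isclose(smin_lag_schedule(0), 0.675)
        assert np.isclose(smin_lag_schedule(50), 0.5)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            OnlineOasisAR1(g=0.9, lag=-1)

    def test_merge_counts_logged(self, ar1_traces):
        est = OnlineOasisAR1(g=0.95, lam=1.0, lag=2)
        for y_t in ar1_traces[0].y[:500]:
            est.update(y_t)
        assert len(est.merge_counts) == 500
        assert max(est.merge_counts) <= 10
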