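"""Noise-constrained hyperparameter tuning (lambda, baseline, gamma,
decimation)."""

import numpy as np
import pytest

from oracles import qp_oracle_constrained
from spikedeconv.ar1 import construct_solution, oasis_ar1
from spikedeconv.core import estimate_ar_autocov, estimate_noise_psd
from spikedeconv.synthetic import (ar1_benchmark_spec, simulate_batch,
                                   simulate_trace, sinusoidal_spec)
from spikedeconv.tuning import (apply_dlambda, apply_dphi, decimate_rescale,
                                inverse_rescale, solve_dlambda, solve_dphi,
                                tune_constrained, warm_pools_from_decimated)


class TestAnalyticSteps:
    def test_dlambda_zero_when_constraint_tight(self, ar1_traces):
        y = ar1_traces[0].y
        sigma = estimate_noise_psd(y, frame_rate=30.0)
        st = tune_constrained(y, gamma=0.95, sigma=sigma)
        dlam = solve_dlambda(st.partition, y, sigma=sigma)
        assert abs(dlam) < 1e-3 * max(1.0, st.lam)

    @staticmethod
    def _predicted_c(part, clipped_before):
        # the step's own prediction: pools clipped before the step stay at
        # zero; the rest move linearly (the fixed-clipping-pattern premise
        # of the quadratic)
        g = part.gamma
        c = np.empty(part.T)
        for v, t0, li, was_clipped in zip(part.v, part.t, part.l,
                                          clipped_before):
            c[t0:t0 + li] = 0.0 if was_clipped else v * g ** np.arange(li)
        return c

    def test_dlambda_plugback_exact(self, ar1_traces):
        # after the analytic shift, with the clipping pattern held fixed,
        # the RSS equals sigma^2 T to high precision -- validates the
        # quadratic algebra independent of the approximation
        for tr in ar1_traces[:3]:
            y = tr.y
            sigma = 0.3
            _, _, part = oasis_ar1(y, 0.95, lam=1.0)
            clipped = [v <= 0 for v in part.v]
            dlam = solve_dlambda(part, y, sigma=sigma)
            apply_dlambda(part, dlam)
            c = self._predicted_c(part, clipped)
            rss = np.sum((c - y) ** 2)
            target = sigma ** 2 * y.size
            assert abs(rss - target) / target < 1e-8

    def test_dphi_plugback_exact(self, ar1_traces):
        # same plug-back check for the joint shift/baseline step: shifting
        # the pools and recomputing b = <y - c> lands exactly on sigma^2 T
        for tr in ar1_traces[:3]:
            y = tr.y + 2.0
            sigma = 0.3
            _, _, part = oasis_ar1(y - np.percentile(y, 15), 0.95)
            clipped = [v <= 0 for v in part.v]
            dphi, _ = solve_dphi(part, y, sigma=sigma)
            apply_dphi(part, dphi)
            c = self._predicted_c(part, clipped)
            b_new = np.mean(y - c)
            rss = np.sum((b_new + c - y) ** 2)
            target = sigma ** 2 * y.size
            assert abs(rss - target) / target < 1e-8


class TestTuneConstrained:
    def test_noise_constraint_tight_on_benchmark(self, ar1_traces):
        for tr in ar1_traces:
            sigma = estimate_noise_psd(tr.y, frame_rate=30.0)
            st = tune_constrained(tr.y, gamma=0.95, sigma=sigma)
            assert st.converged
            assert abs(st.rss - sigma ** 2 * tr.spec.T) < \
                1e-4 * sigma ** 2 * tr.spec.T

    def test_lambda_monotone_nondecreasing(self, ar1_traces):
        st = tune_constrained(ar1_traces[0].y, gamma=0.95, sigma=0.3)
        assert np.all(np.diff(st.lam_history) >= -1e-12)

    def test_converged_partition_needs_no_merges(self, ar1_traces):
        st = tune_constrained(ar1_traces[0].y, gamma=0.95, sigma=0.3)
        assert st.merge_history[-1] == 0

    def test_matches_constrained_oracle(self, short_ar1_trace):
        tr = short_ar1_trace
        st = tune_constrained(tr.y, gamma=0.95, sigma=0.3)
        orac = qp_oracle_constrained(tr.y, (0.95,), 0.3)
        assert orac.status == "optimal"
        ours = st.s.sum()
        assert abs(ours - orac.objective) <= 1e-3 * max(1.0, orac.objective)
        assert abs(st.lam - orac.lam_dual) / orac.lam_dual < 0.05

    def test_pure_noise_yields_nearly_empty_spikes(self):
        y = np.random.default_rng(11).normal(0, 0.3, 2000)
        st = tune_constrained(y, gamma=0.95, sigma=0.3)
        assert (st.s > 1e-6).sum() <= 10

    def test_baseline_recovery(self):
        rng = np.random.default_rng(5)
        b_true = 4.2
        tr = simulate_trace(ar1_benchmark_spec(b=b_true), rng)
        st = tune_constrained(tr.y, gamma=0.95, sigma=0.3, optimize_b=True)
        assert abs(st.b - b_true) < 5 * 0.3 / np.sqrt(tr.spec.T) + 0.05

    def test_known_b_equals_shifted_lambda_only(self, ar1_traces):
        y = ar1_traces[0].y + 3.0
        st_b = tune_constrained(y, gamma=0.95, sigma=0.3, b=3.0)
        st_0 = tune_constrained(y - 3.0, gamma=0.95, sigma=0.3)
        assert np.allclose(st_b.s, st_0.s, atol=1e-10)

    def test_gamma_recovered_from_conservative_init(self):
        tr = simulate_trace(sinusoidal_spec(b=0.0), 21)
        st = tune_constrained(tr.y, gamma=0.90, sigma=0.3, optimize_g=True,
                              max_iter=30)
        assert abs(st.g - 0.95) < 0.02

    def test_full_optimization_beats_autocov_gamma(self):
        # median |gamma_hat - 0.95| with optimization below the
        # autocovariance initializer's error on correlated spiking
        err_opt, err_auto = [], []
        for tr in simulate_batch(sinusoidal_spec(), 8, seed=77):
            g0 = float(estimate_ar_autocov(tr.y, p=1)[0])
            err_auto.append(abs(g0 - 0.95))
            st = tune_constrained(tr.y, gamma=g0, sigma=None,
                                  optimize_b=True, optimize_g=True,
                                  max_iter=30)
            err_opt.append(abs(st.g - 0.95))
        assert np.median(err_opt) < np.median(err_auto)


class TestDecimation:
    def test_identity_at_k1(self):
        y = np.arange(12.0)
        yd, sc = decimate_rescale(y, 1, gamma=0.9, sigma=0.3, lam=2.0)
        assert np.allclose(yd, y)
        assert sc["gamma"] == 0.9 and sc["sigma"] == 0.3 and sc["lam"] == 2.0
        inv = inverse_rescale(0.9, 2.0, 1)
        assert inv == {"gamma": 0.9, "lam": 2.0}

    def test_forward_rules(self):
        y = np.arange(25.0)
        yd, sc = decimate_rescale(y, 10, gamma=0.95, sigma=0.3)
        assert yd.size == 2  # incomplete tail dropped
        assert np.isclose(yd[0], np.mean(y[:10]))
        assert np.isclose(sc["gamma"], 0.95 ** 10)
        assert np.isclose(sc["sigma"], 0.3 / np.sqrt(10))

    def test_mu_invariance_roundtrip(self):
        g_dec, lam_dec = 0.95 ** 10, 7.3
        inv = inverse_rescale(g_dec, lam_dec, 10)
        assert np.isclose(inv["gamma"], 0.95)
        assert np.isclose(inv["lam"] * (1 - inv["gamma"]),
                          lam_dec * (1 - g_dec), rtol=1e-12)

    def test_k_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            decimate_rescale(np.arange(5.0), 6)

    def test_warm_pool_structure(self):
        starts, lengths = warm_pools_from_decimated([5], k=10, T=200)
        assert sum(lengths) == 200
        assert np.all(np.diff(starts) > 0)
        # frames around the upsampled spike time (50) are singletons
        singles = {s for s, l in zip(starts, lengths) if l == 1}
        assert {45, 50, 60}.issubset(singles)

    def test_warm_started_solution_close_to_cold(self, ar1_traces):
        tr = ar1_traces[0]
        from spikedeconv.pipeline import tune_decimated
        st_cold = tune_constrained(tr.y, gamma=0.95, sigma=0.3)
        st_warm = tune_decimated(tr.y, gamma0=0.95, sigma=0.3, k=10)
        from spikedeconv.synthetic import spike_correlation
        assert spike_correlation(st_cold.s, st_warm.s) > 0.95
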