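"""Benchmark protocols: simulation + deconvolution recipes.

Each runner simulates a batch of traces under the standard benchmark
conditions and runs one or more deconvolution variants.  The AR
coefficients and noise level of the benchmark conditions are passed to the
solvers as known inputs (they are stated parameters of the protocol); the
hyperparameter-optimization scenario instead estimates everything from the
data (autocovariance, high-frequency power spectrum, percentile baseline).
Runners return per-trace spike-train correlations keyed by variant name.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .ar1 import l0_deconvolve, oasis_ar1, oasis_ar1_limited_lag
from .arp import (construct_solution_arp, jitter_correction,
                  oasis_arp_greedy, oasis_arp_noise_constrained)
from .core import estimate_noise_psd, kernel_from_ar
from .onnls import onnls, onnls_noise_constrained
from .synthetic import (AR1_GAMMA, AR2_GAMMA, ar1_benchmark_spec,
                        ar2_benchmark_spec, simulate_batch, sinusoidal_spec,
                        smoothed_spike_correlation, spike_correlation)
from .tuning import tune_constrained

__all__ = [
    "run_ar1_benchmark",
    "run_ar2_benchmark",
    "run_sinusoidal_table1",
    "run_lag_sweep",
    "run_merge_stats",
    "run_long_trace",
]


def run_ar1_benchmark(seed: int = 0, n_traces: int = 20, T: int = 3000):
    """l1 noise-constrained vs hard-threshold (s_min = 0.5) vs l0 variants
    on the AR(1) benchmark."""
    g = AR1_GAMMA
    out = {"l1_constrained": [], "smin_0.5": [], "l0_constrained": []}
    for tr in simulate_batch(ar1_benchmark_spec(T=T), n_traces, seed):
        sigma = tr.spec.sigma  # a stated benchmark condition
        st = tune_constrained(tr.y, gamma=g, sigma=sigma)
        out["l1_constrained"].append(spike_correlation(st.s, tr.s))
        _, s_hard, _ = oasis_ar1(tr.y, g, s_min=0.5)
        out["smin_0.5"].append(spike_correlation(s_hard, tr.s))
        _, s_l0, _, _ = l0_deconvolve(tr.y, g, sigma, s_l1=st.s)
        out["l0_constrained"].append(spike_correlation(s_l0, tr.s))
    return out


def _restriction_mask(spike_frames, T: int, radius: int = 1) -> np.ndarray:
    mask = np.zeros(T, dtype=bool)
    for f in spike_frames:
        mask[max(0, f - radius):min(T, f + radius + 1)] = True
    return mask


def run_ar2_benchmark(seed: int = 0, n_traces: int = 20, T: int = 3000,
                      window: int = 200, shift: int = 100):
    """Exact convex vs greedy thresholded (+-jitter, +-restricted NNLS)
    variants on the AR(2) benchmark, plus Gaussian-smoothed correlations."""
    g = AR2_GAMMA
    h = kernel_from_ar(g, length=window).taps
    out = {k: [] for k in
           ["convex", "greedy_thresh", "greedy_thresh_jitter",
            "restricted_nnls", "smoothed_greedy_thresh",
            "smoothed_restricted_nnls"]}
    for tr in simulate_batch(ar2_benchmark_spec(T=T), n_traces, seed):
        sigma = tr.spec.sigma  # a stated benchmark condition
        # exact convex: greedy dual seeds the primal noise-constrained solve
        _, s_seed, _, lam_seed = oasis_arp_noise_constrained(tr.y, g, sigma)
        s_cvx, _ = onnls_noise_constrained(tr.y, h, sigma, lam0=lam_seed,
                                           s0=s_seed, window=window,
                                           shift=shift)
        out["convex"].append(spike_correlation(s_cvx, tr.s))
        # greedy hard threshold
        _, s_hard, part = oasis_arp_greedy(tr.y, g, s_min=0.5)
        out["greedy_thresh"].append(spike_correlation(s_hard, tr.s))
        out["smoothed_greedy_thresh"].append(
            smoothed_spike_correlation(s_hard, tr.s))
        # local jitter correction of the spike times
        part, spikes = jitter_correction(part, tr.y)
        _, s_jit = construct_solution_arp(part)
        out["greedy_thresh_jitter"].append(spike_correlation(s_jit, tr.s))
        # NNLS restricted to the proximity of the thresholded spikes
        mask = _restriction_mask(spikes, tr.spec.T)
        mask[0] = True
        s_restr = onnls(tr.y, h, lam=0.0, window=window, shift=shift,
                        support_mask=mask, s0=s_jit * mask)
        out["restricted_nnls"].append(spike_correlation(s_restr, tr.s))
        out["smoothed_restricted_nnls"].append(
            smoothed_spike_correlation(s_restr, tr.s))
    return out


def run_sinusoidal_table1(seed: int = 0, n_traces: int = 20, T: int = 3000):
    """Hyperparameter-optimization variants on sinusoidal-rate AR(1) traces
    with a positive baseline (which of lam, b, gamma are optimized, and the
    pool-restricted / decimated accelerations of the gamma step)."""
    from .core import estimate_ar_autocov, init_phi_percentile
    from .pipeline import tune_decimated

    out = {k: [] for k in
           ["none", "lam", "lam_b", "lam_b_gamma", "lam_b_gamma_5pools",
            "lam_b_gamma_decimate", "lam_b_gamma_decimate_5pools"]}
    for tr in simulate_batch(sinusoidal_spec(T=T), n_traces, seed):
        y = tr.y
        fr = tr.spec.frame_rate
        sigma = estimate_noise_psd(y, frame_rate=fr)
        g0 = float(estimate_ar_autocov(y, p=1)[0])
        b0 = init_phi_percentile(y, 15.0)
        # no optimization: estimate everything once, lam = 0
        _, s_plain, _ = oasis_ar1(y - b0, g0)
        out["none"].append(spike_correlation(s_plain, tr.s))
        st = tune_constrained(y, gamma=g0, sigma=sigma, b=b0)
        out["lam"].append(spike_correlation(st.s, tr.s))
        st = tune_constrained(y, gamma=g0, sigma=sigma, optimize_b=True)
        out["lam_b"].append(spike_correlation(st.s, tr.s))
        st = tune_constrained(y, gamma=g0, sigma=sigma, optimize_b=True,
                              optimize_g=True)
        out["lam_b_gamma"].append(spike_correlation(st.s, tr.s))
        st = tune_constrained(y, gamma=g0, sigma=sigma, optimize_b=True,
                              optimize_g=True, n_gamma_pools=5)
        out["lam_b_gamma_5pools"].append(spike_correlation(st.s, tr.s))
        for key, npools in [("lam_b_gamma_decimate", None),
                            ("lam_b_gamma_decimate_5pools", 5)]:
            s_dec = tune_decimated(y, gamma0=g0, sigma=sigma, k=10,
                                   optimize_b=True, optimize_g=True,
                                   n_gamma_pools=npools, frame_rate=fr)
            out[key].append(spike_correlation(s_dec.s, tr.s))
    return out


def _lag_estimator_rss(y, g, lam, lag):
    c, _ = oasis_ar1_limited_lag(y, g, lam=lam, lag=lag)
    r = c - y
    return float(r @ r)


def tune_lambda_limited_lag(y, g, sigma: float, lag: int,
                            xtol: float = 1e-3):
    """Choose lam so the committed limited-lag estimate meets the noise
    constraint ||c - y||^2 = sigma^2 T (bisection; smaller lags admit fewer
    dynamics constraints and need larger lam)."""
    y = np.asarray(y, dtype=float)
    target = sigma * sigma * y.size
    f = lambda lam: _lag_estimator_rss(y, g, lam, lag) - target
    if f(0.0) >= 0:
        return 0.0
    hi = 1.0
    while f(hi) < 0 and hi < 1e6:
        hi *= 4
    return float(brentq(f, 0.0, hi, xtol=xtol))


def run_lag_sweep(seed: int = 0, n_traces: int = 20, T: int = 3000,
                  lags=(0, 1, 2, 3, 5, 10)):
    """Correlation of the limited-lag online estimator vs lag.

    Two estimator variants, mirroring the batch modes: the l1 variant tunes
    lam per lag so the noise constraint on the committed estimate is tight
    (smaller lags admit fewer constraints and get larger lam); the
    hard-threshold variant uses the lag-dependent minimum spike size
    ``s_min = 0.5 + 0.175 exp(-lag)``, approaching the batch value 0.5.
    'unlimited' entries are the corresponding offline solutions.
    """
    from .ar1 import oasis_ar1, smin_lag_schedule

    g = AR1_GAMMA
    out = {}
    for prefix in ("l1", "smin"):
        for lag in lags:
            out[f"{prefix}_lag_{lag}"] = []
        out[f"{prefix}_unlimited"] = []
    for tr in simulate_batch(ar1_benchmark_spec(T=T), n_traces, seed):
        sigma = tr.spec.sigma
        st = tune_constrained(tr.y, gamma=g, sigma=sigma)
        out["l1_unlimited"].append(spike_correlation(st.s, tr.s))
        _, s_b, _ = oasis_ar1(tr.y, g, s_min=0.5)
        out["smin_unlimited"].append(spike_correlation(s_b, tr.s))
        for lag in lags:
            lam = tune_lambda_limited_lag(tr.y, g, sigma, lag)
            _, s_lag = oasis_ar1_limited_lag(tr.y, g, lam=lam, lag=lag)
            out[f"l1_lag_{lag}"].append(
                spike_correlation(s_lag, tr.s) if s_lag.std() > 0 else 0.0)
            _, s_h = oasis_ar1_limited_lag(tr.y, g,
                                           s_min=smin_lag_schedule(lag),
                                           lag=lag)
            out[f"smin_lag_{lag}"].append(
                spike_correlation(s_h, tr.s) if s_h.std() > 0 else 0.0)
    return out


def run_merge_stats(seed: int = 0, n_traces: int = 5, T: int = 3000,
                    gammas=(0.9, 0.95, 0.98, 0.99),
                    lams=(0.0, 0.5, 1.0, 2.5, 5.0)):
    """Distribution of pool merges per observation timestep across a wide
    hyperparameter range on AR(1) fixtures.  Returns a dict with the merge
    histogram and summary fractions."""
    counts = {}
    for tr in simulate_batch(ar1_benchmark_spec(T=T), n_traces, seed):
        for g in gammas:
            for lam in lams:
                *_, merges = oasis_ar1(tr.y, g, lam=lam, count_merges=True)
                for m in merges:
                    counts[m] = counts.get(m, 0) + 1
    total = sum(counts.values())
    frac01 = (counts.get(0, 0) + counts.get(1, 0)) / total
    frac4plus = sum(v for k, v in counts.items() if k >= 4) / total
    return {"histogram": counts, "frac_0_or_1": frac01,
            "frac_4_or_more": frac4plus, "max_merges": max(counts),
            "n_steps": total}


def run_long_trace(seed: int = 0, n_traces: int = 5, T: int = 300_000):
    """Noise-constrained l1 deconvolution with lam tuned on the full trace,
    at recording lengths where linear scaling matters."""
    g = AR1_GAMMA
    corrs = []
    for tr in simulate_batch(ar1_benchmark_spec(T=T), n_traces, seed):
        sigma = tr.spec.sigma
        st = tune_constrained(tr.y, gamma=g, sigma=sigma)
        corrs.append(spike_correlation(st.s, tr.s))
    return {"l1_constrained_full": corrs}
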