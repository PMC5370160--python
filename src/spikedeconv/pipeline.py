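"""End-to-end deconvolution pipeline with hyperparameter self-tuning.

The full procedure for a raw trace is:

1. initialize the AR coefficients from the autocovariance, the noise level
   from the high-frequency power spectrum, the baseline from a low
   percentile of the data, and lam = 0;
2. optionally decimate a batch of the data (AR(1) only) and run the
   noise-constrained hyperparameter loop there, then rescale the tuned
   hyperparameters back to the native frame rate exactly;
3. solve on the full data with the dual active-set method, warm-started
   from the decimated solution's pool structure;
4. for the l0 (hard shrinkage) mode, add spikes at the largest values of
   the l1 solution until the noise constraint is met;
5. for AR order p > 1, refine the greedy dual solution with warm-started
   windowed NNLS, which yields the exact primal solution.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ar1 import PoolPartition, construct_solution, l0_deconvolve, oasis_ar1, \
    warm_sweep
from .arp import oasis_arp_greedy, oasis_arp_noise_constrained
from .core import (FluorescenceTrace, ModelParams, estimate_ar_autocov,
                   estimate_noise_psd, init_phi_percentile, kernel_from_ar)
from .onnls import onnls_noise_constrained
from .tuning import (TuningState, decimate_rescale, inverse_rescale,
                     tune_constrained, warm_pools_from_decimated)

__all__ = ["PipelineConfig", "DeconvResult", "deconvolve", "batch_deconvolve",
           "tune_decimated"]

BATCH_FRAMES = 10_000  # hyperparameters are tuned on at most this many frames


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline (all stages)."""

    p: int = 1                     # AR order
    sparsity: str = "l1"           # "l1" (soft) or "l0" (hard shrinkage)
    optimize: tuple = ("lam",)     # subset of {"lam", "b", "gamma"}
    decimate: int = 1              # decimation factor for tuning (p=1 only)
    gamma_pools: int = None        # pool restriction for the gamma step
    lag: int = None                # online lag; None = batch
    window: int = 200              # ONNLS window (p > 1)
    shift: int = 100               # ONNLS window step
    gamma: tuple = None            # known AR coefficients (skip estimation)
    sigma: float = None            # known noise level
    b: float = None                # known baseline
    lam: float = None              # fixed sparsity weight (skips tuning)
    s_min: float = None            # explicit hard threshold (skips l0 search)
    kernel: object = None          # explicit response kernel taps (ONNLS)
    restrict_support: bool = False  # rerun NNLS near the thresholded spikes
    seed: int = 0

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("AR order must be >= 1")
        if self.sparsity not in ("l1", "l0"):
            raise ValueError("sparsity must be 'l1' or 'l0'")
        if self.decimate < 1:
            raise ValueError("decimation factor must be >= 1")
        unknown = set(self.optimize) - {"lam", "b", "gamma"}
        if unknown:
            raise ValueError(f"unknown optimize flags {unknown}")


@dataclass
class DeconvResult:
    """Denoised calcium, deconvolved activity, final parameters and
    per-stage diagnostics for one trace."""

    c: np.ndarray
    s: np.ndarray
    params: ModelParams
    partition: object
    diagnostics: dict = field(default_factory=dict)


def tune_decimated(y, gamma0: float, sigma: float, k: int = 10,
                   optimize_b: bool = False, optimize_g: bool = False,
                   b: float = 0.0, n_gamma_pools=None,
                   frame_rate: float = 30.0) -> TuningState:
    """Tune hyperparameters on k-fold decimated data, rescale them back,
    and solve the full trace warm-started from the decimated spikes."""
    y = np.asarray(y, dtype=float)
    yd, sc = decimate_rescale(y, k, gamma=gamma0, sigma=sigma,
                              frame_rate=frame_rate)
    st = tune_constrained(yd, gamma=sc.get("gamma", gamma0),
                          sigma=sc["sigma"], optimize_b=optimize_b,
                          optimize_g=optimize_g, b=b,
                          n_gamma_pools=n_gamma_pools,
                          frame_rate=frame_rate / k)
    inv = inverse_rescale(st.g, st.lam, k)
    g_full, lam_full = inv["gamma"], inv["lam"]
    spikes_dec = np.flatnonzero(st.s > 0)
    structure = warm_pools_from_decimated(spikes_dec, k, y.size)
    return tune_constrained(y, gamma=g_full, sigma=sigma,
                            optimize_b=optimize_b, b=st.b,
                            warm_structure=structure, frame_rate=frame_rate)


def _as_trace(trace, frame_rate):
    if isinstance(trace, FluorescenceTrace):
        return trace
    return FluorescenceTrace(np.asarray(trace, dtype=float), frame_rate)


def deconvolve(trace, config: PipelineConfig = None,
               frame_rate: float = 30.0) -> DeconvResult:
    """Full deconvolution of one fluorescence trace."""
    cfg = config or PipelineConfig()
    tr = _as_trace(trace, frame_rate)
    y = tr.values
    T = tr.T
    t_start = time.perf_counter()
    diags = {}

    # --- arbitrary-kernel path: straight to the primal solver ---------------
    if cfg.kernel is not None:
        h = np.asarray(cfg.kernel, dtype=float)
        sigma = cfg.sigma if cfg.sigma is not None else \
            estimate_noise_psd(y, frame_rate=tr.frame_rate)
        b0 = cfg.b if cfg.b is not None else init_phi_percentile(y, 15.0)
        from .onnls import onnls
        if cfg.lam is not None:
            s = onnls(y - b0, h, lam=cfg.lam, window=cfg.window,
                      shift=cfg.shift)
            lam = cfg.lam
        else:
            s, lam = onnls_noise_constrained(y - b0, h, sigma,
                                             window=cfg.window,
                                             shift=cfg.shift)
        c = np.convolve(s, h)[:T]
        params = ModelParams(gamma=(0.0,), sigma=sigma, b=b0, lam=lam)
        diags["runtime_s"] = time.perf_counter() - t_start
        return DeconvResult(c=c, s=s, params=params, partition=None,
                            diagnostics=diags)

    # --- initialization -----------------------------------------------------
    gamma = (np.atleast_1d(np.asarray(cfg.gamma, dtype=float))
             if cfg.gamma is not None else estimate_ar_autocov(y, p=cfg.p))
    sigma = cfg.sigma if cfg.sigma is not None else \
        estimate_noise_psd(y, frame_rate=tr.frame_rate)
    optimize_b = "b" in cfg.optimize and cfg.b is None
    optimize_g = "gamma" in cfg.optimize
    b0 = cfg.b if cfg.b is not None else \
        (init_phi_percentile(y, 15.0) if not optimize_b else 0.0)
    diags["init"] = {"gamma": tuple(gamma), "sigma": sigma}

    batch = y[:min(T, BATCH_FRAMES)]

    if cfg.p == 1:
        g = float(gamma[0])
        if cfg.lam is not None:
            lam, b_hat = cfg.lam, b0
        elif "lam" in cfg.optimize:
            if cfg.decimate > 1:
                st = tune_decimated(batch, gamma0=g, sigma=sigma,
                                    k=cfg.decimate, optimize_b=optimize_b,
                                    optimize_g=optimize_g, b=b0,
                                    n_gamma_pools=cfg.gamma_pools,
                                    frame_rate=tr.frame_rate)
            else:
                st = tune_constrained(batch, gamma=g, sigma=sigma,
                                      optimize_b=optimize_b,
                                      optimize_g=optimize_g, b=b0,
                                      n_gamma_pools=cfg.gamma_pools,
                                      frame_rate=tr.frame_rate)
            g, lam, b_hat = st.g, st.lam, st.b if optimize_b else b0
            diags["tuning"] = {"lam": lam, "gamma": g, "b": b_hat,
                               "iterations": st.n_iter,
                               "converged": st.converged}
        else:
            lam, b_hat = 0.0, b0

        if cfg.sparsity == "l0":
            if cfg.s_min is not None:
                c, s, part = oasis_ar1(y - b_hat, g, s_min=cfg.s_min)
                params = ModelParams(gamma=(g,), sigma=sigma, b=b_hat,
                                     s_min=cfg.s_min)
            else:
                s_l1 = None
                if T == batch.size and "lam" in cfg.optimize \
                        and cfg.decimate == 1 and cfg.lam is None:
                    s_l1 = st.s
                c, s, s_min_hat, part = l0_deconvolve(y - b_hat, g, sigma,
                                                      s_l1=s_l1)
                params = ModelParams(gamma=(g,), sigma=sigma, b=b_hat,
                                     s_min=s_min_hat)
        elif cfg.lag is not None:
            from .ar1 import oasis_ar1_limited_lag
            c, s = oasis_ar1_limited_lag(y - b_hat, g, lam=lam, lag=cfg.lag)
            part = None
            params = ModelParams(gamma=(g,), sigma=sigma, b=b_hat, lam=lam)
        elif T == batch.size and "lam" in cfg.optimize \
                and cfg.decimate == 1 and cfg.lam is None:
            c, s, part = st.c, st.s, st.partition
            params = ModelParams(gamma=(g,), sigma=sigma, b=b_hat, lam=lam)
        else:
            c, s, part = oasis_ar1(y - b_hat, g, lam=lam)
            params = ModelParams(gamma=(g,), sigma=sigma, b=b_hat, lam=lam)
    else:
        # AR(p > 1): greedy dual solve, then exact primal refinement
        gv = tuple(gamma)
        yb = y - b0
        if cfg.sparsity == "l0" or cfg.s_min is not None:
            s_min = cfg.s_min if cfg.s_min is not None else 0.5
            c, s, part = oasis_arp_greedy(yb, gv, s_min=s_min)
            from .arp import jitter_correction, construct_solution_arp
            part, spikes = jitter_correction(part, yb)
            c, s = construct_solution_arp(part)
            if cfg.restrict_support:
                # exact NNLS rerun allowed only near the thresholded spikes
                from .onnls import onnls
                from .protocols import _restriction_mask
                h = kernel_from_ar(gv, length=cfg.window).taps
                mask = _restriction_mask(spikes, T)
                mask[0] = True
                s = onnls(yb, h, window=cfg.window, shift=cfg.shift,
                          support_mask=mask, s0=s * mask)
                c = np.convolve(s, h)[:T]
            params = ModelParams(gamma=gv, sigma=sigma, b=b0, s_min=s_min)
        else:
            cg, sg, part, lam = oasis_arp_noise_constrained(yb, gv, sigma)
            h = kernel_from_ar(gv, length=cfg.window).taps
            s, lam = onnls_noise_constrained(yb, h, sigma, lam0=lam, s0=sg,
                                            window=cfg.window,
                                            shift=cfg.shift)
            c = np.convolve(s, h)[:T]
            params = ModelParams(gamma=gv, sigma=sigma, b=b0, lam=lam)
            diags["tuning"] = {"lam": lam}

    diags["runtime_s"] = time.perf_counter() - t_start
    return DeconvResult(c=c, s=s, params=params, partition=part,
                        diagnostics=diags)


def batch_deconvolve(traces, config: PipelineConfig = None,
                     frame_rate: float = 30.0) -> list:
    """Independent deconvolution of many traces; per-trace failures are
    isolated and reported in the result list as DeconvResult with an
    'error' diagnostic."""
    results = []
    for i, tr in enumerate(traces):
        try:
            results.append(deconvolve(tr, config, frame_rate))
        except Exception as exc:  # noqa: BLE001 - isolate per-trace failures
            warnings.warn(f"trace {i}: {exc}")
            results.append(DeconvResult(
                c=None, s=None, params=None, partition=None,
                diagnostics={"error": str(exc), "index": i}))
    return results
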