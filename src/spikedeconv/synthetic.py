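"""Synthetic fluorescence traces reproducing the benchmark protocols.

Spike trains are Poisson (homogeneous, or inhomogeneous with a sinusoidal
instantaneous rate), filtered by stable AR(1)/AR(2) dynamics, plus i.i.d.
Gaussian noise and an optional constant baseline.  The default benchmark
conditions are 100 s at 30 Hz (T = 3000 frames) with

* AR(1): gamma = 0.95, sigma = 0.3
* AR(2): gamma = (1.7, -0.712), sigma = 1

The mean firing rate defaults to 0.5 Hz, a typical cortical value in this
literature and consistent with the spike density of the benchmark figures;
the sinusoidal protocol uses mean 0.5 Hz, amplitude 0.45 Hz, period 25 s
and baseline b = 1 by default.

Spike-train similarity is quantified by the Pearson correlation between the
deconvolved activity and the true (binned) spike train, optionally after
convolving both with a Gaussian of one bin width, which forgives +-1 frame
timing errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .core import is_stable

__all__ = [
    "SimulationSpec",
    "SimTrace",
    "simulate_trace",
    "simulate_batch",
    "ar1_benchmark_spec",
    "ar2_benchmark_spec",
    "sinusoidal_spec",
    "spike_correlation",
    "smoothed_spike_correlation",
    "benchmark_suite",
]

AR1_GAMMA = 0.95
AR1_SIGMA = 0.3
AR2_GAMMA = (1.7, -0.712)
AR2_SIGMA = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated fluorescence trace."""

    T: int = 3000
    frame_rate: float = 30.0
    rate: float = 0.5                 # mean firing rate, Hz
    rate_profile: str = "homogeneous"  # or "sinusoidal"
    rate_amplitude: float = 0.45      # Hz, sinusoidal only
    rate_period: float = 25.0         # s, sinusoidal only
    gamma: tuple = (AR1_GAMMA,)
    sigma: float = AR1_SIGMA
    b: float = 0.0

    def __post_init__(self):
        if self.T < 1 or self.frame_rate <= 0:
            raise ValueError("need T >= 1 and frame_rate > 0")
        if self.rate < 0 or self.sigma < 0:
            raise ValueError("rate and sigma must be >= 0")
        if self.rate_profile not in ("homogeneous", "sinusoidal"):
            raise ValueError(f"unknown rate profile {self.rate_profile!r}")
        if self.rate_profile == "sinusoidal" and \
                self.rate_amplitude > self.rate:
            raise ValueError("sinusoidal rate would go negative")
        if not is_stable(self.gamma):
            raise ValueError("unstable AR coefficients")


class SimTrace(NamedTuple):
    y: np.ndarray       # observed fluorescence
    c: np.ndarray       # noiseless calcium
    s: np.ndarray       # spike counts per bin
    spec: SimulationSpec


def _rate_per_bin(spec: SimulationSpec) -> np.ndarray:
    dt = 1.0 / spec.frame_rate
    if spec.rate_profile == "homogeneous":
        return np.full(spec.T, spec.rate * dt)
    t = np.arange(spec.T) * dt
    rate = spec.rate + spec.rate_amplitude * np.sin(
        2 * np.pi * t / spec.rate_period)
    return rate * dt


def simulate_trace(spec: SimulationSpec, rng) -> SimTrace:
    """Draw one trace: Poisson spikes -> AR filter -> noise + baseline."""
    rng = np.random.default_rng(rng)
    s = rng.poisson(_rate_per_bin(spec)).astype(float)
    g = np.atleast_1d(np.asarray(spec.gamma, dtype=float))
    c = lfilter([1.0], np.concatenate(([1.0], -g)), s)
    y = c + spec.b + rng.normal(0.0, spec.sigma, spec.T)
    return SimTrace(y, c, s, spec)


def simulate_batch(spec: SimulationSpec, n: int, seed: int) -> list:
    """n independent traces from one spec, seeded reproducibly."""
    ss = np.random.SeedSequence(seed)
    return [simulate_trace(spec, np.random.default_rng(child))
            for child in ss.spawn(n)]


def ar1_benchmark_spec(**overrides) -> SimulationSpec:
    kw = dict(gamma=(AR1_GAMMA,), sigma=AR1_SIGMA)
    kw.update(overrides)
    return SimulationSpec(**kw)


def ar2_benchmark_spec(**overrides) -> SimulationSpec:
    kw = dict(gamma=AR2_GAMMA, sigma=AR2_SIGMA)
    kw.update(overrides)
    return SimulationSpec(**kw)


def sinusoidal_spec(**overrides) -> SimulationSpec:
    kw = dict(rate_profile="sinusoidal", b=1.0, gamma=(AR1_GAMMA,),
              sigma=AR1_SIGMA)
    kw.update(overrides)
    return SimulationSpec(**kw)


# ---------------------------------------------------------------------------
# similarity metrics


def spike_correlation(s_hat, s_true) -> float:
    """Pearson correlation between inferred and true spike trains."""
    a = np.asarray(s_hat, dtype=float)
    b = np.asarray(s_true, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spike trains must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance spike train: correlation undefined "
                         "(empty deconvolution?)")
    return float(np.corrcoef(a, b)[0, 1])


def smoothed_spike_correlation(s_hat, s_true, width: float = 1.0) -> float:
    """Correlation after convolving both trains with a Gaussian of standard
    deviation ``width`` bins (forgiving small timing errors)."""
    if width <= 0:
        raise ValueError("width must be > 0")
    return spike_correlation(gaussian_filter1d(np.asarray(s_hat, float), width),
                             gaussian_filter1d(np.asarray(s_true, float), width))


# ---------------------------------------------------------------------------
# benchmark harness


def _mean_sem(values) -> tuple:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def benchmark_suite(scenario: str, seed: int = 0, n_traces: int = 20,
                    **kwargs) -> pd.DataFrame:
    """Run a named simulation scenario and report mean +- SEM correlations.

    Scenarios
    ---------
    ar1_benchmark : l1 noise-constrained vs hard threshold (s_min = 0.5) vs
        l0 noise-constrained deconvolution on AR(1) traces.
    ar2_benchmark : exact convex (noise-constrained ONNLS), greedy
        thresholded, jitter-corrected, support-restricted NNLS, and
        Gaussian-smoothed variants on AR(2) traces.
    sinusoidal_table1 : hyperparameter-optimization variants (which of
        lam, b, gamma are tuned; pool-restricted and decimated gamma
        estimation) on sinusoidal-rate AR(1) traces with baseline.
    lag_sweep : limited-lag online estimation as a function of lag.
    """
    from . import protocols

    runners = {
        "ar1_benchmark": protocols.run_ar1_benchmark,
        "ar2_benchmark": protocols.run_ar2_benchmark,
        "sinusoidal_table1": protocols.run_sinusoidal_table1,
        "lag_sweep": protocols.run_lag_sweep,
    }
    if scenario not in runners:
        raise ValueError(f"unknown scenario {scenario!r}; choose from "
                         f"{sorted(runners)}")
    per_variant = runners[scenario](seed=seed, n_traces=n_traces, **kwargs)
    rows = []
    for variant, corrs in per_variant.items():
        m, sem = _mean_sem(corrs)
        rows.append({"variant": variant, "correlation": m, "sem": sem,
                     "n": len(corrs)})
    return pd.DataFrame(rows)
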