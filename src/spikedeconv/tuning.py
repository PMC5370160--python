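"""Dual noise-constrained hyperparameter optimization for AR(1) deconvolution.

Rather than hand-picking the sparsity weight lam, the noise-constrained
formulation minimizes ``||s||_1`` subject to ``s = G c >= 0`` and
``||c - y||^2 <= sigma^2 T``, treating lam as the dual variable of the
residual constraint.  The loop starts at lam = 0 and alternates

1. an analytic lam (or total-shift phi, when the baseline b is unknown)
   update that, holding the pool structure fixed, moves the residual sum of
   squares exactly onto ``sigma^2 T`` (solving a quadratic in the step),
2. a warm-started re-run of the active-set solver to re-enforce the decay
   constraints (touching only the z current pools), and
3. optionally a coordinate-descent step in the AR coefficient gamma,
   minimizing the pool-wise RSS polynomial by bounded scalar search (or a
   joint bounded quasi-Newton step in (gamma, b)).

In practice the lam sequence is non-decreasing and the loop converges after
a handful of passes.  Hyperparameters can be estimated on temporally
decimated data and rescaled exactly back to the native frame rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .ar1 import PoolPartition, construct_solution, oasis_ar1, warm_sweep
from .core import estimate_ar_autocov, estimate_noise_psd, init_phi_percentile

__all__ = [
    "TuningState",
    "solve_dlambda",
    "solve_dphi",
    "optimize_gamma",
    "decimate_rescale",
    "inverse_rescale",
    "warm_pools_from_decimated",
    "tune_constrained",
]


@dataclass
class TuningState:
    """Converged (or best-effort) state of the noise-constrained loop."""

    lam: float
    b: float
    g: float
    partition: PoolPartition
    c: np.ndarray
    s: np.ndarray
    rss: float
    sigma: float
    n_iter: int
    converged: bool
    lam_history: list = field(default_factory=list)
    rss_history: list = field(default_factory=list)
    merge_history: list = field(default_factory=list)

    @property
    def phi(self) -> float:
        return self.b + self.lam * (1.0 - self.g)


def _shift_factors(part: PoolPartition) -> np.ndarray:
    """Per-pool dv/dlam = -(1 - gamma^{l_i} (1 - delta_{iz})) / w_i.

    The last pool's factor is 1/w_z because the final frame's shift is lam
    itself rather than lam (1 - gamma).
    """
    g = part.gamma
    f = np.array([(1.0 - g ** li) for li in part.l])
    f[-1] = 1.0
    return f / np.asarray(part.w)


def _residual_blocks(part: PoolPartition, y: np.ndarray):
    """chi_it = y_{t_i+t} - c_{t_i+t}, concatenated over pools.

    Pools clipped at zero (v <= 0) contribute chi = y: their fit is 0 and
    stays 0 when the sparsity weight grows.
    """
    g = part.gamma
    out = np.empty(part.T)
    for v, t0, li in zip(part.v, part.t, part.l):
        out[t0:t0 + li] = y[t0:t0 + li] - max(v, 0.0) * g ** np.arange(li)
    return out


def _xi_lambda(part: PoolPartition) -> np.ndarray:
    """xi_it = (1 - gamma^{l_i}(1-delta_{iz})) / w_i * gamma^t, concatenated.

    Clipped pools (v <= 0) have zero sensitivity: the nonnegativity
    constraint is active there, so their fit does not respond to lam.
    """
    g = part.gamma
    f = _shift_factors(part)
    out = np.empty(part.T)
    for fi, v, t0, li in zip(f, part.v, part.t, part.l):
        out[t0:t0 + li] = (fi * g ** np.arange(li)) if v > 0 else 0.0
    return out


def _quadratic_root(alpha: float, beta: float, eps: float) -> float:
    disc = beta * beta - 4.0 * alpha * eps
    if disc < 0:
        warnings.warn("negative discriminant in the noise-constraint step; "
                      "returning the boundary solution")
        return -beta / (2.0 * alpha)
    return (-beta + np.sqrt(disc)) / (2.0 * alpha)


def solve_dlambda(part: PoolPartition, y, gamma: float = None,
                  sigma: float = None) -> float:
    """Analytic sparsity step: the dlam that makes the predicted RSS equal
    ``sigma^2 T`` under the fixed-pool-structure approximation."""
    y = np.asarray(y, dtype=float)
    if gamma is not None and gamma != part.gamma:
        raise ValueError("partition was solved under a different gamma")
    xi = _xi_lambda(part)
    chi = _residual_blocks(part, y)
    alpha = xi @ xi
    beta = 2.0 * (chi @ xi)
    eps = chi @ chi - sigma * sigma * y.size
    return _quadratic_root(alpha, beta, eps)


def apply_dlambda(part: PoolPartition, dlam: float):
    """Shift every pool value by its analytic sensitivity to lam."""
    f = _shift_factors(part)
    for i in range(part.z):
        part.v[i] -= dlam * f[i]


def solve_dphi(part: PoolPartition, y, gamma: float = None,
               sigma: float = None):
    """Analytic total-shift step for unknown baseline.

    Returns ``(dphi, b_hat)`` where ``b_hat = <y - c>`` is the baseline
    implied by the current fit.  The quadratic accounts for b_hat tracking
    the shift: each unit of dphi lowers the fit by ``xi`` and raises the
    baseline by the mean of the per-pool sensitivities.
    """
    y = np.asarray(y, dtype=float)
    g = part.gamma
    T = part.T
    f = _shift_factors(part) / (1.0 - g)   # dv_i/dphi magnitudes
    # mean change of c over the whole trace per unit dphi; clipped pools
    # (v <= 0) are pinned at zero and do not respond
    dbar = sum(fi * (1.0 - g ** li) / (1.0 - g)
               for fi, v, li in zip(f, part.v, part.l) if v > 0) / T
    xi = np.empty(T)
    for fi, v, t0, li in zip(f, part.v, part.t, part.l):
        xi[t0:t0 + li] = (fi * g ** np.arange(li)) if v > 0 else 0.0
    xi -= dbar
    chi = _residual_blocks(part, y)
    b_hat = chi.mean()
    chi = chi - b_hat
    alpha = xi @ xi
    beta = 2.0 * (chi @ xi)
    eps = chi @ chi - sigma * sigma * T
    return _quadratic_root(alpha, beta, eps), float(b_hat)


def apply_dphi(part: PoolPartition, dphi: float):
    f = _shift_factors(part) / (1.0 - part.gamma)
    for i in range(part.z):
        part.v[i] -= dphi * f[i]


def _pool_order(part: PoolPartition, n_pools):
    """Indices of the pools used for the gamma step: all, or the n_pools
    with largest max(0, v) * l (large isolated calcium events)."""
    if n_pools is None or n_pools >= part.z:
        return list(range(part.z))
    score = np.array([max(0.0, v) * li for v, li in zip(part.v, part.l)])
    return list(np.argsort(-score)[:n_pools])


def optimize_gamma(part: PoolPartition, y, phi: float = 0.0, b_hat: float = 0.0,
                   n_pools=None, joint_b: bool = False):
    """Coordinate-descent step in the AR coefficient.

    Minimizes the residual sum of squares over the current pool structure
    with the pool values held at their current fits, which is an exact
    block-coordinate step of the joint objective in (values, gamma): the
    subsequent warm-started re-solve refits the values and re-merges pools
    under the new coefficient.  (Refitting the values inside the gamma
    search instead couples the step to the current — possibly wrong —
    partition and biases the decay estimate toward the partition's own
    gamma.)  ``b_hat`` is the baseline added back to the prediction; with
    ``joint_b`` the pair (gamma, b) is minimized jointly with L-BFGS-B,
    else gamma alone by bounded scalar search on [0, 1).
    """
    y = np.asarray(y, dtype=float)
    idx = _pool_order(part, n_pools)
    blocks = [(part.t[i], part.l[i], max(0.0, part.v[i])) for i in idx]

    def rss(g, b):
        tot = 0.0
        for t0, li, v in blocks:
            r = b + v * g ** np.arange(li) - y[t0:t0 + li]
            tot += r @ r
        return tot

    lo, hi = 1e-6, 1.0 - 1e-6
    if joint_b:
        res = minimize(lambda x: rss(x[0], x[1]), x0=[part.gamma, b_hat],
                       method="L-BFGS-B", bounds=[(lo, hi), (None, None)])
        g_new, b_new = float(res.x[0]), float(res.x[1])
    else:
        res = minimize_scalar(lambda g: rss(g, b_hat), bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-6})
        g_new, b_new = float(res.x), b_hat
    if g_new >= hi:
        warnings.warn("gamma minimizer at the stability boundary; clamped")
        g_new = hi
    return g_new, b_new


# ---------------------------------------------------------------------------
# decimation


def decimate_rescale(y, k: int, gamma: float = None, sigma: float = None,
                     lam: float = None, frame_rate: float = None):
    """Temporal decimation with exact hyperparameter rescaling.

    Averages blocks of ``k`` frames (an incomplete tail block is dropped),
    divides sigma by sqrt(k), raises gamma to the k-th power and rescales
    lam so the shrinkage ``mu = lam (1 - gamma)`` is invariant.
    Returns ``(y_dec, params)`` with a dict of the rescaled values.
    """
    y = np.asarray(y, dtype=float)
    if k < 1:
        raise ValueError("decimation factor must be >= 1")
    if k > y.size:
        raise ValueError("decimation factor exceeds trace length")
    T = y.size - y.size % k
    yd = y[:T].reshape(-1, k).mean(axis=1)
    params = {}
    if gamma is not None:
        params["gamma"] = gamma ** k
        if lam is not None:
            params["lam"] = (lam * (1.0 - gamma) / (1.0 - gamma ** k)
                             if k > 1 else lam)
    if sigma is not None:
        params["sigma"] = sigma / np.sqrt(k)
    if frame_rate is not None:
        params["frame_rate"] = frame_rate / k
    return yd, params


def inverse_rescale(gamma: float, lam: float, k: int, sigma: float = None):
    """Undo the decimation rescaling: gamma -> gamma^(1/k), lam rescaled so
    that mu = lam (1 - gamma) stays invariant, b unchanged."""
    if k == 1:
        out = {"gamma": gamma, "lam": lam}
    else:
        g_full = gamma ** (1.0 / k)
        out = {"gamma": g_full,
               "lam": lam * (1.0 - gamma) / (1.0 - g_full)}
    if sigma is not None:
        out["sigma"] = sigma * np.sqrt(k)
    return out


def warm_pools_from_decimated(spike_frames_dec, k: int, T: int):
    """Pool-structure warm start for the full-data solve.

    Frames within ``[k (t_i - 1), k (t_i + 1.5)]`` of each upsampled
    decimated spike time become singleton pools (free to hold a spike);
    the remaining stretches are pooled together.  Returns (starts, lengths).
    """
    free = np.zeros(T, dtype=bool)
    for td in np.asarray(spike_frames_dec, dtype=int):
        lo = max(0, k * (td - 1))
        hi = min(T, int(np.ceil(k * (td + 1.5))) + 1)
        free[lo:hi] = True
    starts, lengths = [], []
    t = 0
    while t < T:
        if free[t]:
            starts.append(t); lengths.append(1)
            t += 1
        else:
            t1 = t
            while t1 < T and not free[t1]:
                t1 += 1
            starts.append(t); lengths.append(t1 - t)
            t = t1
    return starts, lengths


# ---------------------------------------------------------------------------
# main loop


def tune_constrained(y, gamma: float = None, sigma: float = None,
                     optimize_b: bool = False, optimize_g: bool = False,
                     b: float = 0.0, frame_rate: float = 30.0,
                     n_gamma_pools=None, max_iter: int = 20,
                     rss_tol: float = 1e-9, s_min: float = 0.0,
                     warm_structure=None) -> TuningState:
    """Noise-constrained AR(1) deconvolution with hyperparameter self-tuning.

    Parameters
    ----------
    y : array
        Fluorescence trace.
    gamma, sigma : float, optional
        AR coefficient and noise level; estimated from the trace
        (autocovariance / high-frequency PSD) when omitted.
    optimize_b : bool
        Treat the baseline as unknown: track the total shift phi
        (initialized at the 15th percentile of y) and recover
        ``b = <y - c>`` at each step.
    optimize_g : bool
        Interleave gamma coordinate-descent steps (jointly with b when
        ``optimize_b``).
    b : float
        Known baseline (ignored when ``optimize_b``).
    n_gamma_pools : int, optional
        Restrict the gamma-step RSS to this many pools (largest value x
        length).
    warm_structure : (starts, lengths), optional
        Initial pool structure (e.g. from a decimated solve) instead of T
        singleton pools.

    Stops when a lam/phi update triggers no merges and the RSS is within
    ``rss_tol`` (relative) of ``sigma^2 T``; hard cap ``max_iter``.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    if gamma is None:
        gamma = float(estimate_ar_autocov(y, p=1)[0])
    g = float(gamma)
    if sigma is None:
        sigma = estimate_noise_psd(y, frame_rate=frame_rate)
    target = sigma * sigma * T

    lam = 0.0
    if optimize_b:
        # start from phi = 15th percentile; with lam = 0 this is all baseline
        phi = init_phi_percentile(y, 15.0)
        b_cur = phi
    else:
        b_cur = b
        phi = b

    def shifted(lam_, b_):
        ym = y - b_ - lam_ * (1.0 - g)
        ym[-1] -= lam_ * g  # final frame shift is lam, not lam(1-gamma)
        return ym

    # initial solve (cold, or warm from a supplied pool structure)
    if warm_structure is not None:
        starts, lengths = warm_structure
        part = PoolPartition([0.0] * len(starts), [1.0] * len(starts),
                             list(starts), list(lengths), g)
        part.recompute_values(shifted(lam, b_cur))
        warm_sweep(part, s_min)
    else:
        _, _, part = oasis_ar1(shifted(lam, b_cur), g, s_min=s_min)

    lam_hist, rss_hist, merge_hist = [lam], [], []
    converged = False
    n_it = 0
    rss = np.inf
    for n_it in range(1, max_iter + 1):
        if optimize_b:
            dstep, _ = solve_dphi(part, y, sigma=sigma)
            apply_dphi(part, dstep)
            phi += dstep
        else:
            dstep = solve_dlambda(part, y - b_cur, sigma=sigma)
            lam = max(0.0, lam + dstep)
            apply_dlambda(part, dstep)
        lam_hist.append(lam)

        nm = warm_sweep(part, s_min)
        merge_hist.append(nm)
        if optimize_b:
            c, _ = construct_solution(part, g)
            b_cur = float(np.mean(y - c))
            lam = max(0.0, (phi - b_cur) / (1.0 - g))

        dg = 0.0
        if optimize_g:
            if optimize_b:
                # joint (gamma, b) only with the full pool set: a handful of
                # restricted segments cannot identify the baseline, so the
                # global <y - c> estimate is kept fixed in that case
                g_new, b_new = optimize_gamma(
                    part, y, phi=phi, b_hat=b_cur, n_pools=n_gamma_pools,
                    joint_b=n_gamma_pools is None)
                b_cur = b_new
                lam = max(0.0, (phi - b_cur) / (1.0 - g_new))
            else:
                g_new, _ = optimize_gamma(part, y - b_cur,
                                          phi=lam * (1.0 - g), b_hat=0.0,
                                          n_pools=n_gamma_pools)
            dg = abs(g_new - g)
            if dg > 1e-12:
                g = g_new
                part.gamma = g
                part.recompute_values(shifted(lam, b_cur))
                nm += warm_sweep(part, s_min)
                if optimize_b:
                    c, _ = construct_solution(part, g)
                    b_cur = float(np.mean(y - c))
                    phi = b_cur + lam * (1.0 - g)

        c, _ = construct_solution(part, g)
        rss = float(np.sum((b_cur + c - y) ** 2))
        rss_hist.append(rss)
        if nm == 0 and dg < 1e-3 and abs(rss - target) <= rss_tol * target:
            converged = True
            break

    if not converged:
        warnings.warn(f"noise-constrained tuning did not converge in "
                      f"{max_iter} iterations (RSS/sigma^2 T = "
                      f"{rss / target:.6f})")
    c, s = construct_solution(part, g)
    rss = float(np.sum((b_cur + c - y) ** 2))
    b_hat = b_cur
    return TuningState(lam=lam, b=b_hat, g=g, partition=part, c=c, s=s,
                       rss=rss, sigma=sigma, n_iter=n_it, converged=converged,
                       lam_history=lam_hist, rss_history=rss_hist,
                       merge_history=merge_hist)
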