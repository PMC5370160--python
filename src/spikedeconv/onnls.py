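"""Online non-negative least squares for arbitrary convolution kernels.

The dual active-set solvers operate on the calcium trace; for kernels that
are not first-order Markov (AR(p > 1), or measured response kernels) an
exact solution is obtained in the spike domain instead:

    min_s 1/2 ||K s - y||^2 + lam ||s||_1   s.t.  s >= 0

where ``K`` is the lower-triangular Toeplitz convolution matrix of the
kernel ``h`` (``K_{t,u} = h_{1+t-u}``, unit diagonal, hence invertible).
The l1 penalty is absorbed by shifting the data down by ``mu = lam K^{-T} 1``,
leaving a plain NNLS problem.  Exploiting locality — a spike barely affects
the fit beyond one transient length — the classic Lawson-Hanson active-set
solver is applied warm-started on sliding windows of length ``window``
(about ten transient lengths), stepped by ``shift`` frames while the
already-fixed activity is peeled off the data, which makes the whole pass
O(T).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import solve_banded

from .core import Kernel

__all__ = ["nnls_warm", "onnls", "onnls_noise_constrained", "penalty_shift"]


def nnls_warm(gram, target, s0=None, allowed=None, tol: float = 1e-9,
              max_iter: int = None):
    """Lawson-Hanson NNLS, warm-started.

    Solves ``min_s 1/2 s^T gram s - target^T s  s.t. s >= 0`` (i.e. NNLS
    with ``gram = K^T K`` and ``target = K^T y`` precomputed).  The passive
    set is initialized from the positive entries of ``s0`` instead of the
    empty set; ``allowed`` optionally restricts the support.
    """
    gram = np.asarray(gram, dtype=float)
    q = np.asarray(target, dtype=float)
    n = q.size
    if max_iter is None:
        max_iter = 3 * n + 30
    s = np.zeros(n)
    P = np.zeros(n, dtype=bool)
    if s0 is not None:
        P[:] = np.asarray(s0) > 0
    if allowed is not None:
        allowed = np.asarray(allowed, dtype=bool)
        P &= allowed

    def solve_P():
        idx = np.flatnonzero(P)
        if idx.size == 0:
            return idx, np.empty(0)
        x = np.linalg.solve(gram[np.ix_(idx, idx)], q[idx])
        return idx, x

    idx, x = solve_P()
    for _ in range(max_iter):
        # inner loop: walk back until the passive solution is feasible
        while idx.size and x.min() <= 0:
            neg = x <= 0
            sP = s[idx]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = sP[neg] / (sP[neg] - x[neg])
            alpha = np.min(ratios)
            s[idx] = sP + alpha * (x - sP)
            P[idx[s[idx] <= tol]] = False
            s[~P] = 0.0
            idx, x = solve_P()
        s[:] = 0.0
        s[idx] = x
        w = q - gram @ s
        cand = ~P if allowed is None else (~P & allowed)
        if not np.any(cand) or np.max(w[cand]) <= tol:
            return s
        j = np.flatnonzero(cand)[np.argmax(w[cand])]
        P[j] = True
        idx, x = solve_P()
    warnings.warn("NNLS reached the iteration safeguard")
    return s


def penalty_shift(h: np.ndarray, lam: float, T: int) -> np.ndarray:
    """The data shift ``mu = lam K^{-T} 1`` induced by the l1 penalty,
    computed by a banded triangular solve with the truncated kernel."""
    L = min(len(h), T)
    # K^T is upper banded: (K^T)_{i,j} = h[j-i]; LAPACK band storage
    ab = np.zeros((L, T))
    for k in range(L):
        ab[L - 1 - k, k:] = h[k]
    return solve_banded((0, L - 1), ab, lam * np.ones(T))


def _kernel_taps(kernel) -> np.ndarray:
    return kernel.taps if isinstance(kernel, Kernel) else np.asarray(kernel,
                                                                    dtype=float)


def onnls(y, kernel, lam: float = 0.0, window: int = 200, shift: int = None,
          support_mask=None, s0=None, tol: float = 1e-9, max_passes: int = 5,
          pass_tol: float = 1e-8):
    """Windowed warm-started NNLS deconvolution.

    The classic Lawson-Hanson active-set solver is applied on sliding
    windows of ``window`` frames stepped by ``shift``, peeling the full
    kernel tail of the activity outside each window off its data.  A single
    sweep is the online algorithm; sweeps are repeated (block coordinate
    descent, warm-started) until the solution is stationary, which recovers
    the batch NNLS solution on the whole trace.

    Parameters
    ----------
    y : array
        Fluorescence trace (baseline removed).
    kernel : Kernel or array
        Impulse-response taps, ``h[0] = 1``.
    window, shift : int
        Sliding window length and step; ``shift`` defaults to ``window//2``
        (effective offline); for low-latency streaming it can be as small
        as 1.
    support_mask : bool array, optional
        Restrict nonzero spikes to these frames.
    s0 : array, optional
        Warm-start spike estimate (e.g. the greedy dual solution).
    max_passes, pass_tol : int, float
        Stop sweeping when the largest coordinate change falls below
        ``pass_tol`` (or after ``max_passes`` sweeps).
    """
    y = np.asarray(y, dtype=float)
    h = _kernel_taps(kernel)
    T = y.size
    window = min(window, T)
    if shift is None:
        shift = max(1, window // 2)
    if shift > window:
        raise ValueError("shift must not exceed window")
    if len(h) > window:
        warnings.warn("window shorter than the kernel support; the windowed "
                      "solution is approximate")
    L = len(h)
    # rectangular block: the full kernel column of every in-block spike,
    # so each block solve is an exact coordinate-block step of the global
    # objective (rows beyond the trace end are dropped)
    nrow_full = window + L - 1
    Kfull = np.zeros((nrow_full, window))
    for u in range(window):
        Kfull[u:u + L, u] = h
    cache = {}

    def block_mats(ncols, nrows):
        key = (ncols, nrows)
        if key not in cache:
            Kb = Kfull[:nrows, :ncols]
            cache[key] = (Kb, Kb.T @ Kb)
        return cache[key]

    ym = y - penalty_shift(h, lam, T) if lam != 0 else y.copy()
    s = np.zeros(T) if s0 is None else np.asarray(s0, dtype=float).copy()
    if support_mask is not None:
        support_mask = np.asarray(support_mask, dtype=bool)
        s[~support_mask] = 0.0
    # running convolution K s over the full trace (kept incrementally)
    conv = np.convolve(s, h)[:T] if np.any(s) else np.zeros(T)

    def solve_block(t0, ncols):
        nrows = min(nrow_full, T - t0)
        Kb, gb = block_mats(ncols, nrows)
        prev = s[t0:t0 + ncols].copy()
        # data minus the tails of activity outside the block
        target = ym[t0:t0 + nrows] - (conv[t0:t0 + nrows] - Kb @ prev)
        mask = (support_mask[t0:t0 + ncols]
                if support_mask is not None else None)
        new = nnls_warm(gb, Kb.T @ target, s0=prev, allowed=mask, tol=tol)
        delta = new - prev
        changed = np.flatnonzero(delta)
        for j in changed:
            f = t0 + j
            n_h = min(L, T - f)
            conv[f:f + n_h] += delta[j] * h[:n_h]
        s[t0:t0 + ncols] = new
        return float(np.max(np.abs(delta))) if changed.size else 0.0

    for _ in range(max(1, max_passes)):
        dmax = 0.0
        t = 0
        while t + window <= T:
            dmax = max(dmax, solve_block(t, window))
            t += shift
        if t < T:
            dmax = max(dmax, solve_block(t, T - t))
        if dmax <= pass_tol:
            break
    return s


def _columns(h, frames, T):
    """Dense columns of the full-trace K for the given spike frames."""
    B = np.zeros((T, len(frames)))
    L = len(h)
    for j, f in enumerate(frames):
        n = min(L, T - f)
        B[f:f + n, j] = h[:n]
    return B


def onnls_noise_constrained(y, kernel, sigma: float, lam0: float = 0.0,
                            s0=None, window: int = 200, shift: int = None,
                            support_mask=None, max_iter: int = 10,
                            rss_tol: float = 1e-3):
    """Exact noise-constrained deconvolution by iterating warm-started ONNLS.

    For a fixed active set the solution is linear in lam, so the residual
    sum of squares is an exact quadratic in lam; each iteration solves it
    for ``RSS = sigma^2 T`` and re-runs ONNLS warm-started at the new lam.
    ``lam0``/``s0`` can seed the loop with the fast greedy dual solution.
    Returns ``(s, lam)``.
    """
    y = np.asarray(y, dtype=float)
    h = _kernel_taps(kernel)
    T = y.size
    target = sigma * sigma * T
    lam = lam0
    s = onnls(y, h, lam=lam, window=window, shift=shift,
              support_mask=support_mask, s0=s0)
    for _ in range(max_iter):
        act = np.flatnonzero(s > 0)
        r = y - _columns(h, act, T) @ s[act] if act.size else y.copy()
        rss = float(r @ r)
        if abs(rss - target) <= rss_tol * target:
            break
        if act.size == 0:
            break  # nothing left to shrink
        B = _columns(h, act, T)
        G = B.T @ B
        # s_act(lam) = a - lam * d  on the fixed support
        a = np.linalg.solve(G, B.T @ y)
        d = np.linalg.solve(G, np.ones(act.size))
        # RSS(lam) = ||B a - y||^2 + lam^2 d^T G d - 2 lam d^T B^T (B a - y)
        r0 = B @ a - y
        c0 = float(r0 @ r0)
        c1 = -2.0 * float(d @ (B.T @ r0))
        c2 = float(d @ (G @ d))
        disc = c1 * c1 - 4 * c2 * (c0 - target)
        if c2 <= 0 or disc < 0:
            warnings.warn("degenerate quadratic in the ONNLS sparsity step")
            break
        roots = np.sort(np.roots([c2, c1, c0 - target]))
        pos = roots[roots > 0]
        lam_new = float(pos[0]) if pos.size else lam
        if not np.isfinite(lam_new) or lam_new < 0:
            break
        lam = lam_new
        s = onnls(y, h, lam=lam, window=window, shift=shift,
                  support_mask=support_mask, s0=s)
    return s, lam
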