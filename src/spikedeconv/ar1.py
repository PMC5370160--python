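"""PAVA and the AR(1) online active-set deconvolver (OASIS).

The convex problem solved here is the non-negative LASSO

    min_{c}  1/2 ||c - y||^2 + lam ||G c||_1   s.t.  G c >= 0

for an AR(1) deconvolution operator G.  The constraint ``c_{t+1} >= gamma
c_t`` generalizes the monotonicity constraint of isotonic regression, and
the solver generalizes the pool adjacent violators algorithm (PAVA): it
sweeps once through the series, pooling adjacent frames between inferred
spikes, and merges adjacent pools whenever the decay constraint between them
is violated.  Each merge is O(1), giving an exact O(T) online algorithm.

A pool ``(v, w, t, l)`` summarizes an inter-spike interval starting at frame
``t`` of length ``l``: ``v`` is the fitted value at the first frame (the
remaining frames decay as ``v * gamma^tau``) and ``w = sum_tau gamma^{2 tau}``
is the weight that makes merges O(1).

The hard-threshold (minimum spike size ``s_min``) variant changes only the
merge condition from ``v_{i+1} < gamma^{l_i} v_i`` to ``v_{i+1} <
gamma^{l_i} v_i + s_min``; the l0 variant adds spikes at the largest values
of the l1 solution (splitting pools) until the residual sum of squares drops
below ``sigma^2 T``.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import sparsity_shift

__all__ = [
    "Pool",
    "PoolPartition",
    "pava",
    "merge_pools",
    "oasis_ar1",
    "construct_solution",
    "add_spike_split",
    "l0_deconvolve",
    "OnlineOasisAR1",
    "oasis_ar1_limited_lag",
    "smin_lag_schedule",
]


class Pool(NamedTuple):
    """(value of first frame, weight, start frame, length)."""

    v: float
    w: float
    t: int
    l: int


@dataclass
class PoolPartition:
    """Ordered, contiguous, exhaustive list of pools over ``0..T``.

    This is the solver's entire state: parallel lists of pool values,
    weights, start frames and lengths, plus the gamma and data shift they
    were computed under.
    """

    v: list
    w: list
    t: list
    l: list
    gamma: float
    mu: np.ndarray = None

    @property
    def z(self) -> int:
        return len(self.v)

    @property
    def T(self) -> int:
        return self.t[-1] + self.l[-1] if self.v else 0

    def pools(self):
        return [Pool(*p) for p in zip(self.v, self.w, self.t, self.l)]

    def spike_frames(self) -> np.ndarray:
        """Pool start frames after the first, i.e. the candidate spike times."""
        return np.asarray(self.t[1:], dtype=int)

    def copy(self) -> "PoolPartition":
        return PoolPartition(list(self.v), list(self.w), list(self.t),
                             list(self.l), self.gamma, self.mu)

    def recompute_values(self, ym: np.ndarray, gamma: float = None):
        """Recompute each pool's value and weight directly from the shifted
        data (the closed-form weighted average the merges maintain
        incrementally)."""
        g = self.gamma if gamma is None else gamma
        self.gamma = g
        for i, (t0, li) in enumerate(zip(self.t, self.l)):
            if self.w[i] == np.inf:  # frozen zero prefix stays frozen
                continue
            d = g ** np.arange(li)
            wi = d @ d
            self.v[i] = (ym[t0:t0 + li] @ d) / wi
            self.w[i] = wi

    def construct(self):
        return construct_solution(self, self.gamma)

    def rss(self, y: np.ndarray) -> float:
        c, _ = self.construct()
        return float(np.sum((c - y) ** 2))


def pool_value(ym: np.ndarray, gamma: float, t: int, l: int) -> tuple:
    """Closed-form (value, weight) of a pool over shifted data ``ym``."""
    d = gamma ** np.arange(l)
    w = d @ d
    return float(ym[t:t + l] @ d) / w, float(w)


def merge_pools(pool_i: Pool, pool_next: Pool, gamma: float) -> Pool:
    """Merge two adjacent pools in O(1).

    The merged value is the weight-combined average that equals the direct
    closed-form recomputation over the concatenated data.
    """
    if pool_i.t + pool_i.l != pool_next.t:
        raise ValueError("pools are not adjacent")
    gl = gamma ** pool_i.l
    w = pool_i.w + gl * gl * pool_next.w
    v = (pool_i.w * pool_i.v + gl * pool_next.w * pool_next.v) / w
    return Pool(v, w, pool_i.t, pool_i.l + pool_next.l)


def pava(values) -> np.ndarray:
    """Isotonic regression: least-squares fit by a non-decreasing piecewise
    constant function (pool adjacent violators algorithm)."""
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    v, w, ts = [], [], []
    i = -1
    for t in range(y.size):
        v.append(y[t]); w.append(1.0); ts.append(t)
        i += 1
        while i > 0 and v[i] < v[i - 1]:
            wn = w[i - 1] + w[i]
            v[i - 1] = (w[i - 1] * v[i - 1] + w[i] * v[i]) / wn
            w[i - 1] = wn
            v.pop(); w.pop(); ts.pop()
            i -= 1
    x = np.empty(y.size)
    for vi, wi, ti in zip(v, w, ts):
        x[ti:ti + int(wi)] = vi
    return x


def _validate_ar1(y, g, lam, s_min):
    y = np.asarray(y, dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("NaN in trace")
    if not 0 <= g <= 1:
        raise ValueError("AR(1) solver requires 0 <= gamma <= 1")
    if lam < 0 or s_min < 0:
        raise ValueError("lam and s_min must be >= 0")
    if lam > 0 and s_min > 0:
        raise ValueError("lam and s_min are alternative sparsity modes")
    return y


def oasis_ar1(y, g, lam: float = 0.0, s_min: float = 0.0, mu=None,
              count_merges: bool = False, zero_floor: bool = True):
    """Exact online active-set solution of the AR(1) sparse deconvolution.

    Parameters
    ----------
    y : array
        Fluorescence trace (baseline already removed).
    g : float
        AR(1) coefficient, ``0 <= g < 1`` (``g = 1`` with ``lam = 0``
        reduces the solver to PAVA).
    lam : float
        l1 sparsity weight (soft shrinkage mode).
    s_min : float
        Minimum spike size (hard shrinkage mode, non-convex).
    mu : array, optional
        Explicit per-frame shift; overrides the one derived from ``lam``.
    zero_floor : bool
        Enforce the ``c_1 >= 0`` boundary exactly by freezing a negative
        leading pool at zero; disable to obtain the pure PAVA reduction at
        ``gamma = 1``.

    Returns
    -------
    c, s : ndarray
        Denoised calcium and deconvolved activity.
    partition : PoolPartition
    merges : list of int, only if ``count_merges``
        Number of pool merges performed per incoming sample.
    """
    y = _validate_ar1(y, g, lam, s_min)
    T = y.size
    if mu is None:
        mu = sparsity_shift((g,), lam, T) if lam != 0 else np.zeros(T)
    ym = y - mu
    v, w, ts, ln = [], [], [], []
    merges = [] if count_merges else None
    INF = np.inf
    i = -1
    for t in range(T):
        v.append(ym[t]); w.append(1.0); ts.append(t); ln.append(1)
        i += 1
        m = 0
        while i > 0:
            gl = g ** ln[i - 1]
            if v[i] >= gl * v[i - 1] + s_min:
                break
            if w[i - 1] == INF:
                # absorb into the frozen zero prefix (c >= 0 active)
                ln[i - 1] += ln[i]
            else:
                wn = w[i - 1] + gl * gl * w[i]
                v[i - 1] = (w[i - 1] * v[i - 1] + gl * w[i] * v[i]) / wn
                w[i - 1] = wn
                ln[i - 1] += ln[i]
            v.pop(); w.pop(); ts.pop(); ln.pop()
            i -= 1
            m += 1
        if zero_floor and i == 0 and v[0] < 0.0:
            # the nonnegativity floor c_1 >= 0 binds: freeze the prefix at
            # zero (infinite weight), making the active-set solution exact
            # (zero_floor=False keeps the plain merge dynamics, whose
            # gamma = 1, lam = 0 special case is exactly PAVA)
            v[0] = 0.0
            w[0] = INF
        if count_merges:
            merges.append(m)
    part = PoolPartition(v, w, ts, ln, g, mu)
    c, s = construct_solution(part, g)
    if count_merges:
        return c, s, part, merges
    return c, s, part


def warm_sweep(part: PoolPartition, s_min: float = 0.0) -> int:
    """Re-enforce the decay constraints on an existing partition.

    Sweeps left to right merging adjacent pools that violate
    ``v_{i+1} >= gamma^{l_i} v_i (+ s_min)``, backtracking after each merge
    exactly as the streaming algorithm does.  Returns the number of merges.
    This is the warm start used by the hyperparameter loops: after an
    analytic shift of the pool values, only the z current pools are touched
    instead of T singletons.
    """
    g = part.gamma
    v, w, ts, ln = part.v, part.w, part.t, part.l
    INF = np.inf

    def merge_at(j):
        # merge pools j and j+1 in place
        gl = g ** ln[j]
        if w[j] == INF:
            ln[j] += ln[j + 1]
        else:
            wn = w[j] + gl * gl * w[j + 1]
            v[j] = (w[j] * v[j] + gl * w[j + 1] * v[j + 1]) / wn
            w[j] = wn
            ln[j] += ln[j + 1]
        del v[j + 1], w[j + 1], ts[j + 1], ln[j + 1]

    if v and w[0] != INF and v[0] < 0.0:
        v[0] = 0.0
        w[0] = INF
    i = 0
    nm = 0
    while i < len(v) - 1:
        gl = g ** ln[i]
        if v[i + 1] >= gl * v[i] + s_min:
            i += 1
            continue
        merge_at(i)
        nm += 1
        while i > 0:
            gl = g ** ln[i - 1]
            if v[i] >= gl * v[i - 1] + s_min:
                break
            merge_at(i - 1)
            i -= 1
            nm += 1
        if i == 0 and w[0] != INF and v[0] < 0.0:
            v[0] = 0.0
            w[0] = INF
    return nm


def construct_solution(partition: PoolPartition, gamma: float = None,
                       clip: bool = True):
    """Construct (c, s) from a converged partition.

    Within pool i, ``c_{t_i + tau} = gamma^tau max(0, v_i)`` (negative pool
    values are clipped to zero, enforcing ``c >= 0``); ``s`` is nonzero only
    at pool starts, ``s_t = max(0, c_t - gamma c_{t-1})``, with ``s_0 = c_0``.
    ``clip=False`` skips the nonnegativity clamp (with gamma = 1, lam = 0
    this recovers plain isotonic regression, which has no sign constraint).
    """
    g = partition.gamma if gamma is None else gamma
    T = partition.T
    c = np.empty(T)
    s = np.zeros(T)
    for v, t0, l in zip(partition.v, partition.t, partition.l):
        c[t0:t0 + l] = (max(v, 0.0) if clip else v) * g ** np.arange(l)
        s[t0] = c[t0] - g * c[t0 - 1] if t0 > 0 else c[0]
    if clip:
        np.maximum(s, 0.0, out=s)
    return c, s


# ---------------------------------------------------------------------------
# l0 / hard-threshold machinery


def add_spike_split(partition: PoolPartition, t_s: int, y, gamma: float = None
                    ) -> PoolPartition:
    """Split the pool containing frame ``t_s`` at that frame (add a spike).

    ``t_s`` must lie strictly inside a pool (a pool boundary already carries
    a spike).  Values and weights of the two new pools are recomputed with
    the closed-form weighted average over the raw data (no sparsity shift).
    """
    y = np.asarray(y, dtype=float)
    g = partition.gamma if gamma is None else gamma
    idx = bisect.bisect_right(partition.t, t_s) - 1
    t0, l0 = partition.t[idx], partition.l[idx]
    if t_s == t0 or t_s >= t0 + l0:
        raise ValueError(f"frame {t_s} is a pool boundary, not strictly inside")
    lL = t_s - t0
    lR = l0 - lL
    vL, wL = pool_value(y, g, t0, lL)
    vR, wR = pool_value(y, g, t_s, lR)
    part = partition
    part.v[idx] = vL; part.w[idx] = wL; part.l[idx] = lL
    part.v.insert(idx + 1, vR); part.w.insert(idx + 1, wR)
    part.t.insert(idx + 1, t_s); part.l.insert(idx + 1, lR)
    return part


def _pool_rss(y, g, v, t0, l):
    c = max(v, 0.0) * g ** np.arange(l)
    r = c - y[t0:t0 + l]
    return float(r @ r)


def l0_deconvolve(y, g, sigma: float, s_l1=None):
    """Sparsest deconvolution under the noise constraint (l0 variant).

    Starting from the spikeless fit (a single pool over the whole trace),
    spikes are added one at a time at the largest remaining values of the
    l1 noise-constrained solution ``s_l1`` (computed internally if not
    given), splitting the containing pool, until the residual sum of squares
    drops to ``sigma^2 T``.  Ties in the ranking are broken toward earlier
    frames; frames already holding a spike are skipped.

    Returns ``(c, s, s_min_achieved, partition)`` where ``s_min_achieved``
    is the smallest inferred spike in the final solution.
    """
    y = np.asarray(y, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    T = y.size
    if s_l1 is None:
        from .tuning import tune_constrained  # avoid a circular import
        s_l1 = tune_constrained(y, gamma=g, sigma=sigma).s
    s_l1 = np.asarray(s_l1, dtype=float)
    order = np.argsort(-s_l1, kind="stable")
    v0, w0 = pool_value(y, g, 0, T)
    part = PoolPartition([v0], [w0], [0], [T], g, np.zeros(T))
    pool_rss = [_pool_rss(y, g, v0, 0, T)]
    total = pool_rss[0]
    target = sigma * sigma * T
    for t_s in order:
        if total <= target:
            break
        t_s = int(t_s)
        idx = bisect.bisect_right(part.t, t_s) - 1
        if t_s == part.t[idx]:
            continue  # already a spike here
        add_spike_split(part, t_s, y, g)
        newL = _pool_rss(y, g, part.v[idx], part.t[idx], part.l[idx])
        newR = _pool_rss(y, g, part.v[idx + 1], part.t[idx + 1], part.l[idx + 1])
        total += newL + newR - pool_rss[idx]
        pool_rss[idx] = newL
        pool_rss.insert(idx + 1, newR)
    else:
        if total > target:
            warnings.warn("noise constraint unsatisfiable even with a spike "
                          "at every frame; returning dense solution")
    c, s = construct_solution(part, g)
    spikes = s[s > 0]
    s_min_achieved = float(spikes.min()) if spikes.size else 0.0
    return c, s, s_min_achieved, part


# ---------------------------------------------------------------------------
# online mode with limited lag


def smin_lag_schedule(lag: int) -> float:
    """Minimum spike size as a function of the online lag tau:
    ``0.5 + 0.175 exp(-tau)``, approaching the batch value 0.5."""
    return 0.5 + 0.175 * np.exp(-lag)


@dataclass
class OnlineOasisAR1:
    """Streaming AR(1) deconvolution committing outputs after a fixed lag.

    Each incoming sample is processed by the standard active-set update;
    the estimate for frame ``t - lag`` is committed once sample ``t`` has
    been consumed (i.e. after observing ``lag`` future samples) and never
    changes on later input, while internal pools may keep merging across
    the commitment boundary for the benefit of future frames.
    """

    g: float
    lam: float = 0.0
    s_min: float = 0.0
    lag: int = 0
    v: list = field(default_factory=list)
    w: list = field(default_factory=list)
    ts: list = field(default_factory=list)
    ln: list = field(default_factory=list)
    c: list = field(default_factory=list)   # committed denoised values
    s: list = field(default_factory=list)   # committed deconvolved values
    merge_counts: list = field(default_factory=list)
    _t: int = 0

    def __post_init__(self):
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        _validate_ar1(np.zeros(1), self.g, self.lam, self.s_min)
        self._mu = self.lam * (1.0 - self.g)

    def update(self, y_t: float):
        """Consume one sample; commit the frame ``lag`` steps back, if any."""
        g = self.g
        v, w, ts, ln = self.v, self.w, self.ts, self.ln
        v.append(float(y_t) - self._mu)
        w.append(1.0); ts.append(self._t); ln.append(1)
        i = len(v) - 1
        m = 0
        while i > 0:
            gl = g ** ln[i - 1]
            if v[i] >= gl * v[i - 1] + self.s_min:
                break
            if w[i - 1] == np.inf:
                ln[i - 1] += ln[i]
            else:
                wn = w[i - 1] + gl * gl * w[i]
                v[i - 1] = (w[i - 1] * v[i - 1] + gl * w[i] * v[i]) / wn
                w[i - 1] = wn
                ln[i - 1] += ln[i]
            v.pop(); w.pop(); ts.pop(); ln.pop()
            i -= 1
            m += 1
        if i == 0 and v[0] < 0.0:
            v[0] = 0.0
            w[0] = np.inf
        self.merge_counts.append(m)
        self._t += 1
        k = self._t - 1 - self.lag
        if k >= 0:
            self._commit(k)

    def _commit(self, k: int):
        idx = bisect.bisect_right(self.ts, k) - 1
        t0 = self.ts[idx]
        ck = max(self.v[idx], 0.0) * self.g ** (k - t0)
        if k == 0:
            sk = ck
        elif k == t0:
            sk = max(0.0, ck - self.g * self.c[k - 1])
        else:
            sk = 0.0
        self.c.append(ck)
        self.s.append(sk)

    def finalize(self):
        """End of stream: apply the boundary correction for the final frame
        (whose l1 shift is ``lam`` rather than ``lam (1 - gamma)``), re-merge
        the tail, and commit all remaining frames.

        Returns the full committed ``(c, s)`` arrays.
        """
        if self.lam != 0 and self.v:
            # the last frame's shift under-counted by lam * gamma
            corr = self.lam * self.g
            lz = self.ln[-1]
            if self.w[-1] != np.inf:
                self.v[-1] -= corr * self.g ** (lz - 1) / self.w[-1]
            i = len(self.v) - 1
            while i > 0:
                gl = self.g ** self.ln[i - 1]
                if self.v[i] >= gl * self.v[i - 1] + self.s_min:
                    break
                if self.w[i - 1] == np.inf:
                    self.ln[i - 1] += self.ln[i]
                else:
                    wn = self.w[i - 1] + gl * gl * self.w[i]
                    self.v[i - 1] = (self.w[i - 1] * self.v[i - 1]
                                     + gl * self.w[i] * self.v[i]) / wn
                    self.w[i - 1] = wn
                    self.ln[i - 1] += self.ln[i]
                self.v.pop(); self.w.pop(); self.ts.pop(); self.ln.pop()
                i -= 1
            if i == 0 and self.v[0] < 0.0:
                self.v[0] = 0.0
                self.w[0] = np.inf
        for k in range(len(self.c), self._t):
            self._commit(k)
        return np.asarray(self.c), np.asarray(self.s)


def oasis_ar1_limited_lag(y, g, lam: float = 0.0, s_min: float = 0.0,
                          lag: int = 0):
    """Run the limited-lag online estimator over a full trace.

    With ``lag >= T`` every frame is committed at finalization and the
    result equals the batch solution exactly.
    """
    est = OnlineOasisAR1(g=g, lam=lam, s_min=s_min, lag=int(lag))
    for y_t in np.asarray(y, dtype=float):
        est.update(y_t)
    return est.finalize()
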