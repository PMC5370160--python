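"""Domain types, AR kernels and initial parameter estimation.

The generative model assumes a neuron's intracellular calcium concentration
``c`` follows a stable autoregressive process of order ``p`` driven by the
spike train ``s``::

    c_t = sum_i gamma_i * c_{t-i} + s_t

and the observed fluorescence is ``y_t = c_t + b + eps_t`` with i.i.d.
Gaussian noise of standard deviation ``sigma`` (the fluorescence scale ``a``
is fixed at 1, i.e. a unit spike causes a unit calcium jump).

Equivalently ``c = s * h`` where ``h`` is the (infinite) calcium impulse
response of the AR process, and ``s = G c`` where ``G`` is the banded
deconvolution operator applying the inverse FIR filter ``(1, -gamma_1, ...,
-gamma_p)``.

Internally all frame indices are 0-based half-open; user-facing reports
(CLI, diagnostics) translate to 1-based frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import scipy.sparse
from scipy.signal import welch


__all__ = [
    "FluorescenceTrace",
    "ModelParams",
    "Kernel",
    "TransitionMatrix",
    "ar_roots",
    "is_stable",
    "build_G",
    "kernel_from_ar",
    "sparsity_shift",
    "estimate_noise_psd",
    "estimate_ar_autocov",
    "init_phi_percentile",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FluorescenceTrace:
    """A single-neuron fluorescence time series.

    Parameters
    ----------
    values : ndarray
        Observed fluorescence samples (arbitrary units).
    frame_rate : float
        Acquisition rate in Hz.
    """

    values: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("trace must be a 1-D array with at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def T(self) -> int:
        return self.values.size


def ar_roots(gamma) -> np.ndarray:
    """Characteristic roots of the AR polynomial ``1 - sum_i gamma_i x^i``.

    The process is stable iff all roots have modulus < 1.
    """
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    return np.roots(np.concatenate(([1.0], -g)))


def is_stable(gamma) -> bool:
    """True if the AR process with the given coefficients is stable."""
    return bool(np.all(np.abs(ar_roots(gamma)) < 1.0))


def _check_stable(gamma):
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    if not is_stable(g):
        raise ValueError(
            f"unstable AR coefficients {tuple(g)}: characteristic roots "
            f"{np.abs(ar_roots(g))} must all have modulus < 1"
        )
    return g


@dataclass
class ModelParams:
    """Hyperparameters of the deconvolution model.

    ``lam`` (the l1 sparsity weight) and ``s_min`` (the minimum spike size of
    the hard-threshold variant) are alternative sparsity modes and must not
    both be nonzero in a single solve.
    """

    gamma: tuple
    sigma: float = 0.0
    b: float = 0.0
    lam: float = 0.0
    s_min: float = 0.0
    a: float = field(default=1.0)

    def __post_init__(self):
        self.gamma = tuple(float(g) for g in np.atleast_1d(self.gamma))
        _check_stable(self.gamma)
        if len(self.gamma) == 1 and not 0 <= self.gamma[0] < 1:
            raise ValueError("AR(1) coefficient must satisfy 0 <= gamma < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.lam < 0 or self.s_min < 0:
            raise ValueError("lam and s_min must be >= 0")
        if self.lam > 0 and self.s_min > 0:
            raise ValueError(
                "lam and s_min are alternative sparsity modes; at most one "
                "may be nonzero"
            )
        if self.a != 1.0:
            raise ValueError("fluorescence scale a is fixed at 1")

    @property
    def p(self) -> int:
        return len(self.gamma)


@dataclass(frozen=True)
class Kernel:
    """Truncated calcium impulse response of a stable AR process.

    ``taps[0] == 1`` and ``taps[t] = (A^t)_{1,1}`` (equal to ``gamma**t``
    for an AR(1) process).
    """

    taps: np.ndarray

    def __post_init__(self):
        taps = np.asarray(self.taps, dtype=float)
        if taps.size < 1:
            raise ValueError("kernel needs at least one tap")
        if taps[0] != 1.0:
            raise ValueError("kernel must start with h_1 = 1")
        object.__setattr__(self, "taps", taps)

    def __len__(self) -> int:
        return self.taps.size


class TransitionMatrix:
    """Companion-form state transition of an AR(p) process.

    ``A`` has ``(gamma_1, ..., gamma_p)`` as first row and the identity on
    the subdiagonal; the calcium state evolves as ``zeta_t = A zeta_{t-1} +
    s_t e`` with ``e = (1, 0, ..., 0)``.  ``first_rows(n)`` returns the
    precomputed rows ``(A^t)_{1,:}`` for t = 0..n-1, which are the only parts
    of the matrix powers the solvers need.
    """

    def __init__(self, gamma):
        g = _check_stable(gamma)
        self.gamma = g
        p = g.size
        A = np.zeros((p, p))
        A[0] = g
        if p > 1:
            A[np.arange(1, p), np.arange(p - 1)] = 1.0
        self.A = A
        self.e = np.zeros(p)
        self.e[0] = 1.0
        # cached rows (A^t)_{1,:}
        self._rows = np.zeros((1, p))
        self._rows[0, 0] = 1.0

    @property
    def p(self) -> int:
        return self.gamma.size

    def first_rows(self, n: int) -> np.ndarray:
        """Rows ``(A^t)_{1,:}`` for t = 0, ..., n-1 (shape (n, p))."""
        m = self._rows.shape[0]
        if n > m:
            rows = np.empty((n, self.p))
            rows[:m] = self._rows
            for t in range(m, n):
                rows[t] = rows[t - 1] @ self.A
            self._rows = rows
        return self._rows[:n]

    def impulse_response(self, n: int) -> np.ndarray:
        """Kernel taps ``h_{1+t} = (A^t)_{1,1}`` for t = 0..n-1."""
        return self.first_rows(n)[:, 0]


# ---------------------------------------------------------------------------
# operators


def build_G(gamma, T: int) -> scipy.sparse.csc_matrix:
    """Banded lower-triangular deconvolution operator.

    Applying ``G`` to a calcium series gives ``s_t = c_t - sum_i gamma_i
    c_{t-i}`` (missing history treated as 0).  The matrix is banded with
    bandwidth p and invertible (unit diagonal).
    """
    g = _check_stable(gamma)
    if T < 1:
        raise ValueError("T must be >= 1")
    diags = [np.ones(T)]
    offsets = [0]
    for i, gi in enumerate(g, start=1):
        if i >= T:
            break
        diags.append(np.full(T - i, -gi))
        offsets.append(-i)
    return scipy.sparse.diags(diags, offsets, format="csc")


def kernel_from_ar(gamma, length: int = None, tol: float = 1e-9) -> Kernel:
    """Calcium impulse response of a stable AR process.

    With ``length=None`` the kernel is truncated at the first tap with
    ``|h_t| < tol``, or at 5 decay times of the slowest characteristic root,
    whichever comes first.
    """
    g = _check_stable(gamma)
    if length is not None:
        if length < 1:
            raise ValueError("kernel length must be >= 1")
        n = int(length)
    else:
        rho = np.max(np.abs(ar_roots(g)))
        # decay time in frames of the slowest root
        tau = 1.0 if rho <= 0 else -1.0 / np.log(rho)
        n = max(2, int(np.ceil(5 * tau)))
    tm = TransitionMatrix(g)
    h = tm.impulse_response(n)
    if length is None:
        nz = np.nonzero(np.abs(h) >= tol)[0]
        h = h[: nz[-1] + 1] if nz.size else h[:1]
    return Kernel(h)


def sparsity_shift(gamma, lam: float, T: int) -> np.ndarray:
    """Per-frame shift ``mu`` applied to the data by the l1 penalty.

    ``mu_t = lam * (1 - sum_{i=1}^{min(p, T-1-t)} gamma_i)`` (0-based t);
    these are lam times the column sums of ``G``, so that
    ``mu^T c = lam * ||G c||_1`` for any feasible ``c`` (``G c >= 0``).
    """
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    p = g.size
    mu = np.full(T, lam * (1.0 - g.sum()))
    for t in range(max(0, T - p), T):
        mu[t] = lam * (1.0 - g[: T - 1 - t].sum())
    return mu


# ---------------------------------------------------------------------------
# initial parameter estimation


def _values(trace) -> tuple:
    if isinstance(trace, FluorescenceTrace):
        return trace.values, trace.frame_rate
    return np.asarray(trace, dtype=float), 30.0


def estimate_noise_psd(trace, frame_rate: float = None, nperseg: int = 256,
                       average: str = "logmexp") -> float:
    """Noise standard deviation from the high-frequency power spectrum.

    Averages the Welch periodogram over the upper half of the spectrum
    (normalized frequencies [0.25, 0.5] of the sampling rate), where the
    slow calcium dynamics contribute little power, and converts the
    averaged one-sided density to a standard deviation via
    ``sigma = sqrt(avg(PSD) * fs / 2)``.  The default log-domain mean
    (``exp(mean(log PSD))``) is the field's standard convention and is less
    inflated by residual signal power than the arithmetic mean.
    """
    y, fs = _values(trace)
    if frame_rate is not None:
        fs = frame_rate
    if np.ptp(y) == 0:
        warnings.warn("constant trace: noise estimate is 0")
        return 0.0
    f, pxx = welch(y, fs=fs, nperseg=min(y.size, nperseg))
    band = (f >= 0.25 * fs) & (f <= 0.5 * fs)
    if average == "mean":
        p = np.mean(pxx[band])
    elif average == "median":
        p = np.median(pxx[band])
    elif average == "logmexp":
        p = np.exp(np.mean(np.log(pxx[band] + 1e-300)))
    else:
        raise ValueError(f"unknown averaging convention {average!r}")
    return float(np.sqrt(p * fs / 2.0))


def estimate_ar_autocov(trace, p: int = 1, extra_lags: int = 5) -> np.ndarray:
    """Crude AR coefficient estimate from the empirical autocovariance.

    Solves the lag recursions ``acov_k = sum_i gamma_i acov_{k-i}`` by least
    squares over lags ``p+1 .. p+extra_lags`` (lags <= p are contaminated by
    the observation noise) and clamps the result to stability.  This assumes
    homogeneous Poisson spiking and in practice gives only a crude
    initializer; correlated spiking inflates the estimate.
    """
    y, _ = _values(trace)
    if p not in (1, 2):
        raise ValueError("autocovariance initializer supports p in {1, 2}")
    if y.size < 100:
        raise ValueError("need at least 100 samples to estimate AR coefficients")
    yc = y - y.mean()
    nlags = p + extra_lags
    acov = np.array(
        [yc[: y.size - k] @ yc[k:] / y.size for k in range(nlags + 1)]
    )
    rows = []
    rhs = []
    for k in range(p + 1, nlags + 1):
        rows.append([acov[k - i] for i in range(1, p + 1)])
        rhs.append(acov[k])
    try:
        g, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    except np.linalg.LinAlgError:
        g = None
    if g is None or not np.all(np.isfinite(g)):
        g = np.array([0.9]) if p == 1 else np.array([1.7, -0.7125])
        warnings.warn("degenerate autocovariance; falling back to default AR "
                      f"coefficients {tuple(g)}")
        return g
    if p == 1:
        return np.clip(g, 0.0, 0.9999)
    # clamp to stability via the characteristic roots
    roots = ar_roots(g)
    mods = np.abs(roots)
    if np.any(mods >= 1.0):
        roots = roots * np.minimum(1.0, 0.99 / np.maximum(mods, 1e-12))
        poly = np.real(np.poly(roots))
        g = -poly[1:]
    return np.asarray(g, dtype=float)


def init_phi_percentile(trace, q: float = 15.0) -> float:
    """Initial total shift phi = b + lam(1-gamma) from a low percentile of y."""
    y, _ = _values(trace)
    if y.size == 0:
        raise ValueError("empty trace")
    if not 0 <= q <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(y, q))
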