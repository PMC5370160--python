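"""Independent brute-force references used only in tests.

Generic solvers for the problems the package's active-set methods solve:
the non-negative LASSO via bounded-variable least squares, the
noise-constrained l1 problem via SLSQP with analytic gradients, and
cold-started NNLS from scipy.  These share no code path with the
implementations under test.
"""

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear, minimize

from spikedeconv.core import kernel_from_ar, sparsity_shift


@dataclass
class OracleResult:
    objective: float
    s: np.ndarray
    c: np.ndarray
    status: str
    lam_dual: float = None


def conv_matrix(gamma, T: int) -> np.ndarray:
    """Dense convolution matrix K = G^{-1} (full-length kernel columns)."""
    h = kernel_from_ar(gamma, length=T).taps
    K = np.zeros((T, T))
    for u in range(T):
        K[u:, u] = h[: T - u]
    return K


def qp_oracle_lasso(y, gamma, lam: float) -> OracleResult:
    """Exact solution of the non-negative LASSO by BVLS on the shifted
    NNLS reformulation."""
    y = np.asarray(y, dtype=float)
    T = y.size
    K = conv_matrix(gamma, T)
    # the l1 penalty shifts the data by mu = lam K^{-T} 1 (the column sums
    # of G), leaving a plain NNLS problem
    mu = sparsity_shift(gamma, lam, T)
    res = lsq_linear(K, y - mu, bounds=(0.0, np.inf), method="bvls",
                     tol=1e-14)
    s = res.x
    c = K @ s
    obj = 0.5 * np.sum((c - y) ** 2) + lam * s.sum()
    return OracleResult(obj, s, c, "optimal" if res.success else "failed")


def qp_oracle_constrained(y, gamma, sigma: float) -> OracleResult:
    """Exact solution of min ||s||_1 s.t. s >= 0, ||Ks - y||^2 <= sigma^2 T
    by SLSQP, started from the unpenalized NNLS fit.  The dual variable of
    the residual constraint is converted to the equivalent l1 weight
    lam = -mean_support (K^T (K s - y))."""
    y = np.asarray(y, dtype=float)
    T = y.size
    K = conv_matrix(gamma, T)
    target = sigma * sigma * T
    s0 = lsq_linear(K, y, bounds=(0.0, np.inf), method="bvls", tol=1e-12).x

    def rss_con(s):
        r = K @ s - y
        return target - r @ r

    def rss_jac(s):
        return -2.0 * K.T @ (K @ s - y)

    res = minimize(lambda s: s.sum(), s0, jac=lambda s: np.ones(T),
                   method="SLSQP",
                   bounds=[(0.0, None)] * T,
                   constraints=[{"type": "ineq", "fun": rss_con,
                                 "jac": rss_jac}],
                   options={"maxiter": 2000, "ftol": 1e-10})
    s = np.maximum(res.x, 0.0)
    c = K @ s
    grad = K.T @ (c - y)
    support = s > 1e-6 * max(1.0, s.max())
    lam_dual = float(-grad[support].mean()) if support.any() else np.nan
    # certify optimality from the KKT conditions rather than the solver's
    # status code (SLSQP can stop with a benign linesearch message at the
    # optimum): feasibility, constant negative gradient -lam on the
    # support, and gradient >= -lam off the support
    rss = float(np.sum((c - y) ** 2))
    feasible = rss <= target * (1 + 1e-3)
    if support.any() and np.isfinite(lam_dual) and lam_dual > 0:
        stationary = np.max(np.abs(grad[support] + lam_dual)) \
            <= 1e-2 * lam_dual
        dual_feas = np.min(grad[~support] + lam_dual) >= -1e-2 * lam_dual \
            if (~support).any() else True
    else:
        stationary = dual_feas = False
    status = ("optimal" if (res.success or (feasible and stationary
                                            and dual_feas)) else "failed")
    return OracleResult(float(s.sum()), s, c, status, lam_dual)


def isotonic_oracle(y) -> np.ndarray:
    """Least-squares projection onto the monotone cone by BVLS on the
    difference reparametrization x = x_1 + cumsum of nonnegative steps."""
    y = np.asarray(y, dtype=float)
    T = y.size
    # x = A d with d_0 free, d_{1..} >= 0; A lower triangular of ones
    A = np.tril(np.ones((T, T)))
    lb = np.full(T, 0.0)
    lb[0] = -np.inf
    res = lsq_linear(A, y, bounds=(lb, np.full(T, np.inf)), method="bvls",
                     tol=1e-14)
    return A @ res.x
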