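"""Parameter-scale transforms and constrained-space bijections.

The six EWA learning parameters live on natural scales with different
supports; hierarchical models operate on unconstrained ("transformed")
scales: logit for the unit-interval parameters (sigma, kappa, phi), log
for the positive ones (f, lambda), identity for beta.

Also provides the two constrained bijections the samplers need:

* a stick-breaking simplex transform (for the Dirichlet-distributed step
  vector of monotonic effects), and
* a canonical-partial-correlation transform from unconstrained reals to
  the Cholesky factor of a correlation matrix (for LKJ-distributed
  varying-effect correlations).

Both bijections return analytic log-Jacobians.  Where a gradient of a
scalar function of the transform output is needed, small Jacobian
matrices are obtained by complex-step differentiation, which is exact to
machine precision for these analytic maps.
"""

from __future__ import annotations

import numpy as np

PARAM_NAMES = ("sigma", "kappa", "f", "beta", "lambda", "phi")

# transform kind per parameter, in PARAM_NAMES order
PARAM_TRANSFORMS = ("logit", "logit", "log", "identity", "log", "logit")


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def to_unconstrained(value, kind: str):
    """Natural scale -> transformed (unconstrained) scale."""
    if kind == "logit":
        return logit(value)
    if kind == "log":
        return np.log(value)
    if kind == "identity":
        return np.asarray(value, dtype=float)
    raise ValueError(f"unknown transform kind {kind!r}")


def to_natural(value, kind: str):
    """Transformed scale -> natural scale."""
    if kind == "logit":
        return inv_logit(value)
    if kind == "log":
        return np.exp(value)
    if kind == "identity":
        return np.asarray(value, dtype=float)
    raise ValueError(f"unknown transform kind {kind!r}")


def natural_jacobian(trans_value, kind: str):
    """d(natural)/d(transformed) evaluated at a transformed-scale value."""
    if kind == "logit":
        p = inv_logit(trans_value)
        return p * (1.0 - p)
    if kind == "log":
        return np.exp(trans_value)
    if kind == "identity":
        return np.ones_like(np.asarray(trans_value, dtype=float))
    raise ValueError(f"unknown transform kind {kind!r}")


# ---------------------------------------------------------------------------
# simplex (stick-breaking)
# ---------------------------------------------------------------------------

def simplex_from_unconstrained(y):
    """Map R^(K-1) -> K-simplex via stick breaking.

    Returns (x, log_abs_det_jacobian).  Follows the standard
    stick-breaking construction: z_k = inv_logit(y_k - log(K - k)),
    x_k = z_k * stick_k.
    """
    y = np.asarray(y)
    K = y.shape[0] + 1
    x = np.zeros(K, dtype=y.dtype)
    stick = 1.0 + 0.0 * y[0] if y.dtype == complex else 1.0
    log_det = 0.0 * y[0] if y.dtype == complex else 0.0
    for k in range(K - 1):
        adj = y[k] - np.log(K - k - 1)
        # complex-safe inverse logit
        z = 1.0 / (1.0 + np.exp(-adj))
        x[k] = z * stick
        log_det = log_det + np.log(z) + np.log(1.0 - z) + np.log(stick)
        stick = stick - x[k]
    x[K - 1] = stick
    return x, log_det


def unconstrained_from_simplex(x):
    """Inverse stick-breaking; x strictly positive, sums to 1."""
    x = np.asarray(x, dtype=float)
    K = x.shape[0]
    y = np.empty(K - 1)
    stick = 1.0
    for k in range(K - 1):
        z = x[k] / stick
        y[k] = logit(z) + np.log(K - k - 1)
        stick -= x[k]
    return y


def dirichlet_logpdf(x, alpha: float):
    """Unnormalized log-density of a symmetric Dirichlet."""
    return float((alpha - 1.0) * np.sum(np.log(x)))


# ---------------------------------------------------------------------------
# Cholesky factor of a correlation matrix
# ---------------------------------------------------------------------------

def corr_chol_from_unconstrained(y, K: int):
    """Map R^(K(K-1)/2) -> lower Cholesky factor of a KxK correlation matrix.

    Unconstrained entries are tanh-transformed to canonical partial
    correlations and rows are filled so each has unit norm.  Returns
    (L, log_abs_det_jacobian).
    """
    y = np.asarray(y)
    assert y.shape[0] == K * (K - 1) // 2
    dtype = complex if y.dtype == complex else float
    L = np.zeros((K, K), dtype=dtype)
    L[0, 0] = 1.0
    log_det = 0.0 * y[0] if dtype is complex else 0.0
    idx = 0
    for i in range(1, K):
        row_ss = 0.0 * y[0] if dtype is complex else 0.0  # sum of squares so far
        for j in range(i):
            z = np.tanh(y[idx])
            idx += 1
            rem = 1.0 - row_ss
            L[i, j] = z * np.sqrt(rem)
            # tanh jacobian + row-scaling diagonal term
            log_det = log_det + np.log(1.0 - z * z) + 0.5 * np.log(rem)
            row_ss = row_ss + L[i, j] ** 2
        L[i, i] = np.sqrt(1.0 - row_ss)
    return L, log_det


def unconstrained_from_corr_chol(L):
    """Inverse of :func:`corr_chol_from_unconstrained`."""
    L = np.asarray(L, dtype=float)
    K = L.shape[0]
    y = []
    for i in range(1, K):
        row_ss = 0.0
        for j in range(i):
            rem = 1.0 - row_ss
            z = L[i, j] / np.sqrt(rem)
            y.append(np.arctanh(z))
            row_ss += L[i, j] ** 2
    return np.array(y)


def lkj_chol_logpdf(L, eta: float):
    """Unnormalized log-density of the LKJ prior on a correlation Cholesky factor."""
    K = L.shape[0]
    lp = 0.0
    for k in range(1, K):
        lp += (K - k - 1 + 2.0 * eta - 2.0) * np.log(L[k, k])
    return float(lp)


def _corr_chol_batch(yb, K):
    """Vectorized corr-Cholesky transform over a batch of unconstrained rows.

    ``yb`` is (B, K(K-1)/2); returns (L (B,K,K), log_det (B,)).  Complex
    inputs propagate, enabling batched complex-step differentiation.
    """
    B = yb.shape[0]
    L = np.zeros((B, K, K), dtype=yb.dtype)
    L[:, 0, 0] = 1.0
    log_det = np.zeros(B, dtype=yb.dtype)
    idx = 0
    for i in range(1, K):
        row_ss = np.zeros(B, dtype=yb.dtype)
        for j in range(i):
            z = np.tanh(yb[:, idx])
            idx += 1
            rem = 1.0 - row_ss
            L[:, i, j] = z * np.sqrt(rem)
            log_det = log_det + np.log(1.0 - z * z) + 0.5 * np.log(rem)
            row_ss = row_ss + L[:, i, j] ** 2
        L[:, i, i] = np.sqrt(1.0 - row_ss)
    return L, log_det


def corr_chol_value_jac(y, K: int, eta: float, h: float = 1e-20):
    """Corr-Cholesky transform with Jacobian and LKJ-prior gradient.

    One batched complex-step pass returns ``(L, prior_val, J_L, g_prior)``
    where ``prior_val`` is the LKJ log-density plus transform log-Jacobian,
    ``J_L`` is d vec(L) / dy (K*K x m) and ``g_prior`` its gradient.
    """
    m = y.shape[0]
    yb = np.repeat(y[None, :], m + 1, axis=0).astype(complex)
    yb[np.arange(m), np.arange(m)] += 1j * h
    L, log_det = _corr_chol_batch(yb, K)
    val = log_det
    for k in range(1, K):
        val = val + (K - k - 1 + 2.0 * eta - 2.0) * np.log(L[:, k, k])
    J_L = (L[:m].reshape(m, K * K).imag / h).T
    g_prior = val[:m].imag / h
    return L[m].real, float(val[m].real), J_L, g_prior


def simplex_value_jac(y, alpha: float, h: float = 1e-20):
    """Stick-breaking transform with Jacobian and Dirichlet-prior gradient.

    Returns ``(x, prior_val, J, g_prior)`` with ``prior_val`` the
    Dirichlet(alpha) log-density plus transform log-Jacobian, ``J`` the
    (K x m) Jacobian dx/dy, and ``g_prior`` the prior-value gradient.
    """
    m = y.shape[0]
    K = m + 1
    yb = np.repeat(y[None, :], m + 1, axis=0).astype(complex)
    yb[np.arange(m), np.arange(m)] += 1j * h
    x = np.zeros((m + 1, K), dtype=complex)
    stick = np.ones(m + 1, dtype=complex)
    log_det = np.zeros(m + 1, dtype=complex)
    for k in range(K - 1):
        z = 1.0 / (1.0 + np.exp(-(yb[:, k] - np.log(K - k - 1))))
        x[:, k] = z * stick
        log_det = log_det + np.log(z) + np.log(1.0 - z) + np.log(stick)
        stick = stick - x[:, k]
    x[:, K - 1] = stick
    val = log_det + (alpha - 1.0) * np.sum(np.log(x), axis=1)
    J = (x[:m].imag / h).T
    g_prior = val[:m].imag / h
    return x[m].real, float(val[m].real), J, g_prior


def complex_step_jacobian(fn, y, m_out: int, h: float = 1e-20):
    """Jacobian (m_out x len(y)) of an analytic map by complex-step differentiation."""
    y = np.asarray(y, dtype=float)
    J = np.empty((m_out, y.shape[0]))
    for k in range(y.shape[0]):
        yc = y.astype(complex)
        yc[k] += 1j * h
        J[:, k] = np.imag(fn(yc)) / h
    return J


def complex_step_grad(fn, y, h: float = 1e-20):
    """Gradient of an analytic scalar function by complex-step differentiation."""
    y = np.asarray(y, dtype=float)
    g = np.empty_like(y)
    for k in range(y.shape[0]):
        yc = y.astype(complex)
        yc[k] += 1j * h
        g[k] = np.imag(fn(yc)) / h
    return g
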