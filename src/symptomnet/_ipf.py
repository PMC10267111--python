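"""Iterative proportional fitting for support-constrained Gaussian MLEs.

Fits the precision matrix maximising ``log det K - tr(S K)`` subject to a
fixed zero pattern, cycling edge (2x2) and singleton (1x1) marginal
adjustments with symmetric low-rank Woodbury updates of the working
covariance. The hot loop is JIT-compiled when numba is available; a
vectorised numpy fallback keeps the package importable without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _ipf_sweeps(S, edge_i, edge_j, K, W, tol, max_sweeps):  # pragma: no cover
    p = S.shape[0]
    n_edges = edge_i.shape[0]
    u = np.empty(p)
    v = np.empty(p)
    for _ in range(max_sweeps):
        dmax = 0.0
        for e in range(n_edges):
            i = edge_i[e]
            j = edge_j[e]
            s11 = S[i, i]; s12 = S[i, j]; s22 = S[j, j]
            w11 = W[i, i]; w12 = W[i, j]; w22 = W[j, j]
            dets = s11 * s22 - s12 * s12
            detw = w11 * w22 - w12 * w12
            d11 = s22 / dets - w22 / detw
            d12 = -s12 / dets + w12 / detw
            d22 = s11 / dets - w11 / detw
            step = max(abs(d11), abs(d12), abs(d22))
            if step < 0.1 * tol:
                continue
            if step > dmax:
                dmax = step
            K[i, i] += d11
            K[i, j] += d12
            K[j, i] += d12
            K[j, j] += d22
            detd = d11 * d22 - d12 * d12
            if abs(detd) < 1e-300:
                W[:, :] = np.linalg.inv(K)
                continue
            id11 = d22 / detd; id12 = -d12 / detd; id22 = d11 / detd
            m11 = id11 + w11; m12 = id12 + w12; m22 = id22 + w22
            detm = m11 * m22 - m12 * m12
            im11 = m22 / detm; im12 = -m12 / detm; im22 = m11 / detm
            for r in range(p):
                u[r] = W[r, i]
                v[r] = W[r, j]
            for r in range(p):
                ar = u[r] * im11 + v[r] * im12
                br = u[r] * im12 + v[r] * im22
                for c in range(p):
                    W[r, c] -= ar * u[c] + br * v[c]
        for i in range(p):
            d = 1.0 / S[i, i] - 1.0 / W[i, i]
            if abs(d) < 0.1 * tol:
                continue
            if abs(d) > dmax:
                dmax = abs(d)
            K[i, i] += d
            m = 1.0 / (1.0 / d + W[i, i])
            for r in range(p):
                u[r] = W[r, i]
            for r in range(p):
                um = u[r] * m
                for c in range(p):
                    W[r, c] -= um * u[c]
        if dmax < tol:
            break


def _ipf_sweeps_numpy(S, edge_i, edge_j, K, W, tol, max_sweeps):
    p = S.shape[0]
    for _ in range(max_sweeps):
        dmax = 0.0
        for i, j in zip(edge_i, edge_j):
            A = (int(i), int(j))
            SA = S[np.ix_(A, A)]
            WA = W[np.ix_(A, A)]
            D = np.linalg.inv(SA) - np.linalg.inv(WA)
            step = float(np.abs(D).max())
            if step < 0.1 * tol:
                continue
            dmax = max(dmax, step)
            K[np.ix_(A, A)] += D
            if abs(np.linalg.det(D)) < 1e-300:
                W[:, :] = np.linalg.inv(K)
                continue
            M = np.linalg.inv(np.linalg.inv(D) + WA)
            U = W[:, A].copy()
            W -= U @ M @ U.T
        for i in range(p):
            d = 1.0 / S[i, i] - 1.0 / W[i, i]
            if abs(d) < 0.1 * tol:
                continue
            dmax = max(dmax, abs(d))
            K[i, i] += d
            u = W[:, i].copy()
            W -= np.outer(u, u) / (1.0 / d + W[i, i])
        if dmax < tol:
            break


def constrained_mle(
    S: np.ndarray,
    support: np.ndarray,
    K0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 500,
) -> tuple[np.ndarray, float]:
    """Zero-pattern-constrained Gaussian MLE of the precision matrix.

    ``support`` is a boolean adjacency (off-diagonal pattern); ``K0`` warm
    starts the iteration (typically a graphical-lasso fit with that
    support). Returns the MLE ``K`` and its log-likelihood
    ``log det K - tr(S K)`` (``-inf`` when the constrained MLE is not
    positive definite, e.g. a support too sparse for S).
    """
    S = np.asarray(S, dtype=float)
    edge_i, edge_j = np.nonzero(np.triu(support, k=1))
    if K0 is not None:
        K = K0.copy()
        W = np.linalg.inv(K)
    else:
        K = np.diag(1.0 / np.diag(S))
        W = np.diag(np.diag(S)).astype(float)
    runner = _ipf_sweeps if _HAVE_NUMBA else _ipf_sweeps_numpy
    runner(S, edge_i.astype(np.int64), edge_j.astype(np.int64), K, W,
           float(tol), int(max_sweeps))
    K = (K + K.T) / 2.0
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return K, -np.inf
    return K, float(logdet - np.trace(S @ K))


def constrained_mle_loglik(
    S: np.ndarray,
    support: np.ndarray,
    K0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 500,
) -> float:
    """Log-likelihood of the support-constrained MLE (see
    :func:`constrained_mle`)."""
    return constrained_mle(S, support, K0=K0, tol=tol, max_sweeps=max_sweeps)[1]
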