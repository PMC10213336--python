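"""Graphical LASSO: L1-penalized sparse precision-matrix estimation.

Solves  max_K  log det K - tr(SK) - lam * sum_{i != j} |K_ij|  over positive
definite K by the classic block coordinate descent: each row/column update is
a lasso regression solved by coordinate descent on the current covariance
estimate W.  The diagonal is unpenalized, so W keeps the sample diagonal
(W_ii = S_ii) throughout.

The inner loops are numba-compiled: the stability bootstrap and permutation
comparison test downstream re-estimate networks tens of thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso", "glasso_path", "glasso_objective", "GlassoNonConvergence"]


class GlassoNonConvergence(RuntimeError):
    """Raised when block coordinate descent exhausts max_iter.

    Carries the last iterates as ``W`` and ``K``.
    """

    def __init__(self, message, W=None, K=None):
        super().__init__(message)
        self.W = W
        self.K = K


@njit(cache=True)
def _glasso_inner(S, lam, tol, max_iter, W, B):  # pragma: no cover - jitted
    p = S.shape[0]
    n_off = p * (p - 1) if p > 1 else 1
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    thresh = tol * max(s_off / n_off, 1e-12)

    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    niter = 0
    converged = False
    for it in range(max_iter):
        total_change = 0.0
        for j in range(p):
            mi = 0
            for i in range(p):
                if i == j:
                    continue
                s12[mi] = S[i, j]
                beta[mi] = B[j, mi]
                mj = 0
                for l in range(p):
                    if l == j:
                        continue
                    W11[mi, mj] = W[i, l]
                    mj += 1
                mi += 1
            # lasso:  min 0.5 b'W11 b - s12'b + lam |b|_1
            for _sweep in range(500):
                dmax = 0.0
                for m in range(p - 1):
                    r = s12[m]
                    for l in range(p - 1):
                        if l != m:
                            r -= W11[m, l] * beta[l]
                    if r > lam:
                        bnew = (r - lam) / W11[m, m]
                    elif r < -lam:
                        bnew = (r + lam) / W11[m, m]
                    else:
                        bnew = 0.0
                    d = abs(bnew - beta[m])
                    if d > dmax:
                        dmax = d
                    beta[m] = bnew
                if dmax < 1e-11:
                    break
            mi = 0
            for i in range(p):
                if i == j:
                    continue
                w = 0.0
                for l in range(p - 1):
                    w += W11[mi, l] * beta[l]
                total_change += abs(w - W[i, j])
                W[i, j] = w
                W[j, i] = w
                B[j, mi] = beta[mi]
                mi += 1
        niter = it + 1
        if total_change / n_off < thresh:
            converged = True
            break

    K = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        mi = 0
        for i in range(p):
            if i == j:
                continue
            dot += W[i, j] * B[j, mi]
            mi += 1
        denom = W[j, j] - dot
        if denom < 1e-12:
            denom = 1e-12
        k22 = 1.0 / denom
        K[j, j] = k22
        mi = 0
        for i in range(p):
            if i == j:
                continue
            # each edge gets half from either block; symmetric at convergence
            K[i, j] += -B[j, mi] * k22 * 0.5
            K[j, i] += -B[j, mi] * k22 * 0.5
            mi += 1
    return K, niter, converged


@njit(cache=True)
def _glasso_path_inner(S, lambdas, tol, max_iter):  # pragma: no cover - jitted
    p = S.shape[0]
    L = lambdas.shape[0]
    Ks = np.zeros((L, p, p))
    niters = np.zeros(L, dtype=np.int64)
    convs = np.zeros(L, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p, p - 1))
    for li in range(L):
        K, ni, cv = _glasso_inner(S, lambdas[li], tol, max_iter, W, B)
        Ks[li] = K
        niters[li] = ni
        convs[li] = cv
    return Ks, niters, convs


def _check_S(S) -> np.ndarray:
    S = np.ascontiguousarray(np.asarray(S, dtype=float))
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ValueError("S must be a square matrix with p >= 2")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    return (S + S.T) / 2.0


def glasso(S, lam: float, tol: float = 1e-6, max_iter: int = 200):
    """Fit the graphical lasso at a single penalty.

    Parameters
    ----------
    S : (p, p) symmetric PSD matrix (correlation or covariance).
    lam : nonnegative off-diagonal L1 penalty.
    tol : convergence when the mean absolute off-diagonal change of the
        covariance iterate W drops below ``tol * mean |S_offdiag|``.

    Returns
    -------
    (W, K) : covariance and precision estimates, with ``W @ K ~ I``.

    Raises
    ------
    GlassoNonConvergence
        after ``max_iter`` sweeps, carrying the last iterates.
    """
    S = _check_S(S)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p - 1))
    K, niter, converged = _glasso_inner(S, float(lam), float(tol), int(max_iter), W, B)
    if not converged:
        raise GlassoNonConvergence(
            f"graphical lasso did not converge in {max_iter} iterations", W=W, K=K
        )
    return W, K


def glasso_path(S, lambdas, tol: float = 1e-6, max_iter: int = 200):
    """Fit the graphical lasso along a penalty path with warm starts.

    ``lambdas`` should be in descending order (sparse to dense) so each fit
    warm-starts the next.  Returns (Ks, n_iters, converged_flags).
    """
    S = _check_S(S)
    lambdas = np.ascontiguousarray(np.asarray(lambdas, dtype=float))
    if np.any(lambdas < 0):
        raise ValueError("penalties must be >= 0")
    return _glasso_path_inner(S, lambdas, float(tol), int(max_iter))


def glasso_objective(K, S, lam: float) -> float:
    """Penalized log-likelihood  log det K - tr(SK) - lam * sum_{i!=j}|K_ij|."""
    K = np.asarray(K, dtype=float)
    S = np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    pen = np.sum(np.abs(K)) - np.sum(np.abs(np.diag(K)))
    return float(logdet - np.sum(S * K) - lam * pen)
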