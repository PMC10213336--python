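"""Independent oracles used by the tests.

Each oracle reaches the quantity under test by a different route than the
package (generic convex optimization, direct likelihood maximization, brute
force enumeration) so agreement is informative.
"""

from itertools import combinations

import numpy as np
from scipy import optimize, stats


def glasso_convex_oracle(S: np.ndarray, lam: float) -> float:
    """Maximum of the penalized glasso log-likelihood by generic smooth
    optimization: off-diagonal entries split into positive/negative parts
    (K_ij = u_ij - v_ij, u, v >= 0) so the L1 penalty 2*lam*sum(u+v) —
    matching the ordered-pair penalty lam*sum_{i!=j}|K_ij| — becomes linear,
    then L-BFGS-B with analytic gradients."""
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    m = len(iu[0])

    def f(x):
        d, u, v = x[:p], x[p:p + m], x[p + m:]
        K = np.zeros((p, p))
        K[iu] = u - v
        K = K + K.T
        K[np.diag_indices(p)] = d
        sign, ld = np.linalg.slogdet(K)
        if sign <= 0:
            return 1e10, np.zeros_like(x)
        val = -(ld - np.sum(S * K) - 2 * lam * np.sum(u + v))
        G = -(np.linalg.inv(K) - S)
        return val, np.concatenate(
            [np.diag(G), 2 * G[iu] + 2 * lam, -2 * G[iu] + 2 * lam]
        )

    K0 = np.linalg.inv(S + lam * np.eye(p))
    off = K0[iu]
    x0 = np.concatenate([np.diag(K0), np.clip(off, 0, None), np.clip(-off, 0, None)])
    res = optimize.minimize(
        f, x0, jac=True, method="L-BFGS-B",
        bounds=[(None, None)] * p + [(0, None)] * (2 * m),
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-14},
    )
    return -res.fun


def logistic_ml_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Logistic-regression MLE by direct negative log-likelihood minimization
    (BFGS with analytic gradient); X must already include the intercept."""

    def nll(beta):
        eta = X @ beta
        # log(1 + exp(eta)) - y*eta, numerically stable
        val = np.sum(np.logaddexp(0.0, eta) - y * eta)
        grad = X.T @ (1.0 / (1.0 + np.exp(-eta)) - y)
        return val, grad

    res = optimize.minimize(
        nll, np.zeros(X.shape[1]), jac=True, method="BFGS",
        options={"gtol": 1e-10, "maxiter": 5000},
    )
    return res.x


def wilcoxon_exact_p(x, y) -> float:
    """Exact two-sided permutation p-value of the rank-sum statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    obs = ranks[:n1].sum()
    mu = n1 * (len(combined) + 1) / 2.0
    dev = abs(obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(len(combined)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            count += 1
    return count / total
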