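"""Correlation-matrix input for network estimation.

Ordinal survey items (0–3 Likert responses, the 0–10 fatigue rating, the 2–10
QOL sum) are treated under the latent-Gaussian measurement model: each pair's
polychoric correlation is the correlation of the bivariate normal assumed to
underlie the observed contingency table.  Estimation is the standard two-step
maximum likelihood: thresholds from the marginal cumulative proportions via
the inverse normal CDF, then the correlation maximizing the bivariate-normal
cell likelihood.  Continuous covariates use Pearson correlations; mixed
ordinal/continuous pairs are approximated by Pearson on scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "bvn_cdf",
    "polychoric_corr",
    "CorrelationMatrix",
    "correlation_matrix",
]

# Gauss-Legendre rule reused across all quadrature calls
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)
_ZMAX = 8.5  # |z| beyond this is numerically 0/1 under the standard normal


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    Vectorized over ``h`` and ``k`` (broadcast together); ``rho`` is scalar.
    Uses the conditioning identity
    ``P = int_{-inf}^{h} phi(x) Phi((k - rho x)/sqrt(1-rho^2)) dx``
    evaluated by 48-point Gauss-Legendre quadrature.
    """
    h = np.clip(np.asarray(h, dtype=float), -_ZMAX, _ZMAX)
    k = np.clip(np.asarray(k, dtype=float), -_ZMAX, _ZMAX)
    h, k = np.broadcast_arrays(h, k)
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return stats.norm.cdf(np.minimum(h, k))
        return np.maximum(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0)
    s = np.sqrt(1.0 - rho * rho)
    lo = -_ZMAX
    half = (h - lo) / 2.0  # (m,)
    # nodes mapped onto [lo, h] per element
    x = lo + half[..., None] * (_GL_NODES + 1.0)  # (..., G)
    integrand = stats.norm.pdf(x) * stats.norm.cdf((k[..., None] - rho * x) / s)
    return half * np.sum(integrand * _GL_WEIGHTS, axis=-1)


def _thresholds(codes: np.ndarray, n_cat: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_cat)
    cum = np.cumsum(counts)[:-1] / codes.size
    return stats.norm.ppf(cum)


def polychoric_corr(x, y) -> float:
    """Two-step maximum-likelihood polychoric correlation of two ordinal vectors.

    Thresholds come from the marginal cumulative proportions; the correlation
    maximizes the bivariate-normal likelihood of the observed contingency
    table.  Falls back to the Spearman rank correlation (with a warning) if
    the likelihood optimization fails.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be nonempty and equal-length")
    xcat, xcodes = np.unique(x, return_inverse=True)
    ycat, ycodes = np.unique(y, return_inverse=True)
    if xcat.size < 2 or ycat.size < 2:
        raise ValueError("polychoric correlation requires >= 2 observed categories")

    table = np.zeros((xcat.size, ycat.size))
    np.add.at(table, (xcodes, ycodes), 1.0)
    a = _thresholds(xcodes, xcat.size)  # K1-1 finite thresholds
    b = _thresholds(ycodes, ycat.size)
    agrid = np.concatenate(([-np.inf], a, [np.inf]))
    bgrid = np.concatenate(([-np.inf], b, [np.inf]))
    A, B = np.meshgrid(agrid, bgrid, indexing="ij")

    def nll(rho: float) -> float:
        C = bvn_cdf(A, B, rho)
        # exact limits at the infinite grid edges
        C[0, :] = 0.0
        C[:, 0] = 0.0
        C[-1, :] = stats.norm.cdf(np.clip(bgrid, -_ZMAX, _ZMAX))
        C[:, -1] = stats.norm.cdf(np.clip(agrid, -_ZMAX, _ZMAX))
        C[-1, -1] = 1.0
        pi = np.diff(np.diff(C, axis=0), axis=1)
        pi = np.clip(pi, 1e-12, None)
        return -float(np.sum(table * np.log(pi)))

    try:
        res = optimize.minimize_scalar(
            nll, bounds=(-0.999, 0.999), method="bounded",
            options={"xatol": 1e-6},
        )
        if res.success and np.isfinite(res.fun):
            return float(res.x)
    except Exception:  # pragma: no cover - defensive
        pass
    warnings.warn(
        "polychoric likelihood optimization failed; falling back to Spearman",
        RuntimeWarning,
    )
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric correlation matrix with estimation metadata."""

    values: pd.DataFrame
    method: str
    n: int
    pd_repaired: bool = False

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    @property
    def columns(self):
        return list(self.values.columns)


def _is_ordinal(col: pd.Series, max_levels: int = 11) -> bool:
    vals = col.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        return False
    if np.any(vals != np.floor(vals)):
        return False
    return np.unique(vals).size <= max_levels


def _repair_psd(M: np.ndarray, floor: float = 1e-6):
    vals, vecs = np.linalg.eigh(M)
    if vals.min() >= 0:
        return M, False
    vals = np.clip(vals, floor, None)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R, True


def correlation_matrix(data: pd.DataFrame, method: str = "auto") -> CorrelationMatrix:
    """Pairwise correlation matrix of a data frame.

    method : {"auto", "pearson", "spearman", "polychoric"}
        "auto" uses polychoric for ordinal/ordinal pairs (integer-valued
        columns with at most 11 levels) and Pearson otherwise.  Matrices that
        come out indefinite are repaired by eigenvalue clipping at 1e-6 and
        renormalization to unit diagonal; the repair is flagged.
    """
    if data.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    cols = list(data.columns)
    p = len(cols)
    X = data.to_numpy(dtype=float)
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        R = stats.spearmanr(X).statistic
        if p == 2:
            R = np.array([[1.0, float(R)], [float(R), 1.0]])
    elif method in ("polychoric", "auto"):
        ordinal = [
            method == "polychoric" or _is_ordinal(data[c]) for c in cols
        ]
        R = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                if ordinal[i] and ordinal[j]:
                    r = polychoric_corr(X[:, i], X[:, j])
                else:
                    r = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
                R[i, j] = R[j, i] = r
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    R, repaired = _repair_psd(R)
    return CorrelationMatrix(
        values=pd.DataFrame(R, index=cols, columns=cols),
        method=method,
        n=len(data),
        pd_repaired=repaired,
    )
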