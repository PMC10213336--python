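"""Regularized partial-correlation symptom networks.

A Gaussian graphical model is estimated over the survey items: nodes are
symptoms, edges are partial correlations (association between two symptoms
conditioned on all other nodes).  Sparsity comes from the graphical lasso;
the penalty is selected on a log-spaced path by the extended Bayesian
information criterion

    EBIC(lambda) = -2 L + E ln n + 4 E gamma ln p,

where L is the Gaussian log-likelihood (n/2)(log det K - tr(SK)), E the edge
count and gamma the extra-penalty hyperparameter (0.5 by default; gamma = 0
recovers the plain BIC).

The estimator follows the statsmodels convention: ``SymptomNetworkModel``
holds the data and settings, ``fit()`` returns a ``SymptomNetworkResult``
carrying the selected network, the path diagnostics and summary methods.
``ebic_glasso`` and ``adjusted_network`` are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import CorrelationMatrix, correlation_matrix
from .glasso import glasso_path

__all__ = [
    "EDGE_EPS",
    "ebic",
    "SymptomNetworkModel",
    "SymptomNetworkResult",
    "SymptomNetwork",
    "ebic_glasso",
    "adjusted_network",
]

#: |partial correlation| below this is a structural zero when counting edges
EDGE_EPS = 1e-8


def _edge_count(weights: np.ndarray) -> int:
    iu = np.triu_indices(weights.shape[0], 1)
    return int(np.sum(np.abs(weights[iu]) > EDGE_EPS))


def ebic(K, S, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a precision estimate K against correlation matrix S."""
    K = np.asarray(K, dtype=float)
    S = np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision estimate is not positive definite")
    p = K.shape[0]
    L = (n / 2.0) * (logdet - np.sum(S * K))
    E = _edge_count(_partials(K))
    return float(-2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def _partials(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    P[np.abs(P) <= EDGE_EPS] = 0.0
    return (P + P.T) / 2.0


@dataclass(frozen=True)
class SymptomNetworkResult:
    """Estimated symptom network: edge weights, selection path, metadata."""

    weights: pd.DataFrame          # partial correlations, zero diagonal
    precision: np.ndarray          # selected precision estimate
    correlation: CorrelationMatrix
    lambda_: float
    gamma: float
    ebic_value: float
    n: int
    path: pd.DataFrame             # lambda, ebic, n_edges, converged
    path_monotone: bool

    @property
    def nodes(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def p(self) -> int:
        return len(self.weights)

    @property
    def n_edges(self) -> int:
        return _edge_count(self.weights.to_numpy())

    @property
    def sparsity(self) -> float:
        total = self.p * (self.p - 1) // 2
        return 1.0 - self.n_edges / total if total else 1.0

    def strength(self) -> pd.DataFrame:
        from .metrics import strength_centrality

        return strength_centrality(self)

    def flow(self, target: str):
        from .metrics import flow_edges

        return flow_edges(self, target)

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as a (node_a, node_b, weight) table, |weight| desc."""
        W = self.weights.to_numpy()
        iu = np.triu_indices(self.p, 1)
        rows = [
            (self.nodes[i], self.nodes[j], W[i, j])
            for i, j in zip(*iu)
            if abs(W[i, j]) > EDGE_EPS
        ]
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
        return df.reindex(
            df["weight"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)

    def metadata(self) -> dict:
        return {
            "lambda": self.lambda_,
            "gamma": self.gamma,
            "ebic": self.ebic_value,
            "n": self.n,
            "p": self.p,
            "n_edges": self.n_edges,
            "sparsity": self.sparsity,
            "method": self.correlation.method,
            "pd_repaired": self.correlation.pd_repaired,
            "path_monotone": self.path_monotone,
        }

    def summary(self) -> str:
        meta = self.metadata()
        lines = [
            "Symptom network (EBIC graphical lasso)",
            "=" * 40,
            f"nodes: {self.p}   n: {self.n}   edges: {self.n_edges}"
            f"   sparsity: {self.sparsity:.3f}",
            f"lambda: {self.lambda_:.5f}   gamma: {self.gamma}"
            f"   EBIC: {self.ebic_value:.2f}",
            f"correlation input: {meta['method']}"
            + ("  (PSD-repaired)" if meta["pd_repaired"] else ""),
            "",
            "strongest edges:",
        ]
        for _, r in self.edge_list().head(10).iterrows():
            lines.append(f"  {r.node_a:>8} -- {r.node_b:<8} {r.weight:+.3f}")
        return "\n".join(lines)


# spec-facing alias: the result object IS the network
SymptomNetwork = SymptomNetworkResult


class SymptomNetworkModel:
    """EBIC-gLASSO network model over the columns of a data frame.

    Parameters
    ----------
    data : DataFrame of item/covariate columns (one row per respondent).
    method : correlation input; "auto" uses polychoric for ordinal columns
        and Pearson otherwise (see :func:`symptomnet.correlations.correlation_matrix`).
    gamma : EBIC hyperparameter.
    n_lambda, lambda_min_ratio : log-spaced penalty path from lambda_max
        (largest off-diagonal |correlation|) down to ratio * lambda_max.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        method: str = "auto",
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        tol: float = 1e-6,
        max_iter: int = 200,
    ):
        if data.shape[1] < 2:
            raise ValueError("need at least 2 node columns")
        if len(data) <= data.shape[1]:
            warnings.warn(
                f"n={len(data)} does not exceed p={data.shape[1]}; "
                "network estimation may be unstable",
                UserWarning,
            )
        self.data = data
        self.method = method
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.max_iter = max_iter

    @classmethod
    def from_cohort(cls, scored, nodes=None, **kwargs) -> "SymptomNetworkModel":
        """Build from a ScoredCohort, defaulting to the nine PHQ-9 items."""
        from .cohort import PHQ9_COLS

        nodes = list(nodes) if nodes is not None else list(PHQ9_COLS)
        return cls(scored.data[nodes], **kwargs)

    def fit(self, S: CorrelationMatrix | None = None) -> SymptomNetworkResult:
        """Estimate the network: glasso path, EBIC selection.

        ``S`` may supply a precomputed correlation matrix (same columns).
        """
        if S is None:
            S = correlation_matrix(self.data, method=self.method)
        Sm = S.to_numpy()
        n = S.n
        p = Sm.shape[0]
        lam_max = float(np.max(np.abs(Sm - np.diag(np.diag(Sm)))))
        lam_max = max(lam_max, 1e-4)
        lambdas = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambda)
        Ks, _, convs = glasso_path(Sm, lambdas, tol=self.tol, max_iter=self.max_iter)
        if not convs.any():
            raise RuntimeError("graphical lasso failed to converge at every penalty")

        sign, logdets = np.linalg.slogdet(Ks)
        traces = np.einsum("ij,lji->l", Sm, Ks)
        partial_stack = np.array([_partials(K) for K in Ks])
        iu = np.triu_indices(p, 1)
        counts = (np.abs(partial_stack[:, iu[0], iu[1]]) > EDGE_EPS).sum(axis=1)
        with np.errstate(invalid="ignore"):
            L = (n / 2.0) * (logdets - traces)
        scores = -2.0 * L + counts * np.log(n) + 4.0 * self.gamma * counts * np.log(p)
        scores = np.where(convs & (sign > 0), scores, np.inf)

        best = int(np.argmin(scores))  # ties -> largest lambda (sparsest)
        monotone = bool(np.all(np.diff(counts[convs]) >= 0))
        if not monotone:
            warnings.warn(
                "edge count not monotone along the penalty path", UserWarning
            )
        path = pd.DataFrame(
            {
                "lambda": lambdas,
                "ebic": scores,
                "n_edges": counts,
                "converged": convs,
            }
        )
        nodes = list(self.data.columns)
        return SymptomNetworkResult(
            weights=pd.DataFrame(partial_stack[best], index=nodes, columns=nodes),
            precision=Ks[best],
            correlation=S,
            lambda_=float(lambdas[best]),
            gamma=self.gamma,
            ebic_value=float(scores[best]),
            n=n,
            path=path,
            path_monotone=monotone,
        )


def ebic_glasso(
    data: pd.DataFrame,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    method: str = "auto",
    **kwargs,
) -> SymptomNetworkResult:
    """Estimate a partial-correlation network with EBIC penalty selection."""
    model = SymptomNetworkModel(
        data,
        method=method,
        gamma=gamma,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        **{k: v for k, v in kwargs.items() if k in ("tol", "max_iter")},
    )
    return model.fit(S=kwargs.get("S"))


@dataclass(frozen=True)
class AdjustedNetworkResult(SymptomNetworkResult):
    """Covariate-adjusted symptom subnetwork; the joint fit is retained."""

    joint: SymptomNetworkResult = field(default=None)  # type: ignore[assignment]


def adjusted_network(
    data: pd.DataFrame,
    covariates=("gad7_total", "fatigue"),
    mode: str = "joint",
    **kwargs,
) -> AdjustedNetworkResult:
    """Re-estimate the symptom network adjusting for covariates.

    mode "joint" (default) enters the covariates as extra nodes in one joint
    EBIC-gLASSO fit and returns the symptom-symptom subgraph, whose edges are
    then partial correlations conditioned on the covariates as well.  mode
    "residualize" instead regresses each symptom on the covariates and fits
    the network on the residuals (Pearson input).
    """
    covariates = list(covariates)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"covariate(s) not in data: {missing}")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    symptoms = [c for c in data.columns if c not in covariates]

    if mode == "joint":
        joint = ebic_glasso(data[symptoms + covariates], **kwargs)
        sub_w = joint.weights.loc[symptoms, symptoms]
        return AdjustedNetworkResult(
            weights=sub_w,
            precision=joint.precision[: len(symptoms), : len(symptoms)],
            correlation=joint.correlation,
            lambda_=joint.lambda_,
            gamma=joint.gamma,
            ebic_value=joint.ebic_value,
            n=joint.n,
            path=joint.path,
            path_monotone=joint.path_monotone,
            joint=joint,
        )
    if mode == "residualize":
        X = np.column_stack(
            [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in covariates]
        )
        resid = {}
        for s in symptoms:
            y = data[s].to_numpy(dtype=float)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid[s] = y - X @ coef
        kwargs.setdefault("method", "pearson")
        fit = ebic_glasso(pd.DataFrame(resid), **kwargs)
        return AdjustedNetworkResult(
            weights=fit.weights,
            precision=fit.precision,
            correlation=fit.correlation,
            lambda_=fit.lambda_,
            gamma=fit.gamma,
            ebic_value=fit.ebic_value,
            n=fit.n,
            path=fit.path,
            path_monotone=fit.path_monotone,
            joint=fit,
        )
    raise ValueError(f"unknown adjustment mode {mode!r}")
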