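"""Stability and comparison machinery for estimated networks.

Three resampling procedures:

* case-dropping bootstrap — re-estimate the network on subsamples with an
  increasing proportion of respondents dropped and correlate the subsample
  strength vector with the full-sample one; summarized by the
  correlation-stability coefficient (CS-C): the largest drop proportion at
  which that correlation is at least 0.7 with 95% probability (empirical 5th
  percentile).  CS-C >= 0.25 is minimally acceptable, >= 0.5 preferred.
* nonparametric edge bootstrap — row resampling with replacement, percentile
  confidence intervals per edge weight.
* permutation network comparison test (NCT) — two groups' networks compared
  on global strength (sum of absolute upper-triangle weights) and maximum
  absolute edge difference, against a null built by permuting group labels.

All procedures are deterministic under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ebic_glasso

__all__ = [
    "StabilityResult",
    "case_drop_bootstrap",
    "cs_coefficient",
    "EdgeBootstrapResult",
    "edge_bootstrap",
    "NCTResult",
    "network_comparison_test",
]

DEFAULT_PROPORTIONS = np.round(np.arange(0.05, 0.751, 0.05), 2)


@dataclass(frozen=True)
class StabilityResult:
    """Case-dropping bootstrap correlations between subsample and full strengths."""

    proportions: np.ndarray        # strictly increasing drop proportions
    correlations: np.ndarray       # (len(proportions), B), NaN = failed replicate
    B: int
    seed: int | None
    n_failed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for qi, q in enumerate(self.proportions):
            for b in range(self.B):
                rows.append((q, b, self.correlations[qi, b]))
        return pd.DataFrame(rows, columns=["proportion", "replicate", "correlation"])

    def summary_curve(self) -> pd.DataFrame:
        """Median and 5th/95th percentile correlation per drop proportion."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(self.correlations, axis=1)
            q05 = np.nanpercentile(self.correlations, 5, axis=1)
            q95 = np.nanpercentile(self.correlations, 95, axis=1)
        return pd.DataFrame(
            {"proportion": self.proportions, "median": med, "q05": q05, "q95": q95}
        )


def _strength_vec(fit) -> np.ndarray:
    return np.sum(np.abs(fit.weights.to_numpy()), axis=1)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(
    data: pd.DataFrame,
    proportions=DEFAULT_PROPORTIONS,
    B: int = 1000,
    seed: int | None = None,
    **estimator_kwargs,
) -> StabilityResult:
    """Case-dropping bootstrap of strength-centrality stability.

    For each drop proportion q and each of B replicates, a subsample of
    ceil(n(1-q)) rows is drawn without replacement, the network re-estimated
    with the same settings, and the Pearson correlation between the
    subsample and full-sample strength vectors recorded.  Failed replicates
    (estimation error or zero-variance strengths) are recorded as NaN.
    """
    proportions = np.asarray(proportions, dtype=float)
    if not (np.all(np.diff(proportions) > 0) and proportions[0] > 0 and proportions[-1] < 1):
        raise ValueError("proportions must be strictly increasing within (0, 1)")
    n = len(data)
    p = data.shape[1]
    if n * (1 - proportions[-1]) <= p:
        raise ValueError(
            f"largest drop proportion leaves <= p rows (n={n}, p={p})"
        )
    estimator_kwargs.setdefault("method", "pearson")
    full = ebic_glasso(data, **estimator_kwargs)
    s_full = _strength_vec(full)
    rng = np.random.default_rng(seed)
    corrs = np.full((len(proportions), B), np.nan)
    n_failed = 0
    values = data.reset_index(drop=True)
    for qi, q in enumerate(proportions):
        m = int(np.ceil(n * (1 - q)))
        for b in range(B):
            idx = rng.choice(n, size=m, replace=False)
            try:
                fit = ebic_glasso(values.iloc[idx], **estimator_kwargs)
                corrs[qi, b] = _safe_corr(_strength_vec(fit), s_full)
            except Exception:
                pass
            if not np.isfinite(corrs[qi, b]):
                n_failed += 1
    return StabilityResult(
        proportions=proportions, correlations=corrs, B=B, seed=seed, n_failed=n_failed
    )


def cs_coefficient(
    result: StabilityResult, r_threshold: float = 0.7, prob: float = 0.95
) -> float:
    """Correlation-stability coefficient.

    The largest drop proportion q on the grid whose empirical
    (1-prob)-quantile of bootstrap correlations is >= r_threshold, i.e.
    P(correlation >= r_threshold) >= prob; 0.0 if no grid point qualifies.
    """
    if result.proportions.size == 0:
        raise ValueError("empty proportion grid")
    cs = 0.0
    for qi, q in enumerate(result.proportions):
        vals = result.correlations[qi]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        if np.percentile(vals, 100.0 * (1.0 - prob)) >= r_threshold:
            cs = max(cs, float(q))
    return cs


@dataclass(frozen=True)
class EdgeBootstrapResult:
    """Per-edge nonparametric bootstrap means and percentile CIs."""

    table: pd.DataFrame  # node_a, node_b, sample, boot_mean, ci_lower, ci_upper
    B: int
    seed: int | None
    n_failed: int


def edge_bootstrap(
    data: pd.DataFrame, B: int = 1000, seed: int | None = None, **estimator_kwargs
) -> EdgeBootstrapResult:
    """Row-resampling bootstrap of edge weights with 95% percentile CIs."""
    if B < 100:
        raise ValueError("B must be >= 100 for percentile intervals")
    estimator_kwargs.setdefault("method", "pearson")
    full = ebic_glasso(data, **estimator_kwargs)
    nodes = full.nodes
    p = len(nodes)
    iu = np.triu_indices(p, 1)
    W_full = full.weights.to_numpy()[iu]
    rng = np.random.default_rng(seed)
    n = len(data)
    values = data.reset_index(drop=True)
    draws = np.full((B, len(W_full)), np.nan)
    n_failed = 0
    for b in range(B):
        idx = rng.choice(n, size=n, replace=True)
        try:
            fit = ebic_glasso(values.iloc[idx], **estimator_kwargs)
            draws[b] = fit.weights.to_numpy()[iu]
        except Exception:
            n_failed += 1
    ok = np.isfinite(draws).all(axis=1)
    table = pd.DataFrame(
        {
            "node_a": [nodes[i] for i in iu[0]],
            "node_b": [nodes[j] for j in iu[1]],
            "sample": W_full,
            "boot_mean": draws[ok].mean(axis=0),
            "boot_median": np.median(draws[ok], axis=0),
            "ci_lower": np.percentile(draws[ok], 2.5, axis=0),
            "ci_upper": np.percentile(draws[ok], 97.5, axis=0),
        }
    )
    return EdgeBootstrapResult(table=table, B=B, seed=seed, n_failed=n_failed)


@dataclass(frozen=True)
class NCTResult:
    """Permutation network-comparison test between two groups."""

    global_strength_diff: float
    max_edge_diff: float
    p_global_strength: float
    p_max_edge: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "global_strength_diff": self.global_strength_diff,
            "max_edge_diff": self.max_edge_diff,
            "p_global_strength": self.p_global_strength,
            "p_max_edge": self.p_max_edge,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _nct_stats(W_a: np.ndarray, W_b: np.ndarray) -> tuple[float, float]:
    p = W_a.shape[0]
    iu = np.triu_indices(p, 1)
    gs = abs(np.sum(np.abs(W_a[iu])) - np.sum(np.abs(W_b[iu])))
    me = float(np.max(np.abs(W_a - W_b))) if p else 0.0
    return float(gs), me


def network_comparison_test(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    **estimator_kwargs,
) -> NCTResult:
    """Permutation test of network invariance between two groups.

    Networks are estimated per group with identical settings; the observed
    global-strength difference and maximum absolute edge difference are
    referred to a null distribution built by pooling rows and permuting group
    labels at the original group sizes.  p-values use the add-one rule
    ``(1 + #{perm >= observed}) / (1 + n_perm)`` and so are never exactly 0.
    """
    if list(data_a.columns) != list(data_b.columns):
        raise ValueError("both groups must share the same node columns")
    p = data_a.shape[1]
    if len(data_a) <= p or len(data_b) <= p:
        raise ValueError("each group needs more rows than nodes")
    estimator_kwargs.setdefault("method", "pearson")

    fit_a = ebic_glasso(data_a, **estimator_kwargs)
    fit_b = ebic_glasso(data_b, **estimator_kwargs)
    obs_gs, obs_me = _nct_stats(fit_a.weights.to_numpy(), fit_b.weights.to_numpy())

    pooled = pd.concat([data_a, data_b], ignore_index=True)
    n_a = len(data_a)
    n = len(pooled)
    rng = np.random.default_rng(seed)
    ge_gs = 0
    ge_me = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pa = pooled.iloc[perm[:n_a]]
        pb = pooled.iloc[perm[n_a:]]
        fa = ebic_glasso(pa, **estimator_kwargs)
        fb = ebic_glasso(pb, **estimator_kwargs)
        gs, me = _nct_stats(fa.weights.to_numpy(), fb.weights.to_numpy())
        if gs >= obs_gs:
            ge_gs += 1
        if me >= obs_me:
            ge_me += 1
    return NCTResult(
        global_strength_diff=obs_gs,
        max_edge_diff=obs_me,
        p_global_strength=(1 + ge_gs) / (1 + n_perm),
        p_max_edge=(1 + ge_me) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
    )
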