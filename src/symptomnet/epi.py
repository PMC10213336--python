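"""Epidemiological layer: prevalence, group comparisons, logistic regression, ANCOVA.

Conventions follow common survey-epidemiology reporting practice: Wald
normal-approximation confidence interval for a prevalence (Wilson available
as an option), Pearson chi-square without continuity correction, pooled-
variance two-sample t (df = n1 + n2 - 2), Wilcoxon rank-sum with mid-ranks
and tie-corrected normal approximation (no continuity correction), Wald
intervals exp(beta +/- z * SE) for odds ratios, and a partial F for the group
term of the ANCOVA (for a single-df group term, F = t^2).  Two-sided tests
at 0.05 throughout; no multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "prevalence_wald_ci",
    "ContingencyTable",
    "pearson_chi2",
    "pooled_t_test",
    "pooled_t_test_raw",
    "wilcoxon_rank_sum",
    "LogisticResult",
    "fit_logistic",
    "AncovaResult",
    "ancova_group_effect",
]

_Z975 = stats.norm.ppf(0.975)


def prevalence_wald_ci(
    k: int, n: int, alpha: float = 0.05, method: str = "wald"
) -> tuple[float, float, float]:
    """Proportion with a (1-alpha) confidence interval, as proportions in [0, 1].

    method "wald": p -/+ z * sqrt(p(1-p)/n), clipped to [0, 1];
    method "wilson": the Wilson score interval.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    elif method == "wilson":
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = centre - half, centre + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return p, lo, hi


@dataclass(frozen=True)
class ContingencyTable:
    """r x c cross-tabulated counts with labels."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    @classmethod
    def from_counts(cls, counts, row_labels=None, col_labels=None) -> "ContingencyTable":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise ValueError("counts must be nonnegative integers")
        if counts.sum() == 0:
            raise ValueError("table total must be > 0")
        r, c = counts.shape
        return cls(
            counts=counts.astype(np.int64),
            row_labels=list(row_labels) if row_labels else [f"r{i}" for i in range(r)],
            col_labels=list(col_labels) if col_labels else [f"c{j}" for j in range(c)],
        )

    @classmethod
    def crosstab(cls, a: pd.Series, b: pd.Series) -> "ContingencyTable":
        tab = pd.crosstab(a, b)
        return cls.from_counts(
            tab.to_numpy(), [str(x) for x in tab.index], [str(x) for x in tab.columns]
        )


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, without continuity correction.

    Returns (chi2, df, p) with df = (r-1)(c-1).  A zero row or column margin
    raises, since expected counts are then undefined.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else None
    if counts is None:
        counts = ContingencyTable.from_counts(table).counts
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("zero row/column margin: expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t), n1 + n2 - 2, float(p)


def pooled_t_test_raw(x, y) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from raw data; matches the summary variant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), x.size + y.size - 2, float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum Z with mid-ranks and tie-corrected normal approximation.

    No continuity correction; two-sided p.  If every value is identical the
    statistic is degenerate: returns Z = 0 (p = 1) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # mid-ranks for ties
    R1 = ranks[:n1].sum()
    mu = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        warnings.warn(
            "all values identical across both samples; rank-sum Z degenerate",
            RuntimeWarning,
        )
        return 0.0, 1.0
    z = (R1 - mu) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class LogisticResult:
    """Multiple logistic regression fit: one row per term.

    ``table`` columns: coef, se, p, OR, ci_lower, ci_upper (Wald, 95%).
    """

    table: pd.DataFrame
    converged: bool
    separation_warning: bool
    n: int
    llf: float

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "OR"])

    def summary(self) -> str:
        lines = [
            f"Logistic regression (n={self.n}, logL={self.llf:.2f}, "
            f"converged={self.converged})",
            f"{'term':<28}{'OR':>8}{'95% CI':>18}{'p':>10}",
        ]
        for term, r in self.table.iterrows():
            lines.append(
                f"{term:<28}{r.OR:>8.2f}"
                f"{f'{r.ci_lower:.2f}-{r.ci_upper:.2f}':>18}{r.p:>10.3g}"
            )
        return "\n".join(lines)


def fit_logistic(outcome, design: pd.DataFrame) -> LogisticResult:
    """Maximum-likelihood logistic regression with Wald odds-ratio CIs.

    ``outcome`` is a 0/1 vector; ``design`` holds the coded covariates (an
    intercept is added).  Non-convergence or quasi-separation is flagged on
    the result rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    X = design.astype(float)
    const_cols = [c for c in X.columns if X[c].nunique() == 1]
    if const_cols:
        raise ValueError(f"constant design column(s): {const_cols}")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("n must exceed the number of parameters")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # singular Hessian: (quasi-)complete separation; BFGS still
            # yields the diverging ML path for a flagged result
            separation = True
            fit = sm.Logit(y, Xc).fit(disp=0, method="bfgs", maxiter=500)
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True
    params = fit.params
    se = fit.bse
    if separation or np.any(np.abs(params) > 30):
        separation = True
        warnings.warn(
            "possible complete separation: some coefficients diverge",
            RuntimeWarning,
        )
    zcrit = _Z975
    table = pd.DataFrame(
        {
            "coef": params,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(params / se)),
            "OR": np.exp(params),
            "ci_lower": np.exp(params - zcrit * se),
            "ci_upper": np.exp(params + zcrit * se),
        }
    )
    return LogisticResult(
        table=table,
        converged=bool(fit.mle_retvals.get("converged", True)),
        separation_warning=separation,
        n=len(y),
        llf=float(fit.llf),
    )


@dataclass(frozen=True)
class AncovaResult:
    """Partial-F test for the group effect in a covariate-adjusted linear model."""

    F: float
    df_num: int
    df_den: int
    p: float
    adjusted_means: dict

    def summary(self) -> str:
        return (
            f"ANCOVA group effect: F({self.df_num}, {self.df_den}) = {self.F:.2f}, "
            f"p = {self.p:.3g}; adjusted means: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.adjusted_means.items())
        )


def _aliased_columns(X: np.ndarray, names) -> list[str]:
    aliased = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            aliased.append(names[j])
    return aliased


def ancova_group_effect(y, group, covariates: pd.DataFrame | None = None) -> AncovaResult:
    """ANCOVA: linear model y ~ group + covariates, partial F for group.

    With a single-df binary group the partial (Type-III) F equals the squared
    t of the group coefficient.  Adjusted group means are predictions at the
    covariate means.  A rank-deficient design raises, naming aliased columns.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    if not np.isin(g, [0.0, 1.0]).all():
        raise ValueError("group must be binary 0/1")
    parts = [pd.Series(g, name="group")]
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates.astype(float).reset_index(drop=True))
    X = pd.concat(parts, axis=1)
    Xc = sm.add_constant(X, has_constant="add")
    Xm = Xc.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        aliased = _aliased_columns(Xm, list(Xc.columns))
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y, Xc).fit()
    t = fit.tvalues["group"]
    F = float(t**2)
    df_den = int(fit.df_resid)
    p = float(stats.f.sf(F, 1, df_den))
    means = Xc.mean()
    at0, at1 = means.copy(), means.copy()
    at0["group"] = 0.0
    at1["group"] = 1.0
    adjusted = {
        "group=0": float(fit.params @ at0),
        "group=1": float(fit.params @ at1),
    }
    return AncovaResult(F=F, df_num=1, df_den=df_den, p=p, adjusted_means=adjusted)
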