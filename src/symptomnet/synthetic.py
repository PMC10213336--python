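"""Synthetic guardian cohorts with a known latent network structure.

The generator implements the latent-Gaussian threshold (probit) measurement
model: ordinal item responses arise by cutting latent multivariate-normal
symptom dimensions at fixed thresholds.  This is exactly the model under
which the polychoric correlation is consistent, so parameter recovery by the
downstream network estimator is a meaningful test.

Ground truth is a sparse precision matrix over the latent dimensions (nine
depressive symptoms, optionally a QOL dimension); its implied partial
correlations are what the network estimator should recover.  Covariate
effects couple a shared anxiety factor and a fatigue factor into the symptom
latents (so anxiety/fatigue predict depression, as in real guardian
samples), and depression status depresses the QOL item latents.  Demographic
covariates are drawn from configurable marginals typical of a Chinese
guardian sample (40.1% male, 82.0% married, ...).

Default thresholds are calibrated so that the PHQ-9 >= 5 prevalence is close
to one third.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import CohortTable, PHQ9_COLS, GAD7_COLS

__all__ = [
    "TruthNetwork",
    "build_truth_network",
    "truth_from_partials",
    "random_partial_truth",
    "default_truth",
    "CovariateEffects",
    "GeneratorConfig",
    "generate_cohort",
    "generate_default_cohort",
]


@dataclass(frozen=True)
class TruthNetwork:
    """Ground-truth Gaussian graphical model over latent dimensions."""

    precision: np.ndarray
    labels: list[str]

    def __post_init__(self):
        K = np.asarray(self.precision, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1] or K.shape[0] < 2:
            raise ValueError("precision must be square with p >= 2")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("precision must be positive definite")
        object.__setattr__(self, "precision", (K + K.T) / 2.0)

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def partials(self) -> np.ndarray:
        K = self.precision
        d = np.sqrt(np.diag(K))
        P = -K / np.outer(d, d)
        np.fill_diagonal(P, 0.0)
        return P

    @property
    def support(self) -> np.ndarray:
        mask = np.abs(self.partials) > 1e-12
        np.fill_diagonal(mask, False)
        return mask

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the latent dimensions (inverse precision, scaled)."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.precision, 12).tobytes())
        h.update(",".join(self.labels).encode())
        return h.hexdigest()[:16]


def build_truth_network(
    p: int,
    edge_density: float,
    weight_low: float,
    weight_high: float,
    seed: int | None = None,
    labels=None,
) -> TruthNetwork:
    """Random sparse truth network, positive definite by diagonal dominance.

    Upper-triangle support is Bernoulli(edge_density); nonzero entries have
    magnitude Uniform[weight_low, weight_high] with random sign; the diagonal
    is 1 plus each row's absolute off-diagonal sum.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    if not 0 < weight_low <= weight_high:
        raise ValueError("need 0 < weight_low <= weight_high")
    rng = np.random.default_rng(seed)
    K = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    on = rng.random(len(iu[0])) < edge_density
    mags = rng.uniform(weight_low, weight_high, len(iu[0]))
    signs = rng.choice([-1.0, 1.0], len(iu[0]))
    K[iu] = on * mags * signs
    K = K + K.T
    np.fill_diagonal(K, 1.0 + np.sum(np.abs(K), axis=1))
    labels = list(labels) if labels else [f"L{i + 1}" for i in range(p)]
    return TruthNetwork(precision=K, labels=labels)


def truth_from_partials(p: int, edges: dict, labels=None) -> TruthNetwork:
    """Truth network from explicit partial correlations.

    ``edges`` maps (i, j) index pairs to partial correlations r; the
    precision has unit diagonal and off-diagonal -r, so the implied partials
    equal r exactly.  Raises if the result is not positive definite.
    """
    K = np.eye(p)
    for (i, j), r in edges.items():
        K[i, j] = K[j, i] = -r
    labels = list(labels) if labels else [f"L{i + 1}" for i in range(p)]
    return TruthNetwork(precision=K, labels=labels)


def random_partial_truth(
    p: int,
    n_edges: int,
    weight_low: float = 0.2,
    weight_high: float = 0.4,
    seed: int | None = None,
    signed: bool = False,
    max_row_sum: float = 0.95,
) -> TruthNetwork:
    """Random truth network whose partial correlations hit an exact range.

    Edges are added one at a time (uniformly over free pairs) with magnitude
    Uniform[weight_low, weight_high], rejecting any edge that would push a
    row's absolute off-diagonal sum past ``max_row_sum`` — strict diagonal
    dominance then guarantees positive definiteness while keeping the implied
    partials exactly at their nominal values (unit-diagonal precision).
    """
    if p < 2 or n_edges < 1:
        raise ValueError("need p >= 2 and n_edges >= 1")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[int, int], float] = {}
    row = np.zeros(p)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    rng.shuffle(pairs)
    for i, j in pairs:
        if len(edges) == n_edges:
            break
        w = rng.uniform(weight_low, weight_high)
        if signed and rng.random() < 0.5:
            w = -w
        if row[i] + abs(w) > max_row_sum or row[j] + abs(w) > max_row_sum:
            continue
        edges[(i, j)] = w
        row[i] += abs(w)
        row[j] += abs(w)
    if len(edges) < n_edges:
        raise ValueError("could not place the requested edges under the row-sum cap")
    return truth_from_partials(p, edges)


#: default ground truth: 9 symptom dimensions chained with a few shortcuts,
#: plus a QOL dimension most strongly tied (negatively) to guilt (6),
#: concentration (7) and sleep (3).
_DEFAULT_EDGES = {
    (0, 1): 0.25, (1, 2): 0.25, (2, 3): 0.25, (3, 4): 0.25, (4, 5): 0.25,
    (5, 6): 0.20, (6, 7): 0.20, (7, 8): 0.25,
    (1, 3): 0.20, (3, 6): 0.20,
    (2, 9): -0.15, (5, 9): -0.20, (6, 9): -0.17,
}


def default_truth() -> TruthNetwork:
    return truth_from_partials(
        10, _DEFAULT_EDGES, labels=[f"DEP-{i}" for i in range(1, 10)] + ["QOL"]
    )


@dataclass(frozen=True)
class CovariateEffects:
    """Coupling coefficients of the generative model.

    anxiety_to_symptoms / fatigue_to_symptoms: loading of the shared anxiety
    and fatigue factors onto every symptom latent (before re-standardizing).
    depression_to_qol: downward shift of the QOL item latents for depressed
    respondents.  All zero makes depression independent of QOL.
    """

    anxiety_to_symptoms: float = 0.35
    fatigue_to_symptoms: float = 0.25
    depression_to_qol: float = 0.6


# thresholds calibrated against the default truth + covariate effects:
# PHQ cuts give P(PHQ-9 total >= 5) ~ 1/3; GAD/fatigue/QOL cuts reproduce
# plausible guardian-sample margins (GAD-7 mean ~3, fatigue mean ~3.1,
# global QOL mean ~6.6)
DEFAULT_THRESHOLDS = {
    "phq": np.array([0.55, 1.25, 1.95]),
    "gad": np.array([0.674, 1.175, 1.645]),
    "fatigue": np.array([(k + 0.5 - 3.1) / 2.5 for k in range(10)]),
    "qol": np.array([(k + 0.5 - 3.3) / 1.2 for k in range(1, 5)]),
}

DEFAULT_DEMOGRAPHICS = {
    "male": 0.401,
    "married": 0.820,
    "employed": 0.812,
    "senior_or_above": 0.615,
    "rural": 0.425,
    "physical_disease": 0.047,
    "visit_difficulty": 0.297,
    "medication_compliance_good": 0.704,
    "financial_status": {"poor": 0.213, "fair": 0.690, "good": 0.097},
    "social_media_freq": {"none_minimal": 0.077, "sometimes": 0.323, "often": 0.599},
    "diagnosis": {"mdd": 0.363, "bipolar": 0.147, "schizophrenia": 0.202, "other": 0.288},
    "age_mean": 43.1,
    "age_sd": 11.6,
    "age_min": 18.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic cohort."""

    n: int = 1101
    truth: TruthNetwork = field(default_factory=default_truth)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    effects: CovariateEffects = field(default_factory=CovariateEffects)
    demographics: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    gad_loading: float = 0.7
    qol_loading: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.truth.p < 9:
            raise ValueError("truth network needs at least the 9 symptom dimensions")
        for key, cuts in self.thresholds.items():
            cuts = np.asarray(cuts, dtype=float)
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"thresholds for {key!r} must be strictly increasing")

    def manifest(self) -> dict:
        d = {
            "n": self.n,
            "seed": self.seed,
            "truth_hash": self.truth.content_hash(),
            "truth_labels": self.truth.labels,
            "effects": asdict(self.effects),
            "thresholds": {k: list(np.asarray(v, float)) for k, v in self.thresholds.items()},
            "gad_loading": self.gad_loading,
            "qol_loading": self.qol_loading,
        }
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.manifest(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _threshold_items(z: np.ndarray, cuts: np.ndarray, offset: int = 0) -> np.ndarray:
    """item value = number of thresholds below the latent, plus category offset."""
    return (z[..., None] > cuts).sum(axis=-1) + offset


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw one cohort under the latent-threshold model; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    truth = config.truth
    R = truth.latent_correlation()
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, truth.p)) @ L.T

    anx = rng.standard_normal(n)
    fat = rng.standard_normal(n)
    aa = config.effects.anxiety_to_symptoms
    af = config.effects.fatigue_to_symptoms
    scale = np.sqrt(1.0 + aa**2 + af**2)
    zs = (Z[:, :9] + aa * anx[:, None] + af * fat[:, None]) / scale

    df = pd.DataFrame()
    phq = _threshold_items(zs, np.asarray(config.thresholds["phq"], float))
    for i, col in enumerate(PHQ9_COLS):
        df[col] = phq[:, i]

    lam = config.gad_loading
    g_noise = rng.standard_normal((n, 7))
    g_lat = lam * anx[:, None] + np.sqrt(1 - lam**2) * g_noise
    gad = _threshold_items(g_lat, np.asarray(config.thresholds["gad"], float))
    for i, col in enumerate(GAD7_COLS):
        df[col] = gad[:, i]

    df["fatigue"] = _threshold_items(fat, np.asarray(config.thresholds["fatigue"], float))

    depressed = (phq.sum(axis=1) >= 5).astype(float)
    dep_c = depressed - depressed.mean()
    if "QOL" in truth.labels:
        zq = Z[:, truth.labels.index("QOL")]
    else:
        zq = rng.standard_normal(n)
    rho = config.qol_loading
    beta = config.effects.depression_to_qol
    q_noise = rng.standard_normal((n, 2))
    q_lat = rho * zq[:, None] + np.sqrt(1 - rho**2) * q_noise - beta * dep_c[:, None]
    qol = _threshold_items(q_lat, np.asarray(config.thresholds["qol"], float), offset=1)
    df["qol_1"] = qol[:, 0]
    df["qol_2"] = qol[:, 1]

    dem = config.demographics
    ages = rng.normal(dem["age_mean"], dem["age_sd"], size=n)
    # resample below the floor rather than clip, keeping the shape realistic
    for _ in range(20):
        bad = ages < dem["age_min"]
        if not bad.any():
            break
        ages[bad] = rng.normal(dem["age_mean"], dem["age_sd"], size=bad.sum())
    df["age"] = np.round(np.maximum(ages, dem["age_min"]), 1)
    df["sex"] = np.where(rng.random(n) < dem["male"], "male", "female")
    df["married"] = (rng.random(n) < dem["married"]).astype(int)
    df["employed"] = (rng.random(n) < dem["employed"]).astype(int)
    df["rural"] = (rng.random(n) < dem["rural"]).astype(int)
    df["physical_disease"] = (rng.random(n) < dem["physical_disease"]).astype(int)
    df["visit_difficulty"] = (rng.random(n) < dem["visit_difficulty"]).astype(int)
    df["medication_compliance_good"] = (
        rng.random(n) < dem["medication_compliance_good"]
    ).astype(int)
    df["education"] = np.where(
        rng.random(n) < dem["senior_or_above"], "senior_or_above", "below_senior"
    )
    for col in ("financial_status", "social_media_freq", "diagnosis"):
        levels = list(dem[col].keys())
        probs = np.array(list(dem[col].values()), dtype=float)
        df[col] = rng.choice(levels, size=n, p=probs / probs.sum())
    df["respondent_id"] = [f"R{i + 1:06d}" for i in range(n)]
    return CohortTable.from_dataframe(df)


def generate_default_cohort(n: int = 1101, seed: int = 0) -> CohortTable:
    """Convenience: one cohort under all defaults."""
    return generate_cohort(GeneratorConfig(n=n, seed=seed))
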