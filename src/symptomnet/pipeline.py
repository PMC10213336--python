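"""End-to-end study pipeline: scoring, epidemiology, networks, robustness.

``run_full_analysis`` executes the analysis stages in order — score,
descriptives, logistic regression, ANCOVA, symptom network, centrality,
covariate-adjusted network, stability bootstrap, QOL flow network, and the
optional depressed-subgroup network with a permutation comparison test — and
writes every artifact to the output directory.  Outputs are deterministic:
identical config and seed give byte-identical CSV/JSON files (stage wall
times go to the log, never into artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    BOOL_COLS,
    CATEGORICAL_LEVELS,
    PHQ9_COLS,
    ScoredCohort,
    read_cohort_csv,
    score_cohort,
)
from .epi import (
    ContingencyTable,
    ancova_group_effect,
    fit_logistic,
    pearson_chi2,
    pooled_t_test_raw,
    prevalence_wald_ci,
    wilcoxon_rank_sum,
)
from .metrics import flow_edges, strength_centrality
from .network import adjusted_network, ebic_glasso
from .robustness import (
    DEFAULT_PROPORTIONS,
    case_drop_bootstrap,
    cs_coefficient,
    network_comparison_test,
)
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_analysis", "logistic_design"]

log = logging.getLogger("symptomnet")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one full analysis run."""

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    outdir: str = "symptomnet_out"
    cutoff: int = 5
    gamma: float = 0.5
    n_lambda: int = 100
    network_method: str = "auto"      # correlation input of the reported networks
    resample_method: str = "pearson"  # correlation input inside bootstrap/NCT loops
    boot_B: int = 1000
    boot_proportions: tuple = tuple(DEFAULT_PROPORTIONS)
    n_perm: int = 1000
    seed: int = 0
    subgroup_depressed: bool = False

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.input_csv is None and self.generator is None:
            object.__setattr__(self, "generator", GeneratorConfig(seed=self.seed))

    def to_dict(self) -> dict:
        """Analysis-relevant settings; file-system plumbing (outdir) excluded."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        if self.generator is not None:
            d["generator"] = self.generator.manifest()
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory handles plus file paths for every pipeline artifact."""

    scored: ScoredCohort
    prevalence: dict
    descriptives: pd.DataFrame | None
    logistic: object | None
    ancova: object | None
    network: object
    centrality: pd.DataFrame
    adjusted: object
    adjusted_comparison: dict
    stability: object
    cs: float
    flow: object
    subgroup_network: object | None
    nct: object | None
    manifest: dict
    paths: dict


def logistic_design(scored: ScoredCohort) -> pd.DataFrame:
    """Covariate coding of the depression model.

    age continuous; female indicator; physical disease; financial poor vs
    fair/good; social media often vs else; visit difficulty; GAD-7 total;
    fatigue; diagnosis dummies with "other" reference; compliance poor vs
    good.
    """
    df = scored.data
    return pd.DataFrame(
        {
            "age": df["age"].to_numpy(float),
            "female": (df["sex"] == "female").astype(int),
            "physical_disease": df["physical_disease"],
            "financial_poor": (df["financial_status"] == "poor").astype(int),
            "social_media_often": (df["social_media_freq"] == "often").astype(int),
            "visit_difficulty": df["visit_difficulty"],
            "gad7_total": df["gad7_total"],
            "fatigue": df["fatigue"],
            "diag_mdd": (df["diagnosis"] == "mdd").astype(int),
            "diag_bipolar": (df["diagnosis"] == "bipolar").astype(int),
            "diag_schizophrenia": (df["diagnosis"] == "schizophrenia").astype(int),
            "compliance_poor": 1 - df["medication_compliance_good"],
        }
    )


_CATEGORICAL_DESC = [
    ("sex", None),
    ("married", None),
    ("employed", None),
    ("education", None),
    ("rural", None),
    ("physical_disease", None),
    ("financial_status", None),
    ("social_media_freq", None),
    ("visit_difficulty", None),
    ("diagnosis", None),
    ("medication_compliance_good", None),
]


def describe_cohort(scored: ScoredCohort) -> pd.DataFrame:
    """Descriptive table with univariable depressed vs non-depressed tests.

    Categorical variables get a Pearson chi-square; age and global QOL a
    pooled t; GAD-7 total and fatigue a Wilcoxon rank-sum Z (their
    distributions are heavily skewed).
    """
    df = scored.data
    dep = df["depressed"] == 1
    rows = []
    for var, _ in _CATEGORICAL_DESC:
        series = df[var].astype(str)
        levels = (
            list(CATEGORICAL_LEVELS[var])
            if var in CATEGORICAL_LEVELS
            else sorted(series.unique())
        )
        tab = ContingencyTable.crosstab(series, df["depressed"])
        chi2, dfree, p = pearson_chi2(tab)
        for lev in levels:
            sel = series == lev
            rows.append(
                {
                    "variable": var,
                    "level": lev,
                    "total_n": int(sel.sum()),
                    "total_pct": 100.0 * sel.mean(),
                    "nondep_n": int((sel & ~dep).sum()),
                    "dep_n": int((sel & dep).sum()),
                    "test": "chi2",
                    "statistic": chi2,
                    "df": dfree,
                    "p": p,
                }
            )
    for var, test in [
        ("age", "t"),
        ("gad7_total", "wilcoxon"),
        ("fatigue", "wilcoxon"),
        ("qol_global", "t"),
    ]:
        x = df.loc[~dep, var]
        y = df.loc[dep, var]
        if test == "t":
            stat, dfree, p = pooled_t_test_raw(x, y)
        else:
            stat, p = wilcoxon_rank_sum(x, y)
            dfree = np.nan
        rows.append(
            {
                "variable": var,
                "level": "",
                "total_n": len(df),
                "total_pct": 100.0,
                "nondep_n": int((~dep).sum()),
                "dep_n": int(dep.sum()),
                "test": test,
                "statistic": stat,
                "df": dfree,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=float) + "\n")


def _stamp(obj: dict, config: AnalysisConfig) -> dict:
    obj["config_hash"] = config.content_hash()
    obj["seed"] = config.seed
    return obj


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every analysis stage and persist the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage_t0 = time.perf_counter()

    def _done(stage: str):
        nonlocal stage_t0
        log.info("stage %-22s %.2fs", stage, time.perf_counter() - stage_t0)
        stage_t0 = time.perf_counter()

    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
    boot_seed, perm_seed = int(seeds[1]), int(seeds[2])

    try:
        stage = "load"
        if config.input_csv is not None:
            table = read_cohort_csv(config.input_csv)
        else:
            table = generate_cohort(config.generator)
        _done(stage)

        stage = "score"
        scored = score_cohort(table, cutoff=config.cutoff)
        paths["scored_cohort"] = outdir / "scored_cohort.csv"
        scored.data.to_csv(paths["scored_cohort"], index=False)
        prop, lo, hi = prevalence_wald_ci(scored.n_depressed, scored.n)
        prevalence = _stamp(
            {
                "n": scored.n,
                "n_depressed": scored.n_depressed,
                "n_nondepressed": scored.n_nondepressed,
                "prevalence_pct": round(100 * prop, 1),
                "ci_lower_pct": round(100 * lo, 1),
                "ci_upper_pct": round(100 * hi, 1),
                "cutoff": config.cutoff,
                "n_dropped_incomplete": scored.n_dropped,
            },
            config,
        )
        paths["prevalence"] = outdir / "prevalence.json"
        _write_json(paths["prevalence"], prevalence)
        _done(stage)

        degenerate = scored.n_depressed == 0 or scored.n_nondepressed == 0
        descriptives = logistic = ancova = None
        if degenerate:
            warnings.warn(
                "depressed/non-depressed split is degenerate; skipping group "
                "comparisons, logistic regression and ANCOVA",
                UserWarning,
            )
        else:
            stage = "describe"
            descriptives = describe_cohort(scored)
            paths["descriptives"] = outdir / "table1_descriptives.csv"
            descriptives.to_csv(paths["descriptives"], index=False)
            _done(stage)

            stage = "logit"
            design = logistic_design(scored)
            design = design[[c for c in design.columns if design[c].nunique() > 1]]
            logistic = fit_logistic(scored.data["depressed"], design)
            paths["logistic"] = outdir / "logistic_table.csv"
            logistic.table.to_csv(paths["logistic"])
            _done(stage)

            stage = "ancova"
            covs = design.drop(columns=["gad7_total", "fatigue"], errors="ignore")
            covs = pd.concat(
                [covs.reset_index(drop=True),
                 scored.data[["gad7_total", "fatigue"]].reset_index(drop=True)],
                axis=1,
            )
            ancova = ancova_group_effect(
                scored.data["qol_global"], scored.data["depressed"], covs
            )
            paths["ancova"] = outdir / "ancova.json"
            _write_json(
                paths["ancova"],
                _stamp(
                    {
                        "F": ancova.F,
                        "df_num": ancova.df_num,
                        "df_den": ancova.df_den,
                        "p": ancova.p,
                        "adjusted_means": ancova.adjusted_means,
                    },
                    config,
                ),
            )
            _done(stage)

        stage = "network"
        items = scored.data[PHQ9_COLS]
        network = ebic_glasso(
            items,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            method=config.network_method,
        )
        paths["network_edges"] = outdir / "network_edges.csv"
        network.edge_list().to_csv(paths["network_edges"], index=False)
        paths["network_adjacency"] = outdir / "network_adjacency.csv"
        network.weights.to_csv(paths["network_adjacency"])
        paths["network_meta"] = outdir / "network_meta.json"
        _write_json(paths["network_meta"], _stamp(network.metadata(), config))
        _done(stage)

        stage = "centrality"
        centrality = strength_centrality(network)
        paths["centrality"] = outdir / "centrality.csv"
        centrality.to_csv(paths["centrality"])
        _done(stage)

        stage = "adjusted_network"
        adj_data = scored.data[PHQ9_COLS + ["gad7_total", "fatigue"]]
        adjusted = adjusted_network(
            adj_data,
            covariates=("gad7_total", "fatigue"),
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            method=config.network_method,
        )
        paths["adjusted_edges"] = outdir / "adjusted_edges.csv"
        adjusted.edge_list().to_csv(paths["adjusted_edges"], index=False)
        adj_centrality = strength_centrality(adjusted)
        top3_before = list(centrality.sort_values("rank").index[:3])
        top3_after = list(adj_centrality.sort_values("rank").index[:3])
        adjusted_comparison = _stamp(
            {
                "top3_unadjusted": top3_before,
                "top3_adjusted": top3_after,
                "identical_top3": top3_before == top3_after,
            },
            config,
        )
        paths["adjusted_comparison"] = outdir / "adjusted_comparison.json"
        _write_json(paths["adjusted_comparison"], adjusted_comparison)
        _done(stage)

        stage = "stability"
        stability = case_drop_bootstrap(
            items,
            proportions=np.asarray(config.boot_proportions),
            B=config.boot_B,
            seed=boot_seed,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            method=config.resample_method,
        )
        cs = cs_coefficient(stability)
        paths["stability_curves"] = outdir / "stability_curves.csv"
        stability.to_dataframe().to_csv(paths["stability_curves"], index=False)
        paths["stability_summary"] = outdir / "stability_summary.json"
        _write_json(
            paths["stability_summary"],
            _stamp(
                {
                    "cs_coefficient": cs,
                    "B": stability.B,
                    "n_failed": stability.n_failed,
                    "bootstrap_seed": boot_seed,
                },
                config,
            ),
        )
        _done(stage)

        stage = "flow"
        flow_data = scored.data[PHQ9_COLS + ["qol_global"]]
        flow_net = ebic_glasso(
            flow_data,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            method=config.network_method,
        )
        flow = flow_edges(flow_net, "qol_global")
        paths["flow_qol"] = outdir / "flow_qol.json"
        _write_json(paths["flow_qol"], _stamp(flow.to_dict(), config))
        _done(stage)

        subgroup_network = nct = None
        if config.subgroup_depressed and not degenerate:
            stage = "subgroup_network"
            dep_items = scored.data.loc[scored.data["depressed"] == 1, PHQ9_COLS]
            if len(dep_items) <= len(PHQ9_COLS):
                warnings.warn(
                    "too few depressed respondents for a subgroup network",
                    UserWarning,
                )
            else:
                subgroup_network = ebic_glasso(
                    dep_items,
                    gamma=config.gamma,
                    n_lambda=config.n_lambda,
                    method=config.network_method,
                )
                paths["subgroup_network_edges"] = outdir / "subgroup_network_edges.csv"
                subgroup_network.edge_list().to_csv(
                    paths["subgroup_network_edges"], index=False
                )
                nondep_items = scored.data.loc[scored.data["depressed"] == 0, PHQ9_COLS]
                nct = network_comparison_test(
                    dep_items,
                    nondep_items,
                    n_perm=config.n_perm,
                    seed=perm_seed,
                    gamma=config.gamma,
                    n_lambda=config.n_lambda,
                    method=config.resample_method,
                )
                paths["nct"] = outdir / "nct.json"
                _write_json(paths["nct"], _stamp(nct.to_dict(), config))
            _done(stage)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "seeds": {
                "master": config.seed,
                "bootstrap": boot_seed,
                "permutation": perm_seed,
            },
            "n": scored.n,
            "n_depressed": scored.n_depressed,
            "artifacts": sorted(str(p.name) for p in paths.values()),
        }
        paths["manifest"] = outdir / "manifest.json"
        _write_json(paths["manifest"], manifest)
        _done(stage)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}; partial outputs kept in "
            f"{outdir}"
        ) from exc

    return ReportBundle(
        scored=scored,
        prevalence=prevalence,
        descriptives=descriptives,
        logistic=logistic,
        ancova=ancova,
        network=network,
        centrality=centrality,
        adjusted=adjusted,
        adjusted_comparison=adjusted_comparison,
        stability=stability,
        cs=cs,
        flow=flow,
        subgroup_network=subgroup_network,
        nct=nct,
        manifest=manifest,
        paths={k: str(v) for k, v in paths.items()},
    )
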