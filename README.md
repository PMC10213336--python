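# symptomnet

Epidemiology and symptom-network analysis for depression screening surveys of
**guardians of hospitalized psychiatric patients** (or similar caregiver
cohorts): per-respondent PHQ-9, GAD-7, fatigue NRS and two-item WHOQOL-BREF
records in, and out come the prevalence of clinically relevant depression
with its confidence interval, univariable group comparisons, a multiple
logistic regression of depression correlates, an ANCOVA of quality of life,
and a regularized partial-correlation network of the nine depressive
symptoms with centrality, stability, covariate-adjustment and group
comparison machinery.

It is written for biostatisticians and psychiatric-epidemiology researchers
who want the whole analysis as tested, reproducible code rather than an
ad-hoc script stack — including a synthetic-cohort generator with a *known*
latent network so every estimator can be validated against ground truth.

## The model

**Screening layer.** Each respondent contributes nine PHQ-9 items
x₁,…,x₉ ∈ {0,…,3}; depression is flagged when Σxᵢ ≥ 5. Prevalence gets a
Wald interval p̂ ± z₀.₉₇₅ √(p̂(1−p̂)/n) (Wilson available). Group contrasts
use Pearson χ² without continuity correction, pooled-variance t tests
(df = n₁+n₂−2), and tie-corrected Wilcoxon rank-sum Z statistics. Adjusted
inference uses maximum-likelihood logistic regression with Wald
odds-ratio intervals exp(β̂ ± z·SE), and ANCOVA with a partial F for the
group term.

**Network layer.** The nine symptoms are nodes of a Gaussian graphical
model: edge weights are partial correlations ω_ij = −κ_ij/√(κ_ii κ_jj)
from a sparse precision matrix K estimated by the graphical lasso,

  K̂(λ) = argmax_{K≻0} log det K − tr(SK) − λ Σ_{i≠j} |K_ij|,

with S a polychoric correlation matrix (the items are ordinal
manifestations of latent Gaussian severities). λ is chosen on a 100-point
log-spaced path by the extended Bayesian information criterion
EBIC = −2L + E ln n + 4γE ln p with γ = 0.5. Node importance is strength
centrality s_i = Σ_j |ω_ij|; its robustness is the correlation-stability
coefficient (CS-C) from a case-dropping bootstrap; anxiety (GAD-7 total) and
fatigue enter as extra nodes for the covariate-adjusted network; a flow
layout ranks the direct edges between global QOL and each symptom; and two
groups' networks are compared by a permutation test on global strength and
maximum edge difference.

## Worked example

```python
import symptomnet as sn

# one synthetic guardian cohort of 1,101 respondents (seeded, reproducible)
scored = sn.score_cohort(sn.generate_default_cohort(n=1101, seed=17))
p, lo, hi = sn.prevalence_wald_ci(scored.n_depressed, scored.n)
print(f"prevalence: {100*p:.1f}% (95% CI {100*lo:.1f}-{100*hi:.1f})")

net = sn.SymptomNetworkModel.from_cohort(scored, method="polychoric").fit()
print(net.summary())
print(net.strength().sort_values("rank").round(3).head(3))
```

prints

```
prevalence: 34.2% (95% CI 31.4-37.0)
Symptom network (EBIC graphical lasso)
========================================
nodes: 9   n: 1101   edges: 25   sparsity: 0.306
lambda: 0.03394   gamma: 0.5   EBIC: 8259.06
correlation input: polychoric

strongest edges:
    phq9_2 -- phq9_3   +0.291
    phq9_8 -- phq9_9   +0.284
    ...

        strength  rank  z_strength
phq9_4     0.942     1       1.376
phq9_7     0.910     2       1.197
phq9_2     0.894     3       1.110
```

About a third of the simulated guardians screen positive for depression, and
the network's strongest symptoms are loss of energy (item 4), concentration
difficulties (item 7) and sad mood (item 2) — the pattern the default
generator's latent truth encodes. Each edge weight is the residual
association between two symptoms after conditioning on the other seven.

The same pipeline runs end to end from the shell:

```bash
symptomnet generate --n 1101 --seed 17 --out cohort.csv
symptomnet analyze --input cohort.csv --out results/ --boot 1000 --seed 17
symptomnet compare --input cohort.csv --group-col depressed --n-perm 1000
```

`analyze` writes a descriptive table, the logistic-regression table, the
ANCOVA summary, edge lists and adjacency matrices for the unadjusted and
anxiety/fatigue-adjusted networks, strength centralities, bootstrap
stability curves with the CS-C, the QOL flow ranking and a provenance
manifest; identical config and seed give byte-identical files.

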