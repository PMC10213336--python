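# Methods

## Scope and data model

The package analyses cross-sectional caregiver survey records: nine PHQ-9
depression items (0–3), seven GAD-7 anxiety items (0–3), a single 0–10
fatigue numeric rating, the first two WHOQOL-BREF items (1–5) summed into a
2–10 global QOL score, and demographic/clinical covariates. A respondent
screens positive for clinically relevant depression when the PHQ-9 total is
at least 5 (configurable). Rows with any missing scale item are dropped
(complete-case) and counted; the package does not impute — surveys of this
kind have near-complete response within submitted questionnaires, and any
imputation model would have to be defended separately.

## Epidemiological layer

* **Prevalence CI** — Wald normal approximation p̂ ± z√(p̂(1−p̂)/n), clipped
  to [0,1]; Wilson score interval available via `method="wilson"`. Wald is
  the default because it is what prevalence reports in this literature print.
* **Chi-square** — Pearson χ² = Σ(O−E)²/E without Yates continuity
  correction, df = (r−1)(c−1). A zero margin is an error (expected counts
  undefined), not a silent drop.
* **t test** — pooled variance, df = n₁+n₂−2, from raw data or summary
  statistics (the two agree to numerical precision; the summary form exists
  so printed tables can be checked).
* **Wilcoxon rank-sum** — mid-ranks, tie-corrected variance
  n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))], normal approximation without
  continuity correction, two-sided p. Samples with zero rank variance return
  Z = 0 with a warning.
* **Logistic regression** — maximum likelihood via statsmodels (Newton
  scoring, equivalent to IRLS), Wald p-values and odds-ratio intervals
  exp(β̂ ± z₀.₉₇₅ SE). A singular Hessian (complete or quasi-complete
  separation) falls back to BFGS and flags the result rather than failing;
  collinear or constant design columns are errors naming the column.
  The default covariate coding: age continuous, female indicator, physical
  disease, financial status poor vs fair/good, social-media use often vs
  less, visit difficulty, GAD-7 total, fatigue, patient-diagnosis dummies
  with "other" as reference, and medication compliance poor vs good.
* **ANCOVA** — linear model QOL ~ group + covariates; the single-df group
  effect is tested by the partial F, computed as the squared t of the group
  coefficient (identical to the Type-III F for a 1-df term), with the
  model's residual df as denominator df. Note that a denominator df can
  never exceed n − 2 in this design; reports that print an error df equal to
  the sample size are typographical, and this package always reports the
  standard residual df. Adjusted group means are predictions at covariate
  means. Rank-deficient designs raise an error listing the aliased columns.

Two-sided α = 0.05 throughout; no multiplicity adjustment (matching the
reporting conventions of the surveys this pipeline mirrors).

## Correlation input

Ordinal items are modelled as thresholded latent Gaussians, so the network
input is by default the **polychoric** correlation for ordinal–ordinal
pairs: thresholds from marginal cumulative proportions via Φ⁻¹, then the
two-step ML estimate of the latent correlation maximizing the
bivariate-normal cell likelihood over the observed contingency table.
Continuous covariates (e.g. GAD-7 totals, 0–21) use Pearson; mixed pairs use
Pearson on scores (a polyserial approximation). "Ordinal" means
integer-valued with ≤ 11 levels, which covers the 0–3 items, 0–10 fatigue
and the 2–10 QOL score. Pairwise matrices that come out indefinite are
repaired by eigenvalue clipping at 1e-6 and renormalization to unit
diagonal, and the repair is flagged.

The bivariate normal CDF inside the likelihood is evaluated by 48-point
Gauss–Legendre quadrature of ∫φ(x)Φ((k−ρx)/√(1−ρ²))dx, accurate to ~1e-9
(tested against scipy's multivariate normal), and fast enough for the many
thousands of pairwise likelihood evaluations the estimator needs. Failed
likelihood optimizations fall back to Spearman with a warning.

## Network estimation

The graphical lasso maximizes log det K − tr(SK) − λΣ_{i≠j}|K_ij| (penalty
over ordered pairs, diagonal unpenalized) by block coordinate descent with
inner lasso solves; convergence when the mean absolute off-diagonal change
of the covariance iterate drops below tol·mean|S_offdiag| (tol = 1e-6,
max 200 sweeps). The inner loops are numba-compiled because the resampling
procedures below re-estimate networks tens of thousands of times. W·K
deviates from the identity by < 1e-4 at convergence, and the attained
objective matches an independent generic convex optimizer (L-BFGS-B on a
positive/negative split of the off-diagonals) to machine precision on small
problems — that cross-check is part of the test suite.

λ is selected on a log-spaced 100-point path from λ_max = max|S_ij| down to
0.01·λ_max by minimizing EBIC(λ) = −2L + E ln n + 4γE ln p with L =
(n/2)(log det K − tr(SK)) and E the number of nonzero upper-triangle
partial correlations (|ω| > 1e-8 counts; smaller magnitudes are treated as
structural zeros). γ = 0.5 is the canonical default; γ = 0 reduces to BIC.
Ties prefer the sparser (larger-λ) model. Edge weights are the partial
correlations ω_ij = −K_ij/√(K_iiK_jj).

Edge count is expected to grow monotonically as λ decreases; true lasso
paths can nonetheless let a single edge flicker out briefly, so the fit
records a `path_monotone` flag and warns instead of failing. Warm starts
along the path keep the whole selection under ~2 ms for nine nodes.

**Covariate adjustment** enters the covariates as additional nodes in one
joint estimation and returns the symptom-subgraph; its edges are then
partial correlations conditioned on the covariates as well, which preserves
the semantics of the unadjusted network (residualizing each item first is
available as `mode="residualize"`). The joint fit stays retrievable.

## Centrality, stability, comparison

* **Strength** s_i = Σ_j|ω_ij| is the only centrality index computed — the
  others (closeness, betweenness) are unstable on small psychometric
  networks and are deliberately out of scope. Ranks break ties by node
  order; the handshake identity Σs_i = 2Σ_{i<j}|ω_ij| is asserted on every
  call.
* **Case-dropping bootstrap** re-estimates the network on subsamples of
  ⌈n(1−q)⌉ rows (without replacement) for q = 0.05,…,0.75 and correlates
  subsample with full-sample strengths. The **CS-coefficient** is the
  largest q whose empirical 5th percentile of correlations is ≥ 0.7 ("with
  95% probability, correlation at least 0.7"); ≥ 0.25 is minimally
  acceptable and ≥ 0.5 preferred by the usual guidance. Failed replicates
  (estimation error, zero-variance strengths — e.g. an empty subsample
  network) are recorded as missing and excluded from the percentile.
* **Edge bootstrap** resamples rows with replacement and reports per-edge
  bootstrap mean, median and 2.5/97.5 percentile CI. The percentile CI
  always brackets the bootstrap median; the mean can escape marginally for
  edges whose bootstrap distribution is a spike at zero, which is why the
  median column exists.
* **Network comparison test** compares two groups on the global-strength
  difference |Σ|ω_a| − Σ|ω_b|| and the maximum absolute edge difference,
  against a null built by pooling rows and permuting labels at the original
  group sizes, re-estimating both networks per permutation. p-values use
  the add-one rule (1+#{perm ≥ obs})/(1+B) and are never exactly zero. The
  global-strength test is well calibrated (empirical size ≈ 0.05); the
  max-edge test is conservative (≈ 0.01–0.02), as is typical for
  maximum-type statistics under sparsity.

Resampling procedures default to **Pearson** input internally
(`resample_method`): the polychoric estimate is ~3000× slower per matrix and
its extra sampling noise adds nothing to a stability ranking. The reported
(non-resampled) networks use the polychoric/auto input.

## Synthetic cohorts

The generator draws latent symptom severities from N(0, Σ) where Σ is the
correlation form of a ground-truth sparse precision matrix, then cuts each
latent at fixed thresholds to produce the ordinal items — exactly the model
under which polychoric correlation is consistent, making parameter recovery
meaningful. Unit-diagonal truth precisions are built directly from requested
partial correlations (strict diagonal dominance guarantees positive
definiteness), so the estimand is known exactly.

Couplings emulate the dependence structure of real caregiver data: a shared
anxiety factor (loading 0.35 on each symptom latent, 0.7 on each GAD-7
item) and a fatigue factor (0.25 on symptoms) make anxiety and fatigue
predict depression; depression status shifts the QOL item latents down by
0.6; a QOL latent dimension in the default truth carries negative partials
to sleep, guilt and concentration symptoms. Setting all couplings to zero
makes depression and QOL independent. Demographics are drawn from
configurable marginals typical of a Chinese guardian sample (40.1% male,
82.0% married, age ~N(43.1, 11.6²) truncated at 18, etc.) and are
independent of the symptom process by default.

Default item thresholds were calibrated once against the default truth so
that the PHQ-9 ≥ 5 prevalence is ≈ 1/3 (cuts 0.55/1.25/1.95), with GAD,
fatigue and QOL cuts placed to give realistic margins (GAD-7 mean ≈ 3,
fatigue ≈ 3.1, global QOL ≈ 6.6).

What the generator does **not** emulate: differential item functioning,
response styles (e.g. extreme responding), missingness mechanisms,
demographic–symptom confounding, and longitudinal dynamics. Passing
recovery tests therefore demonstrates estimator correctness under the
latent-Gaussian measurement model, not robustness to its violations.

## Validation design and problem sizes

* Solver optimality: p = 3 correlation matrices, λ ∈ {0, 0.03, 0.1, 0.3},
  against the independent convex oracle, tolerance 1e-6.
* Support recovery: 20 replicates of 9-node truths with six edges whose
  partials sit exactly in [0.2, 0.4], n = 2000 per cohort, Pearson input;
  median sensitivity ≥ 0.8 and specificity ≥ 0.9. Pearson is used here
  deliberately: with polychoric input the extra sampling noise (SD ≈ 0.037
  vs ≈ 0.022 at this n) admits more tiny spurious edges at the selected λ
  and median specificity drops to ≈ 0.85–0.90; polychoric correctness is
  validated separately by its consistency check (estimate within 0.03 of a
  known latent ρ = 0.5 at n = 20,000) and its null behavior.
* Permutation-test calibration: 100 replications of two n = 500 groups from
  a shared generating model, 200 permutations each; empirical size of the
  global-strength test within 0.05 ± 0.03.
* Stability and determinism checks run on reduced bootstrap sizes
  (B = 5–250) — the procedures are seed-deterministic, so size only trades
  Monte-Carlo precision for time. Full analyses default to B = 1000.

## Known limitations

* The depressed-only subgroup network on default synthetic cohorts is
  usually empty: conditioning on PHQ-9 ≥ 5 restricts range and weakens
  within-group item correlations until EBIC prefers zero edges. This is a
  property of the selection criterion at subgroup sample sizes, not a bug;
  the comparison test then trivially reports p = 1.
* Polychoric estimation assumes the latent-Gaussian model; heavy violations
  (e.g. genuinely categorical response processes) bias the input matrix.
* EBIC-gLASSO specificity degrades as the true network densifies — spurious
  small edges appear once λ is pulled down by strong true edges. Edge
  bootstrap CIs are the practical guard against over-reading weak edges.
* Node predictability, bridge/expected-influence centralities, Bayesian
  GGMs and graphical rendering are out of scope.
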