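# Methods

## The analysis in brief

The package analyses paired whole-blood expression cohorts (baseline and one
on-treatment follow-up per patient, patients labelled good or
non-responders) together with a small group of unpaired disease-free
controls, through the lens of predefined gene co-expression modules. Three
questions are asked, each with its own statistical machinery:

1. Which probes change between baseline and follow-up within a response
   group? (paired, covariate-adjusted, variance-moderated t tests)
2. Which modules change, and in which direction? (signed significant-probe
   fractions with Fisher exact tests, Bonferroni-corrected across modules)
3. Does module expression move towards the disease-free state? (patient vs.
   control contrasts from crossed random-intercept models, at baseline and
   follow-up separately)

## Paired differential expression

For a two-timepoint design with a patient random intercept, the timepoint
contrast is estimated exactly by differencing: per probe,
Δᵢ = x_{i,FU} − x_{i,BL} is regressed on an intercept plus centered baseline
covariates (categorical covariates one-hot encoded against a first-level
reference; covariates constant across patients are dropped with a warning).
The intercept is the log2 fold change; patient intercepts cancel
identically, which the test suite confirms by showing the t statistics are
invariant to the patient-intercept SD. Residual df = n − 1 − #covariates.
Optional per-array weights w enter as per-patient precisions of the
difference, 1/(1/w_BL + 1/w_FU).

Variance moderation fits a scaled inverse-χ²(d₀, s₀²) prior to the per-probe
residual variances by moment matching on the log scale: with
e_g = log s²_g − ψ(df_g/2) + log(df_g/2),

    trigamma(d₀/2) = var(e) − mean(ψ′(df_g/2)),     s₀² from mean(e),

where the trigamma inverse is solved by safeguarded Newton iteration. When
the spread of log-variances does not exceed its χ² sampling noise the prior
df is infinite and the prior scale is the arithmetic mean of the s²_g (this
matches the reference R implementation, against which the estimates are
cross-checked to 7 significant digits on a frozen fixture). Posterior
variances s²_post = (d₀s₀² + df·s²)/(d₀ + df) give the moderated t on
d₀ + df degrees of freedom; d₀ = 0 recovers the classical paired t exactly,
a property used as an internal oracle. Probe-level significance is two-sided
p < 0.05 unadjusted.

## Directional module statistics

Probes map to modules via Entrez IDs (GMT gene sets + probe annotation);
probes in no module are retained as background, and a gene present in
several modules contributes its probes to all of them (per-module tests are
computed independently, so overlap is harmless). Each module gets

* a **score** (n_up − n_down)/max(n_sig, 1) ∈ [−1, 1], the signed fraction
  of its significantly changed probes, plotted as the module bar;
* a **Fisher exact p** from a 2×2 contingency table, with Bonferroni
  threshold α/m over the m modules in the catalog (a printed external
  threshold such as 8.5×10⁻³ can be supplied verbatim as an override).

Three table constructions are available. The default, `enrichment`, is
{module, rest} × {significant, not significant}: the exact test decides
whether the module changed at all, and the direction label comes from the
score's sign. This follows the reading that the directional fraction is
descriptive while the Fisher test carries the significance claim, and it is
the only construction with useful power when the rest of the array is quiet
(a directional {module, rest} × {up, down among significant} table — kept as
`background` — conditions on the array-wide significant set, which under a
clean background has near-empty cells and, measured at the study-condition
simulation settings, detects a +0.4 log2 module effect in fewer than half
the replicates; `enrichment` detects it in >99%). A `within` mode
({up-leaning, down-leaning} × {significant, not}) is provided for
sensitivity analysis; it is degenerate whenever all module probes lean the
same way. Probes with p < α and logFC exactly 0 count in neither direction.

The Fisher kernel itself enumerates the hypergeometric support and sums
probabilities ≤ (1 + 10⁻⁷)·P(observed), the standard two-sided convention;
it agrees with exact rational-arithmetic enumeration to < 10⁻¹⁰ relative
error over every table with total ≤ 30, and with an independent library
implementation under randomized tables.

## Patient-vs-control transition models

For one module, one timepoint and one response group, probe-level expression
over the module's probes × (patients at that timepoint + all controls)
follows

    y_ps = β₀ + β₁·[s is control] + r_p + v_subject(s) + ε_ps,

with independent probe intercepts r_p, subject intercepts v (controls
receive intercepts symmetrically with patients) and i.i.d. noise. β₁ is the
effect size — mean control minus patient — so disease elevation appears
negative. Baseline and follow-up are separate fits, matching the reporting
layout; the "transition towards health" signature is a baseline star that
disappears at follow-up.

Because every subject contributes exactly one sample per fit and the
probe × sample grid is complete, the model is a balanced two-way crossed
random-effects layout and REML has a closed form. The GLS estimate of β₁
reduces to ordinary least squares on per-sample module means (their
covariance is equicorrelated, and the shared probe-mean term cancels in the
group contrast), and the variance components come from the three orthogonal
strata:

    σ̂²  = SS_interaction / ((P−1)(S−1))
    σ̂v² = SS_sample-residual / (S−2) − σ̂²/P
    σ̂r² = SS_probe / (P−1) − σ̂²/S

truncated at zero (truncation flags a boundary fit, which is retained).
These equal the iterative REML solution whenever the estimates are interior,
which the tests verify against an independent mixed-model implementation
(agreement to ≥4 decimals in the effect, SE and all three components).
Inference on β₁ uses a Wald z with Var(β₁) = (σ̂v² + σ̂²/P)(1/n_ctl +
1/n_pat); with tens of subjects per fit the normal approximation is
accurate, and the simulation suite measures ~95% coverage of ±2·SE
intervals. No degrees-of-freedom correction (Satterthwaite etc.) is applied.
Covariates are deliberately absent from this model, and controls are not
age-matched; the fit is exactly the two-random-intercept specification.

An optional probe filter restricts a module to probes significant in the
matched differential-expression run (p < 0.05), the stricter reading of the
procedure; the default uses all module probes. Density reports pool
probe-level values per group (patient-baseline, patient-follow-up, control)
through a Gaussian KDE on a common grid.

## Preprocessing

* **Quantile normalization** maps each sample onto the cross-sample mean of
  order statistics; ties receive the mean of the reference values at their
  tied ranks. The transform is idempotent and equalizes column means by
  construction.
* **PCA QC** centers probes, takes an SVD over samples, and screens PC1
  against every metadata variable (Pearson for numeric, one-way ANOVA for
  categorical), flagging samples beyond k·SD (default 4) on PC1/PC2.
* **Batch adjustment** is the parametric empirical-Bayes location/scale
  scheme: per-probe standardization on a model containing batch and
  protected covariates, per-batch per-probe location γ̂ and scale δ̂²
  estimates, shrinkage toward batch-level moments-matched priors (normal for
  γ, inverse-gamma for δ²; iterated posterior updates), adjustment, and
  de-standardization. Two behaviours deserve emphasis. First, shrinkage
  *intentionally* leaves per-probe sampling noise in the observed batch
  means — of the order 2(1−b)·σ/√n per probe, ≈0.09 SD at n = 100/batch and
  σ = 1 under a constant injected shift — because the EB posterior refuses
  to overfit per-probe noise the way exact per-batch centering would; only
  the systematic shift (the across-probe mean difference) is driven to ≈0.
  Reference implementations of the same estimator behave identically.
  Second, a protected covariate perfectly confounded with batch is refused
  with an explicit error: under the fully confounded design in which
  controls are processed separately, the adjustment must run unprotected,
  and then removes any genuine patient-control difference aligned exactly
  with batch — the documented cost of that design, mitigated in practice
  because module contrasts rest on many probes while the batch prior pulls
  per-probe effects toward a common mean.
* **Array weights** use a simplified two-iteration scheme: per-probe fits
  with current weights, then per-sample mean squared standardized residuals,
  inverted and normalized to geometric mean 1. This preserves the contract
  (noisy arrays are down-weighted; a 4× variance array drops below weight
  0.5) without the full per-gene REML of the original method. Weights are
  off by default.

## Synthetic cohorts

The generator draws, in documented order (probe intercepts; per-patient
intercept + covariates; per-control intercept + covariates; noise in
probe × sample order) from a single seeded stream, so identical configs give
bit-identical data:

    x_ps = μ₀ + a_p + u_subj(s) + Σ_m d_m·[patient] + Σ_m t_{m,resp}·[follow-up]
           + batch_shift·[second batch] + covariate terms + ε_ps

Defaults: μ₀ = 7 (a typical log2 intensity), σ_probe = 0.5, σ_patient = 0.3,
σ_noise = 0.7, effects d_m and t_{m,r} of ±0.3 where present, 27 modules ×
20 genes × 1 probe, and cohort sizes 50/20/10 (good/non/controls). Disease
shifts act at both patient timepoints; treatment effects only at follow-up,
so a good-responder transition to health is t_{m,good} ≈ −d_m. Batch
coincides with patient/control status by default (controls processed
separately); an independent-batch mode exists for testing adjustment under a
non-confounded design. Covariates (age, sex, DAS28, concurrent DMARD, HAQ,
smoking) are drawn with realistic demographics but default to zero
expression effect, so covariate adjustment is testable as a no-op.

What the generator does **not** emulate: raw probe-level intensities and
summarization, non-Gaussian platform noise, missingness, probe-level
correlation beyond module co-membership, and covariate-expression
confounding unless requested. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to real-array artefacts.

## Numerical and design choices

* Trigamma inversion: Newton with bisection safeguard on [10⁻⁸, 10¹²],
  relative residual < 10⁻⁸.
* Fisher ties: 1 + 10⁻⁷ relative slack on the observed-cell probability.
* Moderation with fewer than 10 probes falls back to full pooling with a
  warning.
* Bonferroni m defaults to the catalog size, never a hard-coded 27.
* Zero-variance stratum estimates are truncated at 0 and flagged
  (`boundary`), not re-fitted.
* Transition rows for modules with fewer than 2 usable probes (possible
  under the significance filter) are reported as NaN rather than dropped,
  keeping the table shape stable.
* Pipeline runs stage everything in a temporary directory and atomically
  rename on success, so failed runs leave no partial output; the manifest
  records config hash, seed and library versions.
* Simulation-heavy checks use 100–200 replicates at the cohort sizes above;
  these sizes give Monte-Carlo standard errors comfortably inside the
  asserted tolerances (e.g. a binomial SE of ~1.5% on a 95% coverage rate at
  200 replicates).

## Known limitations

* The transition model's closed form relies on the complete probe × sample
  grid; data with missing cells would need the iterative REML path it
  replaces (not implemented — input matrices are required complete).
* Wald z inference on β₁ can be mildly anti-conservative with very few
  controls (< ~5).
* The unprotected batch adjustment under a fully confounded design
  attenuates patient-control contrasts toward the across-probe mean batch
  effect; effect sizes estimated after such an adjustment are conservative.
* EULAR response labels are inputs, not derived from disease-activity
  scores; anti-drug-antibody exclusions and raw-array QC happen upstream of
  this package.
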