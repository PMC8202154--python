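# Methods

This note documents the statistical model behind `bioage`, the assumptions
of the synthetic-cohort generator, the numerical choices, and what the test
suite does and does not establish about real data.

## The estimation model

### Components

Biomarkers are standardized with means and SDs estimated on the *fit
subset* — the healthy rows of one sex — and the sample correlation matrix of
the fit subset is eigen-decomposed.  Loadings are scaled eigenvectors
(loading᷈ᵢⱼ = eigenvectorᵢⱼ·√λⱼ), so eigenvalues sum to the number of
biomarkers *p*.  Components are retained when λ > 1/3: on the correlation
scale the average eigenvalue is exactly 1, so the rule keeps components
describing more than a third of the average variance per biomarker.  The
comparison is strict (λ = 1/3 exactly is dropped).  Retention happens
*before* rotation; varimax is then applied to the retained loadings only.

Varimax maximizes the sum over components of the variance of squared
loadings, by the standard SVD iteration, stopping when the criterion
improves by less than 1e-8 (max 1000 iterations; non-convergence warns and
returns the best iterate).  Kaiser row-normalization is off by default and
available as a flag — raw varimax is the simpler referent.  Orthogonality of
the rotation preserves row communalities and the exact in-sample
uncorrelatedness of scores.

Scores are kept at unit sample variance: the score basis is
V·diag(1/√λ)·R for rotation R, so rotated scores have identity sample
covariance on the fit rows.  Any per-component rescaling convention would be
absorbed by the downstream age regressions, so this choice only fixes
reproducibility, not substance.  Two further conventions make repeated runs
byte-identical: each component is sign-flipped so its largest-|loading|
biomarker loads positively, and rotated components are ordered by explained
variance (sum of squared loadings), descending.

Components are characterized by the biomarkers with |rotated loading| > 0.5
(ordered by |loading|); when nothing clears the cutoff the label falls back
to the largest-|loading| biomarker.

### Klemera–Doubal biological age

Each retained score is regressed on CA by OLS over the fit subset
(intercept q, slope k, residual RMSE s with denominator n−2).  The
biological age of a score vector x is

    BA = Σ_j (x_j − q_j) k_j / s_j²  /  Σ_j k_j² / s_j²

CA is not a constituent, so BA can be compared against CA as a predictor.
The normalized weights w_j = (k_j/s_j²)/Σ_i k_i²/s_i² satisfy Σ w_j k_j = 1
identically, which makes the estimator calibration-consistent: a participant
whose every score lies on its regression line at age a gets BA = a.  Two
degeneracies are handled explicitly: a component with |k| ≤ 1e-12 carries no
age signal and is dropped from the sum with a warning (keeping it would add
zero numerator while leaving the weights well-defined but misleading); a
component whose regression fit is numerically exact (s < 1e-8) is flagged
degenerate and its s floored at 1e-8 so weights stay finite.

A CA-corrected variant (adding CA as a pseudo-biomarker with precision
1/s_BA², where s_BA² is the empirical Var(BA−CA) minus the propagated
estimator variance 1/Σ k²/s², floored at 0) is available behind a flag for
comparison; the uncorrected estimator is the documented default.

Component importance is share_j = w_j²·Var(x_j)/Var(BA) with Var(BA) taken
as the sum of the per-component terms; for pairwise-uncorrelated scores this
equals the marginal R² of BA on each score and the shares sum to one.
Importance uses the fit subset's empirical score variances.

Calibration is summarized as mean BA versus mean CA in left-closed
2.5-year CA bins anchored at multiples of the width.  Age-acceleration
groups use closed ±5-year boundaries: BA − CA ≤ −5 is "younger",
≥ +5 "older".

### Survival evaluation

The Cox partial likelihood is implemented directly (Newton iteration from
β = 0, step-halving on likelihood decrease, convergence on |Δll| < 1e-9,
max 100 iterations) because the headline statistic is a ratio of nested
log-likelihood gains and needs exact values at the null as well as the fit:

    proportion explained by BA = (ll_BA − ll_null) / (ll_BA+CA − ll_null)

The formula choice deserves emphasis: "comparing log-likelihoods" admits
several ratios, and this package fixes the share-of-gain form above
(χ²-share alternatives are out of scope).  The proportion is reported as
missing when the combined gain is numerically zero, and a nested-ordering
violation beyond 1e-8 raises rather than silently clipping.

Ties are handled by Efron's correction by default — less biased than
Breslow when follow-up has day granularity — with Breslow behind a flag
(also used by the brute-force oracles, which implement both rules by direct
summation).  Monotone likelihoods (perfect separation) are flagged
non-converged with coefficients capped at |β| = 10; a hazard ratio above
e¹⁰ per unit is not a finite maximizer in practice.

Harrell's C counts, over comparable pairs (the earlier observed time is an
event; at tied times event-versus-censored is comparable, event-versus-event
is not), the fraction where the earlier event had the higher risk score,
with 0.5 for score ties; the concordance computation is delegated to
lifelines and is cross-checked against an O(n²) pair-enumeration oracle in
the tests.  Adjusted C-indices fit a Cox model on the age variable plus
one-hot-encoded sociodemographic covariates and score concordance on the
fitted linear predictor.  Standard errors of C are not reported; the
analytic forms in the literature vary and none is implemented here.

Kaplan–Meier curves and the log-rank test come from lifelines.  The
benchmark mortality score is forward-stepwise Cox on the component scores
(entry p < 0.05 by single-df LRT, removal p > 0.10, the just-added variable
protected from immediate removal); thresholds are conventional defaults.
With no events the log-rank statistic is reported missing; with no entered
component the benchmark predictor is zero, giving C = 0.5.

## The synthetic-cohort generator

The generator produces the structure the analysis assumes, not a calibrated
replica of any real cohort:

- CA ~ Uniform(40, 70) years (the recruitment window of large midlife
  cohorts); latent offset δ ~ Normal(0, σ_δ²) with σ_δ = 8 years by default,
  chosen so that the SD of BA − CA in the healthy subset lands near the
  8–9-year range reported for biomarker ages in midlife populations;
  BA_true = CA + δ.
- Biomarkers: x_j = q_j + k_j·BA_true + u_j.  The default 18-biomarker
  panel spans four correlated blocks (adiposity, lung function, blood
  pressure, lipids) plus six free-standing markers (cystatin C, reaction
  time, IGF-1, grip strength, HbA1c, albumin), with slope signs and rough
  magnitudes following the usual clinical picture and a deliberately flat
  marker (pulse rate) included.  The residual u_j has *total* SD s_j, split
  √ρ·η_g + √(1−ρ)·ε_j between a shared block factor and noise, so two
  same-block biomarkers have residual correlation exactly ρ (default 0.5).
  Women get their own slopes for the markers with known sex-divergent
  trends (lipids, grip strength, IGF-1).
- Outcomes: event times are exponential with rate λ₀·exp(β·(BA_true − mean)),
  censoring uniform on 6–12 years, outcomes conditionally independent given
  BA_true.  Defaults λ₀ = 0.002/0.022 per year and β = 0.09/0.05 per year
  for mortality/admissions give cumulative incidences of a few percent and
  ~20% over follow-up, the right order for a midlife cohort.  The
  exponential form was chosen over Weibull because no baseline shape is
  specified by the analysis and it yields closed-form checks.
- Eligibility: each failure probability follows a logistic curve in δ
  (slope 0.08 logit/year), so the biologically old preferentially fail the
  healthy screen; prior-care episodes are Poisson with a δ-dependent mean.
  Base rates were set so roughly a third to two-fifths of participants pass
  all six rules.

What the generator does **not** emulate: realistic marginal biomarker
distributions, diagnosis coding of outcomes, competing risks, shared
etiology between the two outcomes beyond BA_true, measurement batch
effects, or longitudinal repeat measurements.  Consequently, passing tests
establish the *internal correctness* of the pipeline (estimator algebra,
calibration, nested-likelihood structure, selection effects) — not that any
particular real-world effect size will be reproduced.  In particular,
because the simulated hazards depend on BA_true only, the proportion of the
combined effect explained by BA is structurally high here (≈80–90%); in
real data CA carries information beyond measured biomarkers and the
proportion is lower.

## Healthy filter

Exclusions are attributed to the *first* failing rule in declared order
(medication, self-rated health, walk pace, smoking, prior episodes ≤ 2,
prior disease); only the totals are identifiable from published cohort
descriptions, so the attribution scheme is a package convention, recorded
in the audit table, and the counts always sum to the input size.  Rule
thresholds are configuration, not code.  For the admissions outcome,
participants with a prior age-related admission are removed from the risk
set only; mortality analyses keep them.

## Problem sizes and determinism

Simulation-based tests use cohorts of 10,000–20,000 participants and the
acceptance script uses 20,000 — large enough that 3-standard-error bands on
the checked moments are tight, small enough to run comfortably on one CPU.
All randomness flows from explicit seeds through `numpy.random.default_rng`;
a fixed configuration and seed reproduce every table byte-for-byte.

## Known limitations

- Nonlinear biomarker–age trends are only *diagnosed* (quadratic-term
  t-statistic per biomarker), never modelled; the estimator is linear by
  construction.
- The stepwise benchmark inherits the instability of stepwise selection at
  low event counts; it is a comparator, not a recommended model.
- Missing biomarker values are not imputed; upstream completeness is the
  caller's responsibility (the generator produces complete data).
- The whole-population mode reuses the component and KDM models fitted on
  the healthy subset, then re-evaluates on everyone; it does not refit.
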