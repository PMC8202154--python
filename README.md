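# bioage

Biomarker-based biological age estimation and evaluation for middle-aged
survival cohorts.

Chronological age (CA) is the dominant risk factor for most chronic
diseases, but people age biologically at different rates.  `bioage`
implements a complete, testable pipeline for estimating a composite
**biological age (BA)** from a clinical biomarker panel and for asking
whether BA carries prognostic information about mortality and age-related
hospital admissions beyond CA — the situation of interest being apparently
*healthy* people, where existing diagnoses cannot do the work.

The pipeline, run separately for each sex:

1. **Healthy-subpopulation filter** — medication, self-rated health, walking
   pace, smoking and prior-care rules, with an auditable exclusion trail
   (reduces reverse causality from illness driving both biomarkers and
   outcomes).
2. **Components** — biomarkers are standardized, decomposed by
   correlation-matrix PCA, components with eigenvalue > 1/3 (a third of the
   average variance per biomarker) are retained and varimax-rotated towards
   simple structure, and each component is labelled by its strongly loading
   biomarkers (|loading| > 0.5).
3. **Klemera–Doubal estimation** — each component score *x*ⱼ is regressed on
   CA (intercept *q*ⱼ, slope *k*ⱼ, residual RMSE *s*ⱼ) and BA is the
   precision-weighted inversion

   &nbsp;&nbsp;&nbsp;&nbsp;BA = Σⱼ (*x*ⱼ − *q*ⱼ)·*k*ⱼ/*s*ⱼ² ⁄ Σⱼ *k*ⱼ²/*s*ⱼ²

   with CA deliberately **not** a constituent, so BA and CA can be compared.
   Component importance is each component's share of BA variance.
4. **Survival evaluation** — Cox proportional-hazards fits (Efron ties,
   Newton solver) of CA alone, BA alone and both give the *proportion of the
   combined BA+CA effect explained by BA*,
   (ℓℓ_BA − ℓℓ_null)/(ℓℓ_BA+CA − ℓℓ_null), with likelihood-ratio tests,
   Harrell's C-indices (unadjusted and adjusted for deprivation, smoking,
   alcohol and assessment centre), Kaplan–Meier curves and log-rank tests
   across ±5-year age-acceleration groups, and a stepwise-Cox mortality-score
   benchmark.

Because suitable cohort data (e.g. UK Biobank) are available only by
application, the package ships a first-class **synthetic-cohort generator**:
CA uniform over a 40–70-year recruitment window, a latent offset δ so that
BA_true = CA + δ, biomarkers tracking BA_true linearly with block-correlated
residuals (adiposity / lung / blood-pressure / lipid panels), exponential
outcome hazards driven by BA_true with uniform 6–12-year administrative
censoring, and eligibility fields whose failure probability rises with δ.

## Worked example

```python
from bioage import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulation=SimulationConfig(n_participants=10_000),
    seed=7,
    run_whole_population=True,
)
result = run_pipeline(config)
```

Inspecting the per-sex results prints:

```
sex=M n_healthy=2110 R2=0.435 SD(BA-CA)=9.8y top component=PC1 (fvc, 35.6%)
  mortality: prop explained by BA=0.72 C(CA)=0.763 C(BA)=0.736 C(BA+CA)=0.775 LRT p=2.6e-02
sex=F n_healthy=2140 R2=0.450 SD(BA-CA)=9.6y top component=PC4 (cystatin_c, 19.8%)
  mortality: prop explained by BA=0.85 C(CA)=0.743 C(BA)=0.763 C(BA+CA)=0.775 LRT p=4.3e-04
```

Reading: in the healthy subset the fitted BA describes ~44–45% of the
variation in CA; the lung-function component dominates BA for men and the
kidney-function marker for women; BA alone attains 72–85% of the combined
BA+CA log-likelihood gain for chronic-disease mortality; and adding BA to a
CA-only Cox model significantly improves fit (likelihood-ratio p < 0.05)
while increasing Harrell's C by ~0.01.

The same stages are exposed on the command line (`bioage simulate`,
`filter`, `components`, `kdm`, `evaluate`, `run`); each persists its
artifacts as delimited tables.

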