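# twinwell

Twin–sibling models, genetically informed causal screens, and the MR-DoC
model for studying the overlap between **resilience** and **well-being**.

## The scientific problem

Resilience — staying free of anxious-depressed symptoms despite stressful
life events — correlates strongly with life satisfaction. Is that because
one trait causally shapes the other, or because shared genetic and
environmental factors drive both? With family data and polygenic scores
the question becomes tractable:

1. **Outcome-based resilience.** Standardize the anxious-depressed sum
   score and the count of stressful life events; regress the former on
   the latter with a generalized estimating equation (GEE) clustered by
   family. The resilience score is *predicted minus observed*
   symptom level — positive means fewer symptoms than expected.
2. **Bivariate common-pathway twin model.** With scores at two waves for
   monozygotic (MZ) and dizygotic (DZ) twins plus their siblings, each
   trait gets a unit-variance latent factor loading on both waves, the
   latent variance decomposed into additive-genetic (A) and
   unique-environment (E) parts (dominance D where warranted), plus
   wave-specific A/E residuals. Cross-trait latent correlations rG and
   rE, estimated by full-information maximum likelihood (FIML), split
   the trait covariance:

       % genetic = 100 · rG·√(h²₁h²₂) / (rG·√(h²₁h²₂) + rE·√(e²₁e²₂))

3. **Causality screens.** Within-subject change-score regressions
   (stable confounders cancel in T2−T1 differences) and MZ intrapair
   difference regressions (genetic and shared-environment confounding
   cancel within genetically identical pairs).
4. **MR-DoC.** A polygenic score S instruments the exposure X while twin
   pairs supply the cross-twin cross-trait covariance, so the causal
   path g1 (X→Y) is estimable with the pleiotropic path b2 (S→Y) *free*;
   the environmental correlation rE must be fixed for identification and
   a sensitivity grid profiles the causal estimate over fixed rE values.

Every stage is exercisable on synthetic twin-family data with known
generative truth (`twinwell.simulate`), since the registry data behind
such analyses are restricted.

## Worked example

```python
from twinwell import GenerativeParams, simulate_families
from twinwell.estimators import ResilienceScorer, CommonPathwayModel

params = GenerativeParams.recovery_benchmark(n_pairs=4000)
df = simulate_families(params, seed=7)

df = ResilienceScorer().fit_transform(df)          # adds resilience_t1/t2
model = CommonPathwayModel(sex_specific_specific=False,
                           sex_specific_means=False, seed=0).fit(df)
print({k: round(float(100 * v), 1) for k, v in model.h2_.items()})
print(round(float(model.genetic_covariance_pct_), 1))
```

prints (seed 7):

```
{'wellbeing': 54.2, 'resilience': 59.1}
50.5
```

i.e. the latent (measurement-error-free) heritability of well-being is
estimated at 54.2% and of resilience at 59.1%, and 50.5% of the latent
covariance between the traits is attributed to genetic factors — close
to the generating values (54.8%, 60.9%, 51.2%) at this sample size.

The same analyses are scriptable from the shell:

```bash
twinwell simulate --seed 1 --n-pairs 2000 --out sim/
twinwell prep sim/phenotypes.csv
twinwell report --input sim/phenotypes.csv --seed 1 --out report/
```

## Layout

| module | contents |
| --- | --- |
| `twinwell.params` / `twinwell.simulate` | generative ground truth and the family / MR-DoC pair simulators with an analytic implied-moments oracle |
| `twinwell.phenotypes` | standardization, family-clustered GEE, resilience scores, age effects |
| `twinwell.sem` | FIML engine for family data, the model zoo (common pathway, longitudinal bivariate, MR-DoC, saturated/correlation), LRTs, variance decomposition |
| `twinwell.screens` | change-score and MZ-difference causal screens |
| `twinwell.pgs` | polygenic-score prediction and variant selection |
| `twinwell.mrdoc` | MR-DoC fitting, causal explained variance, rE sensitivity |
| `twinwell.estimators` | scikit-learn-style estimator facade |
| `twinwell.pipeline` / `twinwell.cli` | data contracts, the three-part report pipeline, CLI |
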