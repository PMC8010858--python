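# Methods

## Models

### Outcome-based resilience

Both the anxious-depressed sum score and the life-event count are
standardized per wave (mean 0, SD 1, denominator n−1) over all
individuals observed at that wave. The score is regressed on the count
by a Gaussian GEE with family clusters; resilience is the signed
residual *predicted − observed*, so fewer symptoms than predicted give
a positive score. Missing either input at a wave leaves resilience
missing at that wave — no imputation.

The residualization uses the **independence** working correlation by
default: its point estimate solves the ordinary normal equations, so the
scores are exactly orthogonal to the life-event predictor (the package's
orthogonality invariant); clustering only affects standard errors. The
exchangeable working correlation — the default for every *inferential*
GEE in the package — changes the slope weighting slightly and is
available as an option. Residuals come from the population-averaged
(marginal) prediction, and no covariates other than life events enter
the residualization.

### Family FIML engine

Families are multivariate-normal vectors (members × per-person
variables). Latent components have a kind — A, D, C, E — and the kind
fixes the cross-member correlation scaling: A shares 1 between MZ
co-twins and 0.5 between DZ co-twins, twin–sibling and sibling–sibling
pairs; D shares 1 / 0.25; C 1 / 1; E 0. Model-implied moments are
assembled by path tracing from per-sex loading matrices and per-kind
latent covariance blocks. C and D are never simultaneously free.

The likelihood is full-information: each family contributes the Gaussian
−2 log density of its observed subvector (rows/columns of the implied
moments deleted for missing entries). Families sharing zygosity, member
layout, sexes and missingness pattern are grouped so an evaluation costs
one small Cholesky factorization per distinct pattern. A family with no
observed variables is dropped and counted. A member present in the model
layout but absent from the data is treated as fully missing, which the
marginalization makes exact.

When the latent structure is sex-specific, a cross-sex pair (DOS twins,
brother–sister) uses the average of the female and male latent
correlation blocks — with quantitative (not qualitative) sex differences
there is one set of latent factors, and the average is the symmetric
convention; it is a no-op whenever the latent part is equal across
sexes. Qualitative sex differences (sex-specific genes) are out of
scope.

### Common-pathway model

Per trait, a unit-variance latent factor loads (λ per wave, per sex when
sex-specific) on the wave-1 and wave-2 scores; the latent variance is
decomposed into A (+ D) + E with the E path derived as √(1 − a² − d²),
so squared latent paths are directly standardized shares and the
cross-trait correlation parameters are rG / rD / rE. Wave-specific A
(+ D) + E residual paths complete the measurement part. Identification:
unit latent variance with both loadings free; variance paths are bounded
at zero, which resolves sign indeterminacy (estimates are reported on
the non-negative branch); a path estimated at the bound is flagged as a
boundary solution, not an error.

The model ladder: **I** full sex-specific ADE → **II** all paths equal
across sexes → **III** only the latent decomposition and correlations
equated (loadings and time-specific paths stay sex-specific) → **IV** as
III with D dropped. In this parameterization III → IV removes 11 free
parameters (two latent d paths, rD, and eight sex-specific wave-specific
d paths). Means keep a sex effect throughout; phenotypes may be
pre-residualized for age and age² via `phenotypes.age_effects` before
the SEM — the means model itself carries no age terms.

The latent covariance decomposition is

    cov_G = rG·√(h²₁h²₂) + rD·√(d²₁d²₂),   cov_E = rE·√(e²₁e²₂),
    % genetic = 100·cov_G / (cov_G + cov_E).

### Model testing

Nested models are compared by the likelihood-ratio test: Δ(−2LL) against
χ² with Δdf = the difference in free-parameter counts; AIC = −2LL +
2·(free parameters). The engine recognizes nesting by free-parameter
subsets or by the recorded spec lineage and refuses other pairs. For
variance components the null sits on the boundary of the parameter
space, so the naive χ² reference is conservative there (empirically the
null mean of Δ(−2LL) falls well below Δdf when dropping D); for interior
nulls such as zeroing rA/rE the χ² calibration is exact and the test
suite verifies it. The ACE-vs-ADE choice is advisory: ADE when the mean
MZ correlation exceeds twice the mean DZ/sibling correlation, ties to
ACE.

### Twin-group correlations

Per zygosity group, a constrained saturated model: members exchangeable
(one mean and SD per variable), one within-person correlation matrix,
and one symmetric cross-member correlation matrix per relationship class
(MZ co-twin, DZ co-twin, twin/sibling), all Fisher-z parameterized and
fitted by the same FIML machinery. Confidence intervals are Fisher-z
Wald intervals from the Hessian. Merging the DZ and sibling classes
implements the no-special-twin-environment constraint as an LRT.

### MR-DoC

Observed (S, X, Y) per twin: X = b1·S + a_x·A_x + e_x·E_x and
Y = g1·X + b2·S + a_y·A_y + e_y·E_y, with S behaving like an additive
genetic component (cross-twin sharing 1 MZ / 0.5 DZ, free variance σ²_S,
random mating assumed), residual A factors correlated rA, and E factors
correlated rE — **fixed**, not free, because with two AE traits and one
instrument rE is not identified alongside g1. MZ co-twins carry the
identical score, so S enters once per MZ pair (the duplicate would make
the implied covariance singular and carries no information). Means are
free per variable, equated across twins and zygosity; only twin pairs
enter (siblings are used elsewhere). The causal test is a χ²(1) LRT of
g1 = 0 at α = 0.001; causal explained variance is 100·g1²·Var(X)/Var(Y)
with both variances assembled from the fitted algebra. A weak first
stage (no clear S–X correlation) attaches a warning, not a failure.
`rE_sensitivity` refits over a grid of fixed rE values (default 0, 0.1,
0.2, 0.3, 0.4, 0.5, 0.8); when the generating rE exceeds the fixed
value and a true causal path exists, the causal estimate is biased
upward — a directional property the test suite asserts.

### Causality screens

Change scores are T2 − T1 per individual; the change-on-change
regression is a family-clustered GEE (co-twins both contribute). MZ
intrapair differences are twin1 − twin2 for both-complete MZ pairs;
the difference-on-difference regression is OLS *with* intercept — twin
order is arbitrary, so the intercept's expectation is zero and it merely
absorbs finite-sample asymmetry; all statistics are invariant to label
swapping. Sexes are pooled. Pairs with one member observed are excluded,
not imputed.

### Polygenic-score prediction

The phenotype is regressed on the standardized score plus age, age²,
sex, genotyping platform (dummy-coded against a reference level) and ten
genetic PCs. The p-value comes from the family-clustered GEE; the
incremental explained variance ΔR² is the difference of R² between
nested least-squares fits (covariates vs covariates + score) on complete
cases — the squared-semipartial alternative is numerically close but the
nested-ΔR² definition is the one implemented. Significance uses the
multiple-testing-corrected threshold p < 0.001. Variant selection among
causal-fraction-labelled scores maximizes ΔR².

## Synthetic data

The generator mirrors the analysis models so that every estimate has a
known target. Defaults are the study conditions: latent heritabilities
0.548 (well-being) and 0.609 (resilience), rG 0.71, rE 0.93, wave
loadings 0.8; five zygosity groups in the observed proportions
(MZM 13.9%, DZM 8.6%, MZF 34.1%, DZF 18.7%, DOS 24.7% of twin pairs)
plus 0–2 non-twin siblings per family (probabilities 0.62/0.31/0.07,
matching the observed sibling-to-twin ratio); life events Poisson with
means 1.53 (T1) / 2.19 (T2) truncated at the instrument maxima 16 / 19
and independent across waves (the joint distribution over waves is not
otherwise constrained — independence is the documented choice);
anxious-depression built from the standardized life-event count (slopes
0.11 / 0.27) minus the resilience core, rescaled to means 6.16 / 4.99
and SDs 5.37 / 5.05; well-being rescaled to means 26.5 / 27.3 with SD 6
(the reference well-being dispersion is a standard error, not an SD;
6 is a realistic SD for a 5–35 life-satisfaction sum score); a small
male advantage in resilience (−0.05 SD on symptoms) and a small U-shaped
age effect; wave-level missingness completely at random at 58% (T1) and
17% (T2), matching the per-wave availability. The time-specific variance
(0.66 per wave on top of λ² = 0.64) splits into genetic and
environmental parts following the reported time-specific heritabilities
(well-being 32/37% F and 32/35% M; resilience 45/43% F and 39/36% M,
read as the genetic share of the time-specific variance). Polygenic
scores are standardized A-sharing variables: the well-being score
explains ~0.85% of well-being and ~1.6% of resilience by default, with
seven causal-fraction variants whose fidelity peaks at fraction 0.5;
scores are independent of the trait A factors, so their default effects
add (negligibly) to the genetic variance rather than re-partitioning it.
Optional simultaneous phenotype-level causal paths couple the traits;
moments are exact under the (I − G)⁻¹ mixing. Scores stay continuous by
default (the analyses treat them as continuous); an optional
discretization rounds and clips to the printed ranges.

What the generator does **not** emulate: genotype-level data (SNPs, LD),
assortative mating, informative missingness, skewness/floor effects of
real sum scores, and event-impact heterogeneity. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to those real-data features.

`implied_moments` assembles the exact moments by path tracing and is the
oracle for both the simulator (which composes phenotypes from
independently drawn components — a deliberately separate code path) and
the SEM engine; implied moments condition age effects out, so
moment-matching tests run with the age effect disabled.

## Numerical choices

L-BFGS-B with numeric gradients, bounds on variance paths (≥ 0) and
correlations (|r| ≤ 1), relative −2LL tolerance ~1e−11, five restarts by
default in the engine (fewer where tests and the pipeline can afford
it); the first start uses the spec's start values, the rest perturb them
uniformly. Inadmissible parameter vectors and non-positive-definite
implied covariances return a large finite penalty (1e100), keeping
finite-difference gradients NaN-free. Convergence is declared when the
projected-gradient norm falls below 1e−4 scaled by the magnitude of
−2LL/100 (numeric-gradient noise grows with the likelihood magnitude).
Standard errors come from the central-difference Hessian of −2LL
(covariance = 2·H⁻¹, pseudo-inverse); they are reported as NaN at
boundary solutions rather than invented. Local identifiability can be
checked as the rank of the numeric Jacobian of the stacked implied
moments; the ADE common-pathway model with specific D terms is at best
boundary-identified — as in common usage — and the engine reports the
rank rather than refusing.

Degenerate inputs: a perfect linear fit short-circuits the GEE (zero
sandwich errors); all-zero MZ differences are reported as degenerate
rather than fitted; a constant vector cannot be standardized and raises.

## Problem sizes used by the test suite and acceptance script

Acceptance recovery uses 5,000 MZ + 5,000 DZ pairs × 5 seeds (the
reference design scale). Moment-matching runs at 120,000 pairs per
zygosity group with a 4-Monte-Carlo-SE band, whose width adapts to n.
Screen and MR-DoC property suites use 40–60 replicates at 1,000–8,000
pairs; the interior-null LRT calibration uses 120 replicates of 300
pairs. These sizes are the package's chosen trade-off between Monte
Carlo precision and suite runtime; every tolerance is expressed in
Monte-Carlo standard errors so the checks remain valid at other sizes.

## Known limitations

- The paper-scale absolute df convention (observation-count-based) is
  not reconstructed; only free-parameter counts and Δdf are reported.
- The full sex-specific ladder is expensive under heavy missingness
  (many FIML patterns × ~50 parameters) and is off by default in the
  pipeline; the final model is always fitted.
- The saturated spec covers independent individuals; family-level
  saturated structure is provided by the correlation spec instead.
- Boundary LRTs use the naive χ² reference (conservative for variance
  components), matching common practice in the field.
- The MZ-difference and change-score screens remain confounded by
  nonshared environmental factors; they falsify, never prove, causation.
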