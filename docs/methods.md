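# Methods

## The estimation problem

National household surveys (DHS/MICS-style) ask caretakers of children under
five whether the child had fever in the preceding two weeks, whether care was
sought, and where. From these, two outcomes are defined per country-year:

* **any-medical treatment rate** — among febrile children, the
  survey-weighted proportion taken to any source of legitimate medication
  (public sector, private or NGO facilities, pharmacies). Friends, family,
  and traditional or homeopathic healers are classified non-medical.
* **public fraction** — among children taken for any medical treatment, the
  weighted proportion taken to public-sector care.

The **public treatment rate** is the product of the two.

Surveys are sparse: most countries have a handful of surveys over three
decades, some none at all. The package estimates complete 1990–2020
country-year series for every country in a region map, with 95% intervals,
and population-weighted regional and combined aggregates.

## Survey aggregation

Child-level rows are collapsed with the survey's sampling weights:
`p̂ = Σ wᵢ fᵢ / Σ wᵢ`. The 95% CI is the Wilson score interval evaluated at
the Kish effective sample size `n_eff = (Σw)²/Σw²`, which discounts unequal
weighting without needing cluster identifiers (no linearisation or replicate
weights — a deliberate scope limit). Multiple surveys in one country-year
are pooled by precision-weighted averaging on the logit scale with effective
sample sizes added.

Rates enter the model through the **empirical logit**
`log(p*/(1−p*))`, `p* = (x + 0.5)/(n_eff + 1)`, whose continuity correction
keeps boundary rates finite. Observation weights are the inverse
delta-method variances `n_eff · p*(1−p*)` (an unweighted fit is available by
config flag).

## The model

For outcome Y of country c in region r at year t:

```
logit(Y) = β_r + s_r(t) + b_c + Σ_k s_k(x_k) + ε,   b_c ~ N(0, τ²),  ε ~ N(0, σ²/w)
```

* `β_r` — unpenalized region intercepts (no global intercept).
* `s_r(t)` — one temporal smooth per region: cubic B-spline basis, evenly
  spaced interior knots over the region's observed years, maximum basis
  dimension 5, sum-to-zero constraint absorbed by null-space
  reparameterisation (4 free columns).
* `s_k(x_k)` — covariate smooths shared across regions, maximum basis
  dimension 3. A cubic B-spline basis cannot have fewer than four columns,
  so dimension-3 blocks use quadratic B-splines; the capacity (three basis
  functions) is what matters and is preserved.
* `b_c` — country random effects represented as a ridge-penalized
  indicator block; `τ̂ = σ̂ /√λ_country`.

**Penalty structure.** Each smooth carries the second-order difference
penalty of its B-spline coefficients, transformed into the constrained
space, *plus* a unit-weight shrinkage penalty on that penalty's null space.
The combined block penalty is full rank, so a large smoothing parameter
annihilates the entire term (rather than leaving an unpenalized linear
trend behind). This keeps the infinite-penalty limit interpretable — the
fit collapses to region intercepts — and gives AIC-based covariate
selection a clean "term absent" limit. The cost is that strong smoothing
also shrinks the linear component of a trend; REML chooses the smoothing
level, and in recovery experiments this tradeoff is invisible at the data
sizes used.

**Fitting.** The whole model is one weighted penalized least-squares
problem. Smoothing parameters are grouped by block kind by default (one λ
for all regional trends, one for covariate smooths, one for the country
ridge — three REML dimensions; per-block λ available by config) and chosen
by restricted maximum likelihood: a coarse grid over log λ followed by
Nelder–Mead refinement started at the best grid point, so the returned
optimum is never worse than any grid candidate. With
`A = X'WX + S(λ)` and `D = ‖y − Xβ̂‖²_W + β̂'Sβ̂`,

```
−2ℓ_R = (n − p_f)·log(2πσ²) + D/σ² + log|A| − log|S(λ)|₊ − Σ log wᵢ ,
σ̂² = D/(n − p_f)
```

where `p_f` counts unpenalized coefficients and `|·|₊` is the
pseudo-determinant. The coefficient covariance is `A⁻¹σ̂²` (the usual
Bayesian posterior covariance of a penalized fit). Linear predictors are
clipped at ±15 before inverse-logit, bounding predictions inside
(3·10⁻⁷, 1 − 3·10⁻⁷). At prediction time, covariate smooth inputs are
clipped to the range seen at fitting (penalized-spline extrapolation is
unstable); year inputs may extrapolate but are then governed by tail
fixing.

**Tail fixing.** To avoid unsupported extrapolation, each region's trend is
frozen at its value in the region's first data year for all earlier years,
and replaced by the arithmetic mean of its 2019–2021 values across that
window (value-averaging; averaging the slope instead would be an
alternative reading, not implemented).

## Gap filling

* **No-data countries** borrow the country random effect of their nearest
  neighbour among same-region countries that have ≥5-year data spans
  (avoiding chains of borrowed quantities). Distance is Euclidean in the
  space of principal-component scores of the selected covariates at anchor
  years 2000/2010/2020 (components retained to 90% cumulative variance,
  deterministic sign convention, exact ties broken lexicographically). If a
  region has no eligible donor, the country falls back to a zero effect
  with a logged warning.
* **Short-span countries** (data span < 5 years, including zero) receive
  the regional trend rescaled by the ratio of their own mean anchor-year
  covariate change to the regional donor mean change, clipped to [0, 2] for
  stability; a zero regional mean change falls back to the unscaled trend.
  Countries with ≥5-year spans keep the fitted regional trend unchanged.

## Covariate preparation and selection

Transforms are chosen by profiling the Box-Cox likelihood over
λ ∈ [−2, 3] and snapping the maximiser: λ̂ < 0.5 → log, λ̂ < 1.5 → none,
otherwise square (non-positive data falls back to none). Transformed
covariates are z-scored with the sample sd (ddof = 1, configurable); the
fitted mean/sd are frozen and reapplied to prediction-set and perturbed
values. Subset selection enumerates all candidate subsets up to a maximum
size, screens each subset on approximate Wald p-values of its smooth terms
(all below 0.05 by default), and ranks survivors plus the empty model by
conditional AIC (−2 Gaussian log-likelihood + 2·(edf + 1)).

## Uncertainty propagation

Two layers, matching the 100 × 100 design:

1. **Input perturbation.** Each run replaces every observed rate and
   covariate value by an independent uniform draw over its 95% CI
   (truncated-normal alternative by config; zero-width intervals pass
   through) and refits both models. Covariate selection, transforms,
   standardisation, and donor-match assignments are frozen from the
   unperturbed fit (re-selection per run available by config); smoothing
   parameters are re-estimated each run. Per-run seeds derive from
   `SeedSequence(base_seed, run_index)`.
2. **Coefficient draws.** Each refit contributes `draws_per_run`
   multivariate-normal coefficient draws (mean = estimate, covariance =
   `A⁻¹σ̂²`; a failed factorisation retries once with a 10⁻¹⁰ ridge), each
   predicting every country-year.

The default 100 runs × 100 draws yield 10,000 realisations per
country-year. Intervals are empirical 2.5/97.5 percentiles with linear
interpolation between order statistics; the point estimate is the
realisation mean. Failed runs are skipped and logged; more than 10%
failures aborts. Composition (public rate) and population-weighted
aggregation are applied realisation by realisation *before* summarisation,
so correlation induced by shared runs survives into aggregate intervals.
Population weights are year-specific (the synthetic worlds use notional
under-five populations); the "combined" aggregate pools countries directly.

## The synthetic-data generator

Worlds are generated exactly in the model's additive form: region
intercepts ~ N(base-rate logit, 0.5²); regional trends drawn from the
model's own constrained spline basis and rescaled to a target standard
deviation over years (0.6 logit units by default); country offsets
~ N(0, 0.5²) on the logit scale; covariates as smooth latent series with
linear or centred-quadratic effects, reported on raw scales chosen so the
Box-Cox step recovers the intended transform, with stated CI widths.
Surveys draw febrile children (prevalence 0.27 — fever prevalence is a
nuisance that only controls effective sample size), assign lognormal
cluster-level weight multipliers (a two-stage design caricature; the
within-survey design effect is a knob, not a claim about real surveys),
and treatment outcomes are multinomial so weighted proportions are
unbiased for the truth. Default scale emulates the multi-country study
setting: ~40% of countries without any survey (91 of 151 modelled
countries had data in the motivating setting), surveys every five years,
and roughly two thousand febrile children per survey. Missing-country
selection uses the seeded generator over the identifier-sorted country
list; removal counts use floor(x + 0.5).

What the generator does **not** emulate: cluster-level correlation of
outcomes (weights vary by cluster but outcomes are independent), survey
non-response and recall bias, covariate measurement error correlated in
time, real DHS recode layouts, and country effects correlated with
covariates (available via `effect_covariate_corr` but off by default).
Passing recovery tests therefore demonstrate correctness of the machinery
under the model's own assumptions, not robustness to real-data violations.

## Problem sizes used in the test suite

Recovery uses 50 replicate worlds of 3 regions × 30 countries (surveys
every 3 years, ~600 febrile children per survey, 20 × 20 ensembles);
interval calibration uses 200 replicates of the same design reduced to
2 regions × 10 countries with 10 × 10 ensembles; both include 10% no-data
and 10% short-span countries so every gap-filling path is exercised. The
acceptance script runs a single 3 × 10-country world at study-like
sparsity (40% no-data) with the full 100 × 100 ensemble.

## Known limitations

* **Gap-filled countries are over-confident.** Donor matching copies a
  point random effect and trend borrowing rescales a point trend; neither
  adds the between-country variance τ² or the borrowing error to the
  intervals. When country offsets are uncorrelated with covariates (the
  generator's default), nearest-neighbour matching carries no information
  and realised coverage for no-data countries drops far below nominal
  (≈25% in the calibration study, versus ≈97% for countries with full
  data spans). This is a property of the point-imputation rules, faithfully
  implemented; the calibration test reports the pooled number honestly.
* Intervals for well-observed countries are mildly conservative: input
  perturbation and coefficient draws both carry sampling noise, so the two
  layers overlap.
* The Wald p-values used in selection screening are approximate (block
  Wald statistics against χ² with the block dimension).
* Smoothing-parameter uncertainty is not propagated (no Bayesian treatment
  of λ).
* Two fieldwork-year conventions exist in real surveys; the synthetic
  generator assigns each child its survey year, and nothing here validates
  that choice against external data.
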