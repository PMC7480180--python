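# Methods

`scmeval` estimates the effect of a staggered, practice-level intervention
(such as the vertical integration of GP practices with an acute hospital) on
monthly unplanned-care outcome rates, using synthetic controls with placebo
inference, inverse-variance pooling across practices and a health-economic
conversion of the pooled effect. Because the hospital extracts such studies
use are not public, the package ships a synthetic panel generator that
reproduces the statistical structure the estimator assumes, so the whole
pipeline is testable end to end.

## Outcome model and synthetic-data generator

Each practice `i`, outcome `o` (ED attendance, unplanned admission,
unplanned readmission rates per 100 registered patients per month) and month
`t` is generated as

```
y[i,o,t] = max(0, alpha[i,o] + s_o(t) + gamma[i] * f(t) * c_o + delta_o * post[i,t] + eps[i,o,t])
```

an interactive fixed-effects (latent factor) model: `alpha[i,o]` are
practice intercepts drawn around the outcome means with a between-practice
SD, correlated across outcomes through a latent deprivation axis that also
drives the deprivation-like covariates (IMD, BME %, long-term-condition
prevalence); `f(t)` is one shared smooth standardised factor with loadings
`gamma[i] ~ N(1, factor_loading_sd)` and outcome scale
`c_o = factor_scale * mean_o`; `s_o(t)` is sinusoidal seasonality with a
12-month period; `eps` is Gaussian month noise; `delta_o` is the injected
treatment effect, applied from each treated practice's join month. This is
exactly the data-generating structure that motivates synthetic controls: a
convex combination of donors can match both intercept and factor loading,
so a good pre-period fit extrapolates to the post period.

Default calibration (all per 100 patients per month): outcome means
(2.70, 0.87, 0.12) — the pooled pre-intervention averages of the ten
integrated practices in the motivating study; between-practice SDs
(0.55, 0.20, 0.040) matching the observed spread across practices; month
noise (0.28, 0.11, 0.038) matching within-practice time SDs; seasonal
amplitude 8% of the mean; factor scale 5% of the mean with loading SD 0.3.
Injected effects default to (0, −0.11, −0.021), the study's reported pooled
reductions in admissions and readmissions. Panels default to 48 months with
ten treated practices joining at months 15,15,15,22,25,28,30,32,35,40 (the
study's staggered join pattern with April 2015 as month 1) and 40 donors.
List sizes are truncated-normal over `list_size_range` (default
4000–10000, mean 7000). Configurations whose calibration would clip more
than 10% of draws at zero are rejected as unusable.

What the generator does **not** emulate: patient-level event processes
(rates are drawn directly, though an optional `count_mode` draws Poisson
events against list size), geography and referral catchments, covariate
drift over time, serial correlation in the noise beyond the shared factor,
and policy shocks in the donor pool. Passing tests therefore show the
estimator is correct and calibrated *under the assumed factor structure*,
not that the design assumptions hold in any particular real dataset.

## Donor pools

For each treated practice, donors are all practices not on the intervention
schedule whose list size at the month before the treated practice's join
lies within ±20% (inclusive) of the treated practice's — the study's
similarity constraint, evaluated at the month in which baseline
characteristics are defined. Every inclusion/exclusion is logged. Treated
practices are never donors for each other. An optional categorical column
filter (`group_col`) stands in for the study's geographic restriction,
which synthetic data has no analogue of.

In the orchestrated pipeline the band is widened in 0.05 steps (to at most
`donors.max_tolerance`, default 0.9) when it yields fewer donors than
placebo inference needs, with each widening recorded in the report
warnings. This matters only because a simulated pool of ~40 donors is far
smaller than the hundreds of candidate practices a real study draws on;
practices whose list size falls at the edge of the simulated range would
otherwise have almost no size-similar donors.

## Synthetic-control fit

The fit is the standard nested formulation. Predictors are the pre-period
means of the chosen covariates (staffing counts, population structure,
deprivation, prevalence markers, emergency length of stay, list size) plus
the full monthly pre-period paths of the three outcomes; with
standardisation (default on) each predictor row is divided by its
donor-pool SD. Given diagonal importance weights `V`, the inner problem

```
min_W (X1 - X0 W)' diag(V) (X1 - X0 W),   W >= 0, sum W = 1
```

is solved exactly as a non-negative least-squares system with a heavily
penalised sum-to-one row (penalty 1e4 x the data scale) followed by exact
renormalisation. The outer problem selects `V` to minimise the pre-period
mean squared prediction error (MSPE) of the synthetic outcome paths on the
raw scale, averaged over outcomes and pre-months.

`V` is searched at predictor-group level — one weight per covariate and one
per outcome series (spread uniformly over its monthly rows) — which keeps
the search space low-dimensional while still letting covariates and
outcomes trade off. The search evaluates: an equal-weight start; an
*outcome-only* start that puts weight proportional to each outcome row's
squared scale on the outcome block and zero on covariates; and (by default)
five seeded random Dirichlet starts, each polished by Nelder–Mead on
softmax-parametrised group logits (default 150 iterations). The best
candidate by outer MSPE wins, with exact ties broken by lexicographically
smallest `W`. The fit is deterministic given the settings seed.

The outcome-only start has a useful property: for that `V` the inner
objective is proportional to the outer objective, so its inner solution
*is* the global minimiser of the outer MSPE over the simplex. The nested
search therefore never returns an objective worse than the true optimum of
the stated outer criterion, which is verified against exhaustive
simplex-grid search in the tests. It also means the fast preset
(`FAST_SETTINGS`: fixed starts only, no polish) attains the same objective
at a fraction of the cost; the replicate studies below use it.

Degenerate inputs: predictor rows with zero donor-pool SD are dropped with
a warning; an outcome whose whole pre-path has zero donor variance is an
error; a single-donor pool forces `W = (1)`.

## Effects and placebo inference

The per-practice effect per outcome is a difference-in-differences of
window means:

```
delta = [mean(treated, post) - mean(treated, pre)] - [mean(SC, post) - mean(SC, pre)]
```

with the pre window running from the first panel month to the month before
join, and the post window from join to the last panel month — or to the
month before a practice's exit, for a practice that leaves the programme.

Inference repeats the entire fit with each donor as a pseudo-treated unit
(its pool being the remaining donors, same join month and windows). The
sample SD of the resulting placebo effects is the standard error;
`CI95 = delta ± 1.96 se` and the two-sided p-value uses the standard
normal distribution. The normal approximation (rather than a rank-based
permutation p) is what makes the per-practice estimates poolable by inverse
variance, which needs SEs. Placebos whose fit fails are dropped and logged;
fewer than 10 surviving placebos is an error. An optional
`mspe_ratio_cap` additionally excludes placebos whose pre-period MSPE
exceeds a multiple of the treated practice's (off by default).

## Pooling

Per outcome, fixed-effect inverse-variance pooling uses `w_i = 1/se_i^2`,
`delta = sum(w d)/sum(w)`, `se = sum(w)^(-1/2)`. Heterogeneity:
Cochran's `Q`, `df = k−1`, `I² = max(0, (Q−df)/Q)·100`, with a test-based
CI on `ln H` (`H = sqrt(Q/df)`, floored at 1) mapped back to the I² scale;
`tau²` is DerSimonian–Laird. The model choice follows the study's rule:
fixed effect when the Q test is not significant at 0.05, random effects
(weights `1/(se² + tau²)`) otherwise; the report records which was used.

## Costing

A pooled effect is converted to avoided events as
`monthly = round(|effect|/100 × population)`, `annual = 12 × monthly` —
rounding the monthly count before annualising, which is the convention that
reproduces all four printed event counts of the motivating study (74→888,
14→168) — and to annual savings as `annual × unit_cost`, where
`unit_cost = round(reference_cost × FCE/FAE)` converts a per-consultant-
episode reference cost to a per-admission cost. Rounding is half-up at the
event and whole-currency level. Sensitivity bounds re-run the arithmetic at
the CI bounds of the effect. Admission and readmission savings are never
summed (avoided readmissions may be a subset of avoided admissions). With
the study's inputs (population 67 402, reference cost 1603, ~20M FCE,
~16.6M FAE) the chain gives unit cost 1931 and, for an effect of −0.11,
savings 1 714 728 with bounds 2 803 812 / 695 160.

## Pipeline, determinism and problem sizes

`run_all` executes simulate/load → donor pools → fits → placebos → pooling
→ costing and emits a JSON report (config snapshot, per-practice weights
and effects, pooled results, cost, warnings, seed registry). All
randomness derives from the single top-level seed (the simulator consumes
it directly; each practice's optimiser seed is derived from it), so a rerun
with the same config is byte-identical. Pre/post windows are computed per
practice from the schedule; no common event-time alignment is imposed.

Problem sizes: the demo configuration (10 treated, 40 donors, 48 months)
runs in about two minutes with default optimiser settings. The calibration
studies in the test suite — 20 replicates of the demo programme for
parameter recovery and 20 null panels (200 practice-level tests) for
type-I error — use the fast preset, about 2.5 s per replicate, for a
suite that completes in a few minutes on one CPU.

## Known limitations

- The placebo-SD/normal-approximation inference is approximate for small
  donor pools; rank-based placebo p-values are not implemented because they
  cannot be pooled by inverse variance.
- Diagonal `V` only; no time-varying `V`, penalised/elastic variants or
  cross-validated pre-period splits.
- `tau²` is DerSimonian–Laird only (no REML/Paule–Mandel), and no
  Hartung–Knapp adjustment.
- The outcome-only optimum of the dependent-variable MSPE criterion means
  covariates influence the fit only when they reduce pre-period outcome
  error through the search; this is a known degeneracy of that outer
  criterion, inherited from the standard formulation.
- The cost model is deterministic arithmetic; no probabilistic sensitivity
  analysis.
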