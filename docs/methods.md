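# Methods

This note records the models the package implements, the assumptions they
make, the numerical choices behind them, and what the synthetic-data
tests do and do not establish.

## Data-preparation rules

Blood-lead values are floored at the laboratory reporting limit: anything
at or below 5 µg/dL is recorded as 2.5 µg/dL and flagged; the flag routes
the sample into the censored branch of the meal-model likelihood.
Independence screening keeps a sample if it is more than 56 days after the
last retained sample, or 14–56 days after it but more than 10 µg/dL
higher (a new exposure event on top of a decaying one). A higher value
less than 14 days after the previous sample replaces it — blood lead from
a single ingestion rises over days, so the later draw is the better
measure of that event — and replacements chain left-to-right, each
becoming the comparator for the next decision. A *lower* repeat inside 14
days is dropped; only the rising case is specified by the screening
protocol, and dropping is the conservative reading. Samples preceded by
more than 3 days of veterinary care or 21 days in a field pen are
excluded because treatment (chelation, captive feeding) decouples blood
lead from wild exposure. The screen is idempotent: filtering a filtered
set is a no-op, which the property suite asserts on random sequences.

Behaviour covariates are proportions over the 180 days strictly before a
sampling date: *Proffered*, *Presence* (detected excluding
proffered-feeding observations) and *Coastal* are divided by free-flying
days, *FreeFly* by the window length. A bird with no free-flying days in
the window has undefined metrics and its sample is excluded rather than
imputed. The Bioyear runs September–August and is labelled by its
starting year; outreach compiled for calendar year Y predicts the Bioyear
starting September Y. *SpringSummer* is March–August. Deer tag counts
before calendar 2015 are multiplied by 1.53 to correct a reporting-rule
change (pig tags are left alone; the reporting change concerned deer).
Bimonthly hunt values average the current and previous month, and model
covariates standardise each bimonthly series by its maximum so hunt
coefficients share a 0–1 scale. GPS QC removes 2D fixes, dilution of
precision above 10 (vertical only when reported), altitudes above 4,000 m
and altitude-above-ground at or below −50 m, then thins to 15-minute
intervals; foraging locations are daytime fixes (06:00–20:00 local unless
solar times are supplied) with speed below 5 kph and AGL below 50 m.

## Exposure mixed models

The response is lnPb. Condor ID and Bioyear enter as crossed random
intercepts (fit through a variance-components formulation over a single
grouping). Selection fits are maximum likelihood, not REML, so AICc
comparisons across fixed-effect structures are valid; k counts fixed
effects plus variance parameters including the residual. All-subsets
enumeration respects marginality (interactions only with their main
effects) and is capped (default 4,096 models) to keep the universe
deliberate. Importance metrics follow the two conventions the field uses:
summed Akaike weights per term, and ratios of model-averaged standardised
coefficients under full averaging (absent terms contribute zero) and
subset averaging. Standardisation uses the partial standard deviation,
sd(x)·√(1/VIF)·√((n−1)/(n−k)), which discounts collinear predictors.
Confidence intervals are Wald at 90% (±1.645 SE); p-values are not part
of the contract because their small-sample approximation in crossed LMMs
is method-dependent.

The year-effect decomposition refits nested models with Bioyear as a
categorical *fixed* effect (all years before 2008 pooled as baseline) and
only the ID random intercept, so the year coefficients are estimable
rather than shrunk; a non-nested sequence warns but still computes. The
scientific signature — year effects flattening as behaviour covariates
are added when behaviour truly drives the trend — is asserted on
synthetic data as a variance reduction.

## The contaminated-meal model

Blood lead in a sample is the sum of contributions from N ~ Poisson(λ)
contaminated meals over the preceding 56 days (≈ 4 half-lives of lead in
condor blood), each Gamma with mean μ and shared shape. λ carries the
full covariate set with a log link; μ carries only the intercept and the
targeted-sample flag, because most covariates plausibly act on encounter
frequency rather than on lead per meal. The Gamma mean necessarily
conflates ingested dose with decay time and body-burden exchange; the
model makes no attempt to separate them. The shape is parameterised by
ζ ∈ (1, 2) with shape = (2 − ζ)/(ζ − 1), giving a bounded uniform prior
that spans very skewed (ζ → 2) to near-normal (ζ → 1) per-meal
distributions. Coefficients get uniform (−100, 100) priors.

Density evaluation truncates the Poisson mixture of Gammas at
N_max = max(25, λ + 10√λ), then verifies the Poisson tail mass is below
1e−12 and extends if not — the bound, not the floor, is the guarantee.
(Profiling put the fixed floor at 25; the explicit tail check makes a
larger floor redundant.) Everything is evaluated in log space via
log-sum-exp. Floored samples contribute log P(Y ≤ 5), which includes the
zero-meal mass e^(−λ); recorded values are never zero, so the point mass
appears only inside that censored integral.

The sampler is adaptive random-walk Metropolis-within-Gibbs over the
blocks (β | γ | ζ), with two refinements found necessary for honest
interval coverage at reduced chain lengths: block proposal covariances
adapt to the empirical burn-in covariance (Haario-style, scaled 2.38²/d),
because uncentred covariates make intercept/slope posteriors strongly
correlated; and a coupled "ridge" move shifts the Poisson and Gamma
intercepts in opposite directions, because the compound mean λμ pins
their sum while their difference mixes slowly. Scales adapt only during
burn-in (default: first half discarded) toward a 0.23–0.44 acceptance
window. Three chains with distinct seeds derived from one master seed;
split-R̂ and an autocorrelation ESS are reported for every parameter, and
a run with any R̂ ≥ 1.05 is returned flagged unconverged, never silently.
Full-scale settings are 3 chains × 40,000 iterations thinned by 3; the
test suite uses 3 × 5,000 on n = 2,000 samples, where 90% intervals
cover true Poisson coefficients at a near-nominal rate on average, with
some finite-sample undercoverage for weakly identified coefficients when
censoring is heavy.

"Meaningful meals" (contributions ≥ 10 µg/dL, a recognised exposure
threshold) use the Poisson thinning identity: expected count per window =
λ · P(G ≥ t) with P from the per-meal Gamma. This analytic form is exact
and deterministic; posterior-predictive simulation would estimate the
same quantity with extra noise. Annualisation multiplies by 6.5 (56-day
periods per year) and reports to one decimal, rounding half up.

## Survival and population growth

Known-fate intervals are Bernoulli with a logit link — complete
monitoring means no detection-probability layer is needed. S_Pb censors
deaths of non-lead known cause at death (removed alive); records are also
censored after 365 consecutive captive days and for deaths in the August
2020 wildfire window. The corrected lead-survival series reassigns
unknown-cause deaths to lead in proportion to lead's share of known-cause
deaths; an interval with unknown deaths but no known-cause deaths is
flagged and left uncorrected rather than guessed. Rolling summaries use a
centred 5-year mean with shrinking end windows (a trailing variant is a
parameter away). Breeding success is a binomial mixed model with a
condor-ID random intercept (variational fit; plain GLM when identities
are singletons), with previous-year history (NonBreeder / FailedBreeder /
SuccessfulBreeder) treatment-coded against NB.

The projection matrix is female-only with a fledging-time census and 16
stages. The default wiring — single-year PreBreeder stages PB1–PB5 with
first breeding attempted at age 5, each breeding-history class crossed
with Juvenile/YoungAdult/OlderAdult bands, and two post-release
acclimation stages R1/R2 — is a declarative structure validated to 16
stages, not a hard-coded matrix, because the exact stage composition is a
modelling choice the data must support. FB-J is structurally present to
complete the history × age grid though unoccupied under default
transitions. History updates follow the definitions: success from any
state leads to SuccessfulBreeder; failure sends recruited breeders to
FailedBreeder and never-successful birds back to NonBreeder. Multi-year
bands age geometrically (YoungAdult graduation probability 1/4). The
reproduction row is female × S_FirstYear × (stage survival × Succ):
chick first-year survival is prepaid in fertility, so the first stage
holds yearlings. Release stages receive no within-matrix inflow —
releases are a management input, so they do not move the growth rate.

λ and the stable stage distribution come from power iteration on A + I
(the unit shift guarantees convergence for the periodic and reducible
matrices that arise when rates are zeroed), with tolerance 1e−10 on both
the eigenvalue change and the residual; tests require 1e−8 agreement with
a dense eigensolver.

## Outreach to survival

The Cox model uses lnPb as sole predictor of the hazard over the 56 days
after sampling, excluding targeted samples (drawn because the bird looked
ill) and wildfire deaths. S56(lnPb) uses the baseline cumulative hazard at
56 days under the fitted centring convention. Scenario lnPb distributions
are normal around the fixed-effects prediction with the model's total
unexplained variance (residual plus random intercepts) by default —
appropriate for a flock-wide prediction that marginalises random effects —
switchable to residual-only; the default grid is 401 points over ±4 SD,
widened automatically until pre-normalisation mass is within 1e−6 of 1.
Because S56 is convex in lnPb over the relevant range, averaging the
survival curve over the density differs from evaluating it at the mean;
the weighted average is the estimand. The Contacts × Boxes surface
evaluates that average per cell and summarises it with an OLS plane with
interaction. Ties in the partial likelihood use the fitter's default
handling; ties are rare in 56-day windows.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the estimators
assume: staggered entry, near-daily detection (≈ 346 monitored days per
year via a daily detection probability of 346/365), behaviour proportions
drifting on the logit scale with correlated individual effects
(correlation is a knob, not an assertion — the real covariance among
behaviour metrics is unknown), seasonal-sinusoid hunt series whose raw
tables round-trip through the 1.53 correction, ramping outreach series,
blood lead drawn from the true compound process and floored, and
mortality with log-hazard linear in lnPb, cause labels drawn from a
configurable lead/other mixture with an unknown-cause fraction. One
`numpy.random.default_rng` (PCG64) seed drives everything, so outputs are
bit-reproducible across platforms.

It does not emulate spatial foraging, county-level use, multi-flock
structure, measurement error in behaviour flags, or serial correlation in
exposure beyond what covariates induce. Passing recovery tests therefore
demonstrates estimator correctness under the stated model, not robustness
to the ways real monitoring data violate it.

Two focused study simulators support reduced-scale calibration. The
meal-recovery design draws n = 2,000 samples with an intercept plus one
standard-normal and one uniform Poisson covariate at moderate censoring.
The outreach study uses a normal lnPb truth (intercept 2.2, Boxes effect
−0.15 over a 0–6 range, individual SD 0.5, residual SD 1.2) and an
exponential 56-day hazard (baseline 0.011, lnPb slope 0.6) at 15,000
samples (~600 events); these sizes were set by an error-budget analysis
so the whole-chain survival-gain estimate sits well inside half a
percentage point of the closed-form value — the Cox slope is the binding
error source, and its precision scales with lnPb spread times the square
root of the event count.

## Known limitations

* The crossed-random-effects fit relies on a variance-components trick in
  the mixed-model backend; with very many levels it is the slowest stage
  of all-subsets selection, so term universes should stay small.
* The variational binomial mixed model for breeding success gives
  point estimates and approximate SDs; a likelihood-ratio workflow would
  need a different backend.
* Convergence flags, not reviewers, guard the MCMC: runs that fail
  split-R̂ < 1.05 are returned flagged, and downstream summaries of a
  flagged run are the caller's responsibility.
* The annualisation factor 6.5 treats the year as 6.5 independent 56-day
  windows; no seasonality within the year is carried into that
  extrapolation.
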