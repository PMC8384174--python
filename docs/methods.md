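# Methods

## Models

### Open-population N-mixture density model

Replicated nest counts `y[i,t]` (plot i, survey occasion t) are binomial
thinnings of a latent integer abundance `N[i,t]` truncated at K.
Initial abundance is Poisson (optionally negative-binomial with
dispersion α, variance λ + λ²/α); between occasions the state evolves as
binomial survivors plus Poisson recruits with time-constant survival ω
and recruitment γ. The site likelihood is a forward recursion over
{0..K}; unsurveyed occasions contribute no detection term and are never
imputed. Truncated pmfs are *not* renormalized, so truncation mass is
visible; the default K is the maximum observed count + 100, and
`check_K_stability` refits at larger K and flags coefficient drift above
0.01 (standardized scale). This diagnostic exists because the
negative-binomial mixture can be unidentifiable in exactly this way —
coefficients that grow without bound as K increases — while the Poisson
stays stable.

Maximization is L-BFGS-B on the link scales (log λ, logit p, logit ω,
log γ, log α) from a moment-based start (λ start = mean count / 0.2,
i.e. assuming detection near the plausible low end) plus seeded normal
perturbations (5 starts by default; the bulk simulation experiments use
1–2 starts, verified against the multi-start optimum on replicate
subsets). Standard errors come from the numerically differentiated
observed information; singular information is reported as an
identifiability warning, never silently replaced. Parameters can be
pinned (`fix_gamma`, `fix_omega`, `fixed`) for generating-structure
recovery fits and profile-likelihood intervals; pinned parameters are
excluded from the parameter count and the information matrix.

The closure test reports the Wald intervals for γ and ω and the expected
per-interval percent change in nest numbers, (ω + γ − 1)·100, negative
values being a decline. The empirical-Bayes latent posterior is the
standard finite-HMM forward–backward smoother conditional on the fitted
parameters; the per-plot abundance prediction is the occasion-1
posterior mode with ties broken toward the smaller N (a conservative
abundance). The posterior mean is also exported.

### Model selection and overdispersion

AICc uses the finite-sample correction 2K(K+1)/(n−K−1); the effective n
for the density analysis is the number of plots (the plot is the
independent sampling unit — a convention this package states openly).
QAICc divides the log-likelihood by ĉ and counts one extra parameter for
ĉ when ĉ > 1, so QAICc at ĉ = 1 is exactly AICc. ĉ comes from a
parametric bootstrap: the Pearson-type statistic
Σ (y − E[y])²/max(E[y], 1e-6) over observed cells (the 1e-6 floor guards
cells where p̂ → 0), compared with the same statistic on B datasets
simulated from the fitted model and refitted (warm-started at the fitted
parameters; the observed missingness pattern is preserved so replicates
share the design). ĉ < 1 is clamped to 1 before inflating SEs, the
standard quasi-likelihood practice. Backward stepwise selection drops
detection terms first with the density structure held full, then density
terms with detection fixed at its winner; criterion ties break toward
fewer parameters, and models within Δ ≤ 2 are labelled parsimonious.
Model-averaged predictions use Akaike weights with the usual
unconditional variance Σ wᵢ(varᵢ + (ŷᵢ − ȳ)²).

### Daily nest survival

Each nest contributes (last_active − first_found)·log s for its known
survival interval plus log(1 − s^w) if it failed, where
w = last_checked − last_active is the failure-uncertainty window
(failure in the half-open interval (last_active, last_checked]); this
closed form equals the exact enumeration over the latent failure day.
s is logit-linked to time-constant nest-site and/or plot-scale
covariates; year enters as an indicator. The AICc sample size is total
exposure days. Period survival is s^T with delta-method SE T·s^(T−1)·se(s);
T defaults to 30 days, the egg-to-fledge exposure period. The
tiered evaluation fits a nest-site candidate set, a plot-scale set
(including within-plot SD covariates), and a multi-scale set combining
covariates from models within Δ ≤ 2 of the tier winners; null and
year-only models appear in every tier, and herbaceous biomass and
exotic-grass cover never share a model (r ≈ 0.77 between them).

### Vegetation statistics

`required_sample_size` implements n = z²s²/B² (B = mean × precision,
z = 1.64 for a 90% interval, precision 0.15) with a small-sample t
correction computed as the smallest n ≥ 2 satisfying
n ≥ t(n−1)² s²/B² — the fixed point that the textbook look-up table
tabulates; the naive back-substitution oscillates around it for small n.
The collinearity screen removes the lower-priority member of every pair
with |r| ≥ 0.6 (default priorities: biomass over VOR and grass heights,
shrub cover over shrub height, litter over bare ground), except
biomass/exotic-grass, which are both retained but flagged mutually
exclusive. Cross-scale correlations (nest-site value vs plot mean, plots
with ≥ 1 nest only) use Pearson r with the exact t-based p-value after
configurable log/logit transforms (proportions at exactly 0 or 1 are
nudged by 1/(2n)); "meaningful" requires |r| > 0.6 *and* p < 0.05.

### Productivity

Per plot, productivity = N̂ (posterior mode) × DSR̄^30, where DSR̄ is the
model-averaged daily survival predicted from the plot's vegetation via
the plot-scale candidate set. The regression of productivity on biomass
is ordinary least squares on the raw kg/ha scale so the slope reads
directly as successful nests per plot per kg/ha; an effect is flagged
"predictive" only when its 95% CI excludes 0 and adjusted r² > 0.6.
Jarque–Bera and Breusch–Pagan summaries accompany the fit.
`scale_to_management_unit` converts the slope to any management area via
the unit-to-plot (9 ha) ratio.

## The synthetic-data generator

The generator reproduces the sampling design the analysis assumes:
100 plots of 9 ha; 3 survey occasions 9 days apart with 29% of plots
missing the third; per-survey detection with logit p = a − 0.20·(shrub %),
a set so detection averages ≈ 0.15–0.16; between-survey dynamics
ω = 0.87, γ = 0; daily nest survival 0.93, constant across covariates
(survival in this system showed no vegetation effects, and the default
honors that). Plot covariates are multivariate normal on transformed
scales (log biomass, logit covers, identity slope) with a latent
biomass–exotic correlation of 0.77. Biomass has CV ≈ 0.9 and shrub cover
spans ~0–15%: these spreads are set so that the generator reproduces the
documented effect magnitudes — nest density falling ≈ 12% per 100 kg/ha
(≈ −1.6 per SD of biomass) and detection falling from ≈ 0.38 to ≈ 0.04
as shrub cover runs 0→10%.

Abundance level: 2.65 nests per plot is the number *found* in the field,
not the number present. With daily survival 0.93 a nest is discoverable
on (1 − s³⁰)/(30(1 − s)) ≈ 42% of study days, so the generator
calibrates λ so that E[nests found per plot] = 2.65, implying true mean
abundance ≈ 6.3 per plot (consistent with ~1 new nest per survey pass at
p ≈ 0.16). Experiments that explicitly study a pinned abundance use the
`mean_abundance` override instead.

Encounter histories: nests initiate uniformly over a 20-day window,
survive daily Bernoulli(DSR) up to 30 days; a candidate discovery day is
uniform over the 30-day period and the nest enters the sample only if
still active that day — conditionally the discovery day is uniform over
the active days, and discovery is properly length-biased, so short-lived
nests often die unfound. This is what makes apparent success (~28%)
exceed true 30-day survival (~11%), the survivor bias the exposure
likelihood corrects. Found nests are rechecked every 3 days.

What the generator does *not* emulate: spatial autocorrelation between
plots, renesting linkage (recruitment is memoryless), within-season
initiation pulses, observer-level detection variation, and date/weather
effects on detection (those covariates are generated but carry no effect
by default). Passing recovery tests therefore demonstrates correctness
of the estimators under the stated design, not robustness to every field
complication.

## Numerical choices and conventions

- Sample SD (n−1) everywhere, for covariate standardization and plot-SD
  covariates; coefficients are reported on the standardized scale with
  the (mean, sd) context retained for raw-scale restatement.
- Days are integers from a season origin; intervals half-open for
  exposure arithmetic.
- Cover bins map to midpoints (0–5 → 2.5%, ..., 96–100 → 98%).
- Observer biomass calibration: estimates shifted by the observer's mean
  (estimated − clipped) difference, converted to dry mass by the overall
  mean (green − dry) difference, floored at 0; 0.1 m² frames scale
  g/frame to kg/ha (×100).
- Link-scale parameters are bounded at ±20 during optimization; the
  recruitment bound acts as the γ → 0 boundary.
- Interval coverage in the recovery experiments uses profile-likelihood
  (LR inversion at the true value) rather than Wald intervals, because
  ω̂ sits on its boundary in a nontrivial fraction of replicates at the
  study's low detection, where Wald intervals from the observed
  information are degenerate.

## Known limitations

- At the study design (M = 100, detection ≈ 0.16), the ML estimator of
  the log-abundance intercept is right-skewed: its mean overshoots the
  truth by ≈ 0.1–0.2 (sampling SD ≈ 0.6) even though profile-likelihood
  coverage is nominal. This is a finite-sample property of N-mixture
  likelihoods at low detection — it vanishes by M ≈ 2000 — and the
  corresponding recovery assertion in the test suite documents it as a
  known failure rather than hiding it.
- The empirical-Bayes abundance necessarily loads on the observed
  counts, so the correlation between raw counts and N̂ in simulations is
  strong (≈ 0.7–0.9) across every faithful parameterization tried; a
  weak observed-vs-estimated correlation like the one reported from the
  field data is not reproduced by this model family at this design, and
  the corresponding test records that expectation as unmet.
- Simulation experiment sizes (200 recovery replicates, B = 100/30
  bootstrap, 10–100 replicates for selection behaviour) were chosen so
  the full suite runs in minutes on a single CPU; Monte-Carlo error at
  those sizes is reflected in the stated tolerances.
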