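# nestmix

Detection-corrected nest density, daily nest survival, and plot-scale
productivity for grassland songbirds, estimated from replicated
nest-search surveys.

## The problem

Counting songbird nests by searching a plot misses most of them: rope-drag
surveys detect a given nest with probability well below one, and the set
of active nests changes between survey passes as nests fail and new ones
are initiated. Raw counts therefore underestimate nest density, with a
bias that varies across space (detection falls sharply with shrub cover).
`nestmix` implements the full inference chain that corrects for this:

1. **Nest density** — an open-population N-mixture model for replicated
   counts. The latent number of active nests on plot *i* at occasion *t*
   follows

   N<sub>i1</sub> ~ Poisson(λ<sub>i</sub>), λ<sub>i</sub> = exp(x<sub>i</sub>′β<sub>λ</sub>),
   N<sub>it</sub> | N<sub>i,t−1</sub> = Binomial(N<sub>i,t−1</sub>, ω) + Poisson(γ),
   y<sub>it</sub> | N<sub>it</sub> ~ Binomial(N<sub>it</sub>, p<sub>it</sub>), logit p<sub>it</sub> = w<sub>it</sub>′β<sub>p</sub>,

   fitted by a forward recursion over the truncated latent state
   {0..K}. Estimated survival ω < 1 or recruitment γ > 0 is direct
   evidence that the nest population is not closed within the survey
   window. A negative-binomial initial mixture is available, with
   truncation-stability diagnostics that catch its identifiability
   pathology. Overdispersion is handled with a parametric-bootstrap
   goodness-of-fit test (ĉ), QAICc model selection with backward
   stepwise search, and ĉ-inflated intervals. Per-plot nest abundance
   N̂<sub>i</sub> is the mode of the empirical-Bayes posterior over the
   latent state.

2. **Nest survival** — a daily-survival (DSR) exposure likelihood over
   encounter records (first found, last active, last checked, fate),
   with the failure day integrated over its uncertainty window:
   ℓ = e·log s + [failure]·log(1 − s<sup>w</sup>). Candidate models are
   evaluated in tiers (nest-site, plot-scale, multi-scale) under AICc,
   and period survival is s<sup>30</sup> with a delta-method SE.

3. **Productivity** — expected successful nests per 9-ha plot,
   N̂<sub>i</sub> · s̄<sub>i</sub><sup>30</sup>, regressed on habitat
   covariates (biomass in kg/ha on the raw scale) to produce
   management-unit effect statements.

A synthetic-study generator reproduces the sampling design end to end
(100 plots, 2–3 surveys 9 days apart, detection ≈ 0.16 declining with
shrub cover, ω = 0.87, γ ≈ 0, DSR = 0.93, ~2.65 nests found per plot,
biomass–exotic-grass correlation 0.77), with the full truth channel, so
every stage is verified by parameter-recovery experiments rather than
against undeposited field data.

## Worked example

Generate a synthetic study and run the whole pipeline (a few minutes;
the bootstrap dominates):

```sh
nestmix simulate --seed 5 --out study/ --plots 100

cat > config.yaml <<EOF
seed: 5
density_covs: [biomass, forb_cover, forb_cover^2, slope, slope^2]
detection_covs: [shrub_cover]
survival_plot_covs: [biomass, forb_cover]
productivity_predictor: biomass
bootstrap_B: 100
EOF

nestmix productivity --counts study/counts.csv --nests study/nests.csv \
    --plot-covariates study/plot_covariates.csv --config config.yaml \
    --out results/
```

which logs, for that seed:

```
[nestmix] comparing Poisson vs negative-binomial mixtures
[nestmix] bootstrap goodness of fit (B = 100)
[nestmix] backward stepwise selection (detection, then density)
[nestmix] tiered DSR candidate evaluation
[nestmix] productivity ~ biomass: slope = -0.000431792 (95% CI -0.000518998 to -0.000344586)
```

and writes the report fragments to `results/`. On this realization the
closure test gives ω̂ = 0.93 with a 95% CI of (0.60, 0.99) — below 1, so
the nest population is flagged open within the survey window; the
constant-model daily survival is 0.933 ± 0.005, i.e. 30-day period
survival 0.124 ± 0.020, far below the apparent success rate of 0.32
(survivor bias from finding nests mid-life). The regression slope says
each additional 100 kg/ha of standing herbaceous biomass costs ≈ 0.043
successful nests per 9-ha plot; over a 1000-ha unit and a 1000 kg/ha
biomass contrast that is ≈ 48 fewer successful nests
(`scale_to_management_unit` restates the slope at any management scale).
`results/` contains the model-selection tables, closure test, per-plot
productivity table and DSR predictions, and the regression report.

The same stages are available as library functions
(`nestmix.pipeline.run_density` / `run_survival` / `run_productivity`),
and each underlying operation (`fit_dm`, `latent_posterior`, `fit_dsr`,
`parametric_bootstrap_gof`, `backward_stepwise`, ...) can be used on its
own.

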