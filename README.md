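# nmixtrend

Binomial N-mixture modelling of repeated count surveys: abundance under
imperfect detection, AIC model screening, Bayesian hierarchical trend
estimation, and simulation-based power analysis for monitoring design.

The package grew out of line-transect monitoring of singing male Aquatic
Warblers (*Acrocephalus paludicola*) in fen mires, where each of 50
transects is walked three times within a week every year and raw counts
systematically miss birds.  It is written for ecologists and monitoring
programmes with the same data shape: counts per (site, year, visit), habitat
covariates per (site, year), weather covariates per visit.

## The model

Abundance and observation are separated hierarchically:

    N_it ~ Poisson(lambda_it)                     latent super-population
    y_itj | N_it ~ Binomial(N_it, p_itj)          replicate counts

    log lambda_it = beta0 + b_i + r*t + x_it' beta      (habitat, trend)
    logit p_itj   = alpha_year[t] + alpha' v_itj        (year, weather, habitat)
    b_i ~ Normal(0, sigma_b^2)                          (transect random effect)

Repeated visits within a closure window identify detection probability p
and abundance lambda jointly.  The latent N is marginalized out of the
likelihood (log-sum-exp to a truncation bound K); maximum-likelihood fits
screen a 45-model candidate set by AIC, and the final model is fitted by a
blocked adaptive-Metropolis sampler with vague priors.  Derived posteriors
give annual super-population totals, detection-correction factors versus
the best raw round count, corrected full-census extrapolations, and the
population trend.  See `docs/methods.md` for the full account.

## Worked example

```python
import nmixtrend as nt

# a synthetic survey at the study's scale: 50 transects x 3 years x 3 visits
dataset, truth = nt.generate_dataset(nt.GeneratorConfig(seed=42))

# screen two candidate models by AIC
table, fits = nt.fit_candidate_set(
    dataset,
    [s for s in nt.build_candidate_set()
     if s.label in ("water depth | Year + rain + vegetation height",
                    "water depth | constant")],
)
print(table[["abundance", "detection", "k", "AIC", "dAIC", "wAIC"]])

# fit the Bayesian trend model (desk profile: 3 chains x 20k iterations)
results = nt.TrendModel(dataset).fit(nt.TrendModelConfig.desk(seed=11))
print(results.annual_totals().round(1))
print(results.trend_summary().round(3))
ppc = results.posterior_predictive_check(seed=0)
print(f"Bayesian p-value = {ppc.p_value:.2f}, slope = {ppc.slope:.3f}")
```

Output (abridged):

```
     abundance                        detection   k      AIC   dAIC  wAIC
0  water depth  Year + rain + vegetation height  12  2656.39   0.00   1.0
1  water depth                         constant   8  2668.67  12.28   0.0

        mean    sd    lcl     ucl
year
1     1062.7  70.3  947.0  1229.0
2      968.7  46.5  888.0  1072.0
3      907.1  77.5  785.0  1085.0

mean                   -0.076
sd                      0.062
lcl                    -0.195
ucl                     0.055
pct_change_per_year    -7.296
Bayesian p-value = 0.33, slope = 1.035
```

The annual totals are posterior means of the summed latent abundances
Sigma_i N_it — each with a 95% credible interval, and always at least the
year's best single-round raw count (here 687/665/544): the ratio of the two
is the detection-correction factor.  The trend row is the log-linear change
per year with its credible interval (this replicate was generated with zero
trend, and the interval duly straddles zero); a Bayesian p-value away from
the tails and a predicted-vs-observed slope near 1 indicate adequate fit.

The power analysis compares the mixture model's trend credible interval
with a raw-count regression on identical simulated surveys:

```python
from nmixtrend.power import PowerScenario, run_power_analysis
result = run_power_analysis(PowerScenario(n_sims=100, seed=1, estimator="rawcount"))
print(result.summary())
```

A `nmixtrend` console script exposes the same steps
(`simulate`, `fit-ml`, `fit-bayes`, `power`); see `nmixtrend --help`.

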