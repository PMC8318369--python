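# policyspill

Interdependent program evaluation for staggered, state-level policies whose
effects spill across jurisdiction borders — built around the COVID-19
closure/reopening setting, where one state's shelter-in-place order changed
mobility not only at home but in the counties socially and geographically
connected to it.

The package provides, as a tested pipeline:

- **Network-weighted policy exposures.** County-to-county social
  connectedness scores (the long `ego, alter, sci` format of the Social
  Connectedness Index) are population-weighted, restricted to out-of-state
  alters, and row-normalized, so that a county's *spillover exposure* to a
  policy is the weighted fraction of its alter states that have enacted it.
- **Two-way fixed-effects DiD estimation** of direct and spillover effects
  on log mobility outcomes, with county and day effects absorbed by weighted
  alternating projections, population-weighted WLS, and state-clustered
  standard errors.
- **Dyadic cross-state travel models** on directed county-pair panels, with
  origin/destination policy effects, their full 3×3 interaction grid,
  nearby/distant (<100 km / >100 km) subgroup estimation, and two-way
  origin/destination state clustered standard errors.
- **Fisherian randomization inference** that permutes entire state policy
  timelines across states and rebuilds indicators and exposures per draw.
- **A synthetic-data generator** with known ground truth, so every estimator
  is validated end to end without any proprietary mobility or connectedness
  data.

## Models

Policies are collapsed into three absorbing periods — initial policies (ip),
shelter-in-place (sh), reopening (ro) — with indicator
`D_it^(m) = 1` from the enactment date onward. The county-day models are

```
log Y_it = Σ_m δ_m D_it^(m)                     + θ'X_it + α_i + τ_t + ε_it   (eq1)
log Y_it = Σ_m δ_m D_it^(m) + Σ_m γ_m D̄_it^(m) + θ'X_it + α_i + τ_t + ε_it   (eq2)
```

where `D̄_it^(m) = Σ_j w_ij D_jt^(m)` averages alter counties' indicators
through the row-stochastic connectedness matrix `w`, so δ are direct effects
and γ are spillover effects (in log points; reported as `100·(exp(β)−1)`
percent). The dyadic travel models for flows from origin county *o* to a
destination county *d* in a different state are

```
log Y_odt = Σ_m λ_m D_ot^m + Σ_n ψ_n D_dt^n [+ Σ_mn π_mn D_ot^m D_dt^n]
            + θ1'X_ot + θ2'X_dt + α_od + τ_t + ε_odt                     (eq3/eq4)
```

with directed-pair and day fixed effects; the marginal effect of destination
policy *n* given origin period *m* is `ψ_n + π_mn`.

## Worked example

```python
from policyspill import SimConfig, simulate_all, fit_spillover_did

world = simulate_all(SimConfig(seed=7), dyads=False)   # 40 states x 5 counties x 120 days
fit = fit_spillover_did(world["county_panel"], model="eq2",
                        outcome="locations_visited")
print(fit.tidy()[["term", "estimate", "se", "pct"]].head(6).to_string(index=False))
```

prints

```
  term  estimate       se       pct
  d_ip -0.009960 0.002054 -0.991012
  d_sh -0.032028 0.002114 -3.152028
  d_ro  0.023967 0.002349  2.425685
exp_ip -0.066950 0.005581 -6.475758
exp_sh -0.098145 0.006313 -9.348265
exp_ro  0.158873 0.004586 17.218903
```

i.e. shelter-in-place directly reduced mobility by ≈3.2% while all alter
states sheltering in place reduced it by a further ≈9.3%, and alter-state
reopening raised it by ≈17.2% — against generating values of −2.96%, −9.52%
and +17.35%. The numbered scripts under `analysis/` run the full study:
world construction, weight diagnostics, county DiD, dyadic travel models
with the interaction grid, and randomization inference; each writes its
tables under `results/`.

A command-line interface mirrors the pipeline stages
(`policyspill simulate | weights | exposures | fit | fit-dyadic | ri |
report | run`); `policyspill run --config cfg.yaml` executes every
configured stage and writes coefficient tables plus a reproducibility
manifest.

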