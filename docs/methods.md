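# Methods

## Setting and models

The package evaluates staggered state-level policy interventions whose
effects spill over jurisdiction borders. Policies are collapsed into three
periods — initial policies (ip), shelter-in-place (sh), reopening (ro) —
each encoded as an **absorbing** indicator: `D_it^(m)` switches to 1 on the
enactment date of county *i*'s state (inclusive) and never reverts. Under
this coding the coefficients measure average marginal outcome differences
between consecutive policy periods; a mutually-exclusive period coding would
instead measure differences against the pre-period baseline. Absorbing
coding is the default throughout.

Two county-day difference-in-differences specifications are estimated on
log-transformed mobility outcomes with county (`α_i`) and day (`τ_t`) fixed
effects: a no-spillover model with the three own-state indicators (eq1), and
a spillover model adding the three alter-state exposures (eq2)

    D̄_it^(m) = Σ_j w_ij · D_jt^(m),

where `w` is the row-stochastic connectedness matrix described below, so
every exposure lies in [0, 1] and equals the indicator itself when all
states share one timeline. Estimation is weighted least squares with county
population as weights; the eq2 design nests eq1.

The dyadic travel models regress log flows of a directed cross-state county
pair (origin *o*, destination *d*) on origin and destination policy
indicators — optionally with all nine origin-by-destination products —
absorbing directed-pair and day fixed effects. The device-count outcome is
fit unweighted; the flow-proportion outcome is weighted by origin county
population. The marginal effect of destination policy *n* given origin
period *m* is `ψ_n + π_mn` with delta-method standard error
`sqrt(Var ψ + Var π + 2 Cov)`; at the pre-policy origin baseline the π term
is absent. Subgroups (nearby `< 100 km`, distant `> 100 km`; pairs exactly
at the threshold belong to neither) are estimated by refitting on the masked
sample with their own fixed effects, not by triple interactions, so each
subgroup carries its own pair/day structure.

## Connectedness weights

Raw connectedness scores in the long `ego, alter, sci` format are
transformed in two steps:

1. **Population weighting**: `weight(i, j) = sci(i, j) · pop(j)`; missing
   pairs count as zero, self-weights are removed.
2. **Alter-state restriction, then normalization**: every alter in the
   ego's own state is zeroed (own-state policy is already the direct-effect
   term), and the remaining row is renormalized to sum to one. Egos left
   with no out-of-state mass are *flagged* — their rows stay at zero, they
   are excluded from exposure construction, and they are reported in the
   diagnostics rather than silently renormalized.

Restrict-then-normalize is the implemented order; the transform is exposed
as a function so alternative SCI transformations can be plugged in. The
restriction never changes the ranking of out-of-state alters, and
normalization is idempotent.

## Estimation and inference

Fixed effects are absorbed by **weighted alternating projections**: iterated
weighted group-mean subtraction over the two groupings until the largest
mean removed in a sweep falls below 1e-10 (at most 500 sweeps; failure
raises an error carrying the convergence trace). On balanced panels with
county-constant weights this converges in two sweeps; on every test instance
the result matches an explicit dummy-variable WLS fit (the
Frisch–Waugh–Lovell identity is the central estimator oracle). Singleton
groups are retained. Rank deficiency after demeaning is detected by pivoted
QR and reported with the offending column names.

Weights enter as raw county population, not normalized shares: point
estimates are invariant to the weight scale and the sandwich covariance is
scale-invariant as implemented, so the choice only fixes an interpretation.

Cluster-robust covariance is the CR1 sandwich
`c · (X'WX)⁻¹ (Σ_g s_g s_g') (X'WX)⁻¹` with `s_g` the per-cluster score sum
and `c = G/(G−1) · (N−1)/(N−K)`, where `K` counts both the explicit
regressors and the absorbed fixed-effect dimensions. Confidence intervals
use t critical values with `G − 1` degrees of freedom. Two-way clustering
(origin and destination state for the dyadic models) uses
inclusion–exclusion `V_a + V_b − V_{a∩b}`, each component with its own CR1
factor; if the combination is not positive semidefinite, negative
eigenvalues are truncated at zero and the repair is flagged. With singleton
clusters both schemes collapse to the heteroskedasticity-robust sandwich
with matching correction.

**Randomization inference** tests the sharp null of no policy effect by
permuting entire state timelines (ip, sh, ro as a block) across states —
preserving every within-state ordering and the national adoption profile —
and rebuilding indicators *and* spillover exposures for each draw before
refitting. The statistic is the state-clustered t ratio; the two-sided
Monte-Carlo p-value is `(1 + #{|t*| ≥ |t_obs|}) / (1 + B)`, bounded below by
`1/(B+1)`; exhaustive enumeration (identity included) is available for small
state counts. Because response and control columns do not change across
draws, they are demeaned once and only the policy columns are re-projected
per draw, which keeps B = 199 draws on a ~2,000-row panel around 0.2 s.

## The synthetic generator

The generator is the package's study population; every default is a fixed
condition, not a tuning knob.

- **Geography**: `n_states = 40` states × `counties_per_state = 5` counties,
  centroids jittered (SD 0.7°) around state centers drawn in a
  continental-US-like box; county population log-normal(10.5, 1); mean
  devices ≈ 5% of population with log-normal dispersion, so a realistic
  minority (~10%) of counties falls under the 500-mean-device sample filter.
- **Timelines**: `n_days = 120` from 2020-02-15. Enactment dates are drawn
  uniformly within per-period windows (ip 03-01..05-01, sh 03-15..05-15,
  ro 04-01..06-01), each truncated below at the previous period's draw so
  ip ≤ sh ≤ ro always holds; configuration is rejected if the windows cannot
  guarantee that ordering. A fraction of states adopts partially
  (8% never treated, 10% without sh, 10% without ro). This serves two
  purposes: realism (several US states never issued stay-at-home orders)
  and identification — with fully compressed windows and universal adoption,
  absorbing interaction columns collapse onto main effects (`o_ip·d_ro`
  equals `d_ro` once every state has ip before any reopening), and the
  full interaction model would be unidentified, as it would be on the real
  calendar too.
- **Connectedness**: gravity kernel `pop_i · pop_j / (1 + d_ij)^η` with
  η = 1.5, so an ego's top alters mix nearby counties and distant populous
  ones.
- **County panel**: log outcomes follow eq2 as the data-generating process
  with δ = (−0.01, −0.03, 0.025), γ = (−0.07, −0.10, 0.16) log points,
  θ = (0.004, −0.02) on two AR(1) county-level controls (a temperature-like
  mean-reverting series and a cumulative-case-like drifting series), county
  effects N(0, 0.3²), day effects N(0, 0.1²), noise SD 0.05. Exposures are
  built with the same connectivity/exposure code the estimators consume, so
  zero-noise runs are exactly identified. Four outcomes share the structural
  part and differ in baseline level and noise draw.
- **Dyad panel**: only cross-state directed pairs (optionally subsampled to
  `max_dyad_pairs`); baseline flows are ~0.2% of origin devices with
  gravity-style distance decay, λ = (−0.01, −0.05, 0.04),
  ψ = (−0.01, −0.05, 0.05), and π rows (ip, sh, ro) =
  (0, 0, 0), (0.03, 0.02, 0.07), (0, −0.05, −0.01) — closures at the origin
  amplify the pull of reopened destinations, reopened origins dampen travel
  into still-closed destinations. Origin device counts are held constant
  over days, so count and proportion outcomes differ by a pair-level shift
  absorbed by pair effects.

What the generator does **not** emulate: differential-privacy noise in
device counts, sampling bias of device panels, serial correlation or spatial
correlation in ε beyond what fixed effects induce, endogenous policy timing
(timelines are drawn independently of potential outcomes, so DiD's
identifying assumptions hold by construction), county-level policy
deviations from state policy, bounded proportions for the county-level share
outcomes, and any epidemic dynamics. Passing tests therefore certify the
estimators' algebra and sampling behavior under a correctly specified
log-linear DGP — not robustness to the observational confounds of real
mobility data.

## Numerical and design choices

- Demeaning tolerance 1e-10, max 500 sweeps; group means via `bincount`
  accumulation.
- Percent conversion is the exact `100·(exp(β)−1)` (the `100·β`
  approximation is reported alongside in tidy tables).
- Zero flows are dropped (with a logged count) before the log transform by
  default; a `log(1+Y)` option exists and changes interpretation.
- The indicator is 1 **on** the enactment date.
- Randomization draws are uniform random permutations with the add-one
  p-value correction; exhaustive mode enumerates all orderings and uses the
  plain proportion.
- Reported simulation sizes: oracle-equivalence fixtures use 12 counties /
  4 states / 20 days (county) and 8 directed pairs / 3 states (dyadic);
  recovery and coverage use 200 replicates of the default
  40 × 5 × 120 world; the randomization size study uses 500 sharp-null
  panels of 8 states × 2 counties × 120 days at B = 199. The acceptance
  script uses 60 recovery replicates and 200 size simulations.

## Limitations

- Exposures are computed from county-level indicator series; because policy
  is statewide these coincide with state-aggregated series, but a
  county-level policy extension would need to choose.
- The two-way cluster PSD repair (eigenvalue truncation) changes the
  covariance when triggered; the flag should be checked in small samples.
- The interaction model's identification depends on overlap in adoption
  timing; with near-universal simultaneous adoption the grid is inherently
  not estimable, and the fitter reports the collinear columns rather than
  guessing.
- No wild cluster bootstrap, spatial HAC, adjacency-robust errors,
  event-study leads/lags, or instrumental-variables estimators.
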