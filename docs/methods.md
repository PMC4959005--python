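# Methods

## The estimand and the model

`dislife` quantifies compression (or expansion) of disability: whether
successive birth cohorts of US adults — with and without diagnosed
diabetes — become disabled later and spend fewer of the years between
ages 50 and 70 disabled. Three outcomes are modelled per disability
domain and stratum (sex × diabetes group × birth cohort):

* **DFY** — expected disability-free years within the horizon,
* **DY** — expected disabled years,
* **LYL** — life-years lost to death before age 70
  (`LYL = horizon − DFY − DY` by construction),
* **average onset age** — defined as `baseline age + DFY`.

The engine is a five-state discrete-time Markov cohort model with an
annual cycle: not disabled (ND), short-term disabled (STD, disabled
under one year), not disabled with disability history (NDH), long-term
disabled (LTD), and dead (absorbing). STD and NDH are one-cycle bridge
states that encode the high remission rates seen in panel data: a newly
disabled person spends exactly one cycle in STD and then recovers (to
NDH), dies, or settles into LTD. Four annual hazards drive the chain —
onset, remission, death while non-disabled, death while disabled —
entering the rows as

| from | to STD/NDH | to DEAD | stay |
|------|------------|---------|------|
| ND   | onset → STD | death_nd | 1 − onset − death_nd |
| STD  | remission → NDH | death_dis | remainder → LTD |
| NDH  | onset → STD | death_nd | 1 − onset − death_nd |
| LTD  | remission → NDH | death_dis | remainder stays LTD |

Modelling assumptions worth stating explicitly:

* mortality and onset depend on current disabled/non-disabled status
  only, not on disability history (ND and NDH share a row; STD and LTD
  share exit probabilities);
* long-term disabled persons may recover at the same annual remission
  probability as the short-term disabled;
* occupancy is credited at cycle start with no half-cycle correction.
  This makes `DFY + DY + LYL = horizon` exact and makes the onset-age
  identity `onset = baseline + DFY` hold mechanically — both identities
  are satisfied, to rounding, by every row of the published life tables
  this design mirrors, which is the reason these accounting conventions
  were chosen over first-passage-time definitions;
* DFY counts NDH (post-recovery) years as disability-free, as the onset
  identity requires.

## From biennial waves to annual probabilities

Disability is domain-specific and item-coded: mobility loss is
difficulty with ≥4 of 5 mobility tasks; IADL and ADL disability are
difficulty with ≥1 of 5 tasks in the respective domain. A wave with any
missing item in a domain has missing status for that domain at that
wave only. Diabetes is a fixed person-level population label: a
diagnosis reported at any interview places the person in the diabetes
group for their entire record. Cohort 1 is born 1931–1941 with a 1992
baseline; cohort 2 is born 1942–1947 with a 2002 baseline; anything
else is excluded.

Waves are two years apart, so each transition model is a pooled
logistic regression on wave-pair person-periods — logit-linear in age
(centred at 50) with a sex main effect — fitted separately per
transition × domain × diabetes group × cohort, with cluster-robust
(sandwich) standard errors by person. This is the working-independence
GEE: point estimates equal the pooled logistic fit; the variance is
robust to within-person correlation. Persons disabled in a domain at
their baseline interview are excluded from that domain's incidence and
remission estimation (remission is estimated among the incident
disabled only); mortality models use all observed person-periods by
current state. Onset and remission condition on surviving the interval;
death is a separate binomial model per start state.

Fitted two-year probabilities are converted to annual ones by the
constant-hazard complement root `p₁ = 1 − (1 − p₂)^(1/2)` and clipped
proportionally to the row simplex (onset + death ≤ 1, remission +
death ≤ 1) with a logged warning when a violation occurs.

**Known structural bias of the biennial→annual conversion.** Within a
two-year interval a person can become disabled and recover, or die
after onset; biennial endpoints cannot see this. At a diabetic
operating point (annual onset 0.067, remission 0.159, deaths
0.029/0.045) the exact two-step embedding shows the annualized onset
estimand is 0.0624 (−0.0046), remission 0.1607 (+0.0017), deaths
+0.0006/−0.0013. The remission estimand bias grows with mortality
(conditioning on interval survival selects recovered survivors): up to
+0.027 at the oldest ages of the default curves. The life-table
consequence is small and second-order — DFY is reproduced within about
0.05–0.2 years end-to-end — but per-probability comparisons against
generating curves must use the embedding estimand, not the raw annual
constant, as their reference.

## Attrition and weighting

Wave nonresponse is handled by inverse-probability weighting: a
logistic model of response at each follow-up wave given age, sex, the
previous wave's disability status (last observed, carried forward) and
prior response. A complete survivor pair is weighted by its sampling
weight times `1/p̂(respond at end wave)`; intervals ending in death need
no reweighting because vital status is always recorded (emulating
death-index linkage). Combined weights are renormalized to the analytic
sample size of each model so robust standard errors stay on a sensible
scale.

A property of this design worth knowing: because the five-state process
is memoryless given current state, age, and sex, and because response
depends only on pair-start information, complete-pair estimation is
already consistent — the weights correct the sampling geometry but have
no systematic bias to remove under the synthetic generator's default
missing-at-random mechanism. Weighted and unweighted estimates coincide
to ~1e−5 in practice, so "IPW beats unweighted" comparisons on
synthetic data behave like a fair coin. On real survey data, where
nonresponse can track current (unobserved) health and unmodelled
heterogeneity, IPW matters; passing synthetic tests therefore shows the
weighting machinery is correct, not that attrition bias exists to be
removed in the synthetic world.

## Monte Carlo uncertainty

Coefficient vectors for the four transition models are drawn from their
asymptotic multivariate normal distributions (nearest-positive-definite
repair of the robust covariance when needed), pushed through prediction,
annualization, simplex clipping, and the cohort engine. The default
ensemble is 10,000 draws, 5,000 per sex; tests and the reproduction
script use 500/sex, which is ample for 95% percentile intervals.
Intervals are empirical 2.5/97.5 percentiles (at least 100 draws
required). Cohort and group contrasts use independent ensembles paired
by draw index; the two-sided p-value is `2·min(share ≥ 0, share ≤ 0)`
clipped to 1 and floored at `2/n_draws`. Degenerate strata (no events)
pin their probability at the observed constant with an
infinite-variance flag and are excluded from drawing.

## The synthetic panel generator

Because the source survey data are restricted, a generator emulates
their structure with known ground truth: biennial waves (default 6),
birth-cohort windows and baselines as above, baseline ages 50–62,
item-level disability in three domains, exact death years, wave-level
nonresponse, and lognormal sampling weights normalized to mean 1
(σ = 0.5). Each person evolves annually through the five-state chain
using logit-linear-in-age hazard curves for their sex × diabetes group;
waves observe every second year. One latent disabled/non-disabled state
drives the item draws in all three domains (uniform over qualifying
item patterns), so the classification rule recovers the latent state
exactly and classify-then-estimate is an identity in expectation; an
independent per-domain death process would make vital status
inconsistent across domains, which is why the domains share dynamics.

Default hazard curves are anchored to published US panel estimates for
adults 50–70: diabetic onset near 6.7/100 person-years, remission near
16/100, mortality 2.9/100 non-disabled rising with age and 4.5/100
disabled; the diabetes-free population has roughly a third the onset
hazard, higher remission, and lower mortality; women carry ~0.3 lower
log-odds of death. Diabetes group membership (ever-diagnosed, 10%
baseline prevalence plus 1.2%/year incidence) is drawn first and the
person follows their group's curves throughout, so the ground-truth
life table per group is an exact closure of the cohort engine on the
true curves. Baseline disability prevalence is 10%. Default follow-up
response is ~91% for the non-disabled, dropping for the recently
disabled (−0.8 log-odds), prior nonresponders (−1.2) and with age
(−0.012/year).

What the generator does **not** emulate: survey strata/PSUs and
post-stratified weights, proxy interviews, item-level measurement
error, person-level frailty or duration dependence, and nonresponse
driven by current unobserved health. Passing recovery tests therefore
demonstrates correctness of the estimation and projection machinery
under the model's own assumptions, not robustness to real-data
violations of them.

## Numerical and testing choices

* Determinism: one `numpy` Generator seeded from the config; identical
  seeds give byte-identical panels; Monte Carlo ensembles are
  reproducible from their seed.
* Degenerate inputs: constant-outcome strata are pinned with
  infinite-variance flags; perfect separation falls back to a weakly
  penalized logistic fit (α = 1e−4) with expected-information
  covariance, logged.
* Problem sizes: the microsimulation cross-check uses 200,000 walkers
  (occupancy SE ≤ 0.0011 per cell); end-to-end recovery uses one
  20,000-person single-group panel; the weighting comparison 10
  replicate panels of 20,000; interval coverage 100 replicate panels of
  2,000 persons with 500 draws per sex. These sizes give Monte Carlo
  error comfortably below the tolerances being checked while keeping
  the full suite fast.
* Ages 50–70 only; probabilities predicted outside the fitted age
  support are logit-linear extrapolations and logged as such (cohort 1
  baselines start at 51, so age-50 predictions are one-year
  extrapolations).

## Known limitations

* The complement-root annualization bias described above is inherent to
  biennial observation of an annual chain; a likelihood embedding the
  full two-step transition matrix would remove it at the cost of a
  considerably heavier estimator.
* Remission and mortality of the long-term disabled are not
  distinguished from the short-term disabled; the data's biennial
  spacing cannot identify duration effects beyond the one-cycle bridge.
* Contrasts across cohorts assume independent samples; persons
  appearing in both cohort windows would violate this, but the cohort
  definitions make membership exclusive.
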