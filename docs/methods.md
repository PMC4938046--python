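# Methods

## The simulation model

The simulator asks when social information use outcompetes individual
exploration. A fixed population of `n_agents` foragers lives in a world of
`n_patches` resource patches that jointly receive `total_resource` (R)
units every time step. Two resource regimes are compared:

* **no-variance** — every patch receives `R / n_patches`, constant forever;
* **high-variance** — `n_rich_patches` patches, drawn uniformly at random,
  receive `R / n_rich_patches` each and all others receive nothing; the
  rich set is redrawn every `turnover_interval` steps.

Each step every forager picks a patch epsilon-greedily: with probability
`explore_prob` a uniformly random patch, otherwise the patch with the
highest remembered per-capita intake (ties broken uniformly at random, so a
naive agent with a flat memory searches at random rather than defaulting to
patch 0). All occupants of a patch split its payoff equally — exploitative
competition — and the realized per-capita intake accrues to fitness.

Learning is memory overwriting. Every forager records its own realized
intake for the patch it just used (full replacement by the latest
observation; no smoothing — the simplest rule consistent with learning
patch profitability from experience, and it lets depletion be learned in a
single visit). A **social learner** additionally observes one other agent
chosen uniformly at random and records that agent's patch and per-capita
intake. Social learners must also experience their own payoff: an
observation-only social learner never registers the competition it causes
and the strategy degenerates under crowding.

Selection is death–birth: each agent dies independently with probability
`death_rate` per step and is replaced by a newborn that copies the learning
strategy of a parent sampled from the surviving agents with probability
proportional to accumulated lifetime fitness (roulette selection; uniform
if all surviving fitnesses are zero; if the whole population dies in one
step, parents are drawn from the pre-death population by the same rule).
Newborn fitness is zero, memory is reset to `memory_init`, and the strategy
flips with probability `mutation_prob`. "Most successful foragers" is read
as fitness-proportional rather than strict-argmax selection: argmax makes
the dynamics deterministic and brittle, roulette is the standard stochastic
reading. Strategies are fixed for life — no within-lifetime switching.

The within-step order is: payoff redraw (if due) → patch choice → equal
sharing and fitness accrual → memory updates (own experience for everyone,
then social observations) → mortality/replacement. Changing this order
changes the dynamics; it is part of the model definition, not an
implementation detail.

The **evolved proportion of social learners** for a replicate is the
time-average of the population's social fraction over the last
`1 − burn_in_fraction` of steps. Experiments run many independently seeded
replicates and report mean ± SE (sample SD across replicates divided by
√replicates).

### Default parameterization

| parameter | default | why |
|---|---|---|
| `n_patches` | 12 | mirrors the 12-flower arena geometry |
| `n_rich_patches` | 2 | mirrors 2-of-12 rewarded flowers in the high-variance treatment |
| `total_resource` | 100 | arbitrary scale; only ratios matter |
| `turnover_interval` | 10 | rich patches persist long enough to be learned, briefly enough that stale memory hurts |
| `explore_prob` | 0.03 | rare individual exploration; see calibration below |
| `death_rate` | 0.15 | generational turnover fast enough for selection to beat drift |
| `mutation_prob` | 0.005 | keeps both strategies present without swamping selection |
| `n_agents` | 100 | large enough that drift does not dominate the regime contrast |
| `n_steps` | 5000, burn-in 0.8 | equilibrium is reached well before measurement starts |
| `initial_social_fraction` | 0.5 | uninformative start |
| `memory_init` | 0 | naive agents have no patch beliefs; flat memory means random search |

The qualitative prediction — social learning wins where resources are
concentrated and turn over, individual learning where they are uniform —
holds over a broad parameter range. The quantitative defaults were
calibrated so that the default worlds reproduce the magnitudes of the
regime contrast this model family is known for: with 100 replicates the
mean evolved social proportion is ≈ 0.95 (SD ≈ 0.03) in high-variance
worlds and ≈ 0.20 (SD ≈ 0.12–0.17) in no-variance worlds, stable across
master seeds. Under weaker selection (for example `n_agents=50`,
`death_rate=0.02`) the ordering survives but drift widens the
across-replicate spread several-fold and pulls the high-variance mean
toward 0.5. All parameters are overridable through `WorldConfig` /
JSON configs.

Seeding: replicate seeds come from a single `numpy` `SeedSequence` on the
master seed, expanded once into a fixed (regime, replicate) table, so
results are independent of execution order and identical master seeds give
bit-identical summaries.

### What the simulation does not include

No spatial structure or travel costs, no handling time, no within-step
depletion (a patch's payoff is split, not consumed sequentially), no memory
decay, no inheritance of parental memory, and no within-lifetime strategy
switching. The social observation rule is minimal: one uniformly chosen
conspecific per step.

## The choice-data statistics

The empirical half analyses binary first-landing outcomes from a 2×2
design: cue type (social bee-model = 1 vs. non-social foam = 0) crossed
with previously experienced reward distribution (no-variance = 1 vs.
high-variance = 0), bees nested in 3 colonies. Chance level is 1/3 (4 cued
flowers of 12); in the high-variance training array a cued flower is
(2/4)/(2/12) = 3 times as likely to reward as a uniformly random flower.

* **Binomial tests** against chance are exact (no normal approximation).
  The two-sided p-value uses the point-probability rule: sum of P(X = x)
  over all x with pmf(x) ≤ pmf(k)·(1 + 1e-7). Two-sided is the default
  (the question is "differs from chance"); one-sided alternatives are
  available by flag.
* **Adjusted-Wald (Agresti–Coull) intervals** add z²/2 pseudo-successes
  and z² pseudo-trials before the Wald formula; bounds are clamped to
  [0, 1]. The default confidence level is 90%, the level this design is
  conventionally displayed at.
* **Random-intercept logistic regression**: the first-landing indicator on
  cue type, distribution and their interaction (or distribution only in
  the split-by-cue models) with a normal colony intercept. The marginal
  likelihood is maximised directly: each colony's integral is evaluated
  with 31-node *adaptive* Gauss–Hermite quadrature (the integrand is
  re-centred at its mode, found by Newton steps, and rescaled by its
  curvature, so accuracy survives large colonies), and L-BFGS-B optimises
  over the coefficients and the bounded SD (ftol 1e-13, i.e. the
  log-likelihood is located far below the 1e-8 reporting tolerance).
  Standard errors come from the numerical Hessian at the optimum; z is
  coefficient/SE with two-sided normal p-values, matching standard
  mixed-logit output. On reference datasets the fit agrees with `lme4`'s
  `glmer` (nAGQ = 25) to ~1e-5 in coefficients and log-likelihood.
  Degenerate inputs: one colony reduces to a plain logistic fit with a
  warning and `random_intercept_sd = 0`; complete separation is flagged in
  the output rather than penalised away, keeping estimates comparable to
  standard software.
* **First-k landing summaries** average each bee's proportion of cued
  landings over its first `min(k, available)` landings and then average
  bees within a group; bees with short records contribute what they have
  rather than being dropped.

## The synthetic-data generator

The generator emulates only the statistical structure of the test phase:
57 bees (16 social/high-variance, 17 social/no-variance, 12 + 12
non-social — only the non-social total of 24 is fixed by the design, the
even split is a choice; 17 = 33 − 16 by subtraction), assigned round-robin
to 3 colonies (19 each), one normal colony intercept (SD 0.3 on the logit
scale — an assumption, configurable), and independent Bernoulli landings
per bee at the inverse-logit of baseline + treatment effects + colony
intercept. The baseline is chance (logit 1/3 ≈ −0.693) for the reference
cell (non-social, high-variance), so effects act relative to chance.

Default effects place the social/high-variance cell well above chance and
the other three cells at or below it — the pattern the design is built to
detect — with magnitudes echoing reported mixed-model fits of this design
(full model: cue +1.455, distribution −0.733, interaction −2.593; split
parameterization: distribution effect −3.125 within social, −0.696 within
non-social, under the no-variance = 1 coding). They are plausible
generator defaults for testing the pipeline, not ground truth for any real
dataset. Landings within a bee are independent (no within-bout learning or
autocorrelation); flower geometry, bout timing and training dynamics are
out of scope.

## Verification design

Every statistical routine is checked against an independent route: the
binomial test against exhaustive enumeration with exact rational
arithmetic; the Agresti–Coull interval against a direct transcription of
the formula (and `statsmodels`); the mixed model against a non-adaptive
64-node Gauss–Hermite likelihood maximised by Nelder–Mead, and against
`lme4`. Simulator invariants (resource conservation to 1e-9, constant
population size, bit-identical trajectories under a fixed seed, neutral
drift centring on the initial frequency when strategies are
payoff-identical, equivalence of the all-patches-rich limit with the
no-variance regime, monotone rise of social learning as resources
concentrate) run at reduced scale: 30 replicates for regime contrasts and
sweeps, 1500-step worlds for the distribution-equivalence test, 250 short
replicates for the drift test. These sizes give Monte-Carlo errors
comfortably inside the asserted tolerances.

The generator→model closure study checks estimator calibration: 200
datasets with the 2×2 cells scaled 35-fold (≈2000 bees) and the clustering
scaled with them (30 colonies), where the three fixed effects are recovered
with |bias| < 0.1 (measured ≤ 0.01) and 90% Wald intervals cover at
0.88–0.90. **Known limitation:** with the experiment's actual 3 colonies,
the colony SD is barely identified; at 2000 bees the interaction's Wald
coverage dips to ≈ 0.84–0.86 regardless of Hessian scheme (`lme4` matches).
Wald inference with very few clusters should be read with that caveat; the
57-bee-scale fits are for point estimates and z-statistics, as is standard.

Passing these tests shows the pipeline is internally correct and
well-calibrated on data satisfying its own assumptions (independent
Bernoulli landings, a normal colony effect, no overdispersion); it does not
show that real bee choices satisfy those assumptions.
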