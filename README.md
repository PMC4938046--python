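# beelearn

When should a forager copy others, and when should it rely on its own
exploration? `beelearn` implements both halves of a model-then-experiment
workflow on that question in foraging bumblebees:

1. **An agent-based evolutionary simulation** of foragers competing for
   patchy resources. Individual learners sample patches themselves; social
   learners also watch one random conspecific per step. Everyone on a patch
   shares its payoff equally, and strategies evolve by death–birth
   selection on accumulated intake. The model predicts that social
   learning dominates when resources are concentrated in few,
   turning-over patches (high variance) and stays rare when every patch
   pays the same (no variance) — a *copy-when-uncertain* pattern.
2. **The matching statistical pipeline for bee-choice data**: group
   proportions of first landings on cued flowers, exact binomial tests
   against the 1/3 chance level (4 cued flowers of 12), adjusted-Wald
   (Agresti–Coull) 90% intervals, and random-intercept logistic regression
   (colony as a normal random effect, fitted by marginal maximum
   likelihood with adaptive Gauss–Hermite quadrature) — plus a synthetic
   generator for the 57-bee, 3-colony, 2×2 design (cue type × prior reward
   variance) so the whole pipeline is testable end to end.

See `docs/methods.md` for model details, default parameters and
limitations.

## Worked example: the simulation prediction

```python
from beelearn import ExperimentConfig, run_experiment

summary = run_experiment(ExperimentConfig(n_replicates=30, master_seed=0))
for regime, s in summary.per_regime.items():
    print(f"{regime}: {s.mean:.3f} +/- {s.se:.3f} (SE, n={s.n_replicates})")
```

```
high_variance: 0.955 +/- 0.007 (SE, n=30)
no_variance: 0.177 +/- 0.021 (SE, n=30)
```

In worlds where the whole resource sits in 2 of 12 patches and moves every
10 steps, the population evolves to ~95% social learners; with the same
resource spread evenly it stays around 18%. The gap — not the exact
values — is the model's prediction: social information pays when private
information goes stale quickly.

## Worked example: analysing choice data

```python
from beelearn.synth import GeneratorConfig, generate_choice_dataset
from beelearn.stats import (group_proportion, exact_binomial_test,
                            adjusted_wald_interval, fit_choice_glmm)

records = generate_choice_dataset(GeneratorConfig(seed=1))   # 57 synthetic bees
k, n, prop = group_proportion(records, cue_type=1, distribution=0)
print(f"social/high-variance: {k}/{n} = {prop:.3f} on cued flowers")
print(f"exact binomial vs 1/3: p = {exact_binomial_test(k, n).p_value:.5f}")
ci = adjusted_wald_interval(k, n)
print(f"90% adjusted-Wald CI: [{ci.lower:.3f}, {ci.upper:.3f}]")

social = [r for r in records if r.cue_type == 1]
fit = fit_choice_glmm(social, "distribution_only")
c, s = fit.coefficients["distribution"], fit.standard_errors["distribution"]
print(f"split model (social cue): distribution = {c:.3f} +/- {s:.3f}, "
      f"z = {fit.z_values['distribution']:.3f}, p = {fit.p_values['distribution']:.4f}")
```

```
social/high-variance: 11/16 = 0.688 on cued flowers
exact binomial vs 1/3: p = 0.00556
90% adjusted-Wald CI: [0.480, 0.840]
split model (social cue): distribution = -4.117 +/- 1.540, z = -2.673, p = 0.0075
```

Of the 16 synthetic bees trained with social cues under high reward
variance, 11 landed first on a cued flower — far above the 1/3 chance
line (exact binomial p ≈ 0.006), and the mixed model's negative
distribution coefficient says bees that experienced *no* reward variance
used the cue much less. That is the signature the pipeline is built to
detect.

The same analyses run from the shell:

```sh
beelearn synth --seed 1 --out choices.csv
beelearn analyze --in choices.csv --out results.json --first-k 4,10
beelearn simulate --replicates 100 --seed 0 --out runs/
beelearn sweep --rich-grid 12,6,2 --replicates 30 --seed 0 --out sweep.csv
```

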