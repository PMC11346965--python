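# surprise-bandit

Simulation, model fitting and model comparison for **surprise-modulated
reinforcement learning** in a three-armed bandit task with a bimodal
mid-value bandit.

The scientific question: when an outcome deviates strongly from
expectations (a large unsigned prediction error — *surprise*), do learners
update their value estimates more, less, or no differently than for
ordinary outcomes, and does this differ between groups (e.g. with age)?
The task decouples surprise from outcome probability and from uncertainty
by giving the middle of three bandits an asymmetric bimodal reward
distribution: 20% of its outcomes come from a mode 35 points below the
main one — lower than anything the *low* bandit typically delivers —
making the objectively better mid bandit produce rare, large negative
prediction errors. Overweighting of those events shows up as worse low-mid
than mid-high choice accuracy, choice reversals right after surprising
outcomes, and underestimation of the low-mid value distance.

The package is aimed at computational cognitive modelers: it provides the
full pipeline — task simulation, candidate learning models, fitting,
comparison, recovery, behavioral statistics — runnable end to end on
synthetic cohorts, since no behavioral data ship with the task design.

## Models

All candidates learn bandit values with a delta rule
`V_k <- V_k + α·(R - V_k)` (values start at 50 each run) and map values to
choices through a logistic regression
`p(right) = σ(β0 + β1·V_left + β2·V_right [+ β3·U_left + β4·U_right])`:

| Model | Learning rate | Uncertainty in choice | k |
|---|---|---|---|
| RW | constant α | – | 4 |
| Valence | α_pos / α_neg by PE sign | – | 5 |
| Uncertainty | constant α | U_k ← (1−π)U_k + π·\|PE\| | 7 |
| Surprise | α\* = l + (u−l)·2/(1 + P̂E^−s) | – | 6 |
| UncValence | valence rates | yes | 8 |
| UncSurprise | surprise rate | yes | 9 |

`P̂E` is the unsigned prediction error passed through
`2/(1+e^(−0.1·|PE|)) − 1` and normalized by the value of that transform at
the maximal possible PE (60 points), so α\* runs from `l` (no surprise) to
`u` (maximal surprise) with slope `s ∈ [1,7]`; `u > l` means surprise
*boosts* learning, `u < l` that it suppresses it, and `u = l` recovers RW.

Fitting is nested: a deterministic DIRECT-L search over the learning
parameters, with the betas fit by maximum likelihood in an inner loop, on
free low-mid choices only (excluding trials where either bandit has fewer
than three prior outcomes). Models are compared per participant by AICc
and at the population level by protected exceedance probabilities from
random-effects Bayesian model selection.

## Worked example

```python
import numpy as np
import surprise_bandit as sb

config = sb.TaskConfig()
rng = np.random.default_rng(7)

# a surprise-sensitive agent: learning rate rises from 0.1 to 0.7 with surprise
spec = sb.get_spec("Surprise")
params = sb.ModelParams({"l": 0.1, "u": 0.7, "s": 3.0})
betas = sb.ChoiceCoefficients(0.0, -0.15, 0.15)
ds = sb.generate_participant("sub-001", "older", spec, params, betas, config, rng)

acc = sb.overall_accuracy_by_pair(ds).astype(float)
pre, post = sb.surprise_prepost(ds, "below20")
fit_rw = sb.fit_model(ds.trials, sb.get_spec("RW"), config=config)
fit_sur = sb.fit_model(ds.trials, spec, config=config)
```

Output (values printed by the code above):

```
{'low-high': 0.992, 'low-mid': 0.727, 'mid-high': 0.93}
pre=0.895 post=0.577
RW:       alpha=0.626  negLL=54.45  AICc=117.23
Surprise: l=0.174 u=0.729 s=7.00  negLL=51.04  AICc=114.79
```

The agent masters the easy low-high comparison but performs worst on
low-mid trials (0.727), chooses the mid bandit much less often immediately
after a surprising low outcome (0.895 → 0.577), and is better explained by
the Surprise model than by RW (AICc 114.79 vs 117.23) with recovered
bounds close to the generating ones (l 0.17 vs 0.1, u 0.73 vs 0.7).

A command-line interface wraps the same functions:

```bash
surprise-bandit simulate-cohort --seed 1 --n-younger 8 --n-older 8 --out cohort/
surprise-bandit fit --data cohort/ --models RW,Surprise --out fits.csv
surprise-bandit compare --fits fits.csv --out comparison.json
surprise-bandit analyze --data cohort/ --out analysis.json
```

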