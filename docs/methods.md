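# Methods

## The task

Three bandits deliver rewards bounded to [0, 100] points. The *low* and
*high* bandits are Gaussian with component SD 5.55 and means 33.33 points
apart; the *mid* bandit is a two-component Gaussian mixture (same component
SD) whose total mean is equidistant from the other two. The mixture's
smaller mode carries 20% of the outcome mass and sits 35 points below the
main mode, which places it *below* the mean of the low bandit. This is the
design's central asymmetry: on roughly one in five samples the objectively
better mid bandit produces an outcome worse than anything the low bandit
typically delivers, eliciting a large negative prediction error without
being an improbable event in the task as a whole.

Solving the two linear mixture constraints (weighted component means equal
the total mean; components 35 apart) gives, for a mid mean of 50, a main
mode at 57 and a low mode at 22. The low-high gap of 33.33 is taken as the
primary constant and the neighbor distance derived as half of it (16.665),
since the printed values 16.66 and 33.33 cannot both hold exactly.

Each run schedules 240 choice trials — 192 free choices and 48 guided
choices, both balanced over the three bandit pairs (and guided trials
additionally over the two possible targets within a pair) — plus 16
estimation probes. Probes never occur within the first 10 choice trials and
are at least 10 choice trials apart; positions are drawn directly as order
statistics under the gap constraints rather than by rejection. Four to five
probes are immediately preceded by a guided mid trial rigged to produce a
low-mode outcome. Between runs all means shift by a common uniform draw in
[-14.8, +14.8] points; a shift that would bring any component mean within 3
SD of a reward bound is resampled, which in practice narrows the admissible
shift to about [-5.35, +14.8] given the run-1 anchor (mid mean 50). Rewards
falling outside [0, 100] are redrawn (component and all) rather than
clipped, preserving means and SDs; with all component means at least 3 SD
from the bounds the truncation affects ~0.1% of draws and biases moments
negligibly.

Percentile thresholds for the surprise analysis come from the theoretical
(untruncated) mixture CDF of each run's mid bandit, inverted numerically —
not from the participant's experienced outcomes, whose empirical quantiles
are extremely noisy near the 20th percentile because it falls in the
low-density valley between the two modes.

## Learning models

All six candidates share the delta rule `V[k] <- V[k] + rate * (R - V[k])`
with values initialized to 50 at each run start, and differ in the rate and
in whether an uncertainty trace enters choice:

* **RW** — constant rate `alpha ∈ [0,1]`.
* **Valence** — `alpha_pos` for positive, `alpha_neg` for negative
  prediction errors.
* **Uncertainty** — constant rate plus an associability trace
  `U[k] <- (1-pi) U[k] + pi |PE|`, updated only for the sampled bandit,
  that enters the choice model. `pi ∈ [0,1]` sets the recency weighting.
* **Surprise** — the rate is `alpha* = l + (u-l) * 2/(1 + pe_hat^-s)`,
  a logistic function of the scaled unsigned prediction error `pe_hat`,
  rising (u > l) or falling (u < l) from `l` at PE = 0 to `u` at the
  maximal PE, with slope `s ∈ [1,7]`.
* **UncValence**, **UncSurprise** — the respective update rule combined
  with the uncertainty trace in choice.

`pe_hat` is the transform `f(x) = 2/(1+exp(-0.1 x)) - 1` of `|PE|`, divided
by `f(60)` so the maximal possible prediction error of 60 points maps to
exactly 1; `|PE| > 60` (possible only transiently) is capped first. The
normalization is required for the rate function, whose endpoints are only
attained when `pe_hat` spans [0, 1] exactly. At `pe_hat = 0` the power
`pe_hat^-s` diverges and the limit `alpha* = l` is returned explicitly.

Uncertainty traces start at 0 (a config field, since no initialization is
prescribed by the design). Guided trials whose instruction was violated
reveal no outcome and therefore update neither values nor uncertainties.
One parameter set spans both runs of a participant; latent state resets at
run boundaries.

## Choice model and fitting

Choice of the right-hand option follows a logistic regression on the
offered bandits' latent states:
`p(right) = sigma(b0 + b1 V_left + b2 V_right [+ b3 U_left + b4 U_right])`.

Fitting is nested: a deterministic DIRECT-L global search (scipy's
`direct`, locally biased variant) over the learning parameters within their
boxes, where each outer evaluation replays the model over the trials and
fits the betas by maximum likelihood in an inner loop. The outer budget is
2000 objective evaluations or a relative box-length tolerance of 1e-4,
whichever first (both exposed in `OptimizerConfig`). The inner fit is a
damped-Newton (IRLS) optimization of the logistic likelihood with a ridge
penalty of 1e-6 on the betas — invisible at normal curvature but keeping
the optimum finite under complete separation, which is flagged when any
coefficient exceeds 50. The reported negative log-likelihood is the
unpenalized value at the fitted betas.

The likelihood uses only free choices in low-mid comparisons, and within
those only trials where both offered bandits have already produced at least
three observed outcomes in that run ("first three trials of each bandit"
is read as first three *outcomes*, because guided trials also reveal
rewards). With values pinned to 50 at run start, earlier trials carry large
initialization-driven unsigned prediction errors that would masquerade as
surprise.

Models are compared by AICc with `n` = the number of filtered likelihood
trials (both runs pooled) and `k` counting every fitted quantity including
betas: RW 4, Valence 5, Surprise 6, Uncertainty 7, UncValence 8,
UncSurprise 9. Ties in per-participant winners go to the model with fewer
parameters.

## Random-effects model selection

Population-level comparison treats model frequencies as Dirichlet-
distributed: variational inference yields the posterior Dirichlet weights;
exceedance probabilities are the fraction of posterior samples (default
1e5) in which each model's frequency is largest; the Bayes omnibus risk is
the posterior probability of the equal-frequency null, computed from the
variational free energy of the random-effects model against the null's
exact log evidence; and protected exceedance probabilities follow the
identity `PXP = (1-BOR) * EP + BOR/K`, which holds exactly as computed.
Log model evidence is approximated per participant as `-AICc/2` (a
`-AIC/2` switch exists). Row-wise constants cancel, so EP and PXP are
invariant to per-participant offsets; the K=2 sampler is validated against
the closed-form incomplete-beta integral of the Dirichlet posterior.

## Synthetic cohorts

No behavioral data are distributed with the task design, so all analyses
run on synthetic cohorts. The default cohort mirrors the study: 51 younger
and 51 older agents, each completing two full runs. Agents choose by
Bernoulli draws from the logistic choice model applied to their own latent
state; guided instructions are followed at rate 0.98 (errors reveal no
outcome); estimation responses are the current values plus N(0, 5) noise
clipped to the 0-100 slider, and range responses a noisy linear readout
(gain 2) of the uncertainty trace, clipped to the -50..+50 slider. Range
responses are produced for format completeness only; no analysis here
consumes them, because the underlying behavior is unconstrained by the
design.

Default generating parameters aim at mid-performing human learners:
learning rates (and `l`) uniform on interior sub-ranges of their boxes
rather than the full box, slope `s ~ U(2,5)`, value betas `b2 = -b1 = 0.15`
per point (decisive but far from deterministic), uncertainty betas
±0.05 where applicable. The age manipulation is carried entirely by the
surprise-sensitivity gap: younger agents draw `u - l ~ U(0, 0.25)`, older
agents `U(0.2, 0.45)` (a +0.2 shift). This is a deliberately
stylized, unidimensional stand-in for group differences; real aging data
differ in reaction times, compliance, estimation noise and much else that
the generator does not emulate. Passing end-to-end checks therefore show
that the *pipeline* detects a surprise-sensitivity difference of this size
at these sample sizes — not that real older adults behave this way.

## Validation

* Analytic reductions (Surprise with `l = u`, Valence with equal rates)
  reproduce RW value trajectories exactly; the Uncertainty model's value
  path equals RW's.
* The inner logistic fit matches a brute-force grid oracle on 50-trial
  problems; value weights agree to one grid step (0.01). The intercept is
  compared at the trade-off resolution ~0.5, since a one-step change in the
  value weights shifts the compensating intercept by roughly the mean value
  (~50 x 0.01).
* RW learning-rate recovery over 100 agents at the full trial counts
  (generating `alpha ~ U(0.05, 0.6)`, decisive betas) correlates generating
  and recovered values at r >= 0.7.
* Model recovery uses 10 agents per generating model (and 8 for the
  weak-surprise variant) fitted under all six candidates — sizes chosen to
  keep the default test run short while leaving the expected effects far
  from the decision boundary. Strong-surprise data (`u - l >= 0.5`) are won
  by the Surprise model; near-RW surprise agents (`|u - l| <= 0.08`) leak
  to RW, reproducing the known identifiability caveat: RW is nested in
  every other candidate and wins on parsimony when the extra structure is
  weak.
* The end-to-end check uses a 16 + 16 cohort: low-mid accuracy below
  mid-high accuracy, a post-surprise drop in mid choices that is larger in
  the older group, and a much weaker pre/post difference in the 20th-40th
  percentile control band.

## Numerical and design choices

* Estimation positions are sampled exactly under the gap constraints via
  an order-statistics construction (rejection sampling would accept ~1e-7
  of candidates).
* The pre/post estimator pools window trials across events within a
  participant (one preceding and up to two following free low-mid choices
  per event); group contrasts then operate on per-participant proportions.
  An outcome exactly at a percentile threshold belongs to the upper band
  (left-closed bands).
* Estimation-trial distortion restricts to the second half of each run's
  *usable* probes (those where every bandit has been sampled), since
  earlier probes have no defined objective difference.
* The exclusion rules use a one-sided binomial test (greater than chance,
  alpha = .05) on pooled low-high free choices; the guided-error outlier
  cut is cohort mean + 3 SD, which requires a cohort large enough that a
  single outlier does not inflate the SD past its own value.
* Mixed-effects models and corrected post-hoc batteries are intentionally
  out of scope; the long-format exports contain everything an external LME
  tool needs.

## Known limitations

* The generator produces stationary, well-behaved agents; lapses,
  side biases, drifting attention and reaction-time structure are absent.
* Parameter recovery for the Surprise model's slope `s` is weak at these
  trial counts (few high-surprise trials constrain it), matching the
  general identifiability picture above.
* The `-AICc/2` evidence proxy treats a penalized fit statistic as a log
  marginal likelihood; rankings are insensitive to this choice here, but
  absolute BOR values should not be over-interpreted.
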