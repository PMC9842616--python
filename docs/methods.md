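# Methods

This note documents the generative model, the estimators, the default
parameters and the design choices behind them, and what the simulation
results do and do not establish.

## Task structure

Every choice problem offers a certain outcome of 10 units against a gamble
paying `G` units with probability 0.5, where `G` runs over 10–30. Outcomes
are unsigned magnitudes in storage; the frame column (`gain`/`loss`)
carries the sign, and losses are negative signed values everywhere
internally. Own-choice phases (baseline, transfer at day 0, retest at day
3) use the 11-value grid 10, 12, …, 30; guessing phases (learning with
feedback at day 0, guessing without feedback at day 3) use the 21-value
grid 10, 11, …, 30. Each scenario repeats 4 times per phase, so own phases
have 44 trials and guessing phases 84. Trial order is a uniform seeded
permutation of all trials in a phase — no blocking of repeats; the two
orderings are indistinguishable for every analysis in the package, and the
unblocked one is simpler to reproduce.

The expected value of the gamble equals that of the certain option at
`G = 20` in both frames; this EV-equality point anchors the value coding in
the regression models (centered at 20, scaled by 10).

## Norm schedules

The "group" whose preferences are learned is synthetic. Its choices are
drawn per trial from a schedule `t(G)`: a pilot gambling-rate curve shifted
by ±0.20 (risk-seeking: `pilot + 0.20`; risk-averse: `pilot − 0.20`) and
clipped to [0.05, 0.95] so feedback stays probabilistic. The shift
direction follows the meaning of the labels — a risk-averse group gambles
*less* — with the offset magnitude of 20 percentage points.

By default the pilot curve is the prior-predictive mean gambling rate of
the agent population itself (Monte-Carlo average of the choice rule over
4,000 prior draws, fixed internal seed): a pilot study samples the same
population as the main study, so the ±0.20 norms are guaranteed to sit on
the intended side of the average participant. A purely parametric
alternative (`norms.default_pilot_rates`, logistic in expected value) is
retained for experiments that want a pilot curve decoupled from the agent
priors; with decoupled curves a nominally risk-seeking norm can be *less*
risk-seeking than the simulated population in the loss frame, which washes
out or reverses the conformity effect in that cell.

## Generative agent model

Choice follows a logistic rule over Prospect-Theory value,
`v(x) = x^α` for gains and `−λ x^α` for losses, with
`P(gamble) = logistic(τ·[0.5·v(G) − v(10)] + β₀)`. Probability weighting is
omitted: the gamble probability is fixed at 0.5 throughout the task, so a
weighting function is not identifiable and would only rescale `τ`.

Conformity acts on the probability scale: after learning,
`p_post = (1−w)·p_own + w·t(G)` with weight `w` at day 0 and `w·ρ` at day
3. The mixture is chosen over a latent-utility offset because the study's
outcome measure *is* a probability difference — under the mixture, the
marginal influence in a cell is approximately `w·E[t(G) − p_own(G)]`, which
makes `w` directly interpretable and recoverable from that measure.

During the learning phase the agent guesses the majority's choice and
updates from feedback. The guess probability for value `G` blends the
agent's own choice probability (pseudo-count 0.5), the pooled majority
gamble frequency over all values seen so far (pseudo-count 4), and the
per-value empirical frequency (count 1 per observation). The light prior
and strong pooled term give fast norm learning: with a near-deterministic
schedule, late-phase guesses agree with the realized majority ~86% of the
time, consistent with accurate norm learning; a `learning_rate` of 0
disables updating entirely. The day-3 guessing phase reads out the
retained end-of-learning estimate without further updating.

### Default parameter distributions

| parameter | meaning | default prior |
|---|---|---|
| α | PT curvature (unitless) | Uniform(0.4, 1.1) |
| λ | loss aversion (unitless) | LogNormal(ln 1.5, 0.3) |
| τ | temperature (1/utility) | Gamma(shape 2, scale 0.5) |
| β₀ | gamble bias (log-odds) | Normal(0, 0.3) |
| w | conformity weight | Beta(2, 2) |
| ρ | day-3 persistence | Beta(5, 2) |

These are package defaults chosen to produce behavior in the empirically
reported range (risk aversion in gains, risk seeking in losses, marginal
conformity effects of roughly 0.05–0.15 probability units, most of the
effect retained at day 3); they are not estimates from any dataset. The
default cohort size is 90 participants per frame × norm cell, i.e. a
day-0 sample of 360 per domain.

Self-reported awareness of the norm influence is generated as
`100·logistic(−3.0 + 4.0·w + ε)`, `ε ~ N(0, 1.2²)`. Because the realized
conformity score is a noisy readout of `w`, the latent correlation is
attenuated; these coefficients give a population awareness–conformity
Pearson r of ≈ 0.2 and a mean self-report of ≈ 33 on the 0–100 scale,
the order reported for such debriefing measures.

Each participant draws parameters and all choice randomness from a
dedicated substream spawned from the master seed, so cohorts are
reproducible and participants are independent.

## Estimators

**Per-participant PT fit.** `(α, τ, β₀)` by maximum likelihood with
L-BFGS-B from 5 starting points (bounds α ∈ [0.05, 3], τ ∈ [0, 30],
β₀ ∈ [−5, 5]). Loss aversion is not identifiable from a single frame — it
multiplies the whole loss-frame latent and is absorbed into τ — so λ is
fixed at 1 and reported as such; with both frames present λ = 1 is the
generative convention for recovery studies. Constant responders raise an
error; fits whose likelihood-ratio against a bias-only model is below the
χ²₁ 5% point are flagged non-identifiable (this catches τ ≈ 0
coin-flippers, for whom α is meaningless). Over the narrow 10–30 value
range, α is weakly identified from one frame alone (it trades off with τ
and β₀ along a likelihood ridge); recovery experiments therefore present
both frames. At 200 agents × 176 trials the rank correlation between true
and recovered values is ≈ 0.88 for α and ≈ 0.95 for τ.

**Mixed logit.** Random-intercept logistic regression fitted by maximizing
the marginal likelihood with adaptive Gauss–Hermite quadrature (21 nodes by
default; estimates move by < 1e-4 between 15 and 31 nodes). Per-subject
modes are found by an inner Newton iteration and the quadrature is centered
and scaled at each mode, so a handful of nodes integrates even large
intercept variances accurately. Fixed effects use cell-means coding: one
coefficient per observed phase × norm × frame cell plus a centered
gamble-value slope per frame. Starting values come from a pooled logit;
the covariance matrix is the inverse observed information (numerical
Hessian), symmetrized and eigenvalue-floored against the flat log-σ
direction that appears when σ̂ → 0. Complete separation or optimizer
failure raises an error rather than returning a silent result. With zero
simulated heterogeneity the fixed effects agree with the pooled logit to
about 1e-4.

**Marginal probabilities and contrasts.** A cell's marginal gamble
probability averages the inverse logit over the estimated intercept
distribution (Gauss–Hermite) and over the phase's value grid. Confidence
intervals come from parametric simulation: coefficient vectors drawn from
the fit's asymptotic normal, the marginal recomputed per draw, percentile
bounds. Contrasts are probability-scale differences `M(A) − M(B)`; the
family-wise multiplicity adjustment is single-step max-|z|, with the joint
null distribution of the standardized contrasts taken from the same
(centered) coefficient draws. This is the Monte-Carlo analog of
multivariate-t-based single-step adjustments and is asymptotically
equivalent to them; it avoids committing to any particular
degrees-of-freedom heuristic. Under a simulated null the familywise error
rate at nominal 0.05 measures ≈ 0.05–0.06 over 1,000 datasets. The
calibration run fits the datasets through the model's
`random_intercept=False` path (the data are generated without subject
heterogeneity): the adjustment under test consumes only the
estimate/covariance pair, which that path produces identically, and this
keeps a 1,000-replicate study inside a desk-scale compute budget.

**Influence and persistence.** Raw mode computes per-participant choice
proportions per value and phase, differences them, and puts a t-interval
on the participant-level mean deltas. Model-based mode (the default in the
pipeline) differences model-implied marginal probabilities with
simulation CIs. The two agree within CI width on large simulated cohorts;
the model-based per-value curves are much smoother, which matters for
locating the peak of the influence curve. Persistence is the same
estimator applied to the day-3 retest against the day-0 baseline.

**Entropy analysis.** For each participant × phase × scenario, the gamble
proportion over the 4 repeats is converted to binary entropy (base 2, with
0·log 0 = 0); participant-level phase means enter a two-sided paired
Wilcoxon signed-rank test (zeros dropped, mid-ranks for ties, exact null
for n ≤ 25 without ties, normal approximation with continuity correction
otherwise). Scenario-level pairs are retained in the output for
finer-grained comparisons. Note that with 4 repeats the entropy estimate
is coarse (five possible values per scenario) and biased downward for
interior probabilities; the paired design cancels most of this bias.

**Peak-influence alignment.** The gamble value with the largest |Δp| is
compared with the value where the baseline curve crosses 0.5 (maximal
uncertainty), located by linear interpolation; multiple crossings return
the one nearest the peak, flagged. On model-based curves from default
cohorts the mean distance is ~1–2 value units (≤ 4 across seeds); raw
4-repeat proportion curves are too noisy for reliable peak location.

**Exclusions.** Participants with ≥ 2 of 4 comprehension questions wrong,
with one identical own-choice response across an entire session, or with a
failed attention flag are removed before analysis. The constant-response
rule covers own-choice trials per session by default (guess trials can be
included via a flag); exclusion is a pure, idempotent filter.

## What the simulations show — and what they do not

The synthetic cohort reproduces the structural signatures the analysis is
built to detect: EV sensitivity with opposite slopes by frame, the
Prospect-Theory framing signature (gamble rate < 0.5 in gains and > 0.5 in
losses whenever α < 1, λ > 1, shrinking toward risk neutrality), correctly
signed conformity in every design cell, partial day-3 persistence, and an
awareness–conformity correlation of ≈ 0.2.

The entropy comparison is regime-dependent in the mixture model. Mixing
toward a schedule that is clipped to [0.05, 0.95] pulls *already-extreme*
choice probabilities toward the interior, so under the default priors —
where many agents hold strong preferences at most gamble values —
post-learning entropy rises slightly. The uncertainty-reduction pattern
(baseline entropy > transfer entropy) emerges exactly where the account
predicts it: for uncertain deciders (low τ, choice probabilities near 0.5)
facing steep, near-deterministic schedules, where it is large and highly
significant. Tests and the acceptance script exercise that regime
explicitly and the acceptance script also reports the default-cohort
value with its sign, rather than presenting either as universal.

Features of real data the generator does not emulate: reaction times,
within-session learning or fatigue drifts in own choices, between-session
dropout (only exclusion-rule violators are injected), item-level
comprehension behavior (comprehension is an abstract wrong-answer count),
and any dependence of the conformity weight on the gamble value (w is
constant across scenarios, whereas human conformity may concentrate where
uncertainty is highest). Passing tests therefore establish that the
estimators recover what this generative process encodes — not that the
generative process is the true model of human conformity.

## Numerical conventions

- All randomness flows from integer seeds through `numpy` Generators;
  per-participant substreams come from `SeedSequence.spawn`.
- PT likelihoods use the log-sum-exp-safe Bernoulli form; quadrature
  likelihoods combine node terms with `logsumexp`.
- Optimizer tolerances: 1e-11 (relative loglik) for the mixed logit,
  L-BFGS-B defaults for PT fits; quadrature nodes 21 unless overridden.
- Degenerate inputs are errors, not warnings: constant responses,
  all-identical cohort responses, missing schedule grid values, probability
  arguments outside [0, 1], cells absent from a fit.
- A self-contrast (identical cells) is returned as estimate 0, p = 1
  without Monte-Carlo sampling.
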