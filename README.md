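# riskconform

Simulation and analysis of **social-norm conformity in framed risky
choice**. The task it models is a parametric gain/loss framing paradigm: on
every trial a decision maker chooses between a certain outcome of 10 units
(lives in a moral scenario, currency in a monetary one) and a gamble that
yields `G ∈ [10, 30]` units with probability 0.5. Across two sessions three
days apart, participants state their own choices (baseline), learn a
group's preferences by guessing the majority's choices with feedback
(learning), state their own choices again (transfer), and return for a
retest. The group is synthetic: its choices are drawn from a probabilistic
schedule constructed 20 percentage points above or below a pilot gambling
rate curve, creating *risk-averse* and *risk-seeking* norms.

The package is aimed at researchers who want to simulate such experiments
with known ground truth, stress-test the analysis chain, or run the same
chain on their own trial-level data.

## Model

Agents choose by a logistic rule over Prospect-Theory utilities

```
v(x) =  x^α          (gains)
v(x) = -λ x^α        (losses)

P(gamble) = logistic( τ·[0.5·v(G) − v(10)] + β₀ )
```

with curvature `α`, loss aversion `λ`, temperature `τ` and bias `β₀`.
After learning a norm schedule `t(G)`, the agent's choice probability
becomes the mixture

```
p_post(G) = (1 − w)·p_own(G) + w·t(G)
```

with conformity weight `w` on day 0 and `w·ρ` at the day-3 retest
(`ρ` = persistence). The analysis chain estimates:

- **Random-intercept mixed logit** `y_ij ~ Bernoulli(logistic(x_ij'β + b_i))`,
  `b_i ~ N(0, σ²)`, fitted by adaptive Gauss–Hermite quadrature; marginal
  gamble probabilities per design cell and probability-scale contrasts with
  a Monte-Carlo single-step max-|z| multiplicity adjustment.
- **Per-participant Prospect-Theory fits** by multi-start maximum likelihood.
- **Conformity influence**: ΔP(gamble) between post-learning and baseline
  phases, per gamble value and marginalized, with persistence at day 3.
- **Choice uncertainty** via the binary entropy
  `H(p) = −p log₂ p − (1−p) log₂(1−p)` of repeated choices on identical
  problems, compared between phases with a paired Wilcoxon signed-rank test.
- **QC exclusions**: failed comprehension (≥ 2 of 4 questions wrong),
  constant responders, failed attention checks.

## Worked example

```python
from riskconform import simulate_cohort, fit_mixed_logit, influence_curve
from riskconform.models import ModelSpec

trials, truth, participants = simulate_cohort(
    n_per_cell=90, domains=("moral",), seed=1
)
fit = fit_mixed_logit(trials, ModelSpec(phases=("baseline", "own_d0")))
for norm in ("risk_averse", "risk_seeking"):
    est = influence_curve(
        trials, ("own_d0", "baseline"),
        {"frame": "gain", "norm_type": norm}, fit=fit, n_draws=400,
    )
    print(f"{norm:13s} influence {est.marginal_delta:+.3f} "
          f"[{est.ci_low:+.3f}, {est.ci_high:+.3f}]")
```

```
risk_averse   influence -0.072 [-0.089, -0.055]
risk_seeking  influence +0.109 [+0.090, +0.128]
```

Participants assigned a risk-averse norm gamble about 7 percentage points
less after learning than at baseline; those assigned a risk-seeking norm
about 10 points more — the conformity effect, recovered with the correct
sign in every design cell.

The same chain is available from the shell:

```sh
riskconform simulate --seed 1 --out out/
riskconform qc --trials out/trials.csv --participants out/participants.csv --out out/
riskconform fit --trials out/trials_retained.csv --model mixedlogit --out out/
riskconform analyze --trials out/trials_retained.csv --metric influence --out out/
riskconform report --seed 1 --out out/   # full pipeline + manifest
```

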