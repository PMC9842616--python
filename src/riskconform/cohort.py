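"""Synthetic participants with Prospect-Theory preferences and norm conformity.

Each agent chooses by a logistic rule over Prospect-Theory utilities

    v(x) = x**alpha         (gains)
    v(x) = -lam * x**alpha  (losses)

    P(gamble) = expit( tau * [0.5 * v(G) - v(10)] + beta0 )

where G is the gamble value.  During the learning phase the agent guesses
the majority's choices and tracks their empirical frequencies; after
learning, its own choice probability is a mixture

    p_post = (1 - w) * p_own + w * p_norm

with conformity weight w = w_norm on day 0 and w_norm * persist at the
day-3 retest.  The mixture acts directly on the probability scale, the
same scale as the study's influence measure (difference in gamble
probability between post-learning and baseline phases), which keeps w
identifiable from that measure.

`simulate_cohort` builds a full two-session dataset across the
2 (frame) x 2 (norm) x 2 (domain) design, with known ground-truth
parameters per participant, a self-reported awareness score generated as
a noisy monotone function of the realized conformity weight, and optional
injected rule-breakers for exercising the QC exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import task
from .norms import NormSchedule, build_norm_schedule
from .task import GambleScenario, build_phase_schedule, phase_schedule


@dataclass(frozen=True)
class AgentParams:
    """Generative preference parameters of one agent.

    alpha : PT curvature (> 0; < 1 gives diminishing sensitivity)
    lam : loss-aversion multiplier (> 0)
    tau : choice temperature / inverse noise (>= 0)
    beta0 : frame-independent gamble bias on the latent scale
    w_norm : conformity weight in [0, 1]
    persist : fraction of the conformity weight retained at day 3, in [0, 1]
    """

    alpha: float
    lam: float
    tau: float
    beta0: float
    w_norm: float
    persist: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not 0.0 <= self.w_norm <= 1.0:
            raise ValueError(f"w_norm must be in [0, 1], got {self.w_norm}")
        if not 0.0 <= self.persist <= 1.0:
            raise ValueError(f"persist must be in [0, 1], got {self.persist}")


def pt_utility(magnitude, frame: str, alpha: float, lam: float = 1.0):
    """Prospect-Theory value of an unsigned outcome magnitude."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    m = np.asarray(magnitude, dtype=float)
    if np.any(m < 0):
        raise ValueError("magnitude must be >= 0 (sign is carried by the frame)")
    u = m**alpha
    if frame == "loss":
        u = -lam * u
    elif frame != "gain":
        raise ValueError(f"frame must be 'gain' or 'loss', got {frame!r}")
    return u if u.ndim else float(u)


def choice_prob(
    scenario: GambleScenario, params: AgentParams, norm_shift: float = 0.0
):
    """Probability the agent chooses the gamble, before any norm mixture.

    ``norm_shift`` is an additive offset on the latent (log-odds) scale,
    zero before learning.
    """
    u_gamble = pt_utility(scenario.gamble_value, scenario.frame, params.alpha, params.lam)
    u_certain = pt_utility(scenario.certain_value, scenario.frame, params.alpha, params.lam)
    latent = (
        params.tau * (scenario.gamble_prob * u_gamble - u_certain)
        + params.beta0
        + norm_shift
    )
    return float(expit(latent))


def conformity_shift(
    params: AgentParams,
    schedule: NormSchedule,
    gamble_value: int,
    session: str,
    frame: str,
    domain: str,
) -> float:
    """Post-learning gamble probability: mixture of own preference and norm."""
    if session not in ("D0", "D3"):
        raise ValueError(f"session must be 'D0' or 'D3', got {session!r}")
    w = params.w_norm if session == "D0" else params.w_norm * params.persist
    scen = GambleScenario(gamble_value=gamble_value, frame=frame, domain=domain)
    p_own = choice_prob(scen, params)
    return (1.0 - w) * p_own + w * schedule.p(gamble_value)


class GuessLearner:
    """Tracks the majority's choices during the learning phase.

    The guess probability for value v blends three sources with pseudo-count
    weights: the agent's own choice probability (prior, weight ``prior_n``),
    the pooled majority gamble frequency over all values so far (weight
    ``pool_n``), and the per-value empirical frequency (one count per
    observation).  ``learning_rate`` scales the two data terms; at 0 the
    guess never moves from the agent's own preference.
    """

    def __init__(
        self,
        own_probs: dict[int, float],
        learning_rate: float = 1.0,
        prior_n: float = 0.5,
        pool_n: float = 4.0,
    ):
        self.own_probs = dict(own_probs)
        self.learning_rate = learning_rate
        self.prior_n = prior_n
        self.pool_n = pool_n
        self.counts = {v: [0.0, 0.0] for v in own_probs}  # [gamble, total]
        self.pool = [0.0, 0.0]

    def guess_prob(self, gamble_value: int) -> float:
        g, n = self.counts[gamble_value]
        pg, pn = self.pool
        pool_rate = (pg + 1.0) / (pn + 2.0)
        lr = self.learning_rate
        num = self.prior_n * self.own_probs[gamble_value] + lr * (
            self.pool_n * pool_rate + g
        )
        den = self.prior_n + lr * (self.pool_n + n)
        return num / den

    def observe(self, gamble_value: int, majority_choice: str) -> None:
        is_gamble = 1.0 if majority_choice == "gamble" else 0.0
        self.counts[gamble_value][0] += is_gamble
        self.counts[gamble_value][1] += 1.0
        self.pool[0] += is_gamble
        self.pool[1] += 1.0


def simulate_guess_learning(
    params: AgentParams,
    schedule: NormSchedule,
    trials: list[GambleScenario],
    rng: np.random.Generator,
    learning_rate: float = 1.0,
) -> tuple[list[dict], GuessLearner]:
    """Simulate the guessing-with-feedback phase for one agent.

    Returns one record per trial (guess, majority choice, feedback) and the
    learner state at the end of the phase, which carries the agent's final
    estimate of the group's choice frequencies.
    """
    own_probs = {
        v: choice_prob(replace_value(trials[0], v), params) for v in schedule.grid
    }
    learner = GuessLearner(own_probs, learning_rate=learning_rate)
    records = []
    for scen in trials:
        v = scen.gamble_value
        p_guess = learner.guess_prob(v)
        guess = "gamble" if rng.random() < p_guess else "certain"
        majority = "gamble" if rng.random() < schedule.p(v) else "certain"
        learner.observe(v, majority)
        records.append(
            {
                "gamble_value": v,
                "guess": guess,
                "majority_choice": majority,
                "feedback": "correct" if guess == majority else "incorrect",
            }
        )
    return records, learner


def replace_value(scenario: GambleScenario, gamble_value: int) -> GambleScenario:
    return replace(scenario, gamble_value=int(gamble_value))


@dataclass(frozen=True)
class ParamPriors:
    """Sampling distributions for AgentParams; defaults are package choices."""

    alpha_range: tuple[float, float] = (0.4, 1.1)
    lam_logmean: float = float(np.log(1.5))
    lam_logsd: float = 0.3
    tau_shape: float = 2.0
    tau_scale: float = 0.5
    beta0_sd: float = 0.3
    w_beta: tuple[float, float] = (2.0, 2.0)
    persist_beta: tuple[float, float] = (5.0, 2.0)
    # pin individual parameters while keeping the rest heterogeneous
    w_fixed: float | None = None
    persist_fixed: float | None = None

    def sample(self, rng: np.random.Generator) -> AgentParams:
        w = rng.beta(*self.w_beta) if self.w_fixed is None else self.w_fixed
        rho = (
            rng.beta(*self.persist_beta)
            if self.persist_fixed is None
            else self.persist_fixed
        )
        return AgentParams(
            alpha=float(rng.uniform(*self.alpha_range)),
            lam=float(rng.lognormal(self.lam_logmean, self.lam_logsd)),
            tau=float(rng.gamma(self.tau_shape, self.tau_scale)),
            beta0=float(rng.normal(0.0, self.beta0_sd)),
            w_norm=float(w),
            persist=float(rho),
        )


def fixed_priors(params: AgentParams) -> "DegeneratePriors":
    """Priors degenerate at a single parameter vector (for controlled tests)."""
    return DegeneratePriors(params)


@dataclass(frozen=True)
class DegeneratePriors:
    params: AgentParams

    def sample(self, rng: np.random.Generator) -> AgentParams:
        return self.params


# Awareness model: 100 * expit(a + b * w_norm + noise).  With w_norm ~
# Beta(2, 2) these coefficients give a population awareness-conformity
# Pearson r of about 0.2 (the realized conformity score is a noisy readout
# of w_norm, which attenuates the latent correlation) and a mean
# self-report in the low-to-mid 30s on the 0-100 scale.
AWARENESS_INTERCEPT = -3.0
AWARENESS_SLOPE = 4.0
AWARENESS_NOISE_SD = 1.2


def awareness_score(w_norm: float, rng: np.random.Generator) -> float:
    latent = (
        AWARENESS_INTERCEPT
        + AWARENESS_SLOPE * w_norm
        + rng.normal(0.0, AWARENESS_NOISE_SD)
    )
    return float(100.0 * expit(latent))


def population_pilot_rates(
    frame: str,
    priors=None,
    n_agents: int = 4000,
    seed: int = 12345,
) -> dict[int, float]:
    """Pilot gambling-rate curve implied by the agent population itself.

    A pilot study measures the average gambling rate of participants drawn
    from the same population as the main study, so the default pilot curve
    is the prior-predictive mean of `choice_prob` over the guessing grid
    (Monte-Carlo average over ``n_agents`` prior draws, fixed internal
    seed).  Norm schedules built from this curve are then genuinely more
    risk-averse / risk-seeking than the average participant.
    """
    if priors is None:
        priors = ParamPriors()
    rng = np.random.default_rng(seed)
    grid = np.asarray(task.VALUE_GRID_GUESS, dtype=float)
    sign = 1.0 if frame == "gain" else -1.0
    if frame not in ("gain", "loss"):
        raise ValueError(f"frame must be 'gain' or 'loss', got {frame!r}")
    acc = np.zeros_like(grid)
    for _ in range(n_agents):
        p = priors.sample(rng)
        lam = 1.0 if frame == "gain" else p.lam
        u_g = sign * lam * grid**p.alpha
        u_c = sign * lam * 10.0**p.alpha
        acc += expit(p.tau * (0.5 * u_g - u_c) + p.beta0)
    acc /= n_agents
    return {int(v): float(q) for v, q in zip(grid, acc)}


def _simulate_participant(
    pid: str,
    frame: str,
    norm_type: str,
    domain: str,
    params: AgentParams,
    schedule: NormSchedule,
    rng: np.random.Generator,
    repeats: int,
    constant_responder: bool,
    learning_rate: float = 1.0,
) -> list[dict]:
    rows: list[dict] = []

    def own_phase(phase: str, session: str, post_learning: bool) -> None:
        trials = build_phase_schedule(
            phase, frame, domain, repeats, seed=int(rng.integers(2**31))
        )
        rep_seen: dict[int, int] = {}
        for i, scen in enumerate(trials):
            v = scen.gamble_value
            rep_seen[v] = rep_seen.get(v, 0) + 1
            if constant_responder:
                resp = "certain"
            else:
                if post_learning:
                    p = conformity_shift(params, schedule, v, session, frame, domain)
                else:
                    p = choice_prob(scen, params)
                resp = "gamble" if rng.random() < p else "certain"
            rows.append(
                {
                    "participant_id": pid,
                    "domain": domain,
                    "frame": frame,
                    "norm_type": norm_type,
                    "session": session,
                    "phase": phase,
                    "trial_index": i,
                    "repeat_index": rep_seen[v] - 1,
                    "gamble_value": v,
                    "certain_value": task.CERTAIN_VALUE,
                    "gamble_prob": task.GAMBLE_PROB,
                    "response": resp,
                    "response_type": "own",
                    "feedback": "none",
                }
            )

    def guess_phase(phase: str, session: str, learner: GuessLearner | None):
        trials = build_phase_schedule(
            phase, frame, domain, repeats, seed=int(rng.integers(2**31))
        )
        if learner is None:  # learning phase: run the learner with feedback
            recs, new_learner = simulate_guess_learning(
                params, schedule, trials, rng, learning_rate=learning_rate
            )
            rep_seen: dict[int, int] = {}
            for i, (scen, rec) in enumerate(zip(trials, recs)):
                v = scen.gamble_value
                rep_seen[v] = rep_seen.get(v, 0) + 1
                rows.append(
                    {
                        "participant_id": pid,
                        "domain": domain,
                        "frame": frame,
                        "norm_type": norm_type,
                        "session": session,
                        "phase": phase,
                        "trial_index": i,
                        "repeat_index": rep_seen[v] - 1,
                        "gamble_value": v,
                        "certain_value": task.CERTAIN_VALUE,
                        "gamble_prob": task.GAMBLE_PROB,
                        "response": "certain" if constant_responder else rec["guess"],
                        "response_type": "guess",
                        "feedback": rec["feedback"],
                    }
                )
            return new_learner
        # day-3 guessing, no feedback: report from the retained estimate
        rep_seen = {}
        for i, scen in enumerate(trials):
            v = scen.gamble_value
            rep_seen[v] = rep_seen.get(v, 0) + 1
            p = learner.guess_prob(v)
            resp = "gamble" if rng.random() < p else "certain"
            rows.append(
                {
                    "participant_id": pid,
                    "domain": domain,
                    "frame": frame,
                    "norm_type": norm_type,
                    "session": session,
                    "phase": phase,
                    "trial_index": i,
                    "repeat_index": rep_seen[v] - 1,
                    "gamble_value": v,
                    "certain_value": task.CERTAIN_VALUE,
                    "gamble_prob": task.GAMBLE_PROB,
                    "response": "certain" if constant_responder else resp,
                    "response_type": "guess",
                    "feedback": "none",
                }
            )
        return learner

    own_phase("baseline", "D0", post_learning=False)
    learner = guess_phase("learning", "D0", learner=None)
    own_phase("own_d0", "D0", post_learning=True)
    own_phase("own_d3", "D3", post_learning=True)
    guess_phase("others_d3", "D3", learner=learner)
    return rows


def simulate_cohort(
    n_per_cell: int = 90,
    domains: tuple[str, ...] = task.DOMAINS,
    frames: tuple[str, ...] = task.FRAMES,
    norm_types: tuple[str, ...] = ("risk_averse", "risk_seeking"),
    pilot_rates: dict[str, dict[int, float]] | None = None,
    param_priors=None,
    n_constant_responders: int = 0,
    n_failed_comprehension: int = 0,
    n_failed_attention: int = 0,
    repeats: int = task.DEFAULT_REPEATS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full two-session cohort over the factorial design.

    Returns ``(trials, truth, participants)``: the long-format trial table,
    the ground-truth parameter table, and a per-participant table with the
    condition assignment, awareness score and QC flags (comprehension
    correctness counts, attention-check pass, injected-rule-breaker labels).

    The default cell size (90 per frame x norm x domain cell) matches a
    day-0 sample of 360 participants per domain.  Injected rule-breakers
    are appended on top of ``n_per_cell`` and spread over cells round-robin.
    """
    if n_per_cell < 1:
        raise ValueError(f"n_per_cell must be >= 1, got {n_per_cell}")
    if param_priors is None:
        param_priors = ParamPriors()
    if not hasattr(param_priors, "sample"):
        raise ValueError("param_priors must expose a .sample(rng) method")
    if pilot_rates is None:
        pilot_rates = {
            f: population_pilot_rates(f, priors=param_priors) for f in frames
        }

    cells = [
        (d, f, n) for d in domains for f in frames for n in norm_types
    ]
    roster: list[tuple[str, str, str, str, bool, bool, bool]] = []
    idx = 0
    for d, f, n in cells:
        for _ in range(n_per_cell):
            roster.append((f"p{idx:04d}", d, f, n, False, False, False))
            idx += 1
    for k in range(n_constant_responders):
        d, f, n = cells[k % len(cells)]
        roster.append((f"p{idx:04d}", d, f, n, True, False, False))
        idx += 1
    for k in range(n_failed_comprehension):
        d, f, n = cells[k % len(cells)]
        roster.append((f"p{idx:04d}", d, f, n, False, True, False))
        idx += 1
    for k in range(n_failed_attention):
        d, f, n = cells[k % len(cells)]
        roster.append((f"p{idx:04d}", d, f, n, False, False, True))
        idx += 1

    schedules = {
        (f, n): build_norm_schedule(pilot_rates[f], n)
        for f in frames
        for n in norm_types
    }

    streams = np.random.SeedSequence(seed).spawn(len(roster))
    all_rows: list[dict] = []
    truth_rows: list[dict] = []
    part_rows: list[dict] = []
    for (pid, d, f, n, constant, bad_comp, bad_att), ss in zip(roster, streams):
        rng = np.random.default_rng(ss)
        params = param_priors.sample(rng)
        all_rows.extend(
            _simulate_participant(
                pid, f, n, d, params, schedules[(f, n)], rng, repeats, constant
            )
        )
        truth_rows.append(
            {
                "participant_id": pid,
                "domain": d,
                "frame": f,
                "norm_type": n,
                "alpha": params.alpha,
                "lam": params.lam,
                "tau": params.tau,
                "beta0": params.beta0,
                "w_norm": params.w_norm,
                "persist": params.persist,
            }
        )
        # comprehension: compliant participants get at most 1 of 4 wrong
        n_wrong = int(rng.integers(2, 5)) if bad_comp else int(rng.random() < 0.2)
        part_rows.append(
            {
                "participant_id": pid,
                "domain": d,
                "frame": f,
                "norm_type": n,
                "awareness": awareness_score(params.w_norm, rng),
                "comprehension_wrong": n_wrong,
                "attention_pass": not bad_att,
                "injected_constant": constant,
                "injected_failed_comprehension": bad_comp,
                "injected_failed_attention": bad_att,
            }
        )

    trials = pd.DataFrame(all_rows)
    truth = pd.DataFrame(truth_rows)
    participants = pd.DataFrame(part_rows)
    return trials, truth, participants
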