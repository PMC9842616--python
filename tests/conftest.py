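import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from riskconform import simulate_cohort
from riskconform.cohort import AgentParams, fixed_priors


@pytest.fixture(scope="session")
def small_cohort():
    """16-participant cohort over all 8 design cells (2 per cell)."""
    return simulate_cohort(n_per_cell=2, seed=7)


@pytest.fixture(scope="session")
def moral_cohort():
    """Moral-domain cohort at a size adequate for metric sign checks."""
    trials, truth, participants = simulate_cohort(
        n_per_cell=40, domains=("moral",), seed=11
    )
    return trials, truth, participants


@pytest.fixture(scope="session")
def uncertain_extreme_cohort():
    """Uncertain agents (low tau) facing steep norm schedules: the regime
    where learned norms sharpen choices and entropy drops."""
    grid = range(10, 31)
    pilots = {
        "gain": {v: float(expit(1.5 * (v - 20))) for v in grid},
        "loss": {v: float(expit(-1.5 * (v - 20))) for v in grid},
    }
    priors = fixed_priors(
        AgentParams(alpha=0.8, lam=1.5, tau=0.3, beta0=0.0, w_norm=0.6, persist=0.7)
    )
    trials, _, _ = simulate_cohort(
        n_per_cell=25,
        domains=("moral",),
        pilot_rates=pilots,
        param_priors=priors,
        seed=5,
    )
    return trials


def simulate_logit_trials(
    rng,
    n_subj=40,
    re_sd=1.0,
    cell_beta=None,
    slope=0.8,
    phases=("baseline", "own_d0"),
    repeats=2,
    p_const=None,
):
    """Trials from a known random-intercept logit (test oracle generator).

    ``p_const`` short-circuits the linear predictor with a fixed Bernoulli
    probability (null-simulation mode).
    """
    cell_beta = cell_beta or {"baseline": -0.5, "own_d0": 0.3}
    rows = []
    for pid in range(n_subj):
        b = rng.normal(0, re_sd) if re_sd > 0 else 0.0
        norm = "risk_averse" if pid % 2 == 0 else "risk_seeking"
        for phase in phases:
            for v in range(10, 31, 2):
                for rep in range(repeats):
                    if p_const is not None:
                        p = p_const
                    else:
                        p = expit(cell_beta[phase] + slope * (v - 20) / 10 + b)
                    rows.append(
                        {
                            "participant_id": f"p{pid:03d}",
                            "domain": "moral",
                            "frame": "gain",
                            "norm_type": norm,
                            "session": "D0",
                            "phase": phase,
                            "trial_index": 0,
                            "repeat_index": rep,
                            "gamble_value": v,
                            "certain_value": 10,
                            "gamble_prob": 0.5,
                            "response": "gamble" if rng.random() < p else "certain",
                            "response_type": "own",
                            "feedback": "none",
                        }
                    )
    df = pd.DataFrame(rows)
    df["trial_index"] = df.groupby(["participant_id", "phase"]).cumcount()
    return df


def simulate_pt_agent(params, rng, n_rep=8, frames=("gain", "loss")):
    """Own-choice trials drawn straight from the PT choice rule."""
    from riskconform import choice_prob
    from riskconform.task import GambleScenario

    grid = np.arange(10, 31, 2)
    dfs = []
    for frame in frames:
        ps = np.array(
            [choice_prob(GambleScenario(int(v), frame, "moral"), params) for v in grid]
        )
        vals = np.repeat(grid, n_rep)
        p = np.repeat(ps, n_rep)
        y = rng.random(len(vals)) < p
        dfs.append(
            pd.DataFrame(
                {
                    "gamble_value": vals,
                    "frame": frame,
                    "response": np.where(y, "gamble", "certain"),
                }
            )
        )
    return pd.concat(dfs, ignore_index=True)
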