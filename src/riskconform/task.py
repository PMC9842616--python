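"""Parametric gamble task: scenarios, expected values and phase schedules.

The task offers a choice between a certain option (always 10 units — lives
in the moral domain, currency in the monetary domain) and a gamble paying
``gamble_value`` units with probability 0.5 (nothing otherwise).  In the
loss frame the same magnitudes are losses, carried internally as negative
signed values.  A session is built from five phases:

========== ======= ============== ======== ========
phase      session value grid     response feedback
========== ======= ============== ======== ========
baseline   D0      10..30 step 2  own      no
learning   D0      10..30 step 1  guess    yes
own_d0     D0      10..30 step 2  own      no
own_d3     D3      10..30 step 2  own      no
others_d3  D3      10..30 step 1  guess    no
========== ======= ============== ======== ========

Each scenario repeats 4 times per phase, in a seeded uniform random order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CERTAIN_VALUE = 10
GAMBLE_PROB = 0.5
VALUE_GRID_OWN = tuple(range(10, 31, 2))  # 11 values
VALUE_GRID_GUESS = tuple(range(10, 31))  # 21 values
DEFAULT_REPEATS = 4

FRAMES = ("gain", "loss")
DOMAINS = ("moral", "monetary")
PHASES = ("baseline", "learning", "own_d0", "own_d3", "others_d3")
OWN_PHASES = ("baseline", "own_d0", "own_d3")
GUESS_PHASES = ("learning", "others_d3")

_PHASE_SESSION = {
    "baseline": "D0",
    "learning": "D0",
    "own_d0": "D0",
    "own_d3": "D3",
    "others_d3": "D3",
}


@dataclass(frozen=True)
class GambleScenario:
    """One choice problem: certain 10 vs a 50% gamble of ``gamble_value``."""

    gamble_value: int
    frame: str
    domain: str
    certain_value: int = CERTAIN_VALUE
    gamble_prob: float = GAMBLE_PROB

    def __post_init__(self) -> None:
        if not (10 <= self.gamble_value <= 30):
            raise ValueError(
                f"gamble_value must lie in [10, 30], got {self.gamble_value}"
            )
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if self.certain_value != CERTAIN_VALUE:
            raise ValueError("certain_value is fixed at 10 in this task")
        if self.gamble_prob != GAMBLE_PROB:
            raise ValueError("gamble_prob is fixed at 0.5 in this task")

    @property
    def sign(self) -> int:
        """+1 for the gain frame, -1 for the loss frame."""
        return 1 if self.frame == "gain" else -1


@dataclass(frozen=True)
class PhaseSchedule:
    """Static description of one phase of one session."""

    phase: str
    session: str
    gamble_values: tuple[int, ...]
    repeats: int
    response_type: str
    feedback_enabled: bool

    @property
    def n_trials(self) -> int:
        return len(self.gamble_values) * self.repeats


def phase_schedule(phase: str, repeats: int = DEFAULT_REPEATS) -> PhaseSchedule:
    """Return the static schedule for ``phase`` (grid, session, response type)."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    own = phase in OWN_PHASES
    return PhaseSchedule(
        phase=phase,
        session=_PHASE_SESSION[phase],
        gamble_values=VALUE_GRID_OWN if own else VALUE_GRID_GUESS,
        repeats=repeats,
        response_type="own" if own else "guess",
        feedback_enabled=(phase == "learning"),
    )


def build_phase_schedule(
    phase: str,
    frame: str,
    domain: str,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> list[GambleScenario]:
    """Ordered trial list for one phase: every scenario ``repeats`` times,
    in a uniform random permutation determined by ``seed``.
    """
    sched = phase_schedule(phase, repeats)
    trials = [
        GambleScenario(gamble_value=v, frame=frame, domain=domain)
        for v in sched.gamble_values
        for _ in range(repeats)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def expected_value(scenario: GambleScenario, option: str) -> float:
    """Signed expected value of one option (negative in the loss frame)."""
    if option == "gamble":
        return scenario.sign * scenario.gamble_prob * scenario.gamble_value
    if option == "certain":
        return float(scenario.sign * scenario.certain_value)
    raise ValueError(f"option must be 'gamble' or 'certain', got {option!r}")
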