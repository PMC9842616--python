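"""Group-norm feedback schedules for the learning phase.

The "group" the participant learns about does not exist: its choices are
drawn trial by trial from a probabilistic schedule constructed by shifting
a pilot gambling-rate curve by a fixed offset (default 0.20).  A
risk-seeking norm gambles 20 percentage points more often than the pilot
group at every gamble value; a risk-averse norm 20 points less.
Probabilities are clipped away from 0/1 so the feedback stays stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .task import VALUE_GRID_GUESS

NORM_TYPES = ("risk_averse", "risk_seeking")
DEFAULT_OFFSET = 0.20
DEFAULT_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class NormSchedule:
    """Per-gamble-value probability that the majority chose the gamble."""

    norm_type: str
    offset: float
    p_majority_gamble: dict[int, float] = field(repr=False)

    def p(self, gamble_value: int) -> float:
        try:
            return self.p_majority_gamble[int(gamble_value)]
        except KeyError:
            raise ValueError(
                f"gamble_value {gamble_value} is not on the schedule grid"
            ) from None

    @property
    def grid(self) -> tuple[int, ...]:
        return tuple(sorted(self.p_majority_gamble))


def default_pilot_rates(frame: str) -> dict[int, float]:
    """Package-default pilot gambling-rate curves (stand-ins, not measured).

    Logistic in the gamble's expected value: in losses the curve falls with
    gamble value and crosses 0.5 at the EV-equality point (value 20); in
    gains it rises and crosses 0.5 above 20, mimicking baseline risk
    aversion in gains.
    """
    grid = np.asarray(VALUE_GRID_GUESS, dtype=float)
    if frame == "gain":
        p = expit(0.25 * (grid - 24.0))
    elif frame == "loss":
        p = expit(-0.25 * (grid - 20.0))
    else:
        raise ValueError(f"frame must be 'gain' or 'loss', got {frame!r}")
    return {int(v): float(q) for v, q in zip(grid, p)}


def build_norm_schedule(
    pilot_rates: dict[int, float],
    norm_type: str,
    offset: float = DEFAULT_OFFSET,
    clip: tuple[float, float] = DEFAULT_CLIP,
) -> NormSchedule:
    """Shift a pilot gambling-rate curve into a norm schedule.

    risk_seeking -> pilot + offset, risk_averse -> pilot - offset, then
    clipped to ``clip``.  The pilot curve must cover the full guessing grid
    (10..30 step 1) with rates in [0, 1].
    """
    if norm_type not in NORM_TYPES:
        raise ValueError(f"norm_type must be one of {NORM_TYPES}, got {norm_type!r}")
    lo, hi = clip
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"clip bounds must satisfy 0 < lo < hi < 1, got {clip}")
    missing = sorted(set(VALUE_GRID_GUESS) - {int(v) for v in pilot_rates})
    if missing:
        raise ValueError(f"pilot curve is missing grid values: {missing}")
    bad = {v: p for v, p in pilot_rates.items() if not (0.0 <= p <= 1.0)}
    if bad:
        raise ValueError(f"pilot rates outside [0, 1]: {bad}")
    sign = 1.0 if norm_type == "risk_seeking" else -1.0
    sched = {
        int(v): float(np.clip(pilot_rates[v] + sign * offset, lo, hi))
        for v in VALUE_GRID_GUESS
    }
    return NormSchedule(norm_type=norm_type, offset=offset, p_majority_gamble=sched)


def sample_majority_choice(
    schedule: NormSchedule, gamble_value: int, rng: np.random.Generator
) -> str:
    """Draw the majority's choice at one gamble value (Bernoulli)."""
    p = schedule.p(gamble_value)
    return "gamble" if rng.random() < p else "certain"


def write_schedule(schedule: NormSchedule, path) -> None:
    """Two-column CSV (gamble_value, p_majority_gamble) with a metadata
    header carrying the norm type and offset."""
    with open(path, "w") as fh:
        fh.write(f"# norm_type={schedule.norm_type} offset={schedule.offset}\n")
        fh.write("gamble_value,p_majority_gamble\n")
        for v in schedule.grid:
            fh.write(f"{v},{schedule.p(v)!r}\n")


def read_schedule(path) -> NormSchedule:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        fh.readline()  # column names
        rates: dict[int, float] = {}
        for line in fh:
            if line.strip():
                v, p = line.split(",")
                rates[int(v)] = float(p)
    return NormSchedule(
        norm_type=meta["norm_type"],
        offset=float(meta["offset"]),
        p_majority_gamble=rates,
    )


def feedback_for_guess(guess: str, majority_choice: str) -> str:
    """'correct' iff the guess matches the realized majority choice."""
    for arg in (guess, majority_choice):
        if arg not in ("gamble", "certain"):
            raise ValueError(f"choices must be 'gamble' or 'certain', got {arg!r}")
    return "correct" if guess == majority_choice else "incorrect"
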