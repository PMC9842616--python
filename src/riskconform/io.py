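"""Trial-table schema, CSV readers/writers and the participant exclusions.

The long-format trial CSV has one row per participant x session x phase x
trial with columns::

    participant_id, domain, frame, norm_type, session, phase, trial_index,
    repeat_index, gamble_value, certain_value, gamble_prob, response,
    response_type, feedback

Exclusion rules mirror the study's QC: participants who answer two or more
of the four comprehension questions wrong, who give the same answer on
every own-choice trial of a session, or who fail an attention check are
removed before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .task import DOMAINS, FRAMES, GUESS_PHASES, OWN_PHASES, PHASES

TRIAL_COLUMNS = [
    "participant_id",
    "domain",
    "frame",
    "norm_type",
    "session",
    "phase",
    "trial_index",
    "repeat_index",
    "gamble_value",
    "certain_value",
    "gamble_prob",
    "response",
    "response_type",
    "feedback",
]

_CATEGORICALS = {
    "domain": set(DOMAINS),
    "frame": set(FRAMES),
    "norm_type": {"risk_averse", "risk_seeking"},
    "session": {"D0", "D3"},
    "phase": set(PHASES),
    "response": {"gamble", "certain"},
    "response_type": {"own", "guess"},
    "feedback": {"correct", "incorrect", "none"},
}


class SchemaError(ValueError):
    """Raised when a trial table violates the schema (with row numbers)."""


def validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    problems: list[str] = []
    for col, allowed in _CATEGORICALS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            rows = df.index[bad][:5].tolist()
            problems.append(
                f"column {col!r}: invalid values {sorted(df.loc[bad, col].unique()[:5])} "
                f"at rows {rows}"
            )
    out_of_range = ~df["gamble_value"].between(10, 30)
    if out_of_range.any():
        rows = df.index[out_of_range][:5].tolist()
        problems.append(f"gamble_value outside [10, 30] at rows {rows}")
    fb = df[(df["feedback"] != "none") & (df["phase"] != "learning")]
    if not fb.empty:
        problems.append(
            f"feedback outside the learning phase at rows {fb.index[:5].tolist()}"
        )
    guess = df[(df["response_type"] == "guess") & (~df["phase"].isin(GUESS_PHASES))]
    if not guess.empty:
        problems.append(
            f"guess responses outside guessing phases at rows {guess.index[:5].tolist()}"
        )
    own = df[(df["response_type"] == "own") & (~df["phase"].isin(OWN_PHASES))]
    if not own.empty:
        problems.append(
            f"own responses in guessing phases at rows {own.index[:5].tolist()}"
        )
    dup = df.duplicated(subset=["participant_id", "session", "phase", "trial_index"])
    if dup.any():
        problems.append(
            "duplicate (participant, session, phase, trial_index) at rows "
            f"{df.index[dup][:5].tolist()}"
        )
    if problems:
        raise SchemaError("; ".join(problems))


def write_trials(df: pd.DataFrame, path) -> None:
    validate_trials(df)
    df.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "trial_index": int,
            "repeat_index": int,
            "gamble_value": int,
            "certain_value": int,
        },
    )
    validate_trials(df)
    return df.loc[:, TRIAL_COLUMNS]


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_failed_comprehension: int
    n_constant_response: int
    n_failed_attention: int
    n_retained: int
    flags: pd.DataFrame  # per participant: one bool column per rule

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_failed_comprehension": self.n_failed_comprehension,
            "n_constant_response": self.n_constant_response,
            "n_failed_attention": self.n_failed_attention,
            "n_retained": self.n_retained,
        }


def constant_responders(trials: pd.DataFrame) -> pd.Series:
    """True for participants giving one identical own-choice response over
    an entire session (either session)."""
    own = trials[trials["response_type"] == "own"]
    nuniq = own.groupby(["participant_id", "session"])["response"].nunique()
    flat = nuniq[nuniq <= 1].reset_index()["participant_id"].unique()
    out = pd.Series(False, index=pd.Index(trials["participant_id"].unique(), name="participant_id"))
    out.loc[flat] = True
    return out


def apply_exclusions(
    trials: pd.DataFrame,
    comprehension_wrong: pd.Series,
    attention_pass: pd.Series | None = None,
    comprehension_threshold: int = 2,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Filter participants by the QC rules; returns retained rows + report.

    ``comprehension_wrong`` maps participant_id -> number of the 4
    comprehension questions answered wrong (>= ``comprehension_threshold``
    excludes).  ``attention_pass`` maps participant_id -> bool.  Flags must
    cover every participant present in the records.
    """
    pids = pd.Index(trials["participant_id"].unique(), name="participant_id")
    unknown = pids.difference(comprehension_wrong.index)
    if len(unknown):
        raise ValueError(
            f"records reference participants without comprehension flags: "
            f"{unknown[:5].tolist()}"
        )
    if attention_pass is None:
        attention_pass = pd.Series(True, index=pids)
    unknown = pids.difference(attention_pass.index)
    if len(unknown):
        raise ValueError(
            f"records reference participants without attention flags: "
            f"{unknown[:5].tolist()}"
        )
    comp_fail = comprehension_wrong.loc[pids] >= comprehension_threshold
    const = constant_responders(trials)
    att_fail = ~attention_pass.loc[pids].astype(bool)
    flags = pd.DataFrame(
        {
            "failed_comprehension": comp_fail,
            "constant_response": const.loc[pids],
            "failed_attention": att_fail,
        },
        index=pids,
    )
    excluded = flags.any(axis=1)
    retained = trials[~trials["participant_id"].isin(pids[excluded])].copy()
    report = ExclusionReport(
        n_input=len(pids),
        n_failed_comprehension=int(comp_fail.sum()),
        n_constant_response=int(flags["constant_response"].sum()),
        n_failed_attention=int(att_fail.sum()),
        n_retained=int((~excluded).sum()),
        flags=flags,
    )
    return retained, report
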