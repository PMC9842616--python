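"""Conformity metrics: influence curves, persistence, choice-entropy
uncertainty analysis, peak-influence alignment and the awareness
correlation.

The influence of a learned group norm is measured as the change in gamble
probability between a post-learning phase and baseline, either per gamble
value (the influence curve) or averaged over the value grid (the marginal
influence).  Choice uncertainty is quantified with the binary entropy of
each participant's repeated choices on identical problems,

    H(p) = -p log2 p - (1 - p) log2 (1 - p),

which is 0 for perfectly consistent responding and 1 at p = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from . import models


@dataclass(frozen=True)
class InfluenceEstimate:
    condition: dict
    phase_pair: tuple[str, str]
    per_value_delta: pd.Series  # gamble_value -> delta P(gamble)
    marginal_delta: float
    ci_low: float
    ci_high: float
    n_participants: int

    @property
    def abs_magnitude(self) -> float:
        return abs(self.marginal_delta)


@dataclass(frozen=True)
class EntropySummary:
    per_cell: pd.DataFrame  # participant x phase x gamble_value entropies
    per_participant: pd.DataFrame  # participant-level phase means (wide)
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float


def _own_rates(trials: pd.DataFrame, phase: str, condition: dict) -> pd.DataFrame:
    d = trials[(trials["phase"] == phase) & (trials["response_type"] == "own")]
    for key, val in condition.items():
        d = d[d[key] == val]
    if d.empty:
        raise ValueError(f"no own-choice trials for phase {phase!r} under {condition}")
    g = (
        d.assign(gamble=(d["response"] == "gamble").astype(float))
        .groupby(["participant_id", "gamble_value"])["gamble"]
        .mean()
        .rename("p_gamble")
        .reset_index()
    )
    return g


def influence_curve(
    trials: pd.DataFrame,
    phase_pair: tuple[str, str] = ("own_d0", "baseline"),
    condition: dict | None = None,
    fit: "models.MixedLogitFit | None" = None,
    n_draws: int = 2000,
    seed: int = 0,
) -> InfluenceEstimate:
    """Norm influence: Delta P(gamble) between two phases for one condition.

    Raw mode (default) uses per-participant choice proportions, with a
    t-interval over participants' marginal deltas.  When a fitted mixed
    logit is supplied, deltas come from model-based marginal probabilities
    and the CI from parametric simulation of the coefficients.
    """
    condition = condition or {}
    post, base = phase_pair
    if fit is not None:
        norm_type = condition.get("norm_type")
        frame = condition.get("frame")
        if norm_type is None or frame is None:
            raise ValueError("model-based influence needs norm_type and frame")
        cellA = (post, norm_type, frame)
        cellB = (base, norm_type, frame)
        curveA = models.cell_value_curve(fit, cellA)
        curveB = models.cell_value_curve(fit, cellB)
        per_value = (curveA - curveB).rename("delta")
        res = models.contrast(fit, cellA, cellB, n_draws=n_draws, seed=seed)
        return InfluenceEstimate(
            condition=condition,
            phase_pair=phase_pair,
            per_value_delta=per_value,
            marginal_delta=res.estimate,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            n_participants=fit.n_subjects,
        )

    rates_post = _own_rates(trials, post, condition)
    rates_base = _own_rates(trials, base, condition)
    merged = rates_post.merge(
        rates_base, on=["participant_id", "gamble_value"], suffixes=("_post", "_base")
    )
    merged["delta"] = merged["p_gamble_post"] - merged["p_gamble_base"]
    per_value = merged.groupby("gamble_value")["delta"].mean()
    per_part = merged.groupby("participant_id")["delta"].mean()
    n = len(per_part)
    m = float(per_part.mean())
    if n > 1 and per_part.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, n - 1) * per_part.std(ddof=1) / np.sqrt(n)
    else:
        half = 0.0
    return InfluenceEstimate(
        condition=condition,
        phase_pair=phase_pair,
        per_value_delta=per_value,
        marginal_delta=m,
        ci_low=m - half,
        ci_high=m + half,
        n_participants=n,
    )


def persistence(
    trials: pd.DataFrame,
    condition: dict | None = None,
    fit: "models.MixedLogitFit | None" = None,
    **kwargs,
) -> InfluenceEstimate:
    """Day-3 retention of the conformity effect: own_d3 vs D0 baseline."""
    return influence_curve(
        trials, ("own_d3", "baseline"), condition=condition, fit=fit, **kwargs
    )


def binary_entropy(p):
    """Binary entropy in bits; 0*log2(0) taken as 0. Rejects p outside [0,1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / np.log(2.0)
    return h if h.ndim else float(h)


def wilcoxon_paired(x, y):
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties get mid-ranks; the exact null
    distribution is used for n <= 25 (when there are no tied ranks), the
    normal approximation with continuity correction otherwise.  Returns
    (statistic, p, n_nonzero); a degenerate test (all differences zero)
    returns (nan, nan, 0).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan"), float("nan"), 0
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue), n


def entropy_phase_comparison(
    trials: pd.DataFrame,
    phaseA: str = "baseline",
    phaseB: str = "own_d0",
    condition: dict | None = None,
) -> EntropySummary:
    """Choice entropy per participant x phase x scenario, and the paired
    Wilcoxon test of the participant-level phase means (A vs B).

    Both phases must share the scenario grid with >= 2 repeats; identical
    responding in both phases yields a degenerate (flagged) test.
    """
    condition = condition or {}
    cells = []
    for phase in (phaseA, phaseB):
        g = _own_rates(trials, phase, condition)
        d = trials[(trials["phase"] == phase)]
        counts = d.groupby(["participant_id", "gamble_value"]).size()
        if counts.min() < 2:
            raise ValueError(
                f"phase {phase!r} has scenarios with < 2 repeats; entropy undefined"
            )
        g["phase"] = phase
        g["entropy"] = binary_entropy(g["p_gamble"].to_numpy())
        cells.append(g)
    per_cell = pd.concat(cells, ignore_index=True)
    per_part = (
        per_cell.groupby(["participant_id", "phase"])["entropy"]
        .mean()
        .unstack("phase")
        .dropna()
    )
    stat, p, n_nonzero = wilcoxon_paired(per_part[phaseA], per_part[phaseB])
    return EntropySummary(
        per_cell=per_cell,
        per_participant=per_part,
        statistic=stat,
        p_value=p,
        n_pairs=len(per_part),
        degenerate=(n_nonzero == 0),
    )


@dataclass(frozen=True)
class AlignmentResult:
    peak_value: float
    crossing_value: float | None
    distance: float | None
    crossing_defined: bool
    multiple_crossings: bool


def peak_influence_alignment(
    influence: InfluenceEstimate, baseline_curve: pd.Series
) -> AlignmentResult:
    """Locate the gamble value of strongest influence and the value where
    the baseline gamble probability crosses 0.5 (maximal uncertainty).

    The crossing is found by linear interpolation on the value grid; with
    multiple crossings the one nearest the peak is reported and flagged.
    """
    deltas = influence.per_value_delta
    peak_value = float(deltas.abs().idxmax())
    vals = baseline_curve.index.to_numpy(dtype=float)
    p = baseline_curve.to_numpy(dtype=float)
    crossings = []
    for i in range(len(vals) - 1):
        a, b = p[i] - 0.5, p[i + 1] - 0.5
        if a == 0.0:
            crossings.append(vals[i])
        elif a * b < 0:
            crossings.append(vals[i] + (vals[i + 1] - vals[i]) * (-a) / (b - a))
    if p[-1] == 0.5:
        crossings.append(vals[-1])
    if not crossings:
        return AlignmentResult(peak_value, None, None, False, False)
    crossings = np.unique(crossings)
    nearest = float(crossings[np.argmin(np.abs(crossings - peak_value))])
    return AlignmentResult(
        peak_value=peak_value,
        crossing_value=nearest,
        distance=abs(nearest - peak_value),
        crossing_defined=True,
        multiple_crossings=len(crossings) > 1,
    )


def participant_conformity(
    trials: pd.DataFrame, phase_pair: tuple[str, str] = ("own_d0", "baseline")
) -> pd.Series:
    """Per-participant conformity: mean Delta P(gamble), signed so that a
    shift toward the assigned norm is positive (risk-seeking norm -> +delta,
    risk-averse norm -> -delta)."""
    post, base = phase_pair
    own = trials[trials["response_type"] == "own"]
    rates = (
        own.assign(gamble=(own["response"] == "gamble").astype(float))
        .groupby(["participant_id", "phase"])["gamble"]
        .mean()
        .unstack("phase")
    )
    delta = (rates[post] - rates[base]).dropna()
    norm = own.groupby("participant_id")["norm_type"].first()
    sign = norm.map({"risk_seeking": 1.0, "risk_averse": -1.0})
    return (delta * sign.loc[delta.index]).rename("conformity")


def awareness_conformity_correlation(
    awareness: pd.Series, conformity: pd.Series
) -> CorrelationResult:
    """Pearson correlation between self-reported awareness and conformity,
    reported with its df = n - 2 and two-sided p from the t transform."""
    joined = pd.concat(
        [awareness.rename("a"), conformity.rename("c")], axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    if joined["a"].std(ddof=0) == 0 or joined["c"].std(ddof=0) == 0:
        raise ValueError("zero variance in awareness or conformity vector")
    r, p = stats.pearsonr(joined["a"], joined["c"])
    return CorrelationResult(r=float(r), df=n - 2, p=float(p))
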