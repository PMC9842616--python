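"""Choice models: per-participant Prospect-Theory ML fits and the
random-intercept mixed-effects logit used for all reported gambling rates.

The mixed logit models the binary gamble choice y_ij of subject i on trial j,

    y_ij ~ Bernoulli( expit( x_ij' beta + b_i ) ),   b_i ~ N(0, sigma^2),

with the random intercept integrated out of the likelihood by adaptive
Gauss-Hermite quadrature (nodes centered and scaled at each subject's
conditional mode).  Fixed effects use a cell-means parameterization: one
coefficient per phase x norm x frame design cell, plus a gamble-value slope
per frame with the value centered at 20 (the EV-equality point) and scaled
by 10.  Marginal gamble probabilities average the inverse logit over both
the random-intercept distribution and the phase's value grid; contrasts
between cells carry a Monte-Carlo single-step max-|z| multiplicity
adjustment over the requested family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools import numdiff

from .cohort import AgentParams, choice_prob
from .task import GambleScenario, phase_schedule

VALUE_CENTER = 20.0
VALUE_SCALE = 10.0


class FitError(RuntimeError):
    """Raised when a model fit fails to converge or is not identifiable."""


# ---------------------------------------------------------------------------
# Per-participant Prospect-Theory fit


@dataclass(frozen=True)
class PTFit:
    alpha: float
    tau: float
    beta0: float
    lam: float
    loglik: float
    converged: bool
    identifiable: bool
    n_trials: int


def _pt_negloglik(theta, values, signs, y):
    alpha, tau, beta0 = theta
    # utilities carry the frame sign; lam fixed at 1 (not identifiable
    # within a single frame: it is absorbed into tau)
    u_gamble = signs * values**alpha
    u_certain = signs * 10.0**alpha
    eta = tau * (0.5 * u_gamble - u_certain) + beta0
    # stable Bernoulli loglik
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return -ll


_PT_BOUNDS = [(0.05, 3.0), (0.0, 30.0), (-5.0, 5.0)]


def fit_pt_model(
    trials: pd.DataFrame,
    n_restarts: int = 5,
    seed: int = 0,
    fix_alpha: float | None = None,
) -> PTFit:
    """Maximum-likelihood (alpha, tau, beta0) for one participant's own choices.

    ``trials`` needs columns gamble_value, frame, response.  Loss aversion is
    not identifiable from a single frame (it rescales tau), so lam is
    reported as 1.  Constant responders are flagged non-identifiable and no
    estimate is returned.  ``fix_alpha`` fits the restricted model with the
    curvature pinned (e.g. 1.0 for the risk-neutral fit).
    """
    y = (trials["response"].to_numpy() == "gamble").astype(float)
    values = trials["gamble_value"].to_numpy(dtype=float)
    signs = np.where(trials["frame"].to_numpy() == "gain", 1.0, -1.0)
    n = len(y)
    if n == 0 or y.min() == y.max():
        raise FitError(
            "constant responses: PT parameters are not identifiable for this participant"
        )
    if len(np.unique(values)) < 2:
        raise FitError("need >= 2 distinct gamble values to fit the PT model")

    rng = np.random.default_rng(seed)
    starts = [np.array([0.8, 1.0, 0.0])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.array(
                [rng.uniform(0.2, 1.5), rng.uniform(0.1, 5.0), rng.uniform(-1, 1)]
            )
        )

    if fix_alpha is not None:

        def obj(th2):
            return _pt_negloglik((fix_alpha, th2[0], th2[1]), values, signs, y)

        best = None
        for s in starts:
            res = minimize(obj, s[1:], method="L-BFGS-B", bounds=_PT_BOUNDS[1:])
            if best is None or res.fun < best.fun:
                best = res
        theta = np.array([fix_alpha, *best.x])
        success = bool(best.success)
    else:
        best = None
        for s in starts:
            res = minimize(
                _pt_negloglik,
                s,
                args=(values, signs, y),
                method="L-BFGS-B",
                bounds=_PT_BOUNDS,
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        success = bool(best.success)

    ll = -float(best.fun)
    # value sensitivity: likelihood-ratio against the bias-only model; pure
    # coin-flippers (tau = 0) land here and alpha is then meaningless
    p_null = y.mean()
    ll_null = n * (p_null * np.log(p_null) + (1 - p_null) * np.log(1 - p_null))
    identifiable = bool(2.0 * (ll - ll_null) > 3.84)
    return PTFit(
        alpha=float(theta[0]),
        tau=float(theta[1]),
        beta0=float(theta[2]),
        lam=1.0,
        loglik=ll,
        converged=success,
        identifiable=identifiable,
        n_trials=n,
    )


# ---------------------------------------------------------------------------
# Random-intercept mixed logit


@dataclass(frozen=True)
class ModelSpec:
    """Which trials enter the mixed logit and how cells are formed.

    Cells are every observed phase x norm x frame combination; a gamble-value
    slope is fitted per frame.  By default only own-choice phases enter.
    """

    phases: tuple[str, ...] = ("baseline", "own_d0", "own_d3")
    response_type: str = "own"
    value_slope_by_frame: bool = True
    random_intercept: bool = True
    quad_nodes: int = 21


@dataclass
class MixedLogitFit:
    fixed_effects: pd.Series
    re_sd: float
    loglik: float
    vcov: np.ndarray  # over (fixed effects, log re_sd) when random_intercept
    n_obs: int
    n_subjects: int
    cells: list[tuple[str, str, str]]  # (phase, norm_type, frame)
    slope_names: list[str]
    spec: ModelSpec
    converged: bool = True
    param_names: list[str] = field(default_factory=list)

    def cell_index(self, phase: str, norm_type: str, frame: str) -> int:
        key = (phase, norm_type, frame)
        if key not in self.cells:
            raise ValueError(
                f"cell {key} was not observed in the fitted data; "
                "refusing to extrapolate"
            )
        return self.cells.index(key)


def _build_design(df: pd.DataFrame, spec: ModelSpec):
    d = df[df["phase"].isin(spec.phases)]
    if spec.response_type is not None:
        d = d[d["response_type"] == spec.response_type]
    d = d.reset_index(drop=True)
    if d.empty:
        raise FitError("no trials match the model specification")
    y = (d["response"].to_numpy() == "gamble").astype(float)
    cells = sorted(
        set(zip(d["phase"], d["norm_type"], d["frame"])),
        key=lambda c: (spec.phases.index(c[0]), c[1], c[2]),
    )
    cell_idx = {c: k for k, c in enumerate(cells)}
    n, p_cells = len(d), len(cells)
    vc = (d["gamble_value"].to_numpy(dtype=float) - VALUE_CENTER) / VALUE_SCALE
    frames = sorted(d["frame"].unique())
    slope_names = (
        [f"value_{f}" for f in frames] if spec.value_slope_by_frame else ["value"]
    )
    X = np.zeros((n, p_cells + len(slope_names)))
    rows = np.arange(n)
    ks = np.array(
        [cell_idx[c] for c in zip(d["phase"], d["norm_type"], d["frame"])]
    )
    X[rows, ks] = 1.0
    if spec.value_slope_by_frame:
        for j, f in enumerate(frames):
            X[:, p_cells + j] = vc * (d["frame"].to_numpy() == f)
    else:
        X[:, p_cells] = vc
    names = ["cell_" + "_".join(c) for c in cells] + slope_names
    subj_codes, subj_idx = np.unique(d["participant_id"].to_numpy(), return_inverse=True)
    return X, y, subj_idx, len(subj_codes), cells, slope_names, names


def _agq_loglik(beta, log_sd, X, y, subj_idx, n_subj, z, wlog):
    """Adaptive Gauss-Hermite marginal log-likelihood."""
    sd = np.exp(log_sd)
    eta0 = X @ beta
    # subject modes by Newton on the conditional log-posterior of b_i
    b = np.zeros(n_subj)
    for _ in range(25):
        p = expit(eta0 + b[subj_idx])
        grad = np.bincount(subj_idx, weights=y - p, minlength=n_subj) - b / sd**2
        hess = -np.bincount(subj_idx, weights=p * (1 - p), minlength=n_subj) - 1.0 / sd**2
        step = grad / hess
        b -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta0 + b[subj_idx])
    curv = np.bincount(subj_idx, weights=p * (1 - p), minlength=n_subj) + 1.0 / sd**2
    s = 1.0 / np.sqrt(curv)  # Laplace scale per subject
    # nodes b_ik = b_i + s_i * z_k
    B = b[:, None] + s[:, None] * z[None, :]  # (n_subj, K)
    eta = eta0[:, None] + B[subj_idx, :]  # (n, K)
    ll_rows = y[:, None] * eta - np.logaddexp(0.0, eta)
    ll_subj = np.zeros((n_subj, len(z)))
    for k in range(len(z)):
        ll_subj[:, k] = np.bincount(subj_idx, weights=ll_rows[:, k], minlength=n_subj)
    # integrand: exp(g(b)) * phi(b; 0, sd) ; quadrature in u = (b - bhat)/s
    log_prior = -0.5 * (B / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
    log_terms = ll_subj + log_prior + np.log(s)[:, None] + wlog[None, :] + 0.5 * z[None, :] ** 2
    return float(np.sum(logsumexp(log_terms, axis=1)))


def fit_mixed_logit(trials: pd.DataFrame, spec: ModelSpec | None = None) -> MixedLogitFit:
    """Fit the random-intercept logit (or its pooled reduction).

    Raises :class:`FitError` on non-convergence or complete separation
    rather than returning a silent result.
    """
    if spec is None:
        spec = ModelSpec()
    X, y, subj_idx, n_subj, cells, slope_names, names = _build_design(trials, spec)
    if n_subj < 2:
        raise FitError("mixed logit needs >= 2 subjects")
    if y.min() == y.max():
        raise FitError("all responses identical: model is not estimable")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pooled = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta_start = np.asarray(pooled.params, dtype=float)
            pooled_ok = np.all(np.isfinite(beta_start)) and np.all(
                np.abs(beta_start) < 15
            )
        except Exception:
            pooled_ok = False
    if not pooled_ok:
        raise FitError(
            "pooled logit failed (possible complete separation); "
            "check for cells with constant responses"
        )

    if not spec.random_intercept:
        vcov = np.asarray(pooled.cov_params(), dtype=float)
        return MixedLogitFit(
            fixed_effects=pd.Series(beta_start, index=names),
            re_sd=0.0,
            loglik=float(pooled.llf),
            vcov=vcov,
            n_obs=len(y),
            n_subjects=n_subj,
            cells=cells,
            slope_names=slope_names,
            spec=spec,
            param_names=names,
        )

    z, w = hermegauss(spec.quad_nodes)
    wlog = np.log(w)

    def negll(theta):
        return -_agq_loglik(
            theta[:-1], theta[-1], X, y, subj_idx, n_subj, z, wlog
        )

    theta0 = np.append(beta_start, np.log(0.5))
    res = minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * len(beta_start) + [(-6.0, 3.0)],
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise FitError(f"mixed logit did not converge: {res.message}")
    theta = res.x
    H = numdiff.approx_hess1(theta, negll)
    H = 0.5 * (H + H.T)
    # observed information; guard against a flat log-sd direction at the
    # sigma ~ 0 boundary
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    eigv = np.linalg.eigvalsh(vcov)
    if eigv.min() < 0:
        vcov = vcov - (eigv.min() - 1e-10) * np.eye(len(theta))
    param_names = names + ["log_re_sd"]
    return MixedLogitFit(
        fixed_effects=pd.Series(theta[:-1], index=names),
        re_sd=float(np.exp(theta[-1])),
        loglik=-float(res.fun),
        vcov=vcov,
        n_obs=len(y),
        n_subjects=n_subj,
        cells=cells,
        slope_names=slope_names,
        spec=spec,
        converged=True,
        param_names=param_names,
    )


# ---------------------------------------------------------------------------
# Marginal probabilities and contrasts


@dataclass(frozen=True)
class MarginalEstimate:
    M: float
    ci_low: float
    ci_high: float
    cell: tuple[str, str, str]


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    ci_low: float
    ci_high: float
    t_or_z: float
    p_adjusted: float
    cells: tuple


def _marginal_from_theta(theta, fit: MixedLogitFit, cell_k: int, values=None, nodes=31):
    """Cell marginal probability for one parameter vector: inverse logit
    averaged over the random-intercept distribution and the value grid."""
    p_cells = len(fit.cells)
    beta = theta[: p_cells + len(fit.slope_names)]
    phase, _, frame = fit.cells[cell_k]
    if values is None:
        values = np.asarray(phase_schedule(phase).gamble_values, dtype=float)
    vc = (np.asarray(values, dtype=float) - VALUE_CENTER) / VALUE_SCALE
    if fit.spec.value_slope_by_frame:
        slope = beta[p_cells + fit.slope_names.index(f"value_{frame}")]
    else:
        slope = beta[p_cells]
    eta = beta[cell_k] + slope * vc  # (V,)
    if fit.spec.random_intercept:
        sd = np.exp(theta[-1])
        z, w = hermegauss(nodes)
        w = w / np.sqrt(2 * np.pi)
        probs = expit(eta[:, None] + sd * z[None, :]) @ w
    else:
        probs = expit(eta)
    return float(np.mean(probs))


def _theta_hat(fit: MixedLogitFit) -> np.ndarray:
    theta = fit.fixed_effects.to_numpy()
    if fit.spec.random_intercept:
        theta = np.append(theta, np.log(max(fit.re_sd, 1e-8)))
    return theta


def _theta_draws(fit: MixedLogitFit, n_draws: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(_theta_hat(fit), fit.vcov, size=n_draws)


def marginal_gamble_prob(
    fit: MixedLogitFit,
    cell: tuple[str, str, str] | dict,
    n_draws: int = 2000,
    seed: int = 0,
) -> MarginalEstimate:
    """Model-implied marginal probability of gambling in one design cell,
    with a parametric-simulation 95% CI."""
    if isinstance(cell, dict):
        cell = (cell["phase"], cell["norm_type"], cell["frame"])
    k = fit.cell_index(*cell)
    M = _marginal_from_theta(_theta_hat(fit), fit, k)
    draws = _theta_draws(fit, n_draws, seed)
    ms = np.array([_marginal_from_theta(t, fit, k, nodes=15) for t in draws])
    lo, hi = np.percentile(ms, [2.5, 97.5])
    return MarginalEstimate(
        M=M, ci_low=float(min(lo, M)), ci_high=float(max(hi, M)), cell=cell
    )


def contrast(
    fit: MixedLogitFit,
    cellA: tuple[str, str, str],
    cellB: tuple[str, str, str],
    family: list[tuple[tuple, tuple]] | None = None,
    n_draws: int = 4000,
    seed: int = 0,
) -> ContrastResult:
    """Probability-scale contrast M(A) - M(B) with a single-step max-|z|
    adjustment over ``family`` (defaults to the single contrast).

    The adjustment samples the fitted coefficients' joint normal with the
    fit's covariance and refers each contrast's z to the Monte-Carlo
    distribution of the maximum absolute standardized contrast.
    """
    if family is None:
        family = [(cellA, cellB)]
    if (cellA, cellB) not in family:
        family = [(cellA, cellB)] + list(family)
    ks = [(fit.cell_index(*a), fit.cell_index(*b)) for a, b in family]
    theta = _theta_hat(fit)
    est = np.array(
        [
            _marginal_from_theta(theta, fit, ka) - _marginal_from_theta(theta, fit, kb)
            for ka, kb in ks
        ]
    )
    draws = _theta_draws(fit, n_draws, seed)
    D = np.empty((n_draws, len(ks)))
    for j, (ka, kb) in enumerate(ks):
        D[:, j] = [
            _marginal_from_theta(t, fit, ka, nodes=15)
            - _marginal_from_theta(t, fit, kb, nodes=15)
            for t in draws
        ]
    sd = D.std(axis=0, ddof=1)
    which = family.index((cellA, cellB))
    if np.any((sd <= 0) & (np.abs(est) > 0)):
        raise FitError("degenerate contrast distribution (singular covariance?)")
    if sd[which] <= 0:  # identical cells: null contrast by construction
        lo, hi = 0.0, 0.0
        return ContrastResult(0.0, lo, hi, 0.0, 1.0, (cellA, cellB))
    live = sd > 0
    z_obs = est[which] / sd[which]
    Z = np.abs((D[:, live] - D[:, live].mean(axis=0)) / sd[live])
    maxZ = Z.max(axis=1)
    p_adj = float(np.mean(maxZ >= abs(z_obs)))
    p_adj = max(p_adj, 1.0 / n_draws)
    lo, hi = np.percentile(D[:, which], [2.5, 97.5])
    c = float(est[which])
    return ContrastResult(
        estimate=c,
        ci_low=float(min(lo, c)),
        ci_high=float(max(hi, c)),
        t_or_z=float(z_obs),
        p_adjusted=min(1.0, p_adj),
        cells=(cellA, cellB),
    )


def cell_value_curve(
    fit: MixedLogitFit, cell: tuple[str, str, str], values=None
) -> pd.Series:
    """Marginal P(gamble) per gamble value for one cell (point estimates)."""
    k = fit.cell_index(*cell)
    phase = cell[0]
    if values is None:
        values = np.asarray(phase_schedule(phase).gamble_values, dtype=float)
    theta = _theta_hat(fit)
    probs = [
        _marginal_from_theta(theta, fit, k, values=np.array([v])) for v in values
    ]
    return pd.Series(probs, index=np.asarray(values, dtype=int), name="p_gamble")


def expected_choice_prob(params: AgentParams, frame: str, values, domain: str = "moral"):
    """Generative baseline P(gamble) per value (no norm), as an array."""
    return np.array(
        [
            choice_prob(GambleScenario(int(v), frame, domain), params)
            for v in values
        ]
    )
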