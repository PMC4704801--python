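"""Two-cycle ECME estimation of the dynamic factor model.

Each iteration has two cycles.

Cycle 1 is the closed-form EM update of classical (cross-sectional)
factor analysis applied to the pooled second-moment matrix C_yy of all
subject-visit observation vectors: with current loadings f and
idiosyncratic variances d,

    gamma = (f f' + diag d)^{-1} f,          omega = 1 - gamma' f,
    B_half = C_yy gamma (gamma' C_yy gamma + N omega)^{-1},
    D_new  = diag(C_yy - C_yy gamma B_half') / N,

where N is the pooled count of observation vectors.  This yields the
updated idiosyncratic variances and an intermediate loading estimate.

Cycle 2 maximizes the exact dynamic (Kalman prediction-error) panel
log-likelihood over the p shared loadings with the variances held fixed
— a conditional maximization of the actual likelihood, which is what
makes the scheme an ECME rather than a plain ECM.

Because the cycle-1 update targets the pooled covariance rather than
the dynamic likelihood, a raw D step can occasionally reduce the panel
log-likelihood.  Two safeguards keep the iteration an ascent algorithm
with a stationary limit: the D step is damped toward the previous value
until it does not decrease the likelihood, and when even a damped step
fails to ascend, the variances are updated by a numerical conditional
maximization of the dynamic likelihood itself (the "either" step of
ECME).  The reported log-likelihood trace is therefore non-decreasing.

The non-dynamic comparator (CFM) iterates only the cycle-1 updates to
convergence of the implied-covariance likelihood — classical factor
analysis with an i.i.d. N(0,1) factor — and scores visits by the
cross-sectional regression rule u_hat = gamma' y.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kalman import (
    FactorModelParams,
    FilterError,
    init_variance,
    panel_loglik,
    smoothed_factor_paths,
    LOG_2PI,
)

#: Heywood protection: idiosyncratic variances never fall below this.
VARIANCE_FLOOR = 1.0e-6


class EstimationError(RuntimeError):
    pass


@dataclass
class EcmeState:
    """Current parameter point plus the cycle-1 sufficient statistics."""

    f: np.ndarray
    d: np.ndarray
    C_yy: np.ndarray
    n_obs: int

    @property
    def gamma(self) -> np.ndarray:
        """Regression weights (f f' + D)^{-1} f, via the rank-one identity."""
        w = self.f / self.d
        return w / (1.0 + self.f @ w)

    @property
    def omega(self) -> float:
        """Residual factor variance 1 - gamma' f (scalar for q = 1)."""
        return 1.0 - float(self.gamma @ self.f)


@dataclass
class EcmeFit:
    """Result of a DFM or CFM fit."""

    model: str
    params: FactorModelParams
    variable_names: list
    scores: pd.DataFrame
    loglik_trace: list
    n_iter: int
    converged: bool
    settings: dict = field(default_factory=dict)


def pooled_second_moment(panel) -> tuple[np.ndarray, int]:
    """Pooled second-moment matrix of all observation vectors.

    C_yy is the sum over all subject-visits of the outer product of the
    observation vector.  Missing cells are handled by pairwise-complete
    accumulation with each entry rescaled to the common pooled count
    N_obs (the number of visit rows); the result is symmetrized.
    """
    Y = np.concatenate([np.asarray(v, dtype=float) for v in panel.values], axis=0)
    n_obs = Y.shape[0]
    M = (~np.isnan(Y)).astype(float)
    counts = M.T @ M
    if np.any(counts == 0):
        j, k = np.unravel_index(int(np.argmin(counts)), counts.shape)
        vj, vk = panel.variable_names[j], panel.variable_names[k]
        if j == k:
            raise EstimationError(f"variable {vj!r} has no observed values")
        raise EstimationError(f"variables {vj!r} and {vk!r} are never jointly observed")
    Y0 = np.nan_to_num(Y, nan=0.0)
    S = Y0.T @ Y0
    C = S * (n_obs / counts)
    C = 0.5 * (C + C.T)
    return C, n_obs


def cycle1_update(state: EcmeState) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form factor-analysis EM step on the pooled moments.

    Returns the intermediate loadings ``B_half`` and updated variances
    ``D_new`` (floored for Heywood protection).
    """
    g = state.gamma
    om = state.omega
    Cg = state.C_yy @ g
    denom = float(g @ Cg) + state.n_obs * om
    if abs(denom) < 1e-300 or not np.isfinite(denom):
        raise EstimationError("singular cycle-1 normal equations")
    B_half = Cg / denom
    D_new = (np.diag(state.C_yy) - Cg * B_half) / state.n_obs
    D_new = np.maximum(D_new, VARIANCE_FLOOR)
    return B_half, D_new


def _neg_loglik_f(f, d, panel, iv):
    try:
        return -panel_loglik(FactorModelParams(f, d), panel, init=iv)
    except (FilterError, ValueError):
        return np.inf


def cycle2_update(
    panel,
    d_fixed: np.ndarray,
    f_start: np.ndarray,
    init: str | float = "simulation",
    maxiter: int = 40,
) -> tuple[np.ndarray, float]:
    """Maximize the dynamic panel log-likelihood over the shared
    loadings with the variances held fixed.

    Quasi-Newton (L-BFGS-B, numeric gradient) started at ``f_start``;
    the returned point never has lower likelihood than the start.
    Returns ``(f_new, loglik_at_f_new)``.
    """
    iv = init_variance(init) if isinstance(init, str) else float(init)
    d_fixed = np.asarray(d_fixed, dtype=float)
    ll_start = -_neg_loglik_f(np.asarray(f_start, dtype=float), d_fixed, panel, iv)
    if not np.isfinite(ll_start):
        raise EstimationError("cycle-2 starting point has non-finite likelihood")
    res = optimize.minimize(
        _neg_loglik_f,
        np.asarray(f_start, dtype=float),
        args=(d_fixed, panel, iv),
        method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    if np.isfinite(res.fun) and -res.fun >= ll_start:
        return np.asarray(res.x, dtype=float), float(-res.fun)
    return np.asarray(f_start, dtype=float), float(ll_start)


def _ascend_d(f, d_cur, d_prop, panel, iv, ll_cur, maxiter=30):
    """Variance step with guaranteed ascent of the dynamic likelihood.

    Tries the cycle-1 proposal damped toward the current value; if no
    damping level ascends, falls back to a numerical conditional
    maximization over log-variances (proper ECME "either" step).
    """
    for alpha in (1.0, 0.5, 0.25, 0.125):
        d_try = np.maximum((1 - alpha) * d_cur + alpha * d_prop, VARIANCE_FLOOR)
        ll = -_neg_loglik_f(f, d_try, panel, iv)
        if ll >= ll_cur - 1e-10:
            return d_try, ll
    # numerical CM step on log d
    def neg(z):
        return _neg_loglik_f(f, np.exp(z), panel, iv)

    res = optimize.minimize(
        neg, np.log(d_cur), method="L-BFGS-B", options={"maxiter": maxiter}
    )
    if np.isfinite(res.fun) and -res.fun >= ll_cur - 1e-10:
        return np.maximum(np.exp(res.x), VARIANCE_FLOOR), float(-res.fun)
    return d_cur, ll_cur


def _principal_axis_start(C: np.ndarray, n_obs: int) -> tuple[np.ndarray, np.ndarray]:
    """First-factor principal-axis solution of the pooled covariance."""
    R = C / n_obs
    vals, vecs = np.linalg.eigh(R)
    lam, v = vals[-1], vecs[:, -1]
    f0 = v * np.sqrt(max(lam, VARIANCE_FLOOR))
    if f0.sum() < 0:
        f0 = -f0
    d0 = np.maximum(np.diag(R) - f0 **2, 0.05 * np.diag(R))
    d0 = np.maximum(d0, VARIANCE_FLOOR)
    return f0, d0


def _cfm_implied_loglik(f, d, C, n_obs):
    """Gaussian log-likelihood of N(0, f f' + D) given pooled moments."""
    p = f.size
    h = float(np.sum(f * f / d))
    logdet = float(np.sum(np.log(d))) + np.log1p(h)
    # tr(Sigma^{-1} C)/n via Woodbury
    w = f / d
    tr = float(np.sum(np.diag(C) / d)) - float(w @ C @ w) / (1.0 + h)
    return -0.5 * (n_obs * p * LOG_2PI + n_obs * logdet + tr)


def _cfm_em(C, n_obs, f0, d0, tol, max_iter):
    f, d = f0.copy(), d0.copy()
    trace = [_cfm_implied_loglik(f, d, C, n_obs)]
    converged = False
    for _ in range(max_iter):
        B_half, d_new = cycle1_update(EcmeState(f, d, C, n_obs))
        f, d = B_half, d_new
        trace.append(_cfm_implied_loglik(f, d, C, n_obs))
        if abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    return f, d, trace, converged


def _regression_scores(f, d, panel) -> pd.DataFrame:
    """Cross-sectional regression factor scores gamma' y, visit by visit,
    restricted to the observed components."""
    rows = []
    for i, sid in enumerate(panel.subject_ids):
        v = np.asarray(panel.values[i], dtype=float)
        for j, t in enumerate(panel.times[i]):
            obs = np.flatnonzero(~np.isnan(v[j]))
            fo, do = f[obs], d[obs]
            h = float(np.sum(fo * fo / do))
            g = (fo / do) / (1.0 + h)
            rows.append(
                {
                    "subject": sid,
                    "time": float(t),
                    "score": float(g @ v[j, obs]),
                    "score_var": 1.0 / (1.0 + h),
                }
            )
    return pd.DataFrame(rows)


def _smoothed_scores(params, panel, init) -> pd.DataFrame:
    means, variances = smoothed_factor_paths(params, panel, init=init)
    rows = []
    for i, sid in enumerate(panel.subject_ids):
        for j, t in enumerate(panel.times[i]):
            rows.append(
                {
                    "subject": sid,
                    "time": float(t),
                    "score": float(means[i][j]),
                    "score_var": float(variances[i][j]),
                }
            )
    return pd.DataFrame(rows)


def fit_dfm(
    panel,
    init_params: FactorModelParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    init: str | float = "simulation",
    inner_maxiter: int = 40,
    seed: int | None = None,
) -> EcmeFit:
    """Fit the dynamic factor model by the two-cycle ECME iteration.

    Parameters
    ----------
    panel : PanelData
        Measures should be centered (e.g. standardized) per variable.
    init_params : FactorModelParams, optional
        Starting point; default is a cycle-1-only (CFM) fit from a
        principal-axis start.
    init : str or float
        Initial-state prior for the filter during estimation.  The
        default is the proper unit-scale prior ("simulation", variance
        2): a diffuse proxy (huge proper variance kappa) is *not* usable
        when the loadings are free, because the term f f' kappa acts as
        an unconstrained rank-one level component — the optimizer then
        drives f toward zero while kappa f^2 absorbs the entire
        between-subject variance and the dynamics degenerate.  A float
        sets the prior variance explicitly.
    inner_maxiter : int
        Iteration cap of the numerical conditional maximizations inside
        one outer iteration; ascent is guaranteed regardless.
    """
    if panel.n_subjects < 2:
        raise EstimationError("need at least 2 subjects")
    C, n_obs = pooled_second_moment(panel)
    if n_obs < panel.p:
        raise EstimationError("need at least p pooled visits")
    iv = init_variance(init)
    if init_params is not None:
        f = np.asarray(init_params.f, dtype=float).copy()
        d = np.asarray(init_params.d, dtype=float).copy()
    else:
        f0, d0 = _principal_axis_start(C, n_obs)
        f, d, _, _ = _cfm_em(C, n_obs, f0, d0, tol=1e-8, max_iter=500)
    ll = panel_loglik(FactorModelParams(f, d), panel, init=iv)
    trace = [ll]
    converged = False
    n_iter = 0
    for k in range(max_iter):
        n_iter = k + 1
        B_half, d_prop = cycle1_update(EcmeState(f, d, C, n_obs))
        d, ll_d = _ascend_d(f, d, d_prop, panel, iv, ll, maxiter=inner_maxiter)
        # choose the better start for the loading search
        ll_bhalf = -_neg_loglik_f(B_half, d, panel, iv)
        start = B_half if ll_bhalf > ll_d else f
        f, ll_new = cycle2_update(panel, d, start, init=iv, maxiter=inner_maxiter)
        if ll_new < ll_d - 1e-8:  # cycle2 never returns a worse point than its start
            f, ll_new = f, ll_d
        trace.append(ll_new)
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        warnings.warn(
            f"DFM fit did not converge in {max_iter} iterations "
            f"(last change {trace[-1] - trace[-2]:.3g})",
            RuntimeWarning,
        )
    # scores are computed at the sign-canonical parameters; smoothing at
    # flipped loadings flips the factor path with them, so no extra flip
    params = FactorModelParams(f, d).canonical_sign()
    scores = _smoothed_scores(params, panel, init=iv)
    settings = {
        "tol": tol,
        "max_iter": max_iter,
        "init": init if isinstance(init, str) else float(init),
        "inner_maxiter": inner_maxiter,
        "seed": seed,
    }
    return EcmeFit(
        model="dfm",
        params=params,
        variable_names=list(panel.variable_names),
        scores=scores,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        settings=settings,
    )


def fit_cfm(
    panel,
    init_params: FactorModelParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int | None = None,
) -> EcmeFit:
    """Fit the non-dynamic factor model (observation equation only).

    The factor is treated as i.i.d. N(0,1) across visits; estimation
    iterates the closed-form cycle-1 updates to convergence of the
    implied-covariance likelihood, and visits are scored by the
    cross-sectional regression rule.
    """
    if panel.n_subjects < 2:
        raise EstimationError("need at least 2 subjects")
    C, n_obs = pooled_second_moment(panel)
    if n_obs < panel.p:
        raise EstimationError("need at least p pooled visits")
    if init_params is not None:
        f0 = np.asarray(init_params.f, dtype=float).copy()
        d0 = np.asarray(init_params.d, dtype=float).copy()
    else:
        f0, d0 = _principal_axis_start(C, n_obs)
    f, d, trace, converged = _cfm_em(C, n_obs, f0, d0, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn(f"CFM fit did not converge in {max_iter} iterations", RuntimeWarning)
    params = FactorModelParams(f, d).canonical_sign()
    scores = _regression_scores(params.f, params.d, panel)
    settings = {"tol": tol, "max_iter": max_iter, "seed": seed}
    return EcmeFit(
        model="cfm",
        params=params,
        variable_names=list(panel.variable_names),
        scores=scores,
        loglik_trace=trace,
        n_iter=max(len(trace) - 1, 0),
        converged=converged,
        settings=settings,
    )


def extract_scores(fit: EcmeFit, panel=None) -> pd.DataFrame:
    """Factor-score table in long format, one row per observed
    subject-visit (smoothed means for the DFM, regression scores for the
    CFM), with the panel's group/pair/covariate columns merged in when a
    panel is given."""
    scores = fit.scores.copy()
    if panel is not None:
        meta = pd.DataFrame({"subject": panel.subject_ids})
        if panel.group is not None:
            meta["group"] = panel.group
        if panel.pair_ids is not None:
            meta["pair"] = panel.pair_ids
        if panel.covariates is not None:
            for c in panel.covariates.columns:
                meta[c] = panel.covariates[c].to_numpy()
        scores = scores.merge(meta, on="subject", how="left")
    return scores
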