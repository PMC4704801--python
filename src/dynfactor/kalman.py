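"""Per-subject state space for the random-walk factor model.

Each subject i carries a scalar latent factor u that follows a random
walk observed through p measures:

    y_ij = f * u_ij + e_ij,            e_ij ~ N(0, diag(d))
    u_i,j+1 = u_ij + eta_ij,           eta_ij ~ N(0, tau_ij)

where tau_ij is the raw time gap (years) between visits j and j+1, and
the loading vector f and idiosyncratic variances d are shared across
subjects.  Because subjects are independent and share parameters, the
stacked n*p-dimensional filter factorizes exactly into n scalar-state
filters; that factorization is what makes the model tractable for large
n, and it is used everywhere below.

The filter uses the rank-one (Woodbury) form of the measurement update,
so one visit costs O(p): with h = f' D^{-1} f and prior variance P,

    F = P f f' + D,     |F| = (prod d) (1 + P h),
    F^{-1} f = (f / d) / (1 + P h),
    posterior variance = P / (1 + P h).

The exact Gaussian log-likelihood accumulates via the prediction-error
decomposition: sum over visits of N(v_t; 0, F_t) restricted to the
observed components.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))

#: proper-prior variance standing in for a diffuse initial condition
DIFFUSE_VAR = 1.0e7


class FilterError(RuntimeError):
    """Numerical failure inside the Kalman recursion."""


@dataclass
class FactorModelParams:
    """Shared loading vector and idiosyncratic variances (q = 1)."""

    f: np.ndarray
    d: np.ndarray
    q: int = 1

    def __post_init__(self):
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if self.q != 1:
            raise ValueError("only q=1 (one factor per subject) is supported")
        if self.f.shape != self.d.shape or self.f.ndim != 1:
            raise ValueError("f and d must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("loadings must be finite")
        if np.any(self.d <= 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("idiosyncratic variances must be positive and finite")

    @property
    def p(self) -> int:
        return self.f.size

    def canonical_sign(self) -> "FactorModelParams":
        """Resolve the sign indeterminacy: the loadings sum positive.

        Factor paths must be flipped jointly with f by the caller."""
        if self.f.sum() < 0:
            return FactorModelParams(-self.f, self.d.copy(), self.q)
        return self


def init_variance(init: str | float, presample_gap: float = 1.0) -> float:
    """Prior variance of the state at the first visit.

    ``"diffuse"``
        large proper variance (default for real data, where nothing is
        known about the factor level at entry).
    ``"simulation"``
        matches the synthetic generator, in which the factor starts at
        N(0, 1) one ``presample_gap`` before the first visit, so the
        first-visit state has variance ``1 + presample_gap``.
    A float is passed through unchanged.
    """
    if isinstance(init, str):
        if init == "diffuse":
            return DIFFUSE_VAR
        if init == "simulation":
            return 1.0 + float(presample_gap)
        raise ValueError(f"unknown init policy {init!r}")
    v = float(init)
    if v <= 0:
        raise ValueError("initial variance must be positive")
    return v


@dataclass
class SubjectSystem:
    """State-space matrices for one subject: identity transition, gap-
    proportional state innovation variances, shared observation model."""

    f: np.ndarray
    d: np.ndarray
    gaps: np.ndarray          # tau_j, one per step between consecutive visits
    init_mean: float = 0.0
    init_var: float = DIFFUSE_VAR

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.gaps = np.atleast_1d(np.asarray(self.gaps, dtype=float)) if np.size(self.gaps) else np.empty(0)
        if np.any(self.gaps <= 0):
            raise ValueError(f"visit gaps must be positive, got {self.gaps.tolist()}")
        if self.init_var <= 0:
            raise ValueError("initial variance must be positive")

    @property
    def n_visits(self) -> int:
        return self.gaps.size + 1


def assemble_system(
    params: FactorModelParams,
    times,
    init: str | float = "diffuse",
    presample_gap: float = 1.0,
) -> SubjectSystem:
    """Build the per-subject system from visit times.

    The state innovation variance between consecutive visits equals the
    raw gap tau (random-walk variance accrues linearly in elapsed time).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    gaps = np.diff(times)
    if np.any(gaps <= 0):
        raise ValueError(f"visit times must be strictly increasing, got {times.tolist()}")
    return SubjectSystem(
        f=params.f,
        d=params.d,
        gaps=gaps,
        init_mean=0.0,
        init_var=init_variance(init, presample_gap),
    )


@dataclass
class KalmanRun:
    """Filter (and optionally smoother) output for one subject."""

    innovations: list = field(default_factory=list)       # per visit, observed comps
    innovation_vars: list = field(default_factory=list)   # per visit, full F_t matrix
    observed: list = field(default_factory=list)          # per visit, indices observed
    pred_mean: np.ndarray | None = None
    pred_var: np.ndarray | None = None
    filtered_mean: np.ndarray | None = None
    filtered_var: np.ndarray | None = None
    smoothed_mean: np.ndarray | None = None
    smoothed_var: np.ndarray | None = None
    loglik: float = 0.0

    def standardized_innovations(self) -> list:
        """Per-visit innovations scaled by the square root of the
        diagonal of F_t (one value per observed measure)."""
        out = []
        for v, F in zip(self.innovations, self.innovation_vars):
            out.append(v / np.sqrt(np.diag(F)) if v.size else v)
        return out


def kalman_filter(y: np.ndarray, system: SubjectSystem, store: bool = True) -> KalmanRun:
    """Exact filter for one subject.

    ``y`` is (T, p) with ``nan`` marking missing cells; each measurement
    update is restricted to the observed components, and a fully missing
    visit contributes a time update only.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    T, p = y.shape
    if T != system.n_visits:
        raise ValueError(f"y has {T} visits but the system has {system.n_visits}")
    f, d = system.f, system.d
    a, P = float(system.init_mean), float(system.init_var)
    run = KalmanRun()
    pm = np.empty(T)
    pv = np.empty(T)
    fm = np.empty(T)
    fv = np.empty(T)
    ll = 0.0
    for t in range(T):
        if t > 0:
            P += system.gaps[t - 1]
        pm[t], pv[t] = a, P
        obs = np.flatnonzero(~np.isnan(y[t]))
        if obs.size:
            fo, do, yo = f[obs], d[obs], y[t, obs]
            h = float(np.sum(fo * fo / do))
            denom = 1.0 + P * h
            if denom <= 0 or not np.isfinite(denom):
                raise FilterError(f"innovation variance not positive definite at visit {t}")
            v = yo - fo * a
            # Woodbury: v' F^{-1} v and log|F| without forming F
            b = float(np.sum(v * fo / do))
            quad = float(np.sum(v * v / do)) - P * b * b / denom
            logdet = float(np.sum(np.log(do))) + np.log(denom)
            ll += -0.5 * (obs.size * LOG_2PI + logdet + quad)
            a = a + (P / denom) * b
            P = P / denom
            if store:
                run.innovations.append(v)
                run.innovation_vars.append(pv[t] * np.outer(fo, fo) + np.diag(do))
                run.observed.append(obs)
        elif store:
            run.innovations.append(np.empty(0))
            run.innovation_vars.append(np.empty((0, 0)))
            run.observed.append(obs)
        fm[t], fv[t] = a, P
    if not np.isfinite(ll):
        raise FilterError("non-finite log-likelihood")
    run.pred_mean, run.pred_var = pm, pv
    run.filtered_mean, run.filtered_var = fm, fv
    run.loglik = ll
    return run


def kalman_smoother(run: KalmanRun, system: SubjectSystem) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-interval (RTS) smoother for the scalar random-walk state.

    Returns smoothed means and variances; also stored on ``run``.
    """
    if run.filtered_mean is None:
        raise ValueError("run the filter before smoothing")
    T = run.filtered_mean.size
    sm = np.array(run.filtered_mean, dtype=float)
    sv = np.array(run.filtered_var, dtype=float)
    for t in range(T - 2, -1, -1):
        C = run.filtered_var[t] / run.pred_var[t + 1]
        sm[t] = run.filtered_mean[t] + C * (sm[t + 1] - run.pred_mean[t + 1])
        sv[t] = run.filtered_var[t] + C * C * (sv[t + 1] - run.pred_var[t + 1])
    run.smoothed_mean, run.smoothed_var = sm, sv
    return sm, sv


# ---------------------------------------------------------------------------
# vectorized panel paths (complete data, shared visit times)
# ---------------------------------------------------------------------------

def _dense_filter(f, d, Y, gaps, init_var, return_states=False):
    """Filter all subjects at once when data are complete and visit times
    are shared.  Subjects share P_t and the Kalman gain; only the means
    differ, so the cost per visit is two matrix-vector products."""
    n, T, p = Y.shape
    w = f / d
    h = float(f @ w)
    sum_log_d = float(np.sum(np.log(d)))
    a = np.zeros(n)
    P = float(init_var)
    ll = 0.0
    if return_states:
        A_f = np.empty((T, n))
        P_f = np.empty(T)
        A_p = np.empty((T, n))
        P_p = np.empty(T)
    inv_d = 1.0 / d
    for t in range(T):
        if t > 0:
            P += gaps[t - 1]
        V = Y[:, t, :] - np.outer(a, f)
        denom = 1.0 + P * h
        b = V @ w
        quad = float(np.einsum("ij,ij->", V * inv_d, V)) - P * float(b @ b) / denom
        ll += -0.5 * (n * p * LOG_2PI + n * (sum_log_d + np.log(denom)) + quad)
        if return_states:
            A_p[t], P_p[t] = a, P
        a = a + (P / denom) * b
        P = P / denom
        if return_states:
            A_f[t], P_f[t] = a, P
    if not np.isfinite(ll):
        raise FilterError("non-finite log-likelihood in dense filter")
    if return_states:
        return ll, A_f, P_f, A_p, P_p
    return ll


def _dense_smoother(A_f, P_f, A_p, P_p):
    T, n = A_f.shape
    sm = A_f.copy()
    sv = P_f.copy()
    for t in range(T - 2, -1, -1):
        C = P_f[t] / P_p[t + 1]
        sm[t] = A_f[t] + C * (sm[t + 1] - A_p[t + 1])
        sv[t] = P_f[t] + C * C * (sv[t + 1] - P_p[t + 1])
    return sm, sv


def panel_loglik(
    params: FactorModelParams,
    panel,
    init: str | float = "diffuse",
    presample_gap: float = 1.0,
) -> float:
    """Exact Gaussian log-likelihood of the whole panel.

    Subjects are independent, so the panel log-likelihood is the sum of
    per-subject filter log-likelihoods.  A vectorized path is used when
    the panel is regular (shared visit times, no missing cells).
    """
    dense = panel.dense()
    iv = init_variance(init, presample_gap)
    if dense is not None:
        Y, times = dense
        return _dense_filter(params.f, params.d, Y, np.diff(times), iv)
    total = 0.0
    for i, sid in enumerate(panel.subject_ids):
        try:
            system = assemble_system(params, panel.times[i], init=iv)
            total += kalman_filter(panel.values[i], system, store=False).loglik
        except FilterError as e:
            raise FilterError(f"subject {sid!r}: {e}") from e
    return total


def smoothed_factor_paths(
    params: FactorModelParams,
    panel,
    init: str | float = "diffuse",
    presample_gap: float = 1.0,
):
    """Smoothed factor means and variances for every subject-visit.

    Returns ``(means, variances)`` as lists of per-subject arrays aligned
    with ``panel.times``.
    """
    dense = panel.dense()
    iv = init_variance(init, presample_gap)
    if dense is not None:
        Y, times = dense
        _, A_f, P_f, A_p, P_p = _dense_filter(
            params.f, params.d, Y, np.diff(times), iv, return_states=True
        )
        sm, sv = _dense_smoother(A_f, P_f, A_p, P_p)
        return [sm[:, i] for i in range(Y.shape[0])], [sv.copy() for _ in range(Y.shape[0])]
    means, variances = [], []
    for i in range(panel.n_subjects):
        system = assemble_system(params, panel.times[i], init=iv)
        run = kalman_filter(panel.values[i], system, store=False)
        m, v = kalman_smoother(run, system)
        means.append(m)
        variances.append(v)
    return means, variances
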