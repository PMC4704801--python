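"""Evaluation metrics: the trace statistic and residual diagnostics.

The trace statistic is the multivariate R^2 of the regression of the
true latent paths on the estimated ones,

    tr(U' Uhat (Uhat' Uhat)^{-1} Uhat' U) / tr(U' U).

With one factor per subject the paths are stacked over all subjects and
visits into single vectors u and uhat, where the statistic reduces to
the squared uncentered correlation (u' uhat)^2 / ((u'u)(uhat'uhat)).
Stacking is the only arrangement that stays well defined when the
number of visits is smaller than the number of subjects.  The statistic
is invariant to rescaling or sign-flipping the estimate, so the usual
factor-identification ambiguities cannot move it.

Residual diagnostics operate on filter-standardized one-step prediction
errors: a skewness/kurtosis normality test (chi-square, 2 df — the
Bowman–Shenton statistic, identical to Jarque–Bera) and a lag-1
portmanteau (Box–Ljung) test computed within subjects and pooled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TraceStat:
    value: float
    estimator: str = ""
    n: int | None = None
    p: int | None = None
    T: int | None = None
    replicate: int | None = None


def trace_statistic(u_true, u_hat) -> float:
    """Squared uncentered correlation of the stacked latent paths.

    ``u_hat`` identically zero returns 0 by convention; zero-norm
    ``u_true`` is an error.
    """
    u = np.asarray(u_true, dtype=float).ravel()
    v = np.asarray(u_hat, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("true and estimated paths must align")
    uu = float(u @ u)
    if uu == 0.0:
        raise ValueError("true factor path has zero norm")
    vv = float(v @ v)
    if vv == 0.0:
        return 0.0
    uv = float(u @ v)
    return uv * uv / (uu * vv)


def trace_ratio(tr_dfm: float, tr_cfm: float) -> float:
    """Ratio of the two trace statistics; > 1 means the dynamic model
    recovers the latent paths better."""
    if tr_cfm <= 0:
        raise ZeroDivisionError("non-dynamic trace statistic must be positive")
    return float(tr_dfm) / float(tr_cfm)


def _pool(series) -> list:
    if isinstance(series, np.ndarray) and series.ndim == 1:
        return [np.asarray(series, dtype=float)]
    return [np.asarray(s, dtype=float) for s in series]


def residual_diagnostics(series) -> dict:
    """Normality and lag-1 autocorrelation tests on standardized
    one-step prediction errors.

    Parameters
    ----------
    series : 1-D array or list of 1-D arrays
        Standardized innovations; a list is treated as independent
        within-subject series (the portmanteau statistic never crosses
        subject boundaries).

    Returns
    -------
    dict with the Bowman–Shenton normality statistic (chi2, 2 df), the
    lag-1 Box–Ljung statistic (chi2, 1 df), their p-values and the
    pooled count.
    """
    chunks = _pool(series)
    x = np.concatenate(chunks)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 standardized innovations")
    # Bowman–Shenton: n/6 skew^2 + n/24 (kurt-3)^2
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    skew = np.mean((x - m) ** 3) / s2**1.5
    kurt = np.mean((x - m) ** 4) / s2**2
    bs = n * (skew**2 / 6.0 + (kurt - 3.0) ** 2 / 24.0)
    bs_p = float(stats.chi2.sf(bs, 2))

    num = 0.0
    den = 0.0
    for c in chunks:
        c = c[np.isfinite(c)]
        cc = c - m
        if cc.size >= 2:
            num += float(cc[:-1] @ cc[1:])
        den += float(cc @ cc)
    if den == 0:
        raise ValueError("degenerate innovations")
    r1 = num / den
    lb = n * (n + 2.0) * r1 * r1 / (n - 1.0)
    lb_p = float(stats.chi2.sf(lb, 1))
    return {
        "n": int(n),
        "normality_stat": float(bs),
        "normality_p": bs_p,
        "lag1_stat": float(lb),
        "lag1_p": lb_p,
        "lag1_autocorr": float(r1),
    }


def one_step_residuals(params, panel, init="diffuse") -> dict:
    """Filter-standardized one-step prediction errors per variable.

    Returns ``{variable: list of per-subject series}`` suitable for
    :func:`residual_diagnostics`.
    """
    from .kalman import assemble_system, kalman_filter, init_variance

    iv = init_variance(init)
    out = {name: [] for name in panel.variable_names}
    for i in range(panel.n_subjects):
        system = assemble_system(params, panel.times[i], init=iv)
        run = kalman_filter(panel.values[i], system, store=True)
        std = run.standardized_innovations()
        per_var = {name: [] for name in panel.variable_names}
        for v, obs in zip(std, run.observed):
            for val, k in zip(v, obs):
                per_var[panel.variable_names[k]].append(val)
        for name, vals in per_var.items():
            if vals:
                out[name].append(np.asarray(vals))
    return out
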