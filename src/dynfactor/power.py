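"""Matched-pair bootstrap power analysis for group slope contrasts.

The scheme, run on synthetic two-group panels: for each total sample
size n, repeatedly (B times) resample n/2 matched case-control pairs
with replacement, refit both factor models on the resample, regress
each outcome (every raw measure, the non-dynamic factor score, the
dynamic factor score) on time, group, their interaction and baseline
age with correlated random intercepts and slopes per subject, and
record whether the time-by-group interaction is significant at level
alpha.  Power is the rejection proportion; inverting the (isotonized)
power curve at a target gives the required sample size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.isotonic import IsotonicRegression

from .data import standardize
from .ecme import extract_scores, fit_cfm, fit_dfm


class PowerAnalysisError(RuntimeError):
    pass


@dataclass
class PowerConfig:
    """Settings of the bootstrap power study."""

    n_grid: tuple = (120, 240)
    n_boot: int = 1000
    alpha: float = 0.05
    outcomes: list | None = None        # default: raw measures + both factors
    seed: int | None = None
    fit_tol: float = 1e-5
    fit_max_iter: int = 100
    init: str = "simulation"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if any(n % 2 or n < 4 for n in self.n_grid):
            raise ValueError("sample sizes must be even (matched pairs) and >= 4")
        if self.n_boot < 1:
            raise ValueError("need at least one bootstrap replicate")


@dataclass
class SlopeContrast:
    estimate: float
    se: float
    pvalue: float
    converged: bool = True
    fallback_used: bool = False


def fit_slope_contrast(scores: pd.DataFrame, score_col: str = "score") -> SlopeContrast:
    """Mixed-effects slope contrast between groups.

    Fixed effects: intercept, time, group, time x group and baseline age
    (when present); random effects: correlated intercept and slope per
    subject.  The p-value uses the normal reference for the Wald
    statistic of the interaction.  On convergence failure a documented
    fallback with independent random intercept and slope is fitted.
    """
    df = scores.copy()
    if "group" not in df.columns or df["group"].nunique() < 2:
        raise PowerAnalysisError("both groups must be present")
    if df.groupby("subject")["time"].nunique().max() < 2:
        raise PowerAnalysisError("need repeated visits to estimate slopes")
    df["group"] = df["group"].astype(float)
    fixed = f"{score_col} ~ time * group"
    if "age" in df.columns:
        fixed += " + age"

    def _wald(fit):
        name = "time:group"
        est = float(fit.params[name])
        se = float(fit.bse[name])
        from scipy.stats import norm

        p = 2.0 * float(norm.sf(abs(est) / se)) if se > 0 and np.isfinite(se) else np.nan
        return est, se, p

    def _fit_best(model):
        # quasi-Newton REML can report convergence at a poor point when
        # variance ratios are extreme; a derivative-free polish from that
        # point is kept whenever it improves the restricted likelihood
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        try:
            polished = model.fit(
                reml=True, method="powell", start_params=fit.params_object, maxiter=500
            )
            if np.isfinite(polished.llf) and polished.llf > fit.llf + 1e-8:
                return polished
        except Exception:
            pass
        return fit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(fixed, df, groups=df["subject"], re_formula="~time")
            fit = _fit_best(model)
            est, se, p = _wald(fit)
            if np.isfinite(p):
                return SlopeContrast(est, se, p, converged=bool(fit.converged), fallback_used=False)
        except Exception:
            pass
        # fallback: independent random intercept and random slope
        try:
            model = smf.mixedlm(
                fixed,
                df,
                groups=df["subject"],
                re_formula="1",
                vc_formula={"time": "0 + time"},
            )
            fit = _fit_best(model)
            est, se, p = _wald(fit)
            if np.isfinite(p):
                return SlopeContrast(est, se, p, converged=bool(fit.converged), fallback_used=True)
        except Exception as e:
            raise PowerAnalysisError(f"mixed model failed: {e}") from e
    raise PowerAnalysisError("mixed model produced no usable interaction estimate")


@dataclass
class PowerResult:
    """Rejection proportions per outcome and sample size."""

    table: pd.DataFrame   # columns: outcome, n, power, se, n_boot, failures
    config: PowerConfig = field(default=None)

    def curve(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[self.table["outcome"] == outcome].sort_values("n")
        return sub["n"].to_numpy(), sub["power"].to_numpy()


def _resample_pairs(panel, pair_index, n_pairs, rng):
    """Draw n_pairs pairs with replacement; subjects relabeled uniquely."""
    chosen = rng.integers(0, len(pair_index), size=n_pairs)
    idx = [i for pid in chosen for i in pair_index[pid]]
    return panel.subset(idx, relabel=True)


def bootstrap_power(source, config: PowerConfig) -> PowerResult:
    """Bootstrap power for every outcome over the sample-size grid.

    ``source`` is a :class:`~dynfactor.simulate.SimulatedPanel` (or any
    object with a ``panel`` attribute) whose panel carries matched-pair
    ids.  Factor models are refit on every resample; fit failures count
    as non-rejections and are tallied.
    """
    panel = source.panel if hasattr(source, "panel") else source
    if panel.pair_ids is None:
        raise PowerAnalysisError("source panel has no matched-pair ids")
    pairs = {}
    for i, pid in enumerate(panel.pair_ids):
        pairs.setdefault(pid, []).append(i)
    pair_index = [v for v in pairs.values() if len(v) == 2]
    if len(pair_index) < 2:
        raise PowerAnalysisError("need at least two complete matched pairs")

    outcomes = config.outcomes or (list(panel.variable_names) + ["factor_cfm", "factor_dfm"])
    raw_outcomes = [o for o in outcomes if o in panel.variable_names]
    rows = []
    for ni, n in enumerate(config.n_grid):
        n_pairs = n // 2
        rejections = {o: 0 for o in outcomes}
        failures = {o: 0 for o in outcomes}
        for b in range(config.n_boot):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed or 0, ni, b))
            )
            resample = _resample_pairs(panel, pair_index, n_pairs, rng)
            try:
                std_panel, _ = standardize(resample)
            except Exception:
                for o in outcomes:
                    failures[o] += 1
                continue
            long = std_panel.to_frame()
            need_cfm = "factor_cfm" in outcomes
            need_dfm = "factor_dfm" in outcomes
            score_tables = {}
            try:
                if need_cfm:
                    cfm = fit_cfm(std_panel, tol=config.fit_tol, max_iter=config.fit_max_iter)
                    score_tables["factor_cfm"] = extract_scores(cfm, std_panel)
                if need_dfm:
                    dfm = fit_dfm(
                        std_panel,
                        tol=config.fit_tol,
                        max_iter=config.fit_max_iter,
                        init=config.init,
                    )
                    score_tables["factor_dfm"] = extract_scores(dfm, std_panel)
            except Exception:
                for o in ("factor_cfm", "factor_dfm"):
                    if o in outcomes:
                        failures[o] += 1
                score_tables = {k: v for k, v in score_tables.items()}
            for o in outcomes:
                try:
                    if o in raw_outcomes:
                        df = long.rename(columns={o: "score"})[
                            [c for c in ("subject", "time", "group", "age", "score") if c in long.columns or c == "score"]
                        ]
                        res = fit_slope_contrast(df)
                    elif o in score_tables:
                        res = fit_slope_contrast(score_tables[o])
                    else:
                        continue  # factor fit failed; already tallied
                    if res.pvalue < config.alpha:
                        rejections[o] += 1
                except PowerAnalysisError:
                    failures[o] += 1  # conservative: counts as non-rejection
        for o in outcomes:
            phat = rejections[o] / config.n_boot
            rows.append(
                {
                    "outcome": o,
                    "n": n,
                    "power": phat,
                    "se": float(np.sqrt(phat * (1 - phat) / config.n_boot)),
                    "n_boot": config.n_boot,
                    "failures": failures[o],
                }
            )
    return PowerResult(table=pd.DataFrame(rows), config=config)


@dataclass
class RequiredSampleSize:
    n_star: float
    extrapolated: bool
    note: str = ""


def required_sample_size(ns, powers, target: float = 0.8) -> RequiredSampleSize:
    """Invert a power curve at the target power.

    The curve is first made monotone by isotonic regression, then
    linearly interpolated.  Results outside the grid are flagged.
    """
    ns = np.asarray(ns, dtype=float)
    powers = np.asarray(powers, dtype=float)
    if ns.size == 0:
        raise ValueError("empty power curve")
    if ns.size == 1:
        return RequiredSampleSize(
            float(ns[0]), extrapolated=powers[0] < target, note="single grid point"
        )
    order = np.argsort(ns)
    ns, powers = ns[order], powers[order]
    iso = IsotonicRegression(increasing=True).fit(ns, powers)
    mono = iso.predict(ns)
    if mono[0] >= target:
        return RequiredSampleSize(
            float(ns[0]), extrapolated=True, note="target already met at smallest grid size"
        )
    if mono[-1] < target:
        # extrapolate from the last rising segment
        rise = np.flatnonzero(np.diff(mono) > 0)
        if rise.size == 0:
            return RequiredSampleSize(
                float("inf"), extrapolated=True, note="flat power curve below target"
            )
        i = rise[-1]
        slope = (mono[i + 1] - mono[i]) / (ns[i + 1] - ns[i])
        n_star = ns[i + 1] + (target - mono[i + 1]) / slope
        return RequiredSampleSize(float(n_star), extrapolated=True, note="beyond grid")
    i = int(np.argmax(mono >= target))
    if i == 0:
        return RequiredSampleSize(float(ns[0]), extrapolated=False)
    if mono[i] == mono[i - 1]:
        n_star = ns[i]
    else:
        n_star = ns[i - 1] + (target - mono[i - 1]) * (ns[i] - ns[i - 1]) / (
            mono[i] - mono[i - 1]
        )
    return RequiredSampleSize(float(n_star), extrapolated=False)
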