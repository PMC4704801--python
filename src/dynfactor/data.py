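"""Panel data container and long-format CSV input/output.

The canonical on-disk layout is long format: one row per subject-visit,
with columns ``subject,time[,group][,pair][,age],<var1>,...,<varp>``.
Visit times are real-valued years and may be unequally spaced; an empty
measure cell marks a missing observation of that measure at that visit.

Internally data are stored per subject (ragged), because visit counts
differ across subjects and all downstream computation factorizes over
subjects anyway.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: column names with a fixed meaning; everything else is a measure.
RESERVED_COLUMNS = ("subject", "time", "group", "pair", "age")


class PanelParseError(ValueError):
    """A cell in the input file could not be interpreted."""


class PanelValidationError(ValueError):
    """The parsed panel violates a structural invariant."""


@dataclass
class PanelData:
    """Long-format panel of p continuous measures on n subjects.

    Attributes
    ----------
    subject_ids : list
        Ordered unique subject labels.
    times : list of 1-D arrays
        Visit times (years) per subject, strictly increasing.
    values : list of 2-D arrays
        Per subject, a ``(T_i, p)`` array of measures; ``nan`` = missing.
    variable_names : list of str
        Names of the p measures.
    group : array or None
        Optional per-subject binary label (0/1).
    covariates : DataFrame or None
        Per-subject scalar covariates (e.g. baseline ``age``), one row
        per subject in ``subject_ids`` order.
    pair_ids : array or None
        Optional matched-pair identifier per subject.
    """

    subject_ids: list
    times: list
    values: list
    variable_names: list
    group: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    pair_ids: np.ndarray | None = None

    def __post_init__(self):
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        return len(self.variable_names)

    @property
    def n_visits(self) -> np.ndarray:
        return np.array([len(t) for t in self.times])

    @property
    def total_visits(self) -> int:
        return int(self.n_visits.sum())

    @property
    def masks(self) -> list:
        """Per-subject boolean arrays, True where a measure is observed."""
        return [~np.isnan(v) for v in self.values]

    def validate(self) -> None:
        n = len(self.subject_ids)
        if n == 0:
            raise PanelValidationError("panel has no subjects")
        if len(set(map(str, self.subject_ids))) != n:
            raise PanelValidationError("subject ids are not unique")
        if len(self.times) != n or len(self.values) != n:
            raise PanelValidationError("per-subject arrays do not match subject count")
        p = len(self.variable_names)
        for sid, t, v in zip(self.subject_ids, self.times, self.values):
            t = np.asarray(t, dtype=float)
            if t.ndim != 1 or t.size < 1:
                raise PanelValidationError(f"subject {sid!r} has no visits")
            if np.any(np.diff(t) <= 0):
                raise PanelValidationError(
                    f"subject {sid!r} has non-increasing visit times {t.tolist()}"
                )
            v = np.asarray(v, dtype=float)
            if v.shape != (t.size, p):
                raise PanelValidationError(
                    f"subject {sid!r}: values shape {v.shape} != ({t.size}, {p})"
                )
            if np.all(np.isnan(v), axis=1).any():
                raise PanelValidationError(
                    f"subject {sid!r} has a visit with every measure missing"
                )
        if self.group is not None and len(self.group) != n:
            raise PanelValidationError("group labels do not match subject count")
        if self.pair_ids is not None and len(self.pair_ids) != n:
            raise PanelValidationError("pair ids do not match subject count")
        if self.covariates is not None and len(self.covariates) != n:
            raise PanelValidationError("covariate rows do not match subject count")

    # -- conversions -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per subject-visit."""
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for j, t in enumerate(self.times[i]):
                row = {"subject": sid, "time": float(t)}
                if self.group is not None:
                    row["group"] = int(self.group[i])
                if self.pair_ids is not None:
                    row["pair"] = self.pair_ids[i]
                if self.covariates is not None:
                    for c in self.covariates.columns:
                        row[c] = self.covariates.iloc[i][c]
                for k, name in enumerate(self.variable_names):
                    row[name] = self.values[i][j, k]
                rows.append(row)
        return pd.DataFrame(rows)

    def dense(self):
        """Return ``(Y, times)`` with ``Y`` of shape (n, T, p) when every
        subject shares the same visit times and no cell is missing;
        otherwise ``None``.  This regular layout enables the vectorized
        filter path.  The result is cached; panels are treated as
        immutable after construction."""
        if "_dense" in self.__dict__:
            return self.__dict__["_dense"]
        dense = None
        t0 = np.asarray(self.times[0], dtype=float)
        regular = all(
            np.asarray(t, dtype=float).shape == t0.shape
            and np.allclose(np.asarray(t, dtype=float), t0)
            for t in self.times[1:]
        )
        if regular:
            Y = np.stack([np.asarray(v, dtype=float) for v in self.values])
            if not np.isnan(Y).any():
                dense = (Y, t0)
        self.__dict__["_dense"] = dense
        return dense

    def subset(self, indices: Sequence[int], relabel: bool = False) -> "PanelData":
        """New panel restricted to the given subject indices (repeats
        allowed when ``relabel`` is True, e.g. for bootstrap resamples)."""
        indices = list(indices)
        if relabel:
            ids = [f"{self.subject_ids[i]}#{k}" for k, i in enumerate(indices)]
        else:
            ids = [self.subject_ids[i] for i in indices]
            if len(set(ids)) != len(ids):
                raise PanelValidationError("duplicate subjects; use relabel=True")
        return PanelData(
            subject_ids=ids,
            times=[np.array(self.times[i], dtype=float) for i in indices],
            values=[np.array(self.values[i], dtype=float) for i in indices],
            variable_names=list(self.variable_names),
            group=None if self.group is None else np.asarray(self.group)[indices],
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[indices].reset_index(drop=True),
            pair_ids=None if self.pair_ids is None else np.asarray(self.pair_ids)[indices],
        )


def panel_from_frame(df: pd.DataFrame, variable_names: Sequence[str] | None = None) -> PanelData:
    """Build a :class:`PanelData` from a long-format DataFrame.

    Subjects keep their order of first appearance; visit rows must appear
    in strictly increasing time order within each subject.
    """
    if "subject" not in df.columns or "time" not in df.columns:
        raise PanelParseError("input must have 'subject' and 'time' columns")
    if variable_names is None:
        variable_names = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not variable_names:
        raise PanelParseError("no measure columns found")

    dup = df.duplicated(subset=["subject", "time"])
    if dup.any():
        i = int(np.argmax(dup.to_numpy()))
        raise PanelValidationError(
            f"duplicate (subject, time) row: {df.iloc[i]['subject']!r} at t={df.iloc[i]['time']}"
        )

    subject_ids, times, values = [], [], []
    groups, pairs, ages = [], [], []
    has_group = "group" in df.columns
    has_pair = "pair" in df.columns
    cov_cols = [c for c in df.columns if c in ("age",)]
    for sid, sub in df.groupby("subject", sort=False):
        subject_ids.append(sid)
        t = sub["time"].to_numpy(dtype=float)
        times.append(t)
        values.append(sub[list(variable_names)].to_numpy(dtype=float))
        if has_group:
            g = sub["group"].dropna().unique()
            if len(g) != 1:
                raise PanelValidationError(f"subject {sid!r}: group label not constant")
            groups.append(int(g[0]))
        if has_pair:
            pr = sub["pair"].dropna().unique()
            if len(pr) != 1:
                raise PanelValidationError(f"subject {sid!r}: pair id not constant")
            pairs.append(pr[0])
        if cov_cols:
            ages.append([float(sub[c].iloc[0]) for c in cov_cols])

    covariates = pd.DataFrame(ages, columns=cov_cols) if cov_cols else None
    return PanelData(
        subject_ids=subject_ids,
        times=times,
        values=values,
        variable_names=list(variable_names),
        group=np.array(groups, dtype=int) if has_group else None,
        covariates=covariates,
        pair_ids=np.array(pairs) if has_pair else None,
    )


def read_panel(path) -> PanelData:
    """Read a long-format panel CSV.

    Empty measure cells are missing values; a non-numeric measure cell is
    a parse error that names the offending row and column.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    measure_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    for col in ["time"] + measure_cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise PanelParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, data row {row}"
            )
        df[col] = coerced
    return panel_from_frame(df, measure_cols)


def write_panel(panel: PanelData, path) -> None:
    """Write the long-format CSV (inverse of :func:`read_panel`)."""
    panel.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationSpec:
    """Per-variable location/scale used to z-score a panel.

    Means and standard deviations are pooled over all non-missing cells
    (sample standard deviation, ddof=1), so the transform is exactly
    invertible.
    """

    means: np.ndarray
    sds: np.ndarray
    applied: bool = True

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds <= 0):
            raise PanelValidationError("standard deviations must be positive")

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "applied": self.applied,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationSpec":
        return cls(np.asarray(d["means"]), np.asarray(d["sds"]), d.get("applied", True))


def standardize(panel: PanelData) -> tuple[PanelData, StandardizationSpec]:
    """Z-score every measure using its pooled mean and SD.

    Raises if a variable has fewer than 2 non-missing values or zero
    variance (naming the variable).
    """
    stacked = np.concatenate([np.asarray(v, dtype=float) for v in panel.values], axis=0)
    means = np.empty(panel.p)
    sds = np.empty(panel.p)
    for k, name in enumerate(panel.variable_names):
        col = stacked[:, k]
        col = col[~np.isnan(col)]
        if col.size < 2:
            raise PanelValidationError(f"variable {name!r} has fewer than 2 observed values")
        means[k] = col.mean()
        sds[k] = col.std(ddof=1)
        if sds[k] <= 0 or not np.isfinite(sds[k]):
            raise PanelValidationError(f"variable {name!r} has zero variance")
    new_values = [(np.asarray(v, dtype=float) - means) / sds for v in panel.values]
    out = replace(panel, values=new_values)
    return out, StandardizationSpec(means=means, sds=sds, applied=True)


def unstandardize(panel: PanelData, spec: StandardizationSpec) -> PanelData:
    """Exact inverse of :func:`standardize` under the stored spec."""
    new_values = [np.asarray(v, dtype=float) * spec.sds + spec.means for v in panel.values]
    return replace(panel, values=new_values)


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------

def fit_to_dict(fit, seed=None, extra: dict | None = None) -> dict:
    """JSON-ready summary of an :class:`~dynfactor.ecme.EcmeFit`."""
    from . import __version__

    out = {
        "model": fit.model,
        "q": int(fit.params.q),
        "loadings": {v: float(x) for v, x in zip(fit.variable_names, fit.params.f)},
        "variances": {v: float(x) for v, x in zip(fit.variable_names, fit.params.d)},
        "loglik_trace": [float(x) for x in fit.loglik_trace],
        "loglik": float(fit.loglik_trace[-1]),
        "iterations": int(fit.n_iter),
        "converged": bool(fit.converged),
        "settings": dict(fit.settings),
        "scores": fit.scores.to_dict(orient="records"),
        "metadata": {"package_version": __version__, "seed": seed},
    }
    if extra:
        out["metadata"].update(extra)
    return out


def write_results(fit, path, seed=None, extra: dict | None = None) -> dict:
    """Write a fit summary (loadings, variances, scores, likelihood
    trace, run metadata) as JSON; returns the written dict."""
    d = fit_to_dict(fit, seed=seed, extra=extra)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
    return d


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table (e.g. one row per simulation grid cell)."""
    df.to_csv(path, index=False)
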