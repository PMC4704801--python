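"""Synthetic panel generator with known latent trajectories.

The generator emulates the study conditions of a large observational
cognition panel: n independent subjects, each with a scalar latent
trait following a Gaussian random walk, observed at T visits through p
continuous measures with shared loadings and idiosyncratic noise.

Design of one draw:

* loadings ``f_k ~ U(0,1)`` i.i.d., rescaled so ``sum(f) = 1``;
* noise-to-total variance ratios ``beta_k ~ U(0.1, 0.9)`` i.i.d.,
  giving idiosyncratic variances ``d_k = f_k * beta_k / (1 - beta_k)``
  (the 0.1/0.9 endpoints keep parameters off the boundary);
* latent start ``u0 ~ N(0,1)`` one `presample_gap` (default one year)
  before the first visit, then a random-walk step onto each visit with
  variance equal to the elapsed gap tau;
* observations ``y = f * u + e``, ``e ~ N(0, diag d)``.

A two-group extension adds a deterministic drift ``delta * tau`` to the
latent increments of group-1 subjects (a difference in annual rate of
change), with groups matched in pairs on a baseline-age covariate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PanelData

#: gap menu for the random-spacing policy (years)
RANDOM_GAP_CHOICES = (0.5, 1.0, 1.5, 2.0)


@dataclass
class SimulationConfig:
    """Study-design knobs of the synthetic generator."""

    n: int = 100
    p: int = 5
    T: int = 5
    seed: int | None = None
    spacing: object = "unit"        # "unit" | "random" | sequence of T-1 gaps
    presample_gap: float = 1.0
    two_group: bool = False
    delta: float = 0.0              # group-1 latent drift per year
    age_mean: float = 75.7
    age_sd: float = 7.5
    replicates: int = 1

    def __post_init__(self):
        if self.n < 2 or self.p < 1 or self.T < 2:
            raise ValueError("need n >= 2, p >= 1, T >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.two_group and self.n % 2:
            raise ValueError("two balanced groups need an even number of subjects")


@dataclass
class SimulatedPanel:
    """A synthetic panel together with the truth used to generate it."""

    panel: PanelData
    f: np.ndarray
    d: np.ndarray
    beta: np.ndarray
    U: list = field(default_factory=list)   # per-subject latent paths at the visits
    seed: int | None = None

    def stacked_truth(self) -> np.ndarray:
        """All subjects' latent paths stacked into one vector, in the
        same subject-then-visit order as the panel rows."""
        return np.concatenate([np.asarray(u, dtype=float) for u in self.U])


def draw_loadings(p: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. U(0,1) loadings rescaled to sum to one."""
    u = rng.uniform(size=p)
    # a zero draw has probability zero; guard anyway so the sum is safe
    u = np.maximum(u, 1e-12)
    return u / u.sum()


def draw_idio_variances(f: np.ndarray, rng: np.random.Generator):
    """Noise ratios beta ~ U(0.1, 0.9) and the implied variances
    d_k = f_k beta_k / (1 - beta_k)."""
    f = np.asarray(f, dtype=float)
    beta = rng.uniform(0.1, 0.9, size=f.size)
    d = f * beta / (1.0 - beta)
    return d, beta


def _draw_gaps(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subject gap matrix of shape (n, T-1)."""
    n, T = config.n, config.T
    if isinstance(config.spacing, str):
        if config.spacing == "unit":
            return np.ones((n, T - 1))
        if config.spacing == "random":
            return rng.choice(RANDOM_GAP_CHOICES, size=(n, T - 1))
        raise ValueError(f"unknown spacing policy {config.spacing!r}")
    gaps = np.asarray(config.spacing, dtype=float)
    if gaps.shape != (T - 1,) or np.any(gaps <= 0):
        raise ValueError("fixed gap vector must have T-1 positive entries")
    return np.tile(gaps, (n, 1))


def simulate_panel(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    f: np.ndarray | None = None,
    d: np.ndarray | None = None,
) -> SimulatedPanel:
    """Draw one synthetic panel (parameters redrawn unless supplied)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, p, T = config.n, config.p, config.T
    if f is None:
        f = draw_loadings(p, rng)
        d, beta = draw_idio_variances(f, rng)
    else:
        f = np.asarray(f, dtype=float)
        if d is None:
            d, beta = draw_idio_variances(f, rng)
        else:
            d = np.asarray(d, dtype=float)
            beta = d / (f + d)  # implied ratio, for bookkeeping only

    gaps = _draw_gaps(config, rng)
    times = np.concatenate([np.zeros((n, 1)), np.cumsum(gaps, axis=1)], axis=1)

    group = None
    pair_ids = None
    covariates = None
    drift = np.zeros(n)
    if config.two_group:
        half = n // 2
        group = np.repeat([0, 1], half)
        pair_ids = np.concatenate([np.arange(half), np.arange(half)])
        age = rng.normal(config.age_mean, config.age_sd, size=half)
        covariates = pd.DataFrame({"age": np.concatenate([age, age])})
        drift = np.where(group == 1, config.delta, 0.0)

    # latent paths: N(0,1) start one presample gap before the first visit
    u0 = rng.standard_normal(n)
    U = np.empty((n, T))
    U[:, 0] = u0 + np.sqrt(config.presample_gap) * rng.standard_normal(n)
    for j in range(1, T):
        tau = gaps[:, j - 1]
        U[:, j] = U[:, j - 1] + drift * tau + np.sqrt(tau) * rng.standard_normal(n)

    noise = rng.standard_normal((n, T, p)) * np.sqrt(d)
    Y = U[:, :, None] * f + noise

    panel = PanelData(
        subject_ids=[f"s{i:04d}" for i in range(n)],
        times=[times[i] for i in range(n)],
        values=[Y[i] for i in range(n)],
        variable_names=[f"y{k + 1}" for k in range(p)],
        group=group,
        covariates=covariates,
        pair_ids=pair_ids,
    )
    return SimulatedPanel(
        panel=panel, f=f, d=d, beta=beta, U=[U[i] for i in range(n)], seed=config.seed
    )


def simulate_two_group_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedPanel:
    """Balanced case-control panel: group 1 differs from group 0 only in
    the latent annual rate of change (drift ``delta``); pairs are
    matched exactly on baseline age."""
    if not config.two_group:
        from dataclasses import replace

        config = replace(config, two_group=True)
    return simulate_panel(config, rng=rng)


def truth_frame(sim: SimulatedPanel) -> pd.DataFrame:
    """Long-format table of the true latent paths."""
    rows = []
    for i, sid in enumerate(sim.panel.subject_ids):
        for t, u in zip(sim.panel.times[i], sim.U[i]):
            rows.append({"subject": sid, "time": float(t), "u": float(u)})
    return pd.DataFrame(rows)
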