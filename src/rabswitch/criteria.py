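"""Model-selection criteria.

Candidates are scored against the measured total-intensity channels by a
family of criteria (all "smaller is better"):

* ``E`` — average relative root-mean-squared error over the two observed
  channels, normalised so that a model predicting each channel's mean scores
  exactly 1.
* ``R`` — disagreement between the *hidden* active-state trajectories and
  the measured totals, ``R = mean over proteins of min(1 - pearson, 1)``;
  0 means both active states track their totals perfectly.
* ``X`` — normalised distance between the measured and simulated
  Rab5-to-Rab7 dominance switch times.
* ``RX``, ``ER``, ``EX``, ``ERX`` — convex combinations of the above with
  trade-off parameter ``alpha``.
* ``EC``, ``ERC``, ``EXC``, ``ERXC`` — parsimony variants mixing in the model
  process count ``C`` with trade-off ``beta`` (raw count or normalised to
  [0, 1] over the library).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import CriterionError, DatasetError

__all__ = [
    "Dataset",
    "ScoreCard",
    "CriterionConfig",
    "error_E",
    "corr_R",
    "switch_time",
    "switch_X",
    "combine",
    "score",
    "CRITERIA",
]

CRITERIA = ("E", "R", "X", "RX", "ER", "EX", "ERX", "EC", "ERC", "EXC", "ERXC")

#: default persistence window (s) for dominance-switch detection
SWITCH_WINDOW = 5.0


def switch_time(times, a_channel, b_channel, persistence_window: float = SWITCH_WINDOW):
    """Earliest time at which ``b >= a`` and remains so for the window.

    Returns ``None`` when no such time exists.  If the dominance holds from
    the first sample onward, the first time point is returned.  A window that
    runs past the end of the series is satisfied by dominance holding until
    the end.
    """
    times = np.asarray(times, dtype=float)
    a = np.asarray(a_channel, dtype=float)
    b = np.asarray(b_channel, dtype=float)
    if not (len(times) == len(a) == len(b)):
        raise ValueError("times and channels must have equal length")
    ok = b >= a
    # time of the next violation at or after each index (inf if none)
    bad_times = np.where(ok, np.inf, times)
    next_bad = np.minimum.accumulate(bad_times[::-1])[::-1]
    holds = ok & (next_bad > times + persistence_window)
    idx = np.flatnonzero(holds)
    if len(idx) == 0:
        return None
    return float(times[idx[0]])


@dataclass(frozen=True)
class Dataset:
    """Measured two-channel time series with its detected switch time."""

    times: np.ndarray
    rab5: np.ndarray
    rab7: np.ndarray
    t_s: float | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        rab5 = np.asarray(self.rab5, dtype=float)
        rab7 = np.asarray(self.rab7, dtype=float)
        if times.ndim != 1:
            raise DatasetError("times must be one-dimensional")
        if len(times) != len(rab5) or len(times) != len(rab7):
            raise DatasetError("channels must match the length of times")
        if len(times) >= 2 and np.any(np.diff(times) <= 0):
            raise DatasetError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rab5", rab5)
        object.__setattr__(self, "rab7", rab7)

    @classmethod
    def from_arrays(
        cls,
        times,
        rab5,
        rab7,
        *,
        t_s: float | None = None,
        persistence_window: float = SWITCH_WINDOW,
    ) -> "Dataset":
        """Build a dataset, detecting the Rab5-to-Rab7 switch if not given."""
        ds = cls(times, rab5, rab7)
        if t_s is None:
            t_s = switch_time(ds.times, ds.rab5, ds.rab7, persistence_window)
        return replace(ds, t_s=t_s)

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def tmax(self) -> float:
        return float(self.times[-1])

    def __len__(self):
        return len(self.times)


def _rrmse(measured, simulated):
    measured = np.asarray(measured, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    denom = np.sum((measured - measured.mean()) ** 2)
    if denom == 0:
        raise CriterionError("measured channel has zero variance; E is undefined")
    return np.sqrt(np.sum((measured - simulated) ** 2) / denom)


def error_E(dataset: Dataset, sim_rab5, sim_rab7) -> float:
    """Average relative RMSE over the two observed channels."""
    return 0.5 * (_rrmse(dataset.rab5, sim_rab5) + _rrmse(dataset.rab7, sim_rab7))


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0 or not (np.isfinite(sx) and np.isfinite(sy)):
        # a flat (or broken) hidden state cannot explain a switching total
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def corr_R(dataset: Dataset, sim_R5, sim_R7) -> float:
    """Hidden-state disagreement in [0, 1]; 0 is perfect positive correlation."""
    term5 = min(1.0 - _pearson(sim_R5, dataset.rab5), 1.0)
    term7 = min(1.0 - _pearson(sim_R7, dataset.rab7), 1.0)
    return 0.5 * (term5 + term7)


def switch_X(dataset: Dataset, simulated_ts: float | None) -> float:
    """Normalised switch-time distance; a simulation with no switch scores 1."""
    span = dataset.tmax - dataset.t0
    if span <= 0:
        raise CriterionError("dataset time span is empty; X is undefined")
    if dataset.t_s is None:
        raise CriterionError("dataset has no measured switch time; X is undefined")
    if simulated_ts is None:
        return 1.0
    return abs(dataset.t_s - simulated_ts) / span


def combine(
    which: str,
    *,
    E: float | None = None,
    R: float | None = None,
    X: float | None = None,
    C: float | None = None,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> float:
    """Evaluate one named criterion from its components.

    ``C`` is the complexity term on whatever scale the caller uses (raw
    process count or normalised); the parsimony criteria are
    ``beta * fit + (1 - beta) * C``.
    """
    if which not in CRITERIA:
        raise CriterionError(f"unknown criterion {which!r}; choose from {CRITERIA}")
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise CriterionError("alpha and beta must lie in [0, 1]")

    def need(name, value):
        if value is None:
            raise CriterionError(f"criterion {which} requires component {name}")
        return value

    if which == "E":
        return need("E", E)
    if which == "R":
        return need("R", R)
    if which == "X":
        return need("X", X)
    if which == "RX":
        return 0.5 * (need("R", R) + need("X", X))
    if which == "ER":
        return alpha * need("E", E) + (1 - alpha) * need("R", R)
    if which == "EX":
        return alpha * need("E", E) + (1 - alpha) * need("X", X)
    if which == "ERX":
        rx = 0.5 * (need("R", R) + need("X", X))
        return alpha * need("E", E) + (1 - alpha) * rx
    if which == "EC":
        return beta * need("E", E) + (1 - beta) * need("C", C)
    fit = combine(which[:-1], E=E, R=R, X=X, alpha=alpha)
    return beta * fit + (1 - beta) * need("C", C)


@dataclass(frozen=True)
class CriterionConfig:
    """Which criterion drives fitting/ranking, and its trade-off settings."""

    criterion: str = "ERX"
    alpha: float = 0.5
    beta: float = 0.5
    complexity_mode: str = "normalized"  # or "raw"
    complexity_range: tuple[int, int] = (8, 9)  # (Cmin, Cmax) over the library
    switch_window: float = SWITCH_WINDOW

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise CriterionError(f"unknown criterion {self.criterion!r}")
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise CriterionError("alpha and beta must lie in [0, 1]")
        if self.complexity_mode not in ("raw", "normalized"):
            raise CriterionError("complexity_mode must be 'raw' or 'normalized'")

    def complexity_term(self, c: int) -> float:
        if self.complexity_mode == "raw":
            return float(c)
        cmin, cmax = self.complexity_range
        if cmax == cmin:
            return 0.0
        return (c - cmin) / (cmax - cmin)


@dataclass(frozen=True)
class ScoreCard:
    """All criterion values for one fitted model."""

    E: float
    R: float
    X: float
    C: int
    alpha: float = 0.5
    beta: float = 0.5
    C_term: float = field(default=0.0)

    @property
    def RX(self):
        return 0.5 * (self.R + self.X)

    @property
    def ER(self):
        return combine("ER", E=self.E, R=self.R, alpha=self.alpha)

    @property
    def EX(self):
        return combine("EX", E=self.E, X=self.X, alpha=self.alpha)

    @property
    def ERX(self):
        return combine("ERX", E=self.E, R=self.R, X=self.X, alpha=self.alpha)

    @property
    def EC(self):
        return combine("EC", E=self.E, C=self.C_term, beta=self.beta)

    @property
    def ERC(self):
        return combine("ERC", E=self.E, R=self.R, C=self.C_term, alpha=self.alpha, beta=self.beta)

    @property
    def EXC(self):
        return combine("EXC", E=self.E, X=self.X, C=self.C_term, alpha=self.alpha, beta=self.beta)

    @property
    def ERXC(self):
        return combine(
            "ERXC", E=self.E, R=self.R, X=self.X, C=self.C_term, alpha=self.alpha, beta=self.beta
        )

    def value(self, which: str) -> float:
        if which not in CRITERIA:
            raise CriterionError(f"unknown criterion {which!r}")
        return float(getattr(self, which))

    def as_dict(self) -> Mapping[str, float]:
        out = {name: float(getattr(self, name)) for name in CRITERIA}
        out["C"] = int(self.C)
        out["alpha"] = self.alpha
        out["beta"] = self.beta
        return out


def score(dataset: Dataset, trajectory, complexity_count: int, config: CriterionConfig) -> ScoreCard:
    """Score one simulated trajectory against the dataset under all criteria."""
    E = error_E(dataset, trajectory.rab5_hat, trajectory.rab7_hat)
    R = corr_R(dataset, trajectory.R5, trajectory.R7)
    ts_hat = switch_time(
        trajectory.times, trajectory.rab5_hat, trajectory.rab7_hat, config.switch_window
    )
    X = switch_X(dataset, ts_hat)
    return ScoreCard(
        E=E,
        R=R,
        X=X,
        C=complexity_count,
        alpha=config.alpha,
        beta=config.beta,
        C_term=config.complexity_term(complexity_count),
    )
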