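"""Bootstrap practical-identifiability analysis.

A structure's parameters are *practically identifiable* when refitting the
model to repeatedly perturbed data yields tight, uncorrelated estimate
distributions.  Each bootstrap replicate perturbs every measured value with
independent zero-mean Gaussian noise of standard deviation
``noise_level * |value|``, re-estimates the parameters with a
replicate-specific seed, and records the estimate.  The replicate-by-
parameter estimate matrix is then summarised by percentile confidence
intervals, CI-length-to-mean ratios, the pairwise Pearson correlation matrix
of the estimates (near-collinear ridges show up as |r| close to 1), and
flags for estimates piling up against the box bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .criteria import CriterionConfig, Dataset
from .de_fit import FAILURE_PENALTY, DEConfig, minimize_de
from .errors import FitError
from .model_space import IDX_K, ModelStructure, compile_rhs
from . import de_fit

__all__ = [
    "BootstrapResult",
    "bootstrap_estimates",
    "bootstrap_identify",
    "perturb_dataset",
    "summarize_identifiability",
]


@dataclass
class BootstrapResult:
    """Replicate-by-parameter estimate matrix with its provenance."""

    estimates: np.ndarray  # (n_replicates, n_parameters)
    values: np.ndarray  # best objective per replicate
    param_names: tuple[str, ...]
    bounds: np.ndarray  # (n_parameters, 2)
    noise_level: float
    master_seed: int
    fit_seeds: tuple[int, ...]

    @property
    def n_replicates(self) -> int:
        return self.estimates.shape[0]

    def mean(self) -> np.ndarray:
        return self.estimates.mean(axis=0)

    def ci(self, level: float = 95.0) -> np.ndarray:
        """Percentile bootstrap interval, columns (lower, upper)."""
        tail = (100.0 - level) / 2.0
        lo = np.percentile(self.estimates, tail, axis=0)
        hi = np.percentile(self.estimates, 100.0 - tail, axis=0)
        return np.column_stack([lo, hi])

    def ci_length(self, level: float = 95.0) -> np.ndarray:
        ci = self.ci(level)
        return ci[:, 1] - ci[:, 0]

    def correlation(self) -> np.ndarray:
        """Pearson correlation of estimates; degenerate (constant) columns
        contribute 0 off-diagonal and 1 on the diagonal."""
        est = self.estimates
        sd = est.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(est, rowvar=False)
        corr = np.atleast_2d(corr)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        # fully degenerate case (all columns constant) still has unit diagonal
        if np.all(sd == 0):
            corr = np.eye(est.shape[1])
        return corr


def perturb_dataset(dataset: Dataset, noise_level: float, rng: np.random.Generator) -> Dataset:
    """Proportional-Gaussian perturbation of both measured channels.

    The dominance switch time is re-detected on the perturbed channels; if the
    noise destroys the switch, the original switch time is kept so the
    criterion stays computable.
    """
    rab5 = dataset.rab5 + noise_level * np.abs(dataset.rab5) * rng.standard_normal(len(dataset))
    rab7 = dataset.rab7 + noise_level * np.abs(dataset.rab7) * rng.standard_normal(len(dataset))
    out = Dataset.from_arrays(dataset.times, rab5, rab7)
    if out.t_s is None:
        out = Dataset(out.times, out.rab5, out.rab7, t_s=dataset.t_s)
    return out


def bootstrap_estimates(
    objective_factory: Callable[[int, np.random.Generator], Callable[[np.ndarray], float]],
    bounds: np.ndarray,
    param_names: Sequence[str],
    *,
    noise_level: float,
    n_replicates: int,
    de_config: DEConfig | None = None,
    master_seed: int = 0,
    vary_fit_seeds: bool = True,
    log_dims: Sequence[int] = (),
) -> BootstrapResult:
    """Generic bootstrap loop over replicate objectives.

    ``objective_factory(b, rng)`` builds the objective for replicate ``b``
    from a replicate-specific random generator (used to perturb the data).
    With ``vary_fit_seeds=False`` every replicate's optimiser uses the same
    seed, so at noise level 0 all replicates are identical by construction.
    """
    if n_replicates < 2:
        raise FitError("bootstrap needs at least 2 replicates")
    if noise_level < 0:
        raise FitError("noise level must be non-negative")
    de_config = de_config or DEConfig()
    bounds = np.asarray(bounds, dtype=float)
    estimates = np.empty((n_replicates, len(bounds)))
    values = np.empty(n_replicates)
    fit_seeds = []
    for b in range(n_replicates):
        noise_ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(b, 0))
        rng = np.random.default_rng(noise_ss)
        fit_key = (b, 1) if vary_fit_seeds else (0, 1)
        fit_ss = np.random.SeedSequence(entropy=master_seed, spawn_key=fit_key)
        fit_seed = int(fit_ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        objective = objective_factory(b, rng)
        x, f, _, _ = minimize_de(objective, bounds, de_config, fit_seed, log_dims=log_dims)
        estimates[b] = x
        values[b] = f
        fit_seeds.append(fit_seed)
    if np.all(values >= FAILURE_PENALTY):
        raise FitError("all bootstrap replicates failed to fit")
    return BootstrapResult(
        estimates=estimates,
        values=values,
        param_names=tuple(param_names),
        bounds=bounds,
        noise_level=noise_level,
        master_seed=master_seed,
        fit_seeds=tuple(fit_seeds),
    )


def bootstrap_identify(
    structure: ModelStructure,
    dataset: Dataset,
    noise_level: float = 0.1,
    n_replicates: int = 100,
    criterion_config: CriterionConfig | None = None,
    de_config: DEConfig | None = None,
    *,
    master_seed: int = 0,
    vary_fit_seeds: bool = True,
) -> BootstrapResult:
    """Bootstrap identifiability of one structure on one dataset."""
    criterion_config = criterion_config or CriterionConfig()
    rhs = compile_rhs(structure)

    def factory(b: int, rng: np.random.Generator):
        noisy = perturb_dataset(dataset, noise_level, rng) if noise_level > 0 else dataset
        return de_fit.make_objective(structure, noisy, criterion_config, rhs=rhs)

    return bootstrap_estimates(
        factory,
        rhs.bounds,
        rhs.param_names,
        noise_level=noise_level,
        n_replicates=n_replicates,
        de_config=de_config,
        master_seed=master_seed,
        vary_fit_seeds=vary_fit_seeds,
        log_dims=(IDX_K,),
    )


def summarize_identifiability(
    result: BootstrapResult,
    *,
    ci_level: float = 95.0,
    corr_threshold: float = 0.9,
    bound_fraction: float = 0.5,
    bound_tolerance: float = 0.01,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Per-parameter summary table plus flagged high-correlation pairs.

    A parameter is flagged ``at_bound`` when at least ``bound_fraction`` of
    its estimates lie within ``bound_tolerance`` of the box range from either
    bound.  High-correlation pairs (|r| > ``corr_threshold``) are returned
    sorted by |r| descending.
    """
    ci = result.ci(ci_level)
    mean = result.mean()
    length = ci[:, 1] - ci[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean != 0, length / np.abs(mean), np.inf)
    lo = result.bounds[:, 0]
    hi = result.bounds[:, 1]
    span = hi - lo
    near = (result.estimates - lo <= bound_tolerance * span) | (
        hi - result.estimates <= bound_tolerance * span
    )
    at_bound = near.mean(axis=0) >= bound_fraction
    table = pd.DataFrame(
        {
            "parameter": result.param_names,
            "mean": mean,
            "ci_lower": ci[:, 0],
            "ci_upper": ci[:, 1],
            "ci_length": length,
            "ci_to_mean": ratio,
            "at_bound": at_bound,
        }
    )
    corr = result.correlation()
    pairs = []
    for i in range(len(result.param_names)):
        for j in range(i + 1, len(result.param_names)):
            if abs(corr[i, j]) > corr_threshold:
                pairs.append((result.param_names[i], result.param_names[j], float(corr[i, j])))
    pairs.sort(key=lambda p: abs(p[2]), reverse=True)
    return table, pairs
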