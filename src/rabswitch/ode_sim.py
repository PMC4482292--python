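"""Numerical simulation of compiled structures.

The model is integrated on an internal clock that starts at 0 at the onset of
the conversion process.  Measurement time ``t`` maps to internal time
``tau = (t - t0) + td``, where ``t0`` is the first measurement time and the
onset offset ``td`` is an estimated parameter: the data recording is assumed
to begin ``td`` seconds after the process starts.

Only scaled totals are observable: ``Rab5_hat = K * (r5 + R5)`` and
``Rab7_hat = K * (r7 + R7)`` with a common intensity scaling factor ``K``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .model_space import IDX_INIT, IDX_K, IDX_TD, CompiledRHS, ModelStructure, compile_rhs

__all__ = ["Trajectory", "simulate", "simulate_theta", "observe"]

#: default integrator tolerances
RTOL = 1e-6
ATOL = 1e-8


@dataclass
class Trajectory:
    """Result of one simulation.

    ``states`` holds columns ``(r5, R5, r7, R7)`` at the requested measurement
    times; ``outputs`` holds the observable channels ``(Rab5_hat, Rab7_hat)``.
    A failed integration is reported through ``ok=False`` (with ``message``)
    rather than an exception so that parameter estimation can penalise it.
    """

    times: np.ndarray
    states: np.ndarray
    outputs: np.ndarray
    ok: bool = True
    message: str = ""

    @property
    def r5(self):
        return self.states[:, 0]

    @property
    def R5(self):
        return self.states[:, 1]

    @property
    def r7(self):
        return self.states[:, 2]

    @property
    def R7(self):
        return self.states[:, 3]

    @property
    def rab5_hat(self):
        return self.outputs[:, 0]

    @property
    def rab7_hat(self):
        return self.outputs[:, 1]

    def to_frame(self):
        """Trajectory as a pandas DataFrame (t, states, outputs)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "r5": self.r5,
                "R5": self.R5,
                "r7": self.r7,
                "R7": self.R7,
                "Rab5_hat": self.rab5_hat,
                "Rab7_hat": self.rab7_hat,
            }
        )


def observe(states: np.ndarray, K: float) -> np.ndarray:
    """Map hidden states to the two observable intensity channels."""
    if K <= 0:
        raise ValueError(f"scaling factor K must be positive, got {K}")
    states = np.asarray(states, dtype=float)
    totals = np.stack([states[..., 0] + states[..., 1], states[..., 2] + states[..., 3]], axis=-1)
    return K * totals


def _failure(times, message):
    n = len(times)
    nan = np.full((n, 4), np.nan)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=nan,
        outputs=np.full((n, 2), np.nan),
        ok=False,
        message=message,
    )


def simulate_theta(
    rhs: CompiledRHS,
    theta: np.ndarray,
    eval_times: np.ndarray,
    *,
    t0: float | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate a compiled structure for a packed parameter vector.

    This is the fast path used by the fitting loop; :func:`simulate` wraps it
    for mapping-style parameters.
    """
    times = np.asarray(eval_times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("eval_times must be a strictly increasing 1-D grid")
    theta = np.asarray(theta, dtype=float)
    if t0 is None:
        t0 = times[0]
    td = theta[IDX_TD]
    K = theta[IDX_K]
    y0 = theta[IDX_INIT]
    tau = (times - t0) + td
    if tau[0] < 0:
        return _failure(times, f"negative internal start time {tau[0]:g}")
    prepend = tau[0] > 0
    grid = np.concatenate(([0.0], tau)) if prepend else tau

    f = rhs.bind(theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            sol, info = odeint(
                f,
                y0,
                grid,
                rtol=rtol,
                atol=atol,
                full_output=True,
                mxstep=10000,
            )
        except Exception as exc:  # odeint can raise on hard failures
            return _failure(times, f"integrator raised: {exc}")
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        return _failure(times, info["message"])
    states = sol[1:] if prepend else sol
    return Trajectory(times=times, states=states, outputs=observe(states, K))


def simulate(
    structure: ModelStructure,
    params,
    eval_times,
    *,
    t0: float | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    rhs: CompiledRHS | None = None,
) -> Trajectory:
    """Simulate a structure at named parameter values over a measurement grid."""
    if rhs is None:
        rhs = compile_rhs(structure)
    theta = params if isinstance(params, np.ndarray) else rhs.pack(params)
    return simulate_theta(rhs, theta, eval_times, t0=t0, rtol=rtol, atol=atol)
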