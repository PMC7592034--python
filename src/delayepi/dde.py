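"""Method-of-steps integrator for the doubly delayed epidemic DDE.

The NRDE model is the single delay differential equation

    dm/dtau = R0 [1 - m(tau)] [m(tau - tau_i) - m(tau - tau_i - 1)]

for the cumulative fraction m = (I + R)/N, with the recovery time as the
unit delay and the incubation period tau_i as a second delay.  Setting
tau_i = 0 recovers the single-delay NRD model, the DDE analogue of SIR.

The integrator advances with classical 4th-order Runge-Kutta steps on a
fixed uniform grid, serving the delayed arguments by linear interpolation of
the stored solution (method of steps).  The jump of the default history at
tau = 0 propagates derivative discontinuities at tau_i, tau_i + 1, 2 tau_i,
...; a fixed-step scheme with dense storage is robust to these, and formal
high order is unattainable across them anyway, so no discontinuity tracking
is attempted.  The scheme is validated by step-refinement and by the
classical final-size relation (see the seir module tests).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .exceptions import InvalidParameterError
from .params import EpidemicParams, HistorySpec, Trajectory

__all__ = ["integrate_nrde", "integrate_nrd", "delayed_lookup", "default_step"]


def default_step(tau_i: float) -> float:
    """Default grid step: 1/100 of the smallest delay present.

    The delays are the recovery time (1 in dimensionless units) and the
    incubation period tau_i; the step resolves the smaller of the two, with
    a floor of 1e-4 so that very small positive tau_i does not produce an
    unboundedly fine grid.
    """
    scale = min(1.0, tau_i) if tau_i > 0 else 1.0
    return max(scale / 100.0, 1e-4)


def integrate_nrde(
    params: EpidemicParams,
    history: Optional[HistorySpec] = None,
    *,
    horizon: float,
    step: Optional[float] = None,
) -> Trajectory:
    """Integrate the two-delay DDE from tau = 0 to (at least) horizon + tau_i.

    The run is extended past the requested horizon by tau_i so that the
    susceptible and exposed fractions, which read m at advanced times
    (tau + tau_i), are recoverable on the full window [0, horizon].

    Parameters
    ----------
    params : EpidemicParams
    history : HistorySpec, optional
        Pre-epidemic history; defaults to the unit-jump seeding m = 0 on
        [-(1 + tau_i), 0), m(0) = m0.
    horizon : float
        Requested dimensionless end time (> 0).
    step : float, optional
        Grid step h; snapped so that horizon/h is an integer.  Defaults to
        :func:`default_step`.

    Returns
    -------
    Trajectory
        m(tau) on the uniform grid; guaranteed nondecreasing and <= 1.
    """
    if history is None:
        history = HistorySpec()
    if step is None:
        step = default_step(params.tau_i)
    step = float(step)
    horizon = float(horizon)
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    if not math.isfinite(horizon) or horizon < step:
        raise InvalidParameterError(
            f"horizon must be finite and >= step, got horizon={horizon}, step={step}"
        )

    n = int(round(horizon / step))
    h = horizon / n  # snap so the grid hits the horizon exactly
    tau_i = params.tau_i
    r0 = params.r0
    n_ext = int(math.ceil(tau_i / h - 1e-12)) if tau_i > 0 else 0
    total = n + n_ext

    m_pre = history.m_pre
    m0 = history.value_at_zero(params)
    left_limit = float(m_pre(-min(h, 1.0) * 1e-9))
    if m0 < left_limit - 1e-12:
        raise InvalidParameterError(
            "history jump must be upward: m(0) >= lim m(tau) as tau -> 0-"
        )

    vals = [float(m0)]
    inv_h = 1.0 / h

    def lookup(t: float, front: int) -> float:
        # t < 0: history; t in [0, front*h]: linear interpolation of stored
        # values (exact at nodes); t slightly past the front (only possible
        # for tau_i < h, at inner RK stages): clamped to the front value.
        if t < 0.0:
            return float(m_pre(t))
        x = t * inv_h
        i0 = int(x)
        if i0 >= front:
            return vals[front]
        w = x - i0
        return vals[i0] * (1.0 - w) + vals[i0 + 1] * w

    no_latency = tau_i == 0.0

    for k in range(total):
        t = k * h
        y = vals[k]

        def f(tt: float, yy: float) -> float:
            d1 = yy if no_latency else lookup(tt - tau_i, k)
            d2 = lookup(tt - tau_i - 1.0, k)
            return r0 * (1.0 - yy) * (d1 - d2)

        k1 = f(t, y)
        k2 = f(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = f(t + 0.5 * h, y + 0.5 * h * k2)
        k4 = f(t + h, y + h * k3)
        y1 = y + (h / 6.0) * (k1 + 2.0 * (k2 + k3) + k4)
        # monotone nondecreasing and bounded by construction; guard rounding
        if y1 < y:
            y1 = y
        elif y1 > 1.0:
            y1 = 1.0
        vals.append(y1)

    grid = np.arange(total + 1, dtype=float) * h
    return Trajectory(
        tau_grid=grid,
        m_values=np.asarray(vals),
        params=params,
        history=history,
        horizon=n * h,
    )


def integrate_nrd(
    params: EpidemicParams,
    history: Optional[HistorySpec] = None,
    *,
    horizon: float,
    step: Optional[float] = None,
) -> Trajectory:
    """Integrate the single-delay (NRD) model: the tau_i = 0 reduction of
    :func:`integrate_nrde` (same code path, so the reduction is exact)."""
    return integrate_nrde(
        params.with_tau_i(0.0), history, horizon=horizon, step=step
    )


def delayed_lookup(traj: Trajectory, tau: float) -> float:
    """Evaluate m at a (possibly delayed) time against a stored trajectory.

    History values are served for tau < 0, the stored jump value at tau = 0,
    and linear interpolation elsewhere; requests outside
    [-(1 + tau_i), grid end] raise :class:`ContractViolationError`.
    """
    return float(traj.evaluate(tau))
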