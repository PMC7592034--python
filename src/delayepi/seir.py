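"""Reference ODE integrators: dimensionless SEIR and SIR.

The SEIR system, in time units of the recovery time (so the recovery rate
is 1 and the incubation rate is 1/tau_i):

    ds/dtau = -R0 s i
    de/dtau =  R0 s i - e / tau_i
    di/dtau =  e / tau_i - i
    dr/dtau =  i

SIR drops the exposed class (e identically 0, di/dtau = R0 s i - i).  The
initial state mirrors the delay models' unit-jump history: the seed
infection starts infectious, s(0) = s0, i(0) = 1 - s0, e(0) = r(0) = 0
(seeding the exposed class instead is available via ``seed="exposed"``).

Fixed-step classical 4th-order Runge-Kutta at the same default step as the
DDE solver, for like-for-like model comparisons.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .dde import default_step
from .exceptions import InvalidParameterError
from .params import CompartmentSeries, EpidemicParams

__all__ = ["integrate_seir", "integrate_sir"]


def _grid(horizon: float, step: float) -> tuple[int, float]:
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    if horizon < step:
        raise InvalidParameterError(
            f"horizon must be >= step, got horizon={horizon}, step={step}"
        )
    n = int(round(horizon / step))
    return n, horizon / n


def integrate_seir(
    params: EpidemicParams,
    *,
    horizon: float,
    step: Optional[float] = None,
    seed: str = "infectious",
) -> CompartmentSeries:
    """Integrate the dimensionless SEIR model on [0, horizon].

    Requires tau_i > 0 (the incubation rate is 1/tau_i); for tau_i = 0 use
    :func:`integrate_sir`.
    """
    if params.tau_i <= 0:
        raise InvalidParameterError(
            "SEIR requires tau_i > 0; use integrate_sir for the no-latency model"
        )
    if seed not in ("infectious", "exposed"):
        raise InvalidParameterError(f"seed must be 'infectious' or 'exposed', got {seed!r}")
    if step is None:
        step = default_step(params.tau_i)
    n, h = _grid(float(horizon), float(step))
    r0 = params.r0
    delta = 1.0 / params.tau_i

    def rhs(s, e, i, r):
        inf = r0 * s * i
        prog = delta * e
        return -inf, inf - prog, prog - i, i

    if seed == "infectious":
        state = (params.s0, 0.0, params.m0, 0.0)
    else:
        state = (params.s0, params.m0, 0.0, 0.0)
    out = np.empty((n + 1, 4))
    out[0] = state
    s, e, i, r = state
    for k in range(n):
        a1 = rhs(s, e, i, r)
        a2 = rhs(s + 0.5 * h * a1[0], e + 0.5 * h * a1[1], i + 0.5 * h * a1[2], r + 0.5 * h * a1[3])
        a3 = rhs(s + 0.5 * h * a2[0], e + 0.5 * h * a2[1], i + 0.5 * h * a2[2], r + 0.5 * h * a2[3])
        a4 = rhs(s + h * a3[0], e + h * a3[1], i + h * a3[2], r + h * a3[3])
        s += (h / 6.0) * (a1[0] + 2.0 * (a2[0] + a3[0]) + a4[0])
        e += (h / 6.0) * (a1[1] + 2.0 * (a2[1] + a3[1]) + a4[1])
        i += (h / 6.0) * (a1[2] + 2.0 * (a2[2] + a3[2]) + a4[2])
        r += (h / 6.0) * (a1[3] + 2.0 * (a2[3] + a3[3]) + a4[3])
        out[k + 1] = (s, e, i, r)
    tau = np.arange(n + 1, dtype=float) * h
    return CompartmentSeries(tau, out[:, 0], out[:, 1], out[:, 2], out[:, 3])


def integrate_sir(
    params: EpidemicParams,
    *,
    horizon: float,
    step: Optional[float] = None,
) -> CompartmentSeries:
    """Integrate the dimensionless SIR model on [0, horizon] (e identically 0)."""
    if step is None:
        step = default_step(0.0)
    n, h = _grid(float(horizon), float(step))
    r0 = params.r0

    def rhs(s, i, r):
        inf = r0 * s * i
        return -inf, inf - i, i

    s, i, r = params.s0, params.m0, 0.0
    out = np.empty((n + 1, 3))
    out[0] = (s, i, r)
    for k in range(n):
        a1 = rhs(s, i, r)
        a2 = rhs(s + 0.5 * h * a1[0], i + 0.5 * h * a1[1], r + 0.5 * h * a1[2])
        a3 = rhs(s + 0.5 * h * a2[0], i + 0.5 * h * a2[1], r + 0.5 * h * a2[2])
        a4 = rhs(s + h * a3[0], i + h * a3[1], r + h * a3[2])
        s += (h / 6.0) * (a1[0] + 2.0 * (a2[0] + a3[0]) + a4[0])
        i += (h / 6.0) * (a1[1] + 2.0 * (a2[1] + a3[1]) + a4[1])
        r += (h / 6.0) * (a1[2] + 2.0 * (a2[2] + a3[2]) + a4[2])
        out[k + 1] = (s, i, r)
    tau = np.arange(n + 1, dtype=float) * h
    zeros = np.zeros(n + 1)
    return CompartmentSeries(tau, out[:, 0], zeros, out[:, 1], out[:, 2])
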