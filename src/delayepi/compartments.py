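"""Recover compartment time series from the cumulative function.

All four classes are algebraic reads of the single state m(tau):

    s(tau) = 1 - m(tau + tau_i)          (advanced: infected-but-latent
    e(tau) = m(tau + tau_i) - m(tau)      individuals surface at tau + tau_i)
    i(tau) = m(tau) - m(tau - 1)
    r(tau) = m(tau - 1)

With tau_i = 0 the exposed class vanishes and the relations reduce to the
single-delay (SIR-like) ones.  All delayed/advanced reads use the same
linear interpolation as the solver, so the closed-population constraint
s + e + i + r = 1 telescopes exactly at every grid point.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import ContractViolationError
from .params import CompartmentSeries, Trajectory

__all__ = ["recover_compartments", "infectious_series", "recovered_series"]


def recover_compartments(traj: Trajectory) -> CompartmentSeries:
    """Compartment fractions on [0, horizon].

    The trajectory must extend to horizon + tau_i (the solver guarantees
    this) because s and e read m at advanced times.
    """
    h = traj.step
    tau_i = traj.params.tau_i
    if traj.tau_grid[-1] + 1e-9 < traj.horizon + tau_i:
        raise ContractViolationError(
            "trajectory must extend to horizon + tau_i to recover s and e"
        )
    n = int(round(traj.horizon / h))
    tau = traj.tau_grid[: n + 1]
    m_now = traj.m_values[: n + 1]
    m_adv = traj.evaluate(tau + tau_i) if tau_i > 0 else m_now
    m_lag = traj.evaluate(tau - 1.0)
    return CompartmentSeries(
        tau_grid=tau,
        s=1.0 - m_adv,
        e=m_adv - m_now,
        i=m_now - m_lag,
        r=m_lag,
    )


def infectious_series(traj: Trajectory) -> pd.Series:
    """i(tau) = m(tau) - m(tau - 1) as a tau-indexed series."""
    return recover_compartments(traj).series("i")


def recovered_series(traj: Trajectory) -> pd.Series:
    """r(tau) = m(tau - 1) as a tau-indexed series."""
    return recover_compartments(traj).series("r")
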