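"""Parameter containers and shared series types.

Every model in this package works in dimensionless time ``tau``, measured in
units of the mean recovery time ``t_R``.  Transmission enters through the
basic reproduction number ``R0 = beta * t_R`` and the incubation (latent)
period through the dimensionless delay ``tau_i = t_I / t_R``.  The single
state variable of the delay models is the cumulative function ``m(tau)``:
the fraction of the population that is or has been infectious, i.e.
``(I + R) / N``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import ContractViolationError, InvalidParameterError

__all__ = [
    "EpidemicParams",
    "DimensionalParams",
    "HistorySpec",
    "Trajectory",
    "CompartmentSeries",
    "to_dimensionless",
    "to_dimensional",
    "load_config",
    "CONFIG_KEYS",
]

#: keys accepted in a flat YAML/JSON configuration file
CONFIG_KEYS = ("r0", "tau_i", "s0", "epsilon", "horizon", "step")


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class EpidemicParams:
    """Dimensionless epidemic parameters.

    Parameters
    ----------
    r0 : float
        Basic reproduction number, >= 0.
    tau_i : float
        Incubation delay in units of the recovery time, >= 0.  ``tau_i = 0``
        recovers the single-delay (NRD / SIR-like) models.
    s0 : float
        Initial susceptible fraction, in (0, 1].  The initial cumulative
        fraction is always ``m0 = 1 - s0`` (never stored separately, so the
        closed-population constraint holds exactly).
    epsilon : float
        Endemic cutoff fraction used to declare the outbreak over, in (0, 1).
    """

    r0: float
    tau_i: float = 0.0
    s0: float = 0.995
    epsilon: float = 0.0005

    def __post_init__(self) -> None:
        for name in ("r0", "tau_i", "s0", "epsilon"):
            object.__setattr__(self, name, _check_finite(name, getattr(self, name)))
        if self.r0 < 0:
            raise InvalidParameterError(f"r0 must be >= 0, got {self.r0}")
        if self.tau_i < 0:
            raise InvalidParameterError(f"tau_i must be >= 0, got {self.tau_i}")
        if not (0.0 < self.s0 <= 1.0):
            raise InvalidParameterError(f"s0 must be in (0, 1], got {self.s0}")
        if not (0.0 < self.epsilon < 1.0):
            raise InvalidParameterError(f"epsilon must be in (0, 1), got {self.epsilon}")

    @property
    def m0(self) -> float:
        """Initial cumulative fraction, identically ``1 - s0``."""
        return 1.0 - self.s0

    def with_tau_i(self, tau_i: float) -> "EpidemicParams":
        return replace(self, tau_i=tau_i)


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional epidemic parameters; unit-agnostic (time unit must simply
    be consistent between ``beta_rate``, ``t_r`` and ``t_i``).

    Parameters
    ----------
    n : float
        Population size, >= 1.
    beta_rate : float
        Effective infection rate (1/time), >= 0.
    t_r : float
        Average recovery time, > 0; the natural time scale of the models.
    t_i : float
        Average latent (incubation) period, >= 0.
    s0_count : float
        Initial number of susceptible individuals, 0 < s0_count <= n.
    """

    n: float
    beta_rate: float
    t_r: float
    t_i: float
    s0_count: float

    def __post_init__(self) -> None:
        for name in ("n", "beta_rate", "t_r", "t_i", "s0_count"):
            object.__setattr__(self, name, _check_finite(name, getattr(self, name)))
        if self.n < 1:
            raise InvalidParameterError(f"population size must be >= 1, got {self.n}")
        if self.t_r <= 0:
            raise InvalidParameterError(f"recovery time t_r must be > 0, got {self.t_r}")
        if self.t_i < 0:
            raise InvalidParameterError(f"latent period t_i must be >= 0, got {self.t_i}")
        if self.beta_rate < 0:
            raise InvalidParameterError(f"beta_rate must be >= 0, got {self.beta_rate}")
        if self.s0_count > self.n:
            raise InvalidParameterError(
                f"initial susceptibles ({self.s0_count}) exceed population ({self.n})"
            )
        if self.s0_count <= 0:
            raise InvalidParameterError("initial susceptibles must be positive")


def to_dimensionless(dp: DimensionalParams, epsilon: float = 0.0005) -> EpidemicParams:
    """Nondimensionalize: R0 = beta*t_R, tau_i = t_I/t_R, s0 = S0/N."""
    return EpidemicParams(
        r0=dp.beta_rate * dp.t_r,
        tau_i=dp.t_i / dp.t_r,
        s0=dp.s0_count / dp.n,
        epsilon=epsilon,
    )


def to_dimensional(params: EpidemicParams, n: float, t_r: float) -> DimensionalParams:
    """Inverse of :func:`to_dimensionless` given the population size and the
    recovery time (both lost in the dimensionless form)."""
    if t_r <= 0:
        raise InvalidParameterError(f"recovery time t_r must be > 0, got {t_r}")
    return DimensionalParams(
        n=n,
        beta_rate=params.r0 / t_r,
        t_r=t_r,
        t_i=params.tau_i * t_r,
        s0_count=params.s0 * n,
    )


def _zero_history(tau: float) -> float:
    return 0.0


@dataclass(frozen=True)
class HistorySpec:
    """Pre-epidemic history of the cumulative function.

    ``m_pre`` gives m(tau) on the half-open interval [-(1 + tau_i), 0); the
    value at tau = 0 is ``m_at_zero`` (defaults to m0 of the parameters in
    use), so the default history is the unit-jump seeding: m = 0 before the
    outbreak, m(0) = m0 = 1 - s0.

    The history is a function object rather than an array so that arbitrary
    (nondecreasing, [0, 1]-valued) user histories are accepted.
    """

    m_pre: Callable[[float], float] = _zero_history
    m_at_zero: Optional[float] = None

    def value_at_zero(self, params: EpidemicParams) -> float:
        return params.m0 if self.m_at_zero is None else float(self.m_at_zero)


@dataclass(frozen=True)
class Trajectory:
    """Solved cumulative function m(tau) on a uniform grid.

    The grid runs from 0 to at least ``horizon + tau_i`` (the solver extends
    the run so that the susceptible/exposed compartments, which need advanced
    values of m, are recoverable on [0, horizon]).
    """

    tau_grid: np.ndarray
    m_values: np.ndarray
    params: EpidemicParams
    history: HistorySpec
    horizon: float

    @property
    def step(self) -> float:
        return float(self.tau_grid[1] - self.tau_grid[0])

    def evaluate(self, tau: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Evaluate m at arbitrary times in [-(1 + tau_i), grid end].

        Negative arguments are served by the history function; tau = 0 maps
        to the stored jump value m(0); positive arguments are linearly
        interpolated between grid nodes (exact at the nodes).
        """
        arr = np.atleast_1d(np.asarray(tau, dtype=float))
        lo = -(1.0 + self.params.tau_i)
        hi = float(self.tau_grid[-1])
        if np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
            raise ContractViolationError(
                f"m(tau) requested outside [{lo}, {hi}]"
            )
        out = np.empty_like(arr)
        neg = arr < 0
        if np.any(neg):
            out[neg] = [float(self.history.m_pre(t)) for t in arr[neg]]
        if np.any(~neg):
            out[~neg] = np.interp(arr[~neg], self.tau_grid, self.m_values)
        if np.isscalar(tau) or np.ndim(tau) == 0:
            return float(out[0])
        return out

    __call__ = evaluate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.tau_grid, "m": self.m_values})

    def m_series(self) -> pd.Series:
        return pd.Series(self.m_values, index=self.tau_grid, name="m")


@dataclass(frozen=True)
class CompartmentSeries:
    """Susceptible/exposed/infectious/recovered fractions on a uniform grid."""

    tau_grid: np.ndarray
    s: np.ndarray
    e: np.ndarray
    i: np.ndarray
    r: np.ndarray

    @property
    def step(self) -> float:
        return float(self.tau_grid[1] - self.tau_grid[0])

    def series(self, name: str) -> pd.Series:
        return pd.Series(getattr(self, name), index=self.tau_grid, name=name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.tau_grid, "s": self.s, "e": self.e, "i": self.i, "r": self.r}
        )


def load_config(path: Union[str, Path]) -> dict:
    """Load a flat key:value run configuration (YAML or JSON).

    Accepted keys (all optional): r0, tau_i, s0, epsilon, horizon, step.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise InvalidParameterError(f"config {path} must be a flat mapping")
    unknown = set(data) - set(CONFIG_KEYS)
    if unknown:
        raise InvalidParameterError(
            f"unknown config keys {sorted(unknown)}; allowed: {list(CONFIG_KEYS)}"
        )
    return {k: float(v) for k, v in data.items() if v is not None}
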