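"""Epidemic summary statistics.

Final size r_inf, outbreak duration tau_D at an endemic cutoff epsilon,
infectious-curve peak, and the early-time exponential growth rate.  All
operate on tau-indexed pandas Series (as produced by the compartments
module) or on :class:`~delayepi.params.CompartmentSeries`.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import ConvergenceError, InvalidParameterError, InvalidWindowError
from .params import CompartmentSeries, EpidemicParams, Trajectory

__all__ = [
    "final_size",
    "epidemic_duration",
    "peak",
    "estimate_initial_growth",
    "cumulative_excess_series",
    "prepeak_local_maxima",
    "oscillation_count",
    "growth_fit_window",
    "summarize",
]

SeriesLike = Union[pd.Series, Tuple[np.ndarray, np.ndarray]]


def _as_series(obj, name: str) -> pd.Series:
    if isinstance(obj, CompartmentSeries):
        return obj.series(name)
    if isinstance(obj, pd.Series):
        return obj
    tau, vals = obj
    return pd.Series(np.asarray(vals, float), index=np.asarray(tau, float), name=name)


def final_size(cs: Union[CompartmentSeries, pd.Series], tol: float = 1e-8) -> float:
    """Asymptotic recovered fraction r_inf.

    Returns r at the final grid point, after checking that r has settled:
    the change over the last unit of dimensionless time must be below
    ``tol``.  A non-converged horizon raises :class:`ConvergenceError`
    rather than returning a silently biased value.
    """
    r = _as_series(cs, "r")
    tau = r.index.to_numpy()
    h = tau[1] - tau[0]
    back = int(round(1.0 / h))
    if back >= len(r):
        raise ConvergenceError("horizon shorter than one recovery time; extend horizon")
    drift = abs(float(r.iloc[-1]) - float(r.iloc[-1 - back]))
    if drift >= tol:
        raise ConvergenceError(
            f"final size not converged (|r(T) - r(T-1)| = {drift:.3e} >= {tol:.1e}); "
            "extend horizon"
        )
    return float(r.iloc[-1])


def epidemic_duration(i_series: Union[CompartmentSeries, pd.Series], epsilon: float) -> float:
    """Outbreak duration tau_D: the LAST down-crossing of the cutoff.

    tau_D is the largest tau with i(tau) >= epsilon, refined by linear
    interpolation between the bracketing grid points.  With self-excited
    oscillations i may cross epsilon several times; taking the final
    crossing matches the reading that the outbreak is over only once i
    stays below the tolerable endemic level for good.

    Returns 0.0 (the designated "no-epidemic" result) when i never reaches
    epsilon; raises :class:`ConvergenceError` when i is still at or above
    epsilon at the end of the horizon.
    """
    if epsilon <= 0:
        raise InvalidParameterError(f"epsilon must be > 0, got {epsilon}")
    i = _as_series(i_series, "i")
    tau = i.index.to_numpy()
    vals = i.to_numpy()
    if vals[-1] >= epsilon:
        raise ConvergenceError(
            "i still at or above epsilon at the end of the horizon; extend horizon"
        )
    above = np.nonzero(vals >= epsilon)[0]
    if len(above) == 0:
        return 0.0
    k = int(above[-1])  # vals[k] >= eps > vals[k+1]
    frac = (vals[k] - epsilon) / (vals[k] - vals[k + 1])
    return float(tau[k] + frac * (tau[k + 1] - tau[k]))


def peak(i_series: Union[CompartmentSeries, pd.Series]) -> Tuple[float, float]:
    """Global maximum of the infectious curve, earliest tau on ties."""
    i = _as_series(i_series, "i")
    idx = int(np.argmax(i.to_numpy()))
    return float(i.index[idx]), float(i.iloc[idx])


def estimate_initial_growth(
    series: Union[CompartmentSeries, pd.Series],
    fit_window: Tuple[float, float],
) -> float:
    """Least-squares slope of ln(value) versus tau on the fit window.

    The window should sit in the early regime where s is still close to 1;
    for oscillatory runs a window spanning a few oscillation periods
    averages the superimposed ripple out of the slope.
    """
    ser = _as_series(series, "value")
    lo, hi = fit_window
    mask = (ser.index >= lo) & (ser.index <= hi)
    if mask.sum() < 2:
        raise InvalidWindowError(f"fit window {fit_window} covers fewer than 2 grid points")
    vals = ser.to_numpy()[mask]
    if np.any(vals <= 0):
        raise InvalidWindowError(f"nonpositive values inside fit window {fit_window}")
    tau = ser.index.to_numpy()[mask]
    slope = np.polyfit(tau, np.log(vals), 1)[0]
    return float(slope)


def cumulative_excess_series(traj: Trajectory) -> pd.Series:
    """m(tau) - m0 on the requested window: the quantity whose early-time
    log-slope is the growth exponent of the exponential ansatz."""
    n = int(round(traj.horizon / traj.step))
    tau = traj.tau_grid[: n + 1]
    return pd.Series(traj.m_values[: n + 1] - traj.params.m0, index=tau, name="m_excess")


def prepeak_local_maxima(
    i_series: Union[CompartmentSeries, pd.Series],
    prominence: float = 1e-9,
    start: float = 0.0,
) -> int:
    """Count local maxima of i(tau) strictly before its global peak.

    Used to detect self-excited oscillations superimposed on the epidemic
    bell.  The tiny default prominence floor only filters floating-point
    ripple, not genuine undulations; ``start`` discards maxima at or before
    that time.
    """
    i = _as_series(i_series, "i")
    vals = i.to_numpy()
    tau = i.index.to_numpy()
    peak_idx = int(np.argmax(vals))
    if peak_idx < 2:
        return 0
    idx, _ = find_peaks(vals[:peak_idx], prominence=prominence)
    return int(np.sum(tau[idx] > start))


def oscillation_count(
    i_series: Union[CompartmentSeries, pd.Series],
    tau_i: float,
    rel_prominence: float = 0.01,
) -> int:
    """Count genuine self-excited oscillations in the infectious curve.

    Counts pre-peak local maxima of i(tau), excluding the structural echo
    at tau <= tau_i + 1 — the initial seed cohort recovering, which
    produces a maximum in every jump-history run regardless of the
    oscillation regime — and requiring a prominence of at least
    ``rel_prominence`` times the global peak, so that grid-level ripple is
    not mistaken for an undulation.
    """
    i = _as_series(i_series, "i")
    i_peak = float(np.max(i.to_numpy()))
    if i_peak <= 0:
        return 0
    return prepeak_local_maxima(
        i, prominence=rel_prominence * i_peak, start=tau_i + 1.0
    )


def growth_fit_window(
    me_series: pd.Series,
    m0: float,
    lo_mult: float = 50.0,
    hi_level: float = 0.01,
) -> Tuple[float, float]:
    """Fit window for the early-time growth exponent of m - m0.

    The lower edge is where m - m0 first exceeds ``lo_mult * m0`` (the
    transient excited by the jump history has decayed relative to the
    seed); the upper edge is where m - m0 reaches ``hi_level`` (s is still
    >= 1 - hi_level - m0, so the linearized regime holds).  Raises
    :class:`InvalidWindowError` if the run never spans that range.
    """
    tau = me_series.index.to_numpy()
    vals = me_series.to_numpy()
    lo_level = lo_mult * m0
    if lo_level >= hi_level:
        raise InvalidWindowError(
            f"window levels cross: {lo_mult}*m0 = {lo_level} >= {hi_level}"
        )
    if vals[-1] < hi_level:
        raise InvalidWindowError(
            "m - m0 never reaches the upper window level; extend horizon or lower hi_level"
        )
    lo = float(tau[np.argmax(vals >= lo_level)])
    hi = float(tau[np.argmax(vals >= hi_level)])
    if hi <= lo:
        raise InvalidWindowError("degenerate growth window; growth too fast for the grid")
    return lo, hi


def summarize(
    cs: CompartmentSeries,
    params: EpidemicParams,
    epsilon: Optional[float] = None,
    growth_window: Optional[Tuple[float, float]] = None,
) -> dict:
    """Metric report for one run: {r_inf, tau_d, tau_peak, i_peak,
    growth_slope, epsilon, params}.  Non-converged metrics are reported as
    None with the error message in an 'errors' entry."""
    eps = params.epsilon if epsilon is None else epsilon
    report: dict = {
        "epsilon": eps,
        "params": {"r0": params.r0, "tau_i": params.tau_i, "s0": params.s0},
        "errors": {},
    }
    tau_pk, i_pk = peak(cs)
    report["tau_peak"] = tau_pk
    report["i_peak"] = i_pk
    try:
        report["r_inf"] = final_size(cs)
    except ConvergenceError as exc:
        report["r_inf"] = None
        report["errors"]["r_inf"] = str(exc)
    try:
        report["tau_d"] = epidemic_duration(cs, eps)
    except ConvergenceError as exc:
        report["tau_d"] = None
        report["errors"]["tau_d"] = str(exc)
    if growth_window is not None:
        try:
            report["growth_slope"] = estimate_initial_growth(_as_series(cs, "i"), growth_window)
        except InvalidWindowError as exc:
            report["growth_slope"] = None
            report["errors"]["growth_slope"] = str(exc)
    else:
        report["growth_slope"] = None
    return report
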