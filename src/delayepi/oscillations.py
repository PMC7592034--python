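"""Linearized analysis of self-excited oscillations in the two-delay model.

Linearizing the DDE around s ~ 1 and inserting the ansatz

    m(tau) ~ A e^{(alpha + i omega) tau} + B e^{beta tau}

yields the transcendental characteristic relations

    (alpha + i omega) e^{(alpha + i omega) tau_i} / R0 = 1 - e^{-(alpha + i omega)}
    beta e^{beta tau_i} / (1 - e^{-beta}) = R0 .

With the empirically justified approximation alpha ~ 0, the oscillatory
branch reduces to a sinc condition

    sin(omega tau_i) / (omega tau_i) = -1/(2 R0 tau_i) = -gamma_coef ,

which has solutions only when gamma_coef is smaller than gamma0 ~ 0.2172,
the magnitude of the global minimum of sin(x)/x.  That gives the onset
threshold tau_i^(c) = 1/(2 gamma0 R0): no self-excited oscillations below
it, and in particular none at all in the single-delay (tau_i = 0) model.

Naming: the literature reuses beta (infection rate vs growth exponent) and
gamma (recovery rate vs the sinc-condition constant); here they are
``beta_rate``/``beta_exp`` and ``gamma_coef`` respectively.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Tuple

from scipy.optimize import bisect, brentq, minimize

from .exceptions import InvalidParameterError, OutOfRegimeError

__all__ = [
    "GrowthMode",
    "sinc",
    "gamma0",
    "sinc_min_location",
    "critical_tau_I",
    "oscillation_frequencies",
    "growth_exponent_beta",
    "tau_I_from_beta",
    "characteristic_residual",
    "refine_mode",
    "analyze",
    "growth_mode",
]


def sinc(x: float) -> float:
    """sin(x)/x with the removable singularity sinc(0) = 1."""
    if x == 0.0:
        return 1.0
    return math.sin(x) / x


@lru_cache(maxsize=1)
def sinc_min_location() -> float:
    """Location x* of the global minimum of sin(x)/x over x > 0.

    The minimum sits in the first negative lobe, at the stationarity
    condition tan(x) = x on (pi, 3pi/2); solved by bracketed root finding
    to 1e-12."""
    return float(
        brentq(lambda x: math.tan(x) - x, math.pi + 1e-9, 1.5 * math.pi - 1e-9, xtol=1e-12)
    )


def gamma0() -> float:
    """Magnitude of the global minimum of sin(x)/x (about 0.2172).

    Sets the oscillation-onset threshold: the sinc condition has solutions
    only for gamma_coef < gamma0."""
    x = sinc_min_location()
    return abs(sinc(x))


def critical_tau_I(r0: float) -> float:
    """Onset threshold tau_i^(c) = 1/(2 gamma0 R0): below it the linearized
    model has no oscillatory modes."""
    if r0 <= 0:
        raise InvalidParameterError(f"r0 must be > 0, got {r0}")
    return 1.0 / (2.0 * gamma0() * r0)


def oscillation_frequencies(
    r0: float, tau_i: float, omega_max: Optional[float] = None
) -> List[float]:
    """All angular frequencies omega in (0, omega_max] of the alpha ~ 0
    oscillatory modes, ascending.

    Roots of sin(omega tau_i)/(omega tau_i) = -gamma_coef, located by a
    uniform sign-change scan in x = omega tau_i (step pi/1000, finer than
    any sinc lobe) and refined by bisection to ~1e-10.  Empty when
    tau_i = 0 (no second delay, hence no oscillations) or when tau_i is
    below the onset threshold.
    """
    if tau_i < 0:
        raise InvalidParameterError(f"tau_i must be >= 0, got {tau_i}")
    if r0 <= 0 or tau_i == 0.0:
        return []
    gamma_coef = 1.0 / (2.0 * r0 * tau_i)
    if gamma_coef >= gamma0():
        return []
    if omega_max is None:
        omega_max = 20.0 * math.pi / tau_i
    x_max = omega_max * tau_i

    def f(x: float) -> float:
        return sinc(x) + gamma_coef

    step = math.pi / 1000.0
    roots: List[float] = []
    x_prev = step
    f_prev = f(x_prev)
    n_steps = int(math.ceil(x_max / step))
    for k in range(2, n_steps + 1):
        x_cur = min(k * step, x_max)
        f_cur = f(x_cur)
        if f_prev == 0.0:
            roots.append(x_prev)
        elif f_prev * f_cur < 0.0:
            roots.append(float(bisect(f, x_prev, x_cur, xtol=1e-12)))
        x_prev, f_prev = x_cur, f_cur
    return [x / tau_i for x in roots if 0.0 < x / tau_i <= omega_max]


def _beta_lhs(beta: float, tau_i: float) -> float:
    # beta e^{beta tau_i} / (1 - e^{-beta}); continuous with limit 1 at 0+
    if beta == 0.0:
        return 1.0
    return beta * math.exp(beta * tau_i) / (1.0 - math.exp(-beta))


def growth_exponent_beta(r0: float, tau_i: float) -> float:
    """Real growth exponent beta > 0 of the non-oscillatory mode.

    Unique positive root of beta e^{beta tau_i}/(1 - e^{-beta}) = R0; the
    left-hand side tends to 1 as beta -> 0+ and is strictly increasing for
    tau_i >= 0, so a root exists iff R0 > 1 (the epidemic regime).
    Bracketed root finding to ~1e-12.
    """
    if tau_i < 0:
        raise InvalidParameterError(f"tau_i must be >= 0, got {tau_i}")
    if r0 <= 1.0:
        raise OutOfRegimeError(
            f"growth exponent defined only in the epidemic regime R0 > 1, got R0 = {r0}"
        )

    def g(b: float) -> float:
        return _beta_lhs(b, tau_i) - r0

    lo = 1e-12
    hi = 1.0
    while g(hi) < 0.0:
        hi *= 2.0
        if hi > 1e6:  # unreachable for finite r0
            raise OutOfRegimeError("failed to bracket the growth exponent")
    return float(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16))


def tau_I_from_beta(beta_exp: float, r0: float) -> float:
    """Incubation delay with growth exponent ``beta_exp`` at the given R0:
    tau_i = ln[(1 - e^{-beta}) R0 / beta] / beta.

    Defined only while beta/(1 - e^{-beta}) < R0 (otherwise tau_i would be
    <= 0, i.e. the disease would have to appear before the infecting contact).
    Round-trips with :func:`growth_exponent_beta`.
    """
    if beta_exp <= 0:
        raise InvalidParameterError(f"beta_exp must be > 0, got {beta_exp}")
    if r0 <= 0:
        raise InvalidParameterError(f"r0 must be > 0, got {r0}")
    ratio = beta_exp / (1.0 - math.exp(-beta_exp))
    if ratio >= r0:
        raise OutOfRegimeError(
            f"constraint beta/(1 - e^-beta) < R0 violated ({ratio:.6g} >= {r0:.6g}); "
            "tau_i would be <= 0"
        )
    return math.log(r0 / ratio) / beta_exp


def characteristic_residual(alpha: float, omega: float, r0: float, tau_i: float) -> float:
    """Magnitude of the full (unsquared) characteristic relation at
    lambda = alpha + i omega:

        | lambda e^{lambda tau_i} / R0 - (1 - e^{-lambda}) | .

    The sinc-condition roots assume alpha = 0, so their residual here is
    small but generally nonzero; a genuinely complex root drives it to ~0.
    At a real root (omega = 0, alpha = beta) this reduces exactly to the
    real-branch residual.
    """
    lam = complex(alpha, omega)
    res = lam * cmath.exp(lam * tau_i) / r0 - (1.0 - cmath.exp(-lam))
    return abs(res)


def refine_mode(
    r0: float,
    tau_i: float,
    omega_seed: float,
    alpha_seed: float = 0.0,
) -> Tuple[float, float, float]:
    """Refine an oscillatory mode (alpha, omega) by minimizing the full
    characteristic residual, seeded at the alpha = 0 sinc-condition root.

    Returns (alpha, omega, residual)."""
    res = minimize(
        lambda p: characteristic_residual(p[0], p[1], r0, tau_i),
        [alpha_seed, omega_seed],
        method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 5000},
    )
    alpha, omega = float(res.x[0]), float(res.x[1])
    return alpha, omega, characteristic_residual(alpha, omega, r0, tau_i)


@dataclass(frozen=True)
class GrowthMode:
    """Linearized early-time modes at a given (R0, tau_i).

    beta_exp is the real growth exponent (None outside the epidemic
    regime); alpha and omega describe the dominant oscillatory mode under
    the alpha ~ 0 approximation (omega is None below the onset threshold).
    The ansatz amplitudes are set by the history and are not solved for.
    """

    r0: float
    tau_i: float
    beta_exp: Optional[float]
    alpha: float
    omega: Optional[float]
    gamma_coef: Optional[float]
    gamma0: float


def analyze(r0: float, tau_i: float, omega_max: Optional[float] = None) -> dict:
    """Oscillation report for one (R0, tau_i): threshold, frequencies, and
    growth exponent, as a JSON-serializable dict."""
    omegas = oscillation_frequencies(r0, tau_i, omega_max)
    try:
        beta = growth_exponent_beta(r0, tau_i)
    except OutOfRegimeError:
        beta = None
    return {
        "r0": r0,
        "tau_i": tau_i,
        "tau_i_critical": critical_tau_I(r0),
        "oscillatory": len(omegas) > 0,
        "omegas": omegas,
        "beta_exp": beta,
    }


def growth_mode(r0: float, tau_i: float) -> GrowthMode:
    """Bundle the linearized-mode quantities into a :class:`GrowthMode`."""
    omegas = oscillation_frequencies(r0, tau_i)
    try:
        beta = growth_exponent_beta(r0, tau_i)
    except OutOfRegimeError:
        beta = None
    return GrowthMode(
        r0=r0,
        tau_i=tau_i,
        beta_exp=beta,
        alpha=0.0,
        omega=omegas[0] if omegas else None,
        gamma_coef=1.0 / (2.0 * r0 * tau_i) if tau_i > 0 and r0 > 0 else None,
        gamma0=gamma0(),
    )
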