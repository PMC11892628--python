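"""Closed-form Nash-equilibrium solution of the SIR social-distancing game.

In recovered-fraction coordinates the susceptible curve of the equilibrium
epidemic obeys the Riccati equation

    ds/dr = -s (a + b r + b s),     a = R0 - b,   b = alpha * sf / 2,

whose solution (via w = 1/s, which linearizes the equation and is solved
with the integrating factor exp(-a r - b r^2 / 2)) is an error-function
expression.  The final susceptible fraction sf enters its own coefficients,
so it is pinned down self-consistently as the root of sf = s(1 - sf).

From s(r) everything else follows in closed form: the infected fraction
i = 1 - r - s, the equilibrium control k = R0 - (alpha sf / 2) i (distancing
proportional to both prevalence and infection cost), the costates
vs = -alpha (s - sf)/s and vi = -alpha, and the physical time via
t = integral dr' / i(r').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import IntegrationWarning, quad
from scipy.optimize import brentq
from scipy.special import erf, erfcx

from .model_core import Trajectory
from .params import ModelParams

__all__ = [
    "AnalyticCoefficients",
    "susceptible_of_r",
    "solve_self_consistent_sf",
    "equilibrium_control",
    "costate_fields",
    "time_of_r",
    "r_of_time",
    "assemble_equilibrium_trajectory",
]

#: default endpoint cap: the trajectory is truncated where i first falls
#: below this value on the declining branch (the 1/i time integrand
#: diverges at r = rf where i -> 0)
I_CAP = 1e-6


@dataclass
class AnalyticCoefficients:
    """Derived constants of the closed-form equilibrium.

    a = R0 - b and b = alpha*sf/2 are the Riccati coefficients; sf and
    rf = 1 - sf are the final susceptible/recovered fractions; mu is the
    costate integration constant mu = alpha*sf/s0.
    """

    a: float
    b: float
    sf: float
    rf: float
    mu: float

    def K_of_r(self, r, params: ModelParams):
        """Cumulative transmission K(r) = integral of k dr', via K = -ln(s/s0).

        Stored implicitly through the closed-form susceptible curve rather
        than by separate quadrature: s = s0 e^{-K(r)} is exact.
        """
        return -np.log(susceptible_of_r(r, self, params) / params.s0)


def _gauss_segment(x: np.ndarray, x0: float) -> np.ndarray:
    """e^{x^2} * integral_{x0}^{x} e^{-u^2} du, overflow-safe.

    Naive evaluation via e^{x0^2}(erf(x) - erf(x0)) overflows once
    |x0| ~ 30 (high infection cost makes a = R0 - b large negative and the
    erf arguments large).  Each sign configuration is rewritten in terms of
    the scaled complementary error function erfcx(z) = e^{z^2} erfc(z) of
    *positive* arguments, so every factor stays bounded: the surviving
    exponentials e^{x^2 - x0^2} equal e^{G(r)} with G <= 0 on the branch
    where they appear.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    sp = np.sqrt(np.pi) / 2.0

    neg = x <= 0.0  # then x0 <= x <= 0
    if np.any(neg):
        xn = x[neg]
        out[neg] = sp * (erfcx(-xn) - np.exp(xn * xn - x0 * x0) * erfcx(-x0))
    if x0 >= 0.0:
        pos = ~neg
        if np.any(pos):
            xp = x[pos]
            out[pos] = sp * (np.exp(xp * xp - x0 * x0) * erfcx(x0) - erfcx(xp))
    else:
        # mixed sign: x0 < 0 < x only occurs with b > R0, where
        # 0 < x < R0/sqrt(2b) < sqrt(R0/2); e^{x^2} is then harmless.
        mix = ~neg
        if np.any(mix):
            xm = x[mix]
            out[mix] = np.exp(xm * xm) * sp * (erf(xm) - erf(x0))
    return out


def susceptible_of_r(r, coeffs: AnalyticCoefficients, params: ModelParams, *, _check: bool = True):
    """Equilibrium susceptible fraction s(r) in recovered coordinates.

    Valid for r in [r0, rf]; satisfies s(r0) = s0 and reduces to the
    classic s0 e^{-R0 (r - r0)} when the infection cost vanishes (b = 0).
    """
    a, b = coeffs.a, coeffs.b
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if b < 0.0:
        raise ValueError(f"coefficient b must be non-negative, got {b}")
    if _check and (np.any(r < params.r0 - 1e-12) or np.any(r > coeffs.rf + 1e-9)):
        raise ValueError(
            f"r must lie in [r0, rf] = [{params.r0:.3g}, {coeffs.rf:.6g}]"
        )
    s0, r0 = params.s0, params.r0
    if b == 0.0:
        s = s0 * np.exp(-params.R0 * (r - r0))
    else:
        sq = np.sqrt(2.0 * b)
        x = (a + b * r) / sq
        x0 = (a + b * r0) / sq
        G = a * (r - r0) + 0.5 * b * (r * r - r0 * r0)  # = x^2 - x0^2
        w = np.exp(G) / s0 + sq * _gauss_segment(x, x0)  # w = 1/s
        s = 1.0 / w
    return float(s[0]) if scalar else s


def _sf_residual(x: float, params: ModelParams) -> float:
    """g(x) = x - s(1-x) with coefficients built from the trial sf = x."""
    b = params.alpha * x / 2.0
    trial = AnalyticCoefficients(a=params.R0 - b, b=b, sf=x, rf=1.0 - x, mu=np.nan)
    return x - susceptible_of_r(1.0 - x, trial, params, _check=False)


def solve_self_consistent_sf(params: ModelParams) -> AnalyticCoefficients:
    """Determine the final size sf and all derived constants.

    sf is the root of g(x) = x - s(1-x; b = alpha x/2) on (0, 1/R0]:
    bracketing bisection (the residual is negative at x -> 0+ and
    non-negative at the herd-immunity bound 1/R0) followed by a Newton
    polish to |g| < 1e-12.
    """
    if params.alpha < 0:
        raise ValueError("alpha must be non-negative")
    lo, hi = 1e-12, 1.0 / params.R0
    glo, ghi = _sf_residual(lo, params), _sf_residual(hi, params)
    if glo == 0.0:
        sf = lo
    elif ghi == 0.0:
        sf = hi
    elif glo * ghi > 0.0:
        raise RuntimeError(
            "no sign change when bracketing sf: "
            f"g({lo:.3g}) = {glo:.6g}, g(1/R0) = {ghi:.6g}"
        )
    else:
        sf = brentq(_sf_residual, lo, hi, args=(params,), xtol=1e-15, rtol=8.9e-16)
    # Newton polish (secant derivative; the closed form is smooth in x)
    for _ in range(3):
        g = _sf_residual(sf, params)
        if abs(g) < 1e-14:
            break
        h = max(1e-9 * sf, 1e-14)
        dg = (_sf_residual(sf + h, params) - g) / h
        step = g / dg
        if not np.isfinite(step) or abs(step) > 0.1 * sf:
            break
        sf -= step
    resid = _sf_residual(sf, params)
    if abs(resid) > 1e-12:
        raise RuntimeError(f"self-consistency residual {resid:.3e} exceeds 1e-12")
    b = params.alpha * sf / 2.0
    return AnalyticCoefficients(
        a=params.R0 - b, b=b, sf=sf, rf=1.0 - sf, mu=params.alpha * sf / params.s0
    )


def equilibrium_control(i, coeffs: AnalyticCoefficients, params: ModelParams):
    """Nash-equilibrium transmission rate k = R0 - (alpha sf / 2) i.

    The strength of distancing R0 - k is proportional to both prevalence
    and the infection cost: the central behavioral law of the model.
    """
    return params.R0 - coeffs.b * np.asarray(i, dtype=float)


def costate_fields(s, coeffs: AnalyticCoefficients, params: ModelParams):
    """Costates (vs, vi) along the equilibrium, as functions of s.

    vs = -alpha (s - sf)/s is the expected future infection cost of a
    susceptible individual ((s - sf)/s is their probability of eventually
    being infected); vi = -alpha is constant.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < coeffs.sf * (1.0 - 1e-9)):
        raise ValueError(f"s below the final size sf = {coeffs.sf:.6g}")
    vs = -params.alpha * (s - coeffs.sf) / s
    vi = np.full_like(vs, -params.alpha)
    if vs.ndim == 0:
        return float(vs), float(vi)
    return vs, vi


def _infected_of_r(r, coeffs: AnalyticCoefficients, params: ModelParams):
    return 1.0 - np.asarray(r) - susceptible_of_r(r, coeffs, params, _check=False)


def _r_cap(coeffs: AnalyticCoefficients, params: ModelParams, i_cap: float) -> float:
    """Largest r with i(r) = i_cap on the declining branch."""
    # bracket between the peak (i' = 0 at s k = 1) and rf where i -> 0
    f = lambda r: _infected_of_r(r, coeffs, params) - i_cap
    lo, hi = params.r0, coeffs.rf
    # the peak r: di/dr = s k - 1 = 0; bisect on the decreasing branch
    grid = np.linspace(lo, hi, 4097)
    iv = _infected_of_r(grid, coeffs, params)
    ipk = int(np.argmax(iv))
    if iv[ipk] <= i_cap:
        raise ValueError(f"epidemic never exceeds the cap i = {i_cap}")
    return brentq(f, grid[ipk], hi - 1e-15, xtol=1e-15)


def time_of_r(r: float, coeffs: AnalyticCoefficients, params: ModelParams) -> float:
    """Physical time t = F(r) = integral_{r0}^{r} dr' / i(r').

    The integrand 1/i diverges as r -> rf; requests too close to rf raise
    with instructions to cap (see ``assemble_equilibrium_trajectory``).
    """
    if r < params.r0:
        raise ValueError("r below r0")
    if r == params.r0:
        return 0.0
    if _infected_of_r(r, coeffs, params) < 0.5 * I_CAP:
        raise ValueError(
            "r is too close to rf (i(r) < 5e-7): the time integral diverges "
            "there; cap the trajectory at i = I_CAP instead"
        )
    with warnings.catch_warnings():
        # the 1/i integrand spans ~6 decades; quad flags roundoff near the
        # requested 1e-11 tolerance even though the result is converged
        warnings.simplefilter("ignore", IntegrationWarning)
        val, err = quad(
            lambda rr: 1.0 / _infected_of_r(rr, coeffs, params),
            params.r0,
            r,
            epsabs=1e-11,
            epsrel=1e-11,
            limit=400,
        )
    return float(val)


def r_of_time(t: float, coeffs: AnalyticCoefficients, params: ModelParams) -> float:
    """Inverse of the time map: recover r from t by bracketed root finding."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0.0:
        return params.r0
    hi = _r_cap(coeffs, params, I_CAP)
    t_hi = time_of_r(hi, coeffs, params)
    if t > t_hi:
        raise ValueError(f"t={t:.6g} beyond the capped endpoint t={t_hi:.6g}")
    return brentq(lambda r: time_of_r(r, coeffs, params) - t, params.r0, hi, xtol=1e-14)


def _clustered_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """Grid on [lo, hi] with cosine clustering toward both endpoints."""
    u = np.linspace(0.0, np.pi, n)
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(u))


def assemble_equilibrium_trajectory(
    params: ModelParams,
    n_points: int = 2001,
    i_cap: float = I_CAP,
    coeffs: AnalyticCoefficients | None = None,
) -> Trajectory:
    """Full (t, s, i, r, k) equilibrium trajectory from the closed form.

    The r-grid is clustered toward both endpoints (where i is small and
    the time map stiffens) and capped where i first falls below ``i_cap``
    on the declining branch.  Time is obtained by integrating dt/dr = 1/i
    with a high-order adaptive stepper evaluated on the grid.
    """
    if coeffs is None:
        coeffs = solve_self_consistent_sf(params)
    rc = _r_cap(coeffs, params, i_cap)
    rgrid = _clustered_grid(params.r0, rc, n_points)
    s = susceptible_of_r(rgrid, coeffs, params)
    i = 1.0 - rgrid - s
    k = equilibrium_control(i, coeffs, params)
    t = _cumulative_time(rgrid, coeffs, params)
    return Trajectory(t, s, i, rgrid, k)


# 10-point Gauss-Legendre rule on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(10)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _cumulative_time(rgrid: np.ndarray, coeffs: AnalyticCoefficients, params: ModelParams) -> np.ndarray:
    """t on the r-grid by composite Gauss-Legendre quadrature of 1/i(r).

    The grid is clustered where 1/i is steep (both endpoints), so a
    fixed-order panel rule per interval reaches ~1e-10 absolute error
    while staying fully vectorized over panels.
    """
    lo = rgrid[:-1]
    h = np.diff(rgrid)
    nodes = lo[:, None] + h[:, None] * _GL_X[None, :]
    integrand = 1.0 / _infected_of_r(nodes.ravel(), coeffs, params).reshape(nodes.shape)
    seg = h * (integrand * _GL_W[None, :]).sum(axis=1)
    t = np.empty(rgrid.size)
    t[0] = 0.0
    np.cumsum(seg, out=t[1:])
    return t


def summary_dict(params: ModelParams, coeffs: AnalyticCoefficients) -> dict:
    """JSON-ready summary of the closed-form constants."""
    return {
        "R0": params.R0,
        "alpha": params.alpha,
        "sf": coeffs.sf,
        "rf": coeffs.rf,
        "a": coeffs.a,
        "b": coeffs.b,
        "mu": coeffs.mu,
        "epsilon": 1.0 / params.R0 - coeffs.sf,
    }
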