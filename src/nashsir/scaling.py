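"""Limit formulas, crossover costs, regime classification, data collapse.

Two observables summarize an epidemic: the excess cases
epsilon = 1/R0 - sf (infections beyond the herd-immunity minimum) and the
infection peak i_hat = max i.  Both are constant at low infection cost
(nonbehavioral limit, Lambert-W final size) and decay like 1/alpha at high
cost.  Matching the branches defines crossover costs alpha_ex* and
alpha_peak* that organize the R0-alpha phase diagram and collapse the
curves for different R0 onto master curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import lambertw

from . import nash_analytic as na
from .params import ModelParams

__all__ = [
    "ScalingSummary",
    "nonbehavioral_limit",
    "high_cost_asymptotes",
    "crossover_costs",
    "classify_regime",
    "infection_peak",
    "summarize",
    "collapse_tables",
    "phase_table",
]

REGIMES = ("nonbehavioral", "peak-suppressing", "extended-distancing")


@dataclass
class ScalingSummary:
    """Headline quantities of one (R0, alpha) scenario."""

    epsilon: float
    i_peak: float
    t_peak: float
    alpha_ex_star: float
    alpha_peak_star: float
    regime: str


def _lambert_arg(params: ModelParams) -> float:
    return -params.s0 * params.R0 * np.exp(params.R0 * (params.r0 - 1.0))


def nonbehavioral_limit(params: ModelParams) -> tuple[float, float, float]:
    """(sf, epsilon, i_peak) of the constant-behavior epidemic (alpha = 0).

    sf = -W(-s0 R0 e^{R0 (r0-1)})/R0 on the principal branch of the
    Lambert W function; epsilon = (1 + W)/R0; the peak occurs where
    s = 1/R0, giving i_hat = 1 - r0 - (1 + ln(s0 R0))/R0.
    """
    arg = _lambert_arg(params)
    assert arg > -1.0 / np.e, "Lambert argument below the branch point"
    W = float(lambertw(arg).real)
    sf = -W / params.R0
    epsilon = (1.0 + W) / params.R0
    i_peak = 1.0 - params.r0 - (1.0 + np.log(params.s0 * params.R0)) / params.R0
    return sf, epsilon, i_peak


def high_cost_asymptotes(params: ModelParams) -> tuple[float, float]:
    """Large-alpha asymptotes (epsilon, i_peak) = (2R0^2/alpha, 2R0(R0-1)/alpha)."""
    if params.alpha == 0.0:
        raise ValueError("high-cost asymptote undefined at alpha = 0")
    eps = 2.0 * params.R0**2 / params.alpha
    ipk = 2.0 * params.R0 * (params.R0 - 1.0) / params.alpha
    return eps, ipk


def crossover_costs(params: ModelParams) -> tuple[float, float]:
    """(alpha_ex*, alpha_peak*): costs where low- and high-alpha branches meet.

    alpha_ex*  = 2 R0^3 / (1 + W(-s0 R0 e^{R0(r0-1)}))
    alpha_peak* = 2 R0^2 (R0-1) / (R0 (1-r0) - 1 - ln(s0 R0))
    """
    W = float(lambertw(_lambert_arg(params)).real)
    den_ex = 1.0 + W
    den_pk = params.R0 * (1.0 - params.r0) - 1.0 - np.log(params.s0 * params.R0)
    if den_ex <= 0.0 or den_pk <= 0.0:
        raise ValueError("crossover denominators must be positive (requires R0 > 1)")
    return 2.0 * params.R0**3 / den_ex, 2.0 * params.R0**2 * (params.R0 - 1.0) / den_pk


def classify_regime(R0: float, alpha: float, params: ModelParams | None = None) -> str:
    """Place (R0, alpha) in the behavioral phase diagram.

    alpha < alpha_peak*: distancing too weak to matter (nonbehavioral);
    alpha_peak* <= alpha <= alpha_ex*: the peak is suppressed but the
    final size barely moves (peak-suppressing); alpha > alpha_ex*:
    extended distancing with a real reduction in excess cases.  Ties go
    to the middle regime.
    """
    p = params.with_(R0=R0, alpha=alpha, s0=None, i0=None, r0=None) if params else ModelParams(R0=R0, alpha=alpha)
    a_ex, a_pk = crossover_costs(p)
    if alpha < a_pk:
        return "nonbehavioral"
    if alpha <= a_ex:
        return "peak-suppressing"
    return "extended-distancing"


def infection_peak(
    coeffs: na.AnalyticCoefficients, params: ModelParams
) -> tuple[float, float]:
    """(i_hat, t_hat) of the equilibrium epidemic, grid-independent.

    The interior maximum of i satisfies di/dt = 0, i.e. k(r) s(r) = 1;
    the crossing is located by root finding in r on the closed form and
    the time by the exact time map.
    """
    f = lambda r: (
        na.susceptible_of_r(r, coeffs, params, _check=False)
        * (params.R0 - coeffs.b * (1.0 - r - na.susceptible_of_r(r, coeffs, params, _check=False)))
        - 1.0
    )
    lo, hi = params.r0, coeffs.rf - 1e-13
    if f(lo) <= 0.0:  # no interior peak: epidemic declines from the start
        return params.i0, 0.0
    r_hat = brentq(f, lo, hi, xtol=1e-14)
    i_hat = 1.0 - r_hat - na.susceptible_of_r(r_hat, coeffs, params, _check=False)
    t_hat = na.time_of_r(r_hat, coeffs, params)
    return float(i_hat), float(t_hat)


def summarize(params: ModelParams) -> ScalingSummary:
    """Solve the equilibrium and report its scaling observables."""
    coeffs = na.solve_self_consistent_sf(params)
    i_hat, t_hat = infection_peak(coeffs, params)
    a_ex, a_pk = crossover_costs(params)
    return ScalingSummary(
        epsilon=1.0 / params.R0 - coeffs.sf,
        i_peak=i_hat,
        t_peak=t_hat,
        alpha_ex_star=a_ex,
        alpha_peak_star=a_pk,
        regime=classify_regime(params.R0, params.alpha, params),
    )


def collapse_tables(
    R0_list,
    alpha_grid,
    params: ModelParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescaled excess-case and peak tables demonstrating data collapse.

    For each R0, excess cases are reported against alpha/alpha_ex* after
    normalization by the nonbehavioral value, and the peak against
    alpha/alpha_peak* normalized likewise.  Curves for different R0
    then fall on common master curves: ~1 for alpha << alpha*, ~(alpha/
    alpha*)^-1 beyond.
    """
    ex_rows, pk_rows = [], []
    for R0 in R0_list:
        base = (params or ModelParams(R0=R0)).with_(R0=R0, s0=None, i0=None, r0=None)
        _, eps0, ipk0 = nonbehavioral_limit(base)
        a_ex, a_pk = crossover_costs(base)
        for alpha in alpha_grid:
            p = base.with_(alpha=float(alpha))
            coeffs = na.solve_self_consistent_sf(p)
            eps = 1.0 / R0 - coeffs.sf
            ipk, _ = infection_peak(coeffs, p)
            ex_rows.append(
                {"R0": R0, "alpha": alpha, "alpha_rescaled": alpha / a_ex, "eps_rescaled": eps / eps0}
            )
            pk_rows.append(
                {"R0": R0, "alpha": alpha, "alpha_rescaled": alpha / a_pk, "peak_rescaled": ipk / ipk0}
            )
    return pd.DataFrame(ex_rows), pd.DataFrame(pk_rows)


def phase_table(R0_grid, params: ModelParams | None = None) -> pd.DataFrame:
    """Crossover costs over an R0 grid (the phase-diagram boundary curves)."""
    rows = []
    for R0 in R0_grid:
        p = (params or ModelParams(R0=R0)).with_(R0=float(R0), s0=None, i0=None, r0=None)
        a_ex, a_pk = crossover_costs(p)
        rows.append({"R0": R0, "alpha_ex_star": a_ex, "alpha_peak_star": a_pk})
    return pd.DataFrame(rows)
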