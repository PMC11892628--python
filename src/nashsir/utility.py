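"""Closed-form equilibrium utility, its limits, and salvage bookkeeping.

Along the Nash equilibrium the total utility collapses to

    U = -alpha [ (rf - r0) + (sf/2) ( R0 (rf - r0) + ln(sf/s0) ) ],

where the first bracket term is the total infection cost -alpha (rf - r0)
and the remainder the total social-distancing cost.  The distancing term
follows from int (k - R0)^2 dt = (alpha sf / 2)^2 int i dr together with
int k dr = ln(s0/sf), which gives (alpha sf/2) int i dr = R0 (rf - r0)
+ ln(sf/s0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .nash_analytic import AnalyticCoefficients
from .params import ModelParams

__all__ = [
    "UtilityBreakdown",
    "equilibrium_utility_closed_form",
    "utility_limits",
    "salvage_term",
]


@dataclass
class UtilityBreakdown:
    """Total equilibrium utility split into its cost components."""

    total: float
    infection_cost: float
    distancing_cost: float
    salvage: float = 0.0


def equilibrium_utility_closed_form(
    params: ModelParams, coeffs: AnalyticCoefficients
) -> UtilityBreakdown:
    """Equilibrium utility from the closed form (herd-immunity horizon).

    Requires self-consistent coefficients; the salvage term vanishes in
    this limit (i(tf) -> 0) and is reported as 0.
    """
    sf, rf = coeffs.sf, coeffs.rf
    if sf <= 0.0:
        raise ValueError(f"sf must be positive, got {sf}")
    dr = rf - params.r0
    infection = -params.alpha * dr
    distancing = -params.alpha * (sf / 2.0) * (params.R0 * dr + np.log(sf / params.s0))
    return UtilityBreakdown(
        total=infection + distancing,
        infection_cost=infection,
        distancing_cost=distancing,
        salvage=0.0,
    )


def utility_limits(params: ModelParams) -> tuple[float, float]:
    """Per-alpha utility in the two limits, as (U_low/(-alpha), U_high/(-alpha)).

    Low cost (nonbehavioral): U/(-alpha) = 1 + W(-s0 R0 e^{R0(r0-1)})/R0 - r0,
    which is just the attack rate rf - r0 (no distancing cost is paid).
    High cost: U/(-alpha) = (3/2)(1 - r0) - (3 + ln(R0 s0))/(2 R0),
    the closed form evaluated at the saturated final size sf = 1/R0.
    """
    W = float(
        lambertw(-params.s0 * params.R0 * np.exp(params.R0 * (params.r0 - 1.0))).real
    )
    low = 1.0 + W / params.R0 - params.r0
    high = 1.5 * (1.0 - params.r0) - (3.0 + np.log(params.R0 * params.s0)) / (
        2.0 * params.R0
    )
    return low, high


def salvage_term(psi_i_final: float, params: ModelParams) -> float:
    """Post-vaccination utility contribution Uf = -alpha * psi_i(tf).

    After a perfect vaccine at tf the susceptibles vanish, behavior reverts
    to kappa = R0 (zero distancing cost) and the remaining infections decay
    as psi_i(tf) e^{-(t-tf)}; integrating the infection cost over the tail
    gives exactly -alpha psi_i(tf).
    """
    if psi_i_final < 0.0:
        raise ValueError("psi_i_final must be non-negative")
    return -params.alpha * psi_i_final
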