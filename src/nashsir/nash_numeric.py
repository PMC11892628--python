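"""Numerical Nash equilibrium via a Pontryagin forward-backward sweep.

This module solves the same mean-field game as :mod:`nashsir.nash_analytic`
without using the closed form, so the two routes validate each other.  The
individual's Hamiltonian is

    H = -alpha psi_i - (kappa - R0)^2 - (vs - vi) kappa psi_s i - vi psi_i,

maximized by kappa = R0 - (vs - vi) psi_s i / 2 (concave in kappa:
d2H/dkappa2 = -2).  The sweep alternates a forward pass of the state
equations with a backward pass of the costate equations

    dvs/dt = (vs - vi) kappa i,      vs(tf) = 0,
    dvi/dt = alpha + vi,             vi(tf) = -alpha,

and a damped update of the control, iterating to the self-consistent fixed
point k = kappa, s = psi_s, i = psi_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .model_core import Trajectory, horizon, integrate_sir
from .params import ModelParams

__all__ = [
    "AdjointSolution",
    "SweepConfig",
    "SweepError",
    "hamiltonian",
    "hamiltonian_kappa_curvature",
    "best_response",
    "solve_nash_sweep",
    "utility_of_policy",
    "deviation_test",
    "constant_offset",
    "gaussian_bump",
    "scaled_equilibrium_deviation",
]


class SweepError(RuntimeError):
    """Sweep failed to converge; carries the residual history."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class AdjointSolution:
    """Individual-level solution: probabilities, costates and control."""

    t: np.ndarray
    psi_s: np.ndarray
    psi_i: np.ndarray
    vs: np.ndarray
    vi: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.t, self.psi_s, self.psi_i, self.vs, self.vi, self.kappa = (
            np.asarray(a, dtype=float)
            for a in (self.t, self.psi_s, self.psi_i, self.vs, self.vi, self.kappa)
        )


@dataclass
class SweepConfig:
    """Iteration controls for the forward-backward sweep.

    relaxation is the damping factor of the control update (undamped
    fixed-point iteration of mean-field games tends to oscillate); tol is
    the sup-norm threshold on the undamped control residual.
    """

    relaxation: float = 0.2
    tol: float = 1e-8
    max_iter: int = 3000
    grid_size: int = 2001
    adaptive: bool = True
    residuals: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError("relaxation must lie in (0, 1]")
        if self.tol <= 0.0:
            raise ValueError("tol must be positive")


# ---------------------------------------------------------------------------
# Hamiltonian


def hamiltonian(kappa, psi_s, psi_i, i, vs, vi, params: ModelParams):
    """Pontryagin Hamiltonian of the individual decision problem."""
    u = -params.alpha * psi_i - params.xi * (kappa - params.R0) ** 2
    return u - (vs - vi) * kappa * psi_s * i - vi * psi_i


def hamiltonian_kappa_curvature(
    params: ModelParams | None = None,
    state: tuple | None = None,
    h: float = 1e-3,
    rng: np.random.Generator | None = None,
) -> float:
    """d2H/dkappa2 by central finite differences at an arbitrary state.

    The Hamiltonian is exactly quadratic in kappa, so the central second
    difference is exact up to roundoff and the value is the constant -2*xi.
    """
    if params is None:
        params = ModelParams(R0=4.0, alpha=100.0)
    if state is None:
        rng = rng or np.random.default_rng(0)
        psi_s, psi_i, i = rng.uniform(0.0, 1.0, size=3)
        vs, vi = -rng.uniform(0.0, params.alpha + 1.0, size=2)
        kappa = rng.uniform(0.0, 2.0 * params.R0)
    else:
        kappa, psi_s, psi_i, i, vs, vi = state
    H = lambda k: hamiltonian(k, psi_s, psi_i, i, vs, vi, params)
    return (H(kappa + h) - 2.0 * H(kappa) + H(kappa - h)) / (h * h)


# ---------------------------------------------------------------------------
# fixed-step RK4 propagators (sequential in time, scalar Python floats;
# coefficient data is pre-evaluated on nodes and midpoints from splines)


def _forward_state(s0: float, i0: float, k_n, k_m, h: float):
    """RK4 for ds/dt = -k s i, di/dt = k s i - i on a uniform grid.

    k_n are control values on the n nodes, k_m on the n-1 midpoints.
    """
    n = len(k_n)
    s = np.empty(n)
    i = np.empty(n)
    s[0], i[0] = s0, i0
    sc, ic = float(s0), float(i0)
    for j in range(n - 1):
        k0, km, k1 = k_n[j], k_m[j], k_n[j + 1]

        f1s = -k0 * sc * ic
        f1i = -f1s - ic
        s2, i2 = sc + 0.5 * h * f1s, ic + 0.5 * h * f1i
        f2s = -km * s2 * i2
        f2i = -f2s - i2
        s3, i3 = sc + 0.5 * h * f2s, ic + 0.5 * h * f2i
        f3s = -km * s3 * i3
        f3i = -f3s - i3
        s4, i4 = sc + h * f3s, ic + h * f3i
        f4s = -k1 * s4 * i4
        f4i = -f4s - i4
        sc += h / 6.0 * (f1s + 2.0 * f2s + 2.0 * f3s + f4s)
        ic += h / 6.0 * (f1i + 2.0 * f2i + 2.0 * f3i + f4i)
        s[j + 1], i[j + 1] = sc, ic
    return s, i


def _backward_costates(alpha: float, p_n, p_m, h: float):
    """RK4 backward for dvs/dt = (vs - vi) p(t), dvi/dt = alpha + vi.

    p = kappa * i on nodes/midpoints; terminal vs = 0, vi = -alpha.
    """
    n = len(p_n)
    vs = np.empty(n)
    vi = np.empty(n)
    vs[-1], vi[-1] = 0.0, -alpha
    vsc, vic = 0.0, -alpha
    for j in range(n - 1, 0, -1):
        p1, pm, p0 = p_n[j], p_m[j - 1], p_n[j - 1]
        # integrate backward: step -h
        f1s = (vsc - vic) * p1
        f1i = alpha + vic
        v2s, v2i = vsc - 0.5 * h * f1s, vic - 0.5 * h * f1i
        f2s = (v2s - v2i) * pm
        f2i = alpha + v2i
        v3s, v3i = vsc - 0.5 * h * f2s, vic - 0.5 * h * f2i
        f3s = (v3s - v3i) * pm
        f3i = alpha + v3i
        v4s, v4i = vsc - h * f3s, vic - h * f3i
        f4s = (v4s - v4i) * p0
        f4i = alpha + v4i
        vsc -= h / 6.0 * (f1s + 2.0 * f2s + 2.0 * f3s + f4s)
        vic -= h / 6.0 * (f1i + 2.0 * f2i + 2.0 * f3i + f4i)
        vs[j - 1], vi[j - 1] = vsc, vic
    return vs, vi


def _midpoints(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return CubicSpline(t, y)(0.5 * (t[:-1] + t[1:]))


def _damped_iterate(kappa, target, lam):
    return kappa + lam * (target - kappa)


# ---------------------------------------------------------------------------
# best response and Nash sweep


def best_response(
    params: ModelParams,
    population: Trajectory,
    config: SweepConfig | None = None,
) -> AdjointSolution:
    """Optimal individual policy against an exogenous population epidemic.

    Iterates (forward individual probabilities under the current kappa;
    backward costates; update kappa = R0 - (vs - vi) psi_s i / 2 clamped
    at 0, damped by ``relaxation``) until the undamped control residual
    falls below ``tol``.  The second-order condition holds by construction
    (the Hamiltonian is strictly concave in kappa).
    """
    config = config or SweepConfig()
    t = np.linspace(population.t[0], population.t[-1], config.grid_size)
    h = t[1] - t[0]
    i_pop_spline = CubicSpline(population.t, population.i)
    i_n = i_pop_spline(t)
    i_m = i_pop_spline(0.5 * (t[:-1] + t[1:]))

    kappa = np.full(config.grid_size, params.R0)
    lam = config.relaxation
    residuals: list[float] = []
    streak = 0
    for it in range(config.max_iter):
        k_m = _midpoints(t, kappa)
        psi_s, psi_i = _forward_state(params.s0, params.i0, kappa, k_m, h)
        p_n = kappa * i_n
        p_m = k_m * i_m
        vs, vi = _backward_costates(params.alpha, p_n, p_m, h)
        target = np.maximum(params.R0 - 0.5 * (vs - vi) * psi_s * i_n, 0.0)
        res = float(np.max(np.abs(target - kappa)))
        residuals.append(res)
        if res < config.tol:
            kappa = target
            break
        if config.adaptive and len(residuals) > 1:
            if res > residuals[-2]:
                lam = max(lam * 0.5, 1e-3)
                streak = 0
            else:
                streak += 1
                if streak >= 5:
                    lam = min(lam * 1.25, 1.0)
                    streak = 0
        kappa = _damped_iterate(kappa, target, lam)
    else:
        raise SweepError(
            f"best response did not converge in {config.max_iter} iterations "
            f"(last residual {residuals[-1]:.3e}); try a smaller relaxation",
            residuals,
        )
    config.residuals = residuals
    k_m = _midpoints(t, kappa)
    psi_s, psi_i = _forward_state(params.s0, params.i0, kappa, k_m, h)
    vs, vi = _backward_costates(params.alpha, kappa * i_n, k_m * i_m, h)
    return AdjointSolution(t, psi_s, psi_i, vs, vi, kappa)


def solve_nash_sweep(
    params: ModelParams,
    config: SweepConfig | None = None,
    i_end: float = 1e-6,
) -> tuple[Trajectory, AdjointSolution]:
    """Self-consistent Nash equilibrium by forward-backward sweep.

    Imposes the mean-field closure k = kappa, s = psi_s, i = psi_i at every
    iteration: forward SIR under the current k, backward costates, damped
    control update k <- R0 - (vs + alpha) s i / 2.  The horizon starts from
    the nonbehavioral burnout time and is extended geometrically until the
    equilibrium epidemic itself satisfies i(tf) <= ``i_end`` (distancing
    slows the decline of infections, so the baseline horizon can be short).

    Returns the population trajectory and the matching adjoint solution.
    After convergence the trajectory is re-integrated with the adaptive
    high-order stepper for tight forward error.
    """
    config = config or SweepConfig()
    tf = horizon(params)
    kappa = None
    for _extension in range(10):
        t = np.linspace(0.0, tf, config.grid_size)
        h = t[1] - t[0]
        if kappa is None:
            kappa = np.full(config.grid_size, params.R0)
        else:  # warm start on the extended grid
            kappa = np.interp(t, t_prev, kappa)
        lam = config.relaxation
        residuals: list[float] = []
        streak = 0
        converged = False
        for it in range(config.max_iter):
            k_m = _midpoints(t, kappa)
            s, i = _forward_state(params.s0, params.i0, kappa, k_m, h)
            i_m = _midpoints(t, i)
            vs, vi = _backward_costates(params.alpha, kappa * i, k_m * i_m, h)
            target = np.maximum(params.R0 - 0.5 * (vs - vi) * s * i, 0.0)
            res = float(np.max(np.abs(target - kappa)))
            residuals.append(res)
            if res < config.tol:
                kappa = target
                converged = True
                break
            if config.adaptive and len(residuals) > 1:
                if res > residuals[-2]:
                    lam = max(lam * 0.5, 1e-3)
                    streak = 0
                else:
                    streak += 1
                    if streak >= 5:
                        lam = min(lam * 1.25, 1.0)
                        streak = 0
            kappa = _damped_iterate(kappa, target, lam)
        if not converged:
            raise SweepError(
                f"Nash sweep did not converge in {config.max_iter} iterations "
                f"(last residual {residuals[-1]:.3e}); try a smaller relaxation",
                residuals,
            )
        config.residuals = residuals
        k_m = _midpoints(t, kappa)
        s, i = _forward_state(params.s0, params.i0, kappa, k_m, h)
        if i[-1] <= i_end:
            break
        t_prev = t
        tf *= 1.5
    else:
        raise SweepError(
            f"equilibrium epidemic still has i(tf) = {i[-1]:.2e} > {i_end} "
            "after repeated horizon extensions",
            residuals,
        )

    # polish the converged solution with the adaptive stepper
    traj = integrate_sir(params.with_(tf=tf), CubicSpline(t, kappa), t)
    i_m = _midpoints(t, traj.i)
    vs, vi = _backward_costates(params.alpha, kappa * traj.i, k_m * i_m, h)
    adj = AdjointSolution(t, traj.s, traj.i, vs, vi, kappa)
    traj = Trajectory(t, traj.s, traj.i, traj.r, kappa)
    return traj, adj


# ---------------------------------------------------------------------------
# utility evaluation and Nash deviation tests


def utility_of_policy(individual: AdjointSolution, params: ModelParams) -> float:
    """Total utility of a policy by quadrature over its own record.

    U = int_0^tf [-alpha psi_i - xi (kappa - R0)^2] dt + Uf with the
    vaccination salvage Uf = -alpha psi_i(tf).  Integration is exact
    cubic-spline quadrature on the solution grid.
    """
    t = individual.t
    integrand = (
        -params.alpha * individual.psi_i
        - params.xi * (individual.kappa - params.R0) ** 2
    )
    running = float(CubicSpline(t, integrand).integrate(t[0], t[-1]))
    salvage = -params.alpha * float(individual.psi_i[-1])
    return running + salvage


def _utility_against_population(
    kappa_fun,
    population: Trajectory,
    params: ModelParams,
) -> float:
    """U(kappa, k_pop): forward individual probabilities + running utility.

    Integrated as one augmented ODE with tight tolerances so that the
    discretization bias cancels between a deviation and the equilibrium.
    """
    i_pop = CubicSpline(population.t, population.i)
    tf = float(population.t[-1])

    def rhs(t, y):
        psi_s, psi_i, _ = y
        kap = kappa_fun(t)
        flow = kap * psi_s * i_pop(t)
        du = -params.alpha * psi_i - params.xi * (kap - params.R0) ** 2
        return (-flow, flow - psi_i, du)

    sol = solve_ivp(
        rhs,
        (0.0, tf),
        (params.s0, params.i0, 0.0),
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
    )
    if not sol.success:
        raise RuntimeError(f"utility integration failed: {sol.message}")
    psi_i_f = sol.y[1, -1]
    return float(sol.y[2, -1] - params.alpha * psi_i_f)


def deviation_test(
    params: ModelParams,
    equilibrium: Trajectory,
    perturbations: list,
) -> list[float]:
    """Unilateral-deviation margins U(kappa* + delta, k*) - U(kappa*, k*).

    At a Nash equilibrium every margin is <= 0 (up to discretization
    noise).  Each perturbation is a callable delta(t); a deviation that
    drives kappa below 0 anywhere on the grid is rejected.
    """
    k_star = CubicSpline(equilibrium.t, equilibrium.k)
    u_star = _utility_against_population(k_star, equilibrium, params)
    margins = []
    for m, delta in enumerate(perturbations):
        tilde = lambda t: k_star(t) + delta(t)
        probe = tilde(equilibrium.t)
        if np.any(probe < 0.0):
            raise ValueError(
                f"perturbation {m} drives kappa negative "
                f"(min {probe.min():.3g}); controls must stay >= 0"
            )
        margins.append(_utility_against_population(tilde, equilibrium, params) - u_star)
    return margins


# perturbation family: constants, peak-centered bumps, scaled deviations


def constant_offset(c: float):
    return lambda t: c + 0.0 * np.asarray(t)


def gaussian_bump(center: float, width: float, amplitude: float):
    return lambda t: amplitude * np.exp(-0.5 * ((np.asarray(t) - center) / width) ** 2)


def scaled_equilibrium_deviation(equilibrium: Trajectory, params: ModelParams, scale: float):
    """delta(t) = scale * (R0 - k*(t)): stretch or flip the equilibrium's own distancing."""
    k_star = CubicSpline(equilibrium.t, equilibrium.k)
    return lambda t: scale * (params.R0 - k_star(t))
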