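"""Closed-form equilibrium: susceptible curve, final size, control, time map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import lambertw

import nashsir as ns
from nashsir.nash_analytic import AnalyticCoefficients, _infected_of_r


def rk4_susceptible(r_end, params, sf, step=2e-5):
    """Independent fourth-order integration of ds/dr = -s(a + b r + b s)."""
    b = params.alpha * sf / 2.0
    a = params.R0 - b
    f = lambda r, s: -s * (a + b * r + b * s)
    n = max(int(np.ceil((r_end - params.r0) / step)), 1)
    h = (r_end - params.r0) / n
    s, r = params.s0, params.r0
    for _ in range(n):
        k1 = f(r, s)
        k2 = f(r + h / 2, s + h * k1 / 2)
        k3 = f(r + h / 2, s + h * k2 / 2)
        k4 = f(r + h, s + h * k3)
        s += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        r += h
    return s


class TestSusceptibleOfR:
    def test_boundary_value_at_r0(self, params_ref, coeffs_ref):
        assert ns.susceptible_of_r(params_ref.r0, coeffs_ref, params_ref) == pytest.approx(
            params_ref.s0, rel=1e-12
        )

    def test_costless_limit_is_exponential(self):
        p = ns.ModelParams(R0=4.0, alpha=0.0)
        c = ns.solve_self_consistent_sf(p)
        got = ns.susceptible_of_r(0.5, c, p)
        assert got == pytest.approx(p.s0 * np.exp(-4.0 * (0.5 - p.r0)), rel=1e-12)

    def test_matches_rk4_oracle_midrange(self, params_ref, coeffs_ref):
        got = ns.susceptible_of_r(0.3, coeffs_ref, params_ref)
        oracle = rk4_susceptible(0.3, params_ref, coeffs_ref.sf)
        assert got == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("R0", [2.0, 4.0, 8.0])
    @pytest.mark.parametrize("alpha", [0.0, 10.0, 100.0, 1000.0])
    def test_oracle_equivalence_across_grid(self, R0, alpha):
        """Closed form vs direct integration of the Riccati equation."""
        p = ns.ModelParams(R0=R0, alpha=alpha)
        c = ns.solve_self_consistent_sf(p)
        r_probe = p.r0 + 0.5 * (c.rf - p.r0)
        got = ns.susceptible_of_r(r_probe, c, p)
        oracle = rk4_susceptible(r_probe, p, c.sf, step=5e-5)
        assert got == pytest.approx(oracle, rel=1e-8)

    def test_domain_errors(self, params_ref, coeffs_ref):
        with pytest.raises(ValueError):
            ns.susceptible_of_r(coeffs_ref.rf + 0.01, coeffs_ref, params_ref)
        bad = AnalyticCoefficients(a=5.0, b=-1.0, sf=0.1, rf=0.9, mu=0.0)
        with pytest.raises(ValueError):
            ns.susceptible_of_r(0.5, bad, params_ref)


class TestSelfConsistentFinalSize:
    def test_costless_limit_recovers_lambert_w(self):
        p = ns.ModelParams(R0=4.0, alpha=0.0)
        c = ns.solve_self_consistent_sf(p)
        sf_lw = float((-lambertw(-p.s0 * 4.0 * np.exp(4.0 * (p.r0 - 1.0))) / 4.0).real)
        assert c.sf == pytest.approx(sf_lw, abs=1e-10)

    def test_infinite_cost_saturates_herd_immunity_bound(self):
        p = ns.ModelParams(R0=4.0, alpha=1e6)
        c = ns.solve_self_consistent_sf(p)
        assert c.sf == pytest.approx(0.25, abs=1e-4)
        assert c.sf <= 0.25 + 1e-12

    def test_high_cost_asymptote_of_excess_cases(self):
        """1/R0 - sf approaches 2 R0^2 / alpha at large alpha."""
        p = ns.ModelParams(R0=4.0, alpha=6400.0)
        c = ns.solve_self_consistent_sf(p)
        assert (0.25 - c.sf) == pytest.approx(0.005, rel=0.05)

    def test_residual_and_invariants(self, params_ref, coeffs_ref):
        c, p = coeffs_ref, params_ref
        assert c.rf + c.sf == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < c.sf <= 1.0 / p.R0 + 1e-12
        assert c.b == pytest.approx(p.alpha * c.sf / 2.0)
        assert c.a == pytest.approx(p.R0 - c.b)
        assert c.mu == pytest.approx(p.alpha * c.sf / p.s0)
        # final-size identity rf + s0 e^{-K(rf)} = 1
        assert c.rf + p.s0 * np.exp(-c.K_of_r(c.rf, p)) == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        R0=st.floats(1.5, 8.0),
        alpha_lo=st.floats(0.0, 200.0),
        dalpha=st.floats(1.0, 200.0),
    )
    def test_final_size_monotone_in_alpha(self, R0, alpha_lo, dalpha):
        lo = ns.solve_self_consistent_sf(ns.ModelParams(R0=R0, alpha=alpha_lo))
        hi = ns.solve_self_consistent_sf(ns.ModelParams(R0=R0, alpha=alpha_lo + dalpha))
        assert hi.sf >= lo.sf - 1e-12


class TestControlAndCostates:
    def test_control_values(self, params_ref, coeffs_ref):
        # no infections -> default activity; linear in i with slope -alpha sf / 2
        assert ns.equilibrium_control(0.0, coeffs_ref, params_ref) == params_ref.R0
        i = np.array([0.0, 0.1, 0.2])
        k = ns.equilibrium_control(i, coeffs_ref, params_ref)
        slopes = np.diff(k) / np.diff(i)
        assert np.allclose(slopes, -coeffs_ref.b)

    def test_costless_control_is_flat(self):
        p = ns.ModelParams(R0=4.0, alpha=0.0)
        c = ns.solve_self_consistent_sf(p)
        assert np.all(ns.equilibrium_control(np.linspace(0, 0.5, 5), c, p) == 4.0)

    def test_costate_boundary_and_halfway(self, params_ref, coeffs_ref):
        vs, vi = ns.costate_fields(coeffs_ref.sf, coeffs_ref, params_ref)
        assert vs == pytest.approx(0.0, abs=1e-14)
        assert vi == -params_ref.alpha
        vs2, _ = ns.costate_fields(2.0 * coeffs_ref.sf, coeffs_ref, params_ref)
        assert vs2 == pytest.approx(-params_ref.alpha / 2.0)
        with pytest.raises(ValueError):
            ns.costate_fields(coeffs_ref.sf / 2.0, coeffs_ref, params_ref)

    def test_costless_costate_vanishes(self):
        p = ns.ModelParams(R0=4.0, alpha=0.0)
        c = ns.solve_self_consistent_sf(p)
        vs, vi = ns.costate_fields(0.5, c, p)
        assert vs == 0.0 and vi == 0.0


class TestTimeMap:
    def test_time_zero_at_r0(self, params_ref, coeffs_ref):
        assert ns.time_of_r(params_ref.r0, coeffs_ref, params_ref) == 0.0

    def test_costless_case_matches_quadrature_oracle(self):
        """t(r) against adaptive quadrature with the explicit exponential s(r)."""
        p = ns.ModelParams(R0=4.0, alpha=0.0)
        c = ns.solve_self_consistent_sf(p)
        i_of_r = lambda r: 1.0 - r - p.s0 * np.exp(-4.0 * (r - p.r0))
        oracle, _ = quad(lambda r: 1.0 / i_of_r(r), p.r0, 0.2, epsabs=1e-12, epsrel=1e-12)
        assert ns.time_of_r(0.2, c, p) == pytest.approx(oracle, abs=1e-9)

    def test_inverse_map_roundtrip(self, params_ref, coeffs_ref):
        for r in np.linspace(params_ref.r0 * 3, coeffs_ref.rf - 1e-3, 6):
            t = ns.time_of_r(r, coeffs_ref, params_ref)
            assert ns.r_of_time(t, coeffs_ref, params_ref) == pytest.approx(r, abs=1e-8)

    def test_divergent_endpoint_rejected(self, params_ref, coeffs_ref):
        with pytest.raises(ValueError, match="cap"):
            ns.time_of_r(coeffs_ref.rf - 1e-12, coeffs_ref, params_ref)


class TestAssembledTrajectory:
    def test_costless_matches_nonbehavioral_baseline(self):
        p = ns.ModelParams(R0=4.0, alpha=0.0)
        traj = ns.assemble_equilibrium_trajectory(p)
        base = ns.integrate_sir(p, p.R0, traj.t)
        assert np.max(np.abs(traj.s - base.s)) < 1e-8

    def test_invariants_and_construction_identity(self, params_ref, traj_ref, coeffs_ref):
        traj_ref.validate()
        assert traj_ref.i[-1] <= 1e-6 + 1e-12
        # k grid is exactly the control law applied to the i grid
        k_expected = ns.equilibrium_control(traj_ref.i, coeffs_ref, params_ref)
        assert np.array_equal(traj_ref.k, k_expected)
        # i = 1 - r - s by construction
        assert np.max(np.abs(traj_ref.i - (1 - traj_ref.r - traj_ref.s))) < 1e-15

    def test_costate_consistency_along_trajectory(self, params_ref, traj_ref, coeffs_ref):
        """k = R0 - (vs - vi) s i / 2 pointwise, with the closed-form costates."""
        vs, vi = ns.costate_fields(traj_ref.s, coeffs_ref, params_ref)
        k_from_costates = params_ref.R0 - 0.5 * (vs - vi) * traj_ref.s * traj_ref.i
        assert np.max(np.abs(traj_ref.k - k_from_costates)) < 1e-10

    def test_high_cost_peak_near_asymptote(self):
        """Assembled peak at alpha = 64 R0^2 sits within 10% of 2R0(R0-1)/alpha."""
        p = ns.ModelParams(R0=4.0, alpha=1024.0)
        traj = ns.assemble_equilibrium_trajectory(p)
        assert traj.i.max() == pytest.approx(2 * 4 * 3 / 1024.0, rel=0.10)

    @pytest.mark.parametrize("R0", [2.0, 4.0, 8.0])
    def test_control_never_below_one(self, R0):
        """Observed lower bound k >= 1 across costs (tested, not imposed)."""
        for alpha in (0.0, 10.0, 100.0, 1000.0):
            traj = ns.assemble_equilibrium_trajectory(
                ns.ModelParams(R0=R0, alpha=alpha), n_points=801
            )
            assert traj.k.min() >= 1.0

    def test_peak_monotone_nonincreasing_in_alpha(self):
        peaks = [
            ns.assemble_equilibrium_trajectory(
                ns.ModelParams(R0=4.0, alpha=a), n_points=801
            ).i.max()
            for a in (0.0, 50.0, 100.0, 400.0)
        ]
        assert np.all(np.diff(peaks) <= 1e-12)
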