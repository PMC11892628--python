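import numpy as np
import pytest

import nashsir as ns


@pytest.fixture(scope="session")
def params_ref() -> ns.ModelParams:
    """Canonical scenario: R0 = 4, alpha = 100, default early-epidemic seed."""
    return ns.ModelParams(R0=4.0, alpha=100.0)


@pytest.fixture(scope="session")
def coeffs_ref(params_ref):
    return ns.solve_self_consistent_sf(params_ref)


@pytest.fixture(scope="session")
def traj_ref(params_ref, coeffs_ref):
    return ns.assemble_equilibrium_trajectory(params_ref, coeffs=coeffs_ref)


@pytest.fixture(scope="session")
def sweep_ref(params_ref):
    cfg = ns.SweepConfig()
    traj, adj = ns.solve_nash_sweep(params_ref, cfg)
    return traj, adj, cfg


def sup_distance(traj_a, traj_b, fields=("s", "i", "k")) -> float:
    """Sup-norm between two trajectories over the common time support."""
    from scipy.interpolate import CubicSpline

    m = traj_b.t <= traj_a.t[-1]
    return float(
        max(
            np.max(np.abs(getattr(traj_b, f)[m] - CubicSpline(traj_a.t, getattr(traj_a, f))(traj_b.t[m])))
            for f in fields
        )
    )
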