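"""Solve the Nash-equilibrium epidemic for one scenario and inspect it.

A population facing an epidemic with R0 = 4 and infection cost alpha = 100
(in units of the quadratic distancing cost) self-organizes its activity
k(t) = R0 - (alpha sf / 2) i(t): distancing proportional to prevalence.
"""

import nashsir as ns

params = ns.ModelParams(R0=4.0, alpha=100.0)
coeffs = ns.solve_self_consistent_sf(params)
traj = ns.assemble_equilibrium_trajectory(params, coeffs=coeffs)
summary = ns.summarize(params)

print(f"final susceptible fraction sf = {coeffs.sf:.6f}")
print(f"attack rate 1 - sf            = {1 - coeffs.sf:.6f}")
print(f"excess cases eps = 1/R0 - sf  = {summary.epsilon:.6f}")
print(f"infection peak i_hat          = {summary.i_peak:.6f} at t = {summary.t_peak:.3f}")
print(f"strongest distancing: k_min   = {traj.k.min():.4f}  (pre-epidemic k = R0 = {params.R0:g})")
print(f"behavioral regime             = {summary.regime}")

# The numbers say: even a cost of 100 infections' worth of utility only
# trims the peak (0.37 vs 0.40 without behavior) and barely moves the
# final size -- this alpha sits between the two crossover costs.
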