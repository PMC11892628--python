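# Methods

## Model and assumptions

The epidemic is a rescaled SIR model: time in units of the infectious
period (recovery rate 1), compartments s + i + r = 1, and a time-dependent
population transmission rate k(t) ≥ 0 that equals the basic reproduction
number R₀ when behavior is unmodified. Behavior is endogenous: a
representative individual with compartment probabilities ψ_s, ψ_i chooses
an activity κ(t) to maximize

    U = ∫₀^tf [ −α ψ_i − ξ (κ − R₀)² ] dt + U_f,     U_f = −α ψ_i(tf),

against the aggregate epidemic; the Nash equilibrium imposes k = κ,
ψ_s = s, ψ_i = i. Key modelling assumptions, in the package's scope:

- **Constant infection cost α**, paid on infection regardless of epidemic
  state (no hospital-capacity effects).
- **Quadratic distancing cost paid by every compartment** — individuals
  are uncertain of their own status (largely asymptomatic infections), so
  recovered individuals keep distancing. This is the assumption that makes
  the closed form possible.
- **Long horizon**: tf is large enough that herd immunity arrives before
  the vaccine, i(tf) → 0. The short-horizon regime (early vaccine,
  tf ≲ α/R₀²) is out of scope.
- ξ = 1 without loss of generality (choice of utility units); the
  recovery rate is hard-coded to 1, not a parameter.

The salvage term U_f handles the infections still recovering at tf: after
full vaccination s drops to 0, behavior reverts to κ = R₀ (no distancing
cost) and ψ_i decays as e^{−(t−tf)}, whose integrated cost is exactly
−α ψ_i(tf).

## Closed form

With r as the time variable (r is monotone; i = dr/dt) and
K(r) = ∫ k dr′, the susceptible fraction is s = s₀e^{−K(r)} and the
costates along the optimum are v_i = −α and v_s = −α(s − s_f)/s — the
expected future infection cost of a susceptible. The optimal control
k = R₀ − ½(v_s − v_i)si then collapses to k = R₀ − b·i with
b = α s_f/2, and s(r) solves the Riccati equation
ds/dr = −s(a + br + bs), a = R₀ − b.

The substitution w = 1/s linearizes it; the integrating factor
exp(−ar − br²/2) yields

    s(r) = P(r) / [ 1/s₀ + √(πb/2) · e^{(a+br₀)²/(2b)} ·
                    ( erf((a+br)/√(2b)) − erf((a+br₀)/√(2b)) ) ],

with P(r) = exp[−½(r − r₀)(2a + b(r + r₀))]. The final size s_f appears in
its own coefficients and is pinned down as the root of s_f = s(1 − s_f) on
(0, 1/R₀], located by bracketed bisection (the residual has opposite signs
at the bracket ends in the herd-immunity regime) plus a Newton polish to
residual < 1e−12. K is recovered as −ln(s/s₀) rather than by separate
quadrature — exact, and one fewer integral.

**Numerical stability.** At high α the erf arguments reach magnitudes
~√(α/R₀) and e^{(a+br₀)²/(2b)} overflows around α ≈ 4000 (R₀ = 4). The
implementation evaluates the combination e^{x²}∫_{x₀}^{x}e^{−u²}du on
three sign branches via the scaled complementary error function erfcx of
positive arguments; the surviving exponentials are e^{x²−x₀²} = e^{G(r)}
with G ≤ 0 on the branch where they appear, so every factor stays bounded
for arbitrarily large α (validated at α = 10⁷).

**Time map.** Physical time is t = ∫ dr′/i(r′), whose integrand diverges
at r_f. Trajectories are capped where i first falls below `i_cap`
(default 1e−6, configurable) on the declining branch, on an r-grid with
cosine clustering toward both endpoints (where 1/i is steep). The
cumulative map uses composite 10-point Gauss–Legendre panels on that grid
(vectorized; agrees with adaptive quadrature to ~1e−11); scalar queries
(`time_of_r`) use adaptive quadrature, and the inverse map is bracketed
root finding, accurate to better than 1e−8.

## Pontryagin sweep (independent validation)

No algorithm for the equilibrium is implied by the closed form, so the
numerical route is a design choice justified by agreement: a damped
forward–backward sweep on a uniform grid (default 2001 nodes) alternating

1. forward RK4 of the state under the current control,
2. backward RK4 of the costates from v_s(tf) = 0, v_i(tf) = −α,
3. control update k ← R₀ − ½(v_s − v_i)si, clamped at 0, relaxed by
   a damping factor (default 0.2).

Mid-step coefficient values come from cubic splines so RK4 keeps fourth
order. Undamped fixed-point iteration of mean-field games can oscillate;
the damping adapts (halved when the residual grows, grown 1.25× after five
consecutive decreases, capped at 1), converging in ~25–60 iterations to a
sup-norm control residual of 1e−8 across R₀ ∈ {2,4,8}, α ∈ [0,400]. The
converged trajectory is re-integrated with the adaptive stepper
(DOP853, rtol 1e−12/atol 1e−14 — tolerances chosen so the forward error
stays well below the 1e−8 level at which routes are compared).

The horizon starts at the **nonbehavioral** burnout time (first t with
i < 1e−9 under k = R₀, rounded up) and is extended geometrically (×1.5,
warm-started) until the *equilibrium* epidemic satisfies i(tf) ≤ 1e−6:
strong distancing stretches the epidemic (the terminal decay rate is
≈ R₀ε = 2R₀³/α), so a fixed baseline horizon would truncate it.

Agreement between the two routes is ≤ 1.3e−5 in sup-norm over (s, i, k)
on the grid R₀ ∈ {2,4,8} × α ∈ {0,50,100,400}; the costate field
v_s = −α(s − s_f)/s emerges from the backward pass (not imposed) to ~1e−5.

The Nash property is additionally checked directly: unilateral deviations
(constants, Gaussian bumps at the infection peak, sign flips and scalings
of the equilibrium's own distancing) are evaluated against the frozen
population with a tightly-toleranced augmented ODE (state + running
utility), and all margins are ≤ 0, quadratic in the deviation amplitude as
the −2 curvature of the Hamiltonian in κ dictates.

## Scaling laws and phase diagram

Nonbehavioral limit (α = 0): the classic final size
s_f = −W(−s₀R₀e^{R₀(r₀−1)})/R₀ (principal Lambert-W branch) and peak
î = 1 − r₀ − (1 + ln(s₀R₀))/R₀. High-cost limit (α ≫ R₀²):
ε = 2R₀²/α and î = 2R₀(R₀−1)/α. Matching the branches gives

    α*_ex  = 2R₀³ / (1 + W(·)),
    α*_peak = 2R₀²(R₀−1) / (R₀(1−r₀) − 1 − ln(s₀R₀)),

≈ 139 and ≈ 59 at R₀ = 4. Regimes are half-open: α < α*_peak
"nonbehavioral", α*_peak ≤ α ≤ α*_ex "peak-suppressing", α > α*_ex
"extended-distancing" (ties to the middle regime). The peak location is
found grid-independently from the di/dt = 0 condition k(r)s(r) = 1 by
root finding on the closed form.

The asymptotes are approached slowly — the expansion parameter is R₀²/α.
At α = 64R₀², R₀ = 4, both observables are within 10% of their
asymptotes (ε 7.4%, î 9.9%), improving as α grows; at larger R₀ the peak
asymptote needs proportionally larger α. Rescaling α by the crossover and
each observable by its nonbehavioral value collapses the (R₀, α) family
onto master curves; the collapse is tight (< 2% spread across
R₀ ∈ {2,4,8}) deep in either tail and loosest (~50%) right at the
crossover, where neither asymptote applies — the tests encode a 10% band
in the tails and a 55% band at the crossover.

The control bound k ≥ 1 is provable only in the α → ∞ limit; the package
treats it as a tested conjecture and confirms it across the parameter grid
(minimum observed k ≈ 1.26 at R₀ = 4, α = 400).

## Equilibrium utility

Along the equilibrium the utility collapses to

    U = −α [ (r_f − r₀) + (s_f/2)( R₀(r_f − r₀) + ln(s_f/s₀) ) ],

with −α(r_f − r₀) the infection cost and the rest the distancing cost
(derived from ∫(k−R₀)²dt = b²∫i dr and ∫k dr = ln(s₀/s_f); validated
against trajectory quadrature to ~1e−9 relative). Its limits per α are
the nonbehavioral attack rate r_f − r₀ ≈ 0.9802 (R₀ = 4) and the
saturated high-cost value (3/2)(1−r₀) − (3 + ln(R₀s₀))/(2R₀) ≈ 0.9517.
Equilibrium distancing always weakly improves on the nonbehavioral
utility; the difference is the value of self-organized behavior.

When comparing the closed form against time-quadrature, the trajectory is
assembled with `i_cap` = 1e−9 and 20001 nodes: the truncated tail
contributes O(α·i_cap/(R₀ε)) to the utility, which at the default cap of
1e−6 would exceed the 1e−6 relative tolerance in the strongest-distancing
scenarios.

## Defaults and problem sizes

- Initial conditions: r₀ = 1e−6, i₀ = r₀(R₀−1), s₀ = 1 − i₀ − r₀ — an
  early epidemic on the exponential growth branch; overridable.
- Trajectory grids: 2001 clustered nodes (20001 for utility quadrature
  checks); sweep grid 2001 uniform nodes, relaxation 0.2, tolerance 1e−8.
- Root finding: bisection/brentq at ~1e−15, Newton polish; all special
  functions from scipy (lambertw, erf, erfcx).
- Cross-validation grids in the test suite: R₀ ∈ {2,4,8} ×
  α ∈ {0,50,100,400} (solver agreement), × {10,100,400} (utility), chosen
  to span all three behavioral regimes while keeping the default test run
  fast.

## What the generated scenarios do and do not show

All inputs are scalar parameters; there is no data. The package's tests
therefore establish internal mathematical consistency — closed form vs
independent integration, equilibrium vs deviation, formulas vs
quadrature — under the model's assumptions, not fit to any real epidemic.
Real outbreaks violate several assumptions at once (heterogeneous
mixing and risk, imperfect information, finite hospital capacity, waning
immunity, policy interventions), so the value of the results is
qualitative guidance: the proportionality k = R₀ − (αs_f/2)i, the 1/α
scaling regimes, and the crossover costs separating them.

## Known limitations

- The short-horizon (early-vaccine) regime is not implemented; `horizon`
  warns if i(tf) is not negligible.
- Regime labels use sharp half-open thresholds although the underlying
  crossovers are smooth order-of-magnitude markers.
- The sweep's convergence is empirical (damped fixed point); no
  contraction proof is attempted. It has been exercised for α ≤ 6400.
- At extreme cost (α ≳ 10⁵) trajectory assembly still works, but the
  epidemic's duration grows like α/(2R₀³)·ln(1/i_cap) and grids may need
  enlarging for smooth time resolution.
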