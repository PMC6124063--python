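# Methods

## The model

`auxregion` simulates stochastic reaction–diffusion systems whose
concentration spans regimes: where copy numbers are high a deterministic
continuum PDE is an adequate (and cheap) description, where they are low
the discreteness and randomness of individual particles matter.  The
package couples the two descriptions across a point interface I (a plane
in the 3-D slab geometry):

* **PDE subdomain** Ω_P (left of I): the density c(x, t) obeys
  ∂c/∂t = D ∂²c/∂x² + f(c) with zero-flux walls (optionally a
  prescribed-gradient left wall, influx rate D·λ).
* **Brownian subdomain** Ω_B (right of I): every particle carries a
  position updated by x ← x + √(2 D Δt) ξ, ξ ~ N(0,1) per coordinate,
  with mirror reflection at all walls.

Both regimes see a zero-flux condition *at the interface*; all mass
exchange goes through two **auxiliary regions** of width h_a flanking it,
Ω_PA = [I−h_a, I) and Ω_BA = [I, I+h_a).  Inside them mass is
simultaneously represented in its native form and as well-mixed
compartment counts:

* N_PA = ∫_{Ω_PA} c dx (real-valued "pseudo-particles"),
* N_BA = #{particles in Ω_BA} (the half-open convention [I, I+h_a)
  places a particle sitting exactly on the interface in Ω_BA).

The two compartments form a local two-box reaction–diffusion master
equation sampled *exactly* with the Gillespie SSA.  Each particle jumps
across the interface at rate d = D/h_a², so the jump propensities are
α_P = d·N_PA and α_B = d·N_BA, the waiting time is τ = ln(1/u)/α⁰ and
events are selected by cumulative-sum inversion in a fixed enumeration
order (P→B, then B→P, then reaction channels), which makes trajectories
bit-reproducible under a fixed seed.  Enacting a jump converts
representation while conserving mass exactly: P→B withdraws 1/h_a of
density uniformly over Ω_PA and creates one particle uniformly in Ω_BA;
B→P deletes one uniformly chosen Ω_BA particle and deposits 1/h_a of
density over Ω_PA.  When N_PA < 1 the P→B propensity is clamped to zero
so a jump can never drive the density negative; activations of this
clamp are counted so persistent starvation is visible to the user.

Between SSA events the two regimes advance with a shared synchronous
step Δt (θ-method for the PDE, Euler–Maruyama for the particles).  The
event-driven clock runs inside each synchronous window with propensities
refreshed after every event; when the putative next event falls past the
window the event is discarded and redrawn after the update — the
exponential clock is memoryless, so the redraw is statistically
consistent.  An event landing exactly on the update time is processed
before the update.

## Reactions

Reaction placement follows the particle positions:

* in Ω_P, reactions act through the mean-field operator f(c);
* in Ω_B, zeroth-order births fire with probability κ₂ Δt V_B per step
  (a configuration error if ≥ 1) and first-order decay removes each
  particle with the exact probability 1 − e^(−μΔt);
* second-order channels use the λ–ρ scheme: an unordered pair closer
  than ρ reacts with probability P_λ per step — except pairs lying
  entirely inside Ω_BA, which are enacted as compartment events with
  propensity g(N_BA)·κ·V_aux^(1−ν), where V_aux is the physical volume
  of the auxiliary compartment (h_a in 1-D, h_a·L_y·L_z in the slab
  geometry; dimensional analysis of the master equation forces the
  volume form) and g is the combinatorial count (N(N−1)/2 for 2A→∅).

Zeroth- and first-order channels are deliberately *not* routed through
the compartment SSA: for them the per-step Bernoulli enactment and the
compartment event process have identical laws, and the per-step form is
what the microscopic reference uses, so hybrid and reference differ only
in the coupling.  Bimolecular channels must be compartment-based inside
Ω_BA because a pair straddling the interface has no microscopic partner
on the continuum side; this requires ρ < h_a (warned otherwise).

### λ–ρ calibration

P_λ is calibrated by direct simulation of the relative coordinate of a
reactant pair (diffusivity 2D) in a periodic cube: walkers within ρ are
killed with probability P per step and resurrected uniformly, and the
stationary event rate times the box volume is the realized rate
constant.  A fixed-point iteration with common random numbers adjusts P
until that rate matches κ₁ to 1% (relative), starting from the ballistic
estimate P = κ₁Δt/(4πρ³/3).  Simulation-based calibration is used
because at the canonical parameters the per-step RMS displacement
√(4DΔt) ≈ ρ, outside the regime where closed-form Smoluchowski-type
inversions are accurate.  The calibration uses a fixed internal seed
(it is a numerical procedure, like a quadrature) and is cached per
parameter set, so the hybrid and the fully microscopic reference share
the identical P_λ.

A consequence of distance-based pair reactions in *bounded* geometry is
a wall deficit: near a reflective wall part of the interaction sphere
lies outside the domain, reducing the pair-encounter probability by
3·S_box·ρ/(16·V) for uniform positions (≈ 4% for the canonical cuboid).
The well-mixed validation test corrects its mass-action oracle by this
factor; in the hybrid-versus-microscopic comparison the effect is shared
by both arms and cancels.

## Numerical choices

* **θ-method, θ = 0.51 (default).**  Crank–Nicolson (θ = 0.5) is
  second-order but oscillates on step-like data; the slight implicit
  bias damps those modes at the cost of a first-order error term with a
  0.01 coefficient.  The acceptance checks confirm the resulting orders:
  time error halves with Δt, spatial error quarters with h_p.
* **Cell-centred conservative grid.**  The negative Laplacian uses
  reflecting ghost cells, so its column sums vanish and the blended
  update conserves discrete mass identically (observed drift ~1e-13
  relative over 5000 steps).  The prescribed-flux wall enters as a load
  vector adding exactly D·λ·Δt per step.
* **Pre-factorised propagator.**  The grid is at most a few hundred
  cells, so the update matrix is inverted once and each step is a dense
  mat-vec; linear decay (−μc) is folded into the operator, nonlinear
  terms are evaluated explicitly at the old state to keep the solve
  linear.  A banded θ-march (independent code path) serves as the
  fine-grid reference solver.
* **Negative densities** are logged, never clipped — clipping would
  silently corrupt the mass ledger.  The N_PA < 1 clamp uses a 1e-9
  tolerance so that integer-valued occupancies perturbed by accumulated
  rounding are not spuriously clamped.
* **Grid spacing.**  h_p = 0.01 for the 1-D problems and h_p = 0.1 for
  the slab problem; h_a must be an integer multiple of h_p so auxiliary
  regions align with whole cells.
* **RNG.**  One PCG64 generator per repeat, seeded base_seed + repeat
  index; every stochastic operation of that repeat draws from its
  stream, so repeats are reproducible individually and independent of
  execution order.

## Adaptive interface

With thresholds β_u > β_l (hysteresis, preventing oscillation between
two positions), the interface is checked once per synchronous update,
after the PDE/Brownian step — per-event checking would make interface
motion depend on SSA micro-ordering.  At most one move of h_a per check:

* N_PA < β_l → move left: the Ω_PA cells are converted to
  ⌊N_PA⌋ + Bernoulli(N_PA mod 1) particles placed uniformly in the new
  Brownian slab, and the remaining PDE density is rescaled by
  (M_rest + N_PA − n)/M_rest — the multiplicative rescale is chosen
  because it conserves mass exactly *per realization* and is unbiased in
  n; deviations of the factor from 1 beyond 10% are logged.
* N_BA > β_u → move right: the Ω_BA particles are deleted and the slab
  becomes PDE cells at the uniform reduced density N_BA/h_a.

A move that would shrink either subdomain below h_a is suppressed with a
warning.  At the canonical second-order parameters the equilibrium slab
occupancy (≈ 14) exceeds β_u = 9.5, so the interface legitimately walks
to the right guard and stays pinned there late in the run.

## Reference models ("oracles")

For reaction orders ≤ 1 the mean-field PDE *is* the expected density of
the particle model, so the 1-D problems are validated against it: a
cosine-series solution (truncated so the neglected tail is < 1e-10) for
pure diffusion, and a fine-grid (h = 1e-3) banded θ-march for the
boundary-influx/decay problem.  The two oracle routes cross-validate
each other to < 1e-4 relative.  For the second-order problem the
mean equation closes only under a Poisson moment assumption
(Var A = E A), giving the reduced operator
f(C̄) = κ₂L_yL_z − κ₁C̄²/(L_yL_z); because that closure carries its own
bias, the hybrid is compared against the *fully microscopic* simulation
of the whole cuboid (identical λ–ρ calibration), isolating the coupling
as the quantity under test.  The isolated two-auxiliary-box system has
the closed-form mean occupancy M_P(t) = ½[ν₀ − (ν₀ − 2μ_P)e^(−2dt)],
which the ARM reproduces exactly when the synchronous updates are
disabled — the degenerate-limit check.

## Error instrumentation

All profile comparisons live on a common mesh of h_a-wide bins; the
hybrid's contribution to a bin is the PDE integral on the continuum side
and the particle count on the particle side.  The histogram distance
error (HDE) is half the L1 distance between unit-normalised profiles
(0 identical, 1 disjoint).  Region errors compare repeat-averaged
region masses to the reference; the far-slab relative error
E_Rel = (N_M − N_H)/N_M compares the two simulation arms of the
second-order problem.  The free parameters Δt and h_a are swept on a
grid with the diagnostic D·Δt/h_a² recorded per cell: when that ratio is
large the two auxiliary boxes equilibrate between synchronous updates
and the coupling degrades, which the sweep reproduces as an order-of-
magnitude median-HDE separation between ratio ≤ 0.5 and ratio ≥ 5 cells.

### Statistical test design

Two stock checks were reformulated so that their replication unit is
statistically independent:

* *Equilibrium sign test.*  The region-mass error of one repeat is an
  OU-like excursion whose relaxation time (~160 time units, the slowest
  diffusive mode) exceeds the whole record window, so the ~50 record
  points of the averaged series are one effective sample.  The sign test
  for zero median is therefore applied across the S = 200 independent
  repeats (per-repeat time-averaged relative error), at the same 1%
  level.
* *Slab-error sign balance.*  E_Rel(t) shares repeats across time
  points; "oscillates around zero" is tested as: the time-averaged E_Rel
  must lie within 3 bootstrap standard errors of zero (repeats resampled
  in both arms), alongside the |mean| ≤ 0.05 magnitude bound.  Points
  with reference slab occupancy below ~2 particles (t < 1) are excluded
  — the ratio is noise-dominated there.

## What the built-in experiments do and do not show

The canonical problems probe the coupling under equilibrium (tp1),
strong transient flux (tp2), a reacting boundary-driven gradient (tp3)
and second-order kinetics with a moving interface (tp4).  They are
single-species, 1-D or translationally invariant 3-D, with at most a few
hundred particles.  Passing them demonstrates that the interface neither
accumulates nor loses mass, that fluxes and variances match the fine
model where they should, and that the free parameters have a wide safe
region — not that the method is accurate for stiff multi-species
networks, curved interfaces, or geometries without a translationally
invariant reduction, none of which this package implements.  The state
containers are single-species; the propensity structure keeps per-species
arrays so the extension is mechanical, but it is not exercised.

## Problem sizes

The shipped validation uses S = 200 repeats for the 1-D problems,
S = 100 per arm for the second-order problem, 1e5 realizations of the
two-box process, and a 5×5 sweep with S = 20 — sizes at which the 3-SE
bands of the checks are a few particles wide and each suite completes on
a single CPU in minutes.
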