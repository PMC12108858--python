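# Methods

## Model and scope

The package studies a non-autonomous four-species predator–prey system
with feedback control in three nested settings:

1. the **criteria layer** — closed-form constants and sign conditions
   built from coefficient extrema, requiring no integration at all;
2. the **degenerate delay-ODE system** — the reaction dynamics with
   diffusion dropped; spatially homogeneous solutions of the full system
   solve exactly this system;
3. the **full delay-PDE system** on a 1-D interval with zero-flux
   boundaries.

All coefficients are positive ω-periodic functions.  They are stored
structurally (constant term plus sine/cosine terms), so the period
supremum `φ^m` and infimum `φ^l` of every coefficient in the reference
model are exact; a general callable with a declared period falls back to
a 100 001-point grid scan per period with a bounded local polish of the
best bracket, which recovers trig-affine extrema to better than 1e-6
without symbolic machinery.

## Permanence constants

The prey upper bounds are `M1 = (r1^m/a11^l)·exp(r1^m τ11)` (resp. `M2`),
the delay factor accounting for the overshoot a crowding delay permits
above the carrying level.  The control bounds `N_i`, `n_i` are the
stationary extremes of the linear control ODEs under the extreme species
levels.  The predator thresholds `M3*, M4*, m3*, m4*` come from
comparison arguments on the ratio-dependent gain terms and are defined
only when the corresponding margins (H1, H2, H7, H8 numerators and
denominators) are positive; the implementation returns `None` fields and
unsatisfied criteria instead of raising, so a failed hypothesis is data,
not an error.

The chain `0 < m_i ≤ m_i* ≤ M_i* ≤ M_i` (i = 3, 4) involves free
constants `m_i, M_i`.  The theory demands strict inequalities; the
worked example evaluates everything *at* the starred thresholds, and the
package follows that convention by default while exposing a
multiplicative `slack` parameter for users who want strictness.  With
the default choice the reported H7–H10 values and stability margins
reproduce the published four-decimal constants.

Two typographical issues in the published example are resolved in favour
of the defining formulas, and both are logged when the reference fixture
loads:

- the printed control bounds `N1 = 2.3370`, `N2 = 2.5175`, `N3 = 2.3370`
  disagree with their own formulas (which give 2.3323, 2.5140, 2.2778);
  every downstream printed constant (H1 ≈ 8.6633, H5 ≈ 78.3834,
  A1 ≈ 7.8508, …) matches the formula values, so the formulas win;
- the interference-saturation coefficient `b23` is printed with
  oscillation amplitude 0.01 in one equation and 0.1 in another; only
  0.1 reproduces H6 ≈ 82.1211, `m2 ≈ 1.7702` and A2 ≈ 7.7023, so 0.1 is
  the default (`example1_model(verbatim_eq63=True)` restores 0.01).

## Stability margins

Each margin `A_i` starts from the self-damping floor (`a_ii^l` for prey;
the ratio-response sensitivity floor for predators) and subtracts every
destabilizing contribution: direct couplings, control gains `q_i^m`, and
delay-weighted products in which each delay τ multiplies the per-capita
rates that can act over an interval of that length.  Every printed
fraction of the form `X(Y)²` is read as `X/(Y)²`; the bracketed rate
sums multiply their delay factors as printed; and the leading numerators
of A3/A4 use the prey-2 lower bound `m2`.  Each of these groupings was
fixed by requiring numeric agreement with the published four-decimal
values of A1–A4 — a reading that reproduces 7.8508, 7.7023, 1.4256 and
1.4528 simultaneously leaves no freedom.  The margins `B_i` are the
control decay floors `f_i^l` minus delay-weighted feedback loads.

An independent term-by-term oracle (each summand enumerated in a list
and `fsum`-med) agrees with the production evaluator to 1e-12 across
random parameter sets; this guards against transcription slips in the
long expressions.

## Delay-ODE integrator

Fixed-step method of steps.  The step must satisfy
`Δt ≤ (min positive delay)/2`; consequently every delayed argument of
every Runge–Kutta stage lies in the already computed past and no
implicit iteration is needed.  State *and* derivative are stored at
every node, so off-node delayed values use cubic Hermite interpolation,
whose O(Δt⁴) accuracy matches the classical RK4 scheme; the observed
step-halving contraction factor is ≈ 16.  For the reference delays
(0.001–0.01) the default `Δt = 2.5e-4` divides every delay, so lags land
on nodes exactly.

A positivity guard aborts (rather than clips) if any channel falls below
1e-12 — clipping would silently change the model.  Histories must be
strictly positive on `[−τ, 0]`, checked on a sample grid.

An explicit-Euler variant (`method="euler"`) exists solely so the PDE
solver, which is Euler in time, can be validated against an identically
discretized reference: on spatially constant data the two must agree to
rounding, and they do (sup-difference ≈ 1e-15 over t = 5).

## Delay-PDE solver

Method of lines on an endpoint grid over `[0, 2π]` with the three-point
Laplacian; Neumann boundaries are closed by mirror ghost nodes, which
keeps the stencil symmetric and conserves the trapezoidal spatial mean
of a diffusing field to 1e-10.  Time stepping is explicit Euler, refused
unless `Δt ≤ min(Δx²/(2 max d_i^m), (min positive delay)/2)`.  Delayed
fields are read from a ring buffer of the last `⌈τ/Δt⌉ + 1` frames with
linear interpolation in time; lagged times before zero evaluate the
initial-history callables directly.

The reference initial profiles have two quirks, both tolerated and
logged: the species histories are printed on `[−0.005, 0]` although the
maximum delay is 0.01 (they are extended by the same formulas), and the
control profiles take non-positive values at some nodes.  The latter is
harmless — the control equations are linear in `u` with strictly
positive sources, so the controls turn positive immediately — but a
`strict_positive` flag rejects such data for users who want the
textbook setting.  The species guard aborts only on values below −1e-10:
the reference profiles contain isolated exact zeros, which diffusion
lifts without ever producing negative densities.

## Diagnostics

All defect measures use sup norms, matching the uniform-convergence
statements they probe: the periodicity defect is
`sup_t,channel |z(t+ω) − z(t)|` over a tail window, the homogeneity
defect the largest spatial range, the attractivity distance the sup
distance between two trajectories.  The permanence check allows a
default 5 % slack on the box because the theory's bounds are
lim-sup/lim-inf statements and a finite horizon needs head-room; in
practice the reference system sits comfortably inside the box by t = 20
and the defects reach machine precision by t = 30, far below the 1e-3
thresholds the test suite asserts.

## Synthetic models

`random_model` draws each coefficient's constant term log-uniformly
within ±5 % of the reference level and adds one sine or cosine term with
amplitude a fraction < 1 of the constant term, so positivity holds by
construction and the generated systems usually satisfy all 18 criteria —
that is the regime in which ordering and oracle properties are
meaningful.  Random histories for attractivity experiments are constant
vectors drawn log-uniformly in [0.1, 3], spanning the permanence box
without pathological transients.  What the generator deliberately does
not emulate: incommensurate coefficient periods, near-degenerate margins
(criteria barely positive), non-constant random histories, or spatially
rough initial data; conclusions from passing tests are strongest for
smooth, comfortably-inside-the-region systems like the reference model.

## Problem sizes used in the shipped checks

The test suite integrates the delay-ODE system to t = 40 at
Δt = 2.5e-4 from six histories, and the PDE to t = 40 at Δt = 5e-4 on
129 nodes — about two minutes total.  The homogeneous-data equivalence
check uses 65 nodes to t = 5; analytic-limit checks run to t = 5 (ODE)
and t = 1 (PDE).  These horizons sit well past the observed transients
(defects are at machine precision by t = 30) while keeping the suite
quick to run.

## Known limitations

- Only 1-D spatial domains; no 2-D/3-D, no implicit or operator-splitting
  schemes, and no adaptive time stepping (fixed steps keep the delay
  bookkeeping exact and deterministic).
- Distributed (continuous) delays and almost-periodic or stochastic
  coefficients are out of scope.
- The criteria are sufficient, not necessary: a negative margin proves
  nothing about instability.
- The published figures for the reference simulation were produced with
  an unspecified discretization, so they are matched qualitatively (same
  limit cycle, same convergence behaviour), not bit-wise.
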