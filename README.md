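# ppfc — periodic predator–prey dynamics with feedback control

`ppfc` analyses a four-species predator–prey ecosystem — two prey, two
predators — living in a closed 1-D habitat with seasonally varying
(ω-periodic) rates, time delays, ratio-dependent predation and feedback
control.  It answers, numerically and by closed-form criteria, three
questions ecologists ask of such a system:

1. **Permanence** — do all populations stay bounded away from both
   extinction and blow-up?
2. **Periodic coexistence** — does a strictly positive, spatially
   homogeneous ω-periodic solution exist?
3. **Stability** — is that periodic cycle globally attracting, regardless
   of the initial population distribution?

## The model

Species densities `v_i(x,t)` (prey `i = 1,2`, predators `i = 3,4`) and
control variables `u_i(x,t)` obey, on `Ω = [0, 2π]` with zero-flux
boundaries,

```
∂v1/∂t − d1(t)Δv1 = v1 [ r1 − a11 v1(t−τ11) − a12 v2(t−τ12)
                         − a13 v3/(b13 v3 + v1) − a14 v4/(b14 v4 + v1) − k1 u1 ]
∂v3/∂t − d3(t)Δv3 = v3 [ −r3 + a31 v1(t−τ31)/(b13 v3 + v1(t−τ31))
                         + a32 v2(t−τ32)/(b23 v3 + v2(t−τ32)) − a34 v4(t−τ34) + k3 u3 ]
∂u1/∂t = e1 − f1 u1 + q1 v1        (v2, v4, u2..u4 analogous)
```

All coefficients are positive ω-periodic functions; the criteria are
built entirely from their period suprema `φ^m` and infima `φ^l`.  The
predation terms are *ratio-dependent*: consumption saturates in the
predator-to-prey ratio rather than in prey density alone.  Each control
variable `u_i` models a regulatory intervention that tracks its species
(`u̇ = e − f u ± q v`) and feeds back into the growth rate (`∓ k u`).

The package provides:

- **closed-form bounds** `M_i, m_i, N_i, n_i` and the ten sign criteria
  H1–H10 that guarantee permanence of the diffusion-free (degenerate)
  system;
- **Lyapunov stability margins** `A1–A4, B1–B4` (criteria H11–H18) that
  additionally guarantee a globally asymptotically stable, spatially
  homogeneous ω-periodic solution of the full reaction–diffusion system;
- a fixed-step **method-of-steps RK4 integrator** for the delay-ODE
  system and an explicit **method-of-lines solver** for the delay-PDE
  system (Neumann boundaries, CFL-guarded);
- **diagnostics** that measure how well a computed solution satisfies
  periodicity, spatial homogeneity, permanence and attractivity — the
  numeric counterparts of the theory.

## Worked example

The built-in reference model (`ppfc.example1_model()`) has growth rates
like `r1(t) = 22 + cos πt`, competition `a11(t) = 10 + sin πt`, period
ω = 2, unit diffusivities and ten delays between 0.001 and 0.01.

```sh
ppfc fixture example1 --out model.json
ppfc check --model model.json --out report.json --explain
```

prints

```
  H1:     8.663333  ok  [r3^l - a32^m - k3^m N3]
  H2:     9.189474  ok  [r4^l - a42^m - k4^m N4]
  ...
 H11:     7.850842  ok  [A1 > 0]
 H12:     7.702350  ok  [A2 > 0]
 H13:     1.425711  ok  [A3 > 0]
 H14:     1.452777  ok  [A4 > 0]
 H15:     9.438246  ok  [B1 > 0]
 ...
verdict: stable
```

All eighteen margins are positive: the system is permanent (every
solution eventually enters the box `m_i ≤ v_i ≤ M_i`, `n_i ≤ u_i ≤ N_i`
with e.g. `M1 ≈ 2.6150`, `m1 ≈ 1.8600`) and possesses a unique 2-periodic
spatially homogeneous solution that attracts every positive initial
state.  Simulation confirms this quantitatively:

```python
import ppfc

m = ppfc.example1_model()
traj = ppfc.integrate_dde(m, ppfc.HistoryFunctions.constant([1.0]*8),
                          t_max=40.0, dt=2.5e-4)
print(ppfc.periodicity_defect(traj, omega=2.0, window=(30.0, 38.0)))
# 1.0e-14  — the tail is 2-periodic to machine precision
```

and the same run from any other positive constant history lands on the
identical cycle (sup-distance on `t ∈ [30, 40]` below 1e-12).

The equivalent shell workflow:

```sh
ppfc simulate-dde --model model.json --tmax 40 --dt 2.5e-4 --out traj.csv
ppfc bounds --model model.json --out bounds.json
ppfc diagnose --traj traj.csv --bounds bounds.json --omega 2 --out diag.json
ppfc simulate-pde --model model.json --nx 129 --tmax 40 --dt auto --out fields.csv
```

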