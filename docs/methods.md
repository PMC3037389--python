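# Methods

## The model

`hybridcycle` simulates mammalian cell-cycle regulation with a hybrid
discrete/continuous, deterministic/stochastic model. Three cyclins (A, B, E)
are continuous concentration variables obeying piecewise-linear kinetics

    d[CycX]/dt = ks_x − kd_x · [CycX],

where the "constants" ks_x and kd_x depend on six Boolean regulators: two
lumped transcription factors (TFE, driving cyclins E and A early in the
cycle; TFB, driving cyclins B and A late) and four ubiquitination activities
(SCF on cyclin E; Cdc20A on cyclin A; Cdc20B and Cdh1 on cyclins A and B).
The Boolean vector does not update autonomously; it traverses a fixed
nine-state sequence — the dominant "super highway" trajectory of the
underlying switching network — once per cycle:

| n | phase | TFE | TFB | SCF | Cdc20A | Cdc20B | Cdh1 | exit |
|---|------------------|---|---|---|---|---|---|---------------------------|
| 1 | G1a | 0 | 0 | 0 | 0 | 0 | 1 | timer (T_det = 0) |
| 2 | G1b (early) | 1 | 0 | 0 | 0 | 0 | 1 | [CycE]·M ≥ θ_E |
| 3 | G1b (late) | 1 | 0 | 0 | 0 | 0 | 0 | [CycA] ≥ θ_A |
| 4 | S | 1 | 0 | 1 | 0 | 0 | 0 | timer (T_det = 7 h) |
| 5 | G2 | 0 | 1 | 1 | 0 | 0 | 0 | [CycB] ≥ θ_B′ |
| 6 | prophase | 0 | 1 | 1 | 0 | 0 | 0 | timer (0) |
| 7 | prometa/metaphase| 0 | 1 | 1 | 1 | 0 | 0 | timer (0) |
| 8 | anaphase | 0 | 1 | 1 | 1 | 1 | 0 | timer (0) |
| 9 | telophase | 0 | 0 | 1 | 0 | 0 | 1 | [CycB] ≤ θ_B″ → division |

The time spent in state *i* is T_i = T_det,i + T_stoch,i: the deterministic
part is zero, the 7 h DNA-synthesis floor, or the threshold-crossing time of
the controlling cyclin; the stochastic part is exponential with mean λ_i
(λ_1 = 2 h; λ_2 = λ_3 = 0 — the restriction-point and S-entry transitions
fire at their thresholds; λ_4..λ_9 = 0.5 h). Cell mass grows exponentially at
specific rate γ between birth and division (a linear-growth mode is provided
as a configuration switch); at division the mother splits into δ·M and
(1−δ)·M with δ ~ N(0.5, 0.0167). The θ_E condition acts on the cyclin E
*amount* [CycE]·M, so larger-than-average cells pass the early→late G1b
transition sooner: this weak size control is what gives the population a
stationary birth-size distribution.

Because the kinetics inside a state are linear, every trajectory segment is
an exact exponential relaxation C(t) = ks/kd + (C0 − ks/kd)·e^(−kd·t); a
whole life history needs only about a dozen random numbers and a handful of
algebraic evaluations, never a numerical ODE solve.

## Parameters

Defaults live in `src/hybridcycle/data/defaults.toml`, each key tagged
`paper` (a published value of the model) or `calibrated` (chosen here).
The published values are: k′_sa = 5 AU/h and the
state-1 effective degradation k′_da + k‴_da = 1.4 /h for cyclin A; the
threshold quartet θ_A = 12.5, θ_E = 21.25 (amount basis), θ_B″ = 3,
θ_B′ = 80; λ_1 = 2 h and the 7 h S floor; δ ~ N(0.5, 0.0167); the
threshold-noise factor G ~ N(1, 0.033); instrument noise SDs 0.03 (DNA) and
0.15 (cyclins); initial conditions [CycA]=[CycB]=[CycE]=1, M=3; and the
contact-inhibition constants p_0 = 0.5 /h, N_0 = 11,000, N_1 = 500 with 500
seed cells over 10 days.

The remaining rate constants are this package's calibration, fixed once
against three structural targets and then frozen:

1. **Mean cycle length ≈ 20 h.** γ defaults to ln 2 / 20 h ≈ 0.0347 /h;
   balanced exponential growth then pins the mean age at division to the
   mass doubling time exactly, and the duration of the size-controlled
   state 2 absorbs the slack. (`gamma_for_doubling_time` exposes the
   closed-form relation.)
2. **Total cyclin A at S entry ≈ 8 % of the population maximum** (the 99th
   percentile of [CycA]·M in an asynchronous sample), matching the reported
   ~50 of ~600 a.u. at DNA-synthesis onset. This fixed the TFB-driven
   cyclin A synthesis increment at 10 AU/h.
3. **Qualitative cyclin shapes**: modest cyclin A rise in early G1b while
   Cdh1 is still active, dramatic rise after Cdh1 switches off, precipitous
   fall when Cdc20A appears; slow cyclin B rise in late G1/S, rapid
   TFB-driven accumulation in G2, partial (~2-fold) degradation at anaphase
   (Cdc20B) and faster full degradation in telophase (Cdh1, kd 3.05 /h >
   anaphase's 1.55 /h); cyclin E rising only under TFE and destroyed by SCF
   during S.

The per-cycle threshold noise G (one draw per threshold per cycle,
multiplying θ) models cell-to-cell variability in transition machinery; a
configuration switch (`noise.threshold_sd = 0`) disables it.

## Simulation procedures and sizes

**Lineage sampling** follows one cell per generation: simulate a full cycle,
pick one daughter at random, repeat. The standard run is 32,500 iterations
with the first 500 discarded as burn-in (the birth-mass distribution reaches
its stationary form within a few tens of generations; 500 is conservative),
leaving 32,000 histories (~4 s).

**Flow sampling** assigns each history a cycle fraction φ from the ideal
asynchronous age density f(φ) = 2 ln2 · 2^(−φ) via inverse-CDF sampling
(φ = −log₂(1 − r/2)); the state at age φ·A_9 is found against the stored
boundary times (half-open intervals — a cell exactly at a boundary is in the
later state), concentrations and mass are evaluated in closed form, DNA is 1
before S, linearly interpolated to 2 across S, and measured channels are the
true values times independent N(1, σ) factors. Mass is exported noise-free
(no light-scatter error model).

**Contact inhibition** tracks every cell (both daughters) in an event-driven
queue ordered by division time. A cell entering G1a draws its waiting time
from Exp(1/p(N)) at the instantaneous population size N, with
p(N) = p_0 / (1 + exp((N − N_0)/N_1)) — a logistic form satisfying the
required limits (p ≈ p_0 when sparse, → 0 beyond N_0, strictly decreasing).
The drawn wait is kept by default; with `reevaluate_daily=True` cells still
in G1a at a daily snapshot redraw their residual wait at the current density
(exponential memorylessness makes this a clean restart). Cells whose G1a
exit falls beyond the simulated horizon are parked in state 1 (quiescence)
without materializing the rest of their cycle, which also guards the
exponential-growth arithmetic against astronomically long waits. Daily
snapshots record the live count and the G0/G1 (states 1–3), S (4), G2/M
(5–9) percentages. The default 10-day run from 500 cells ends near 2.7×10⁴
cells (~3 s): the plateau overshoots N_0 because cells already past G1a when
the brake engages still complete their cycles.

## Numerical choices

- Concentration thresholds invert in closed form;
  t = (1/kd)·ln((C0 − ks/kd)/(θ − ks/kd)). Amount thresholds solve
  C(t)·M(t) = θ by forward bracketing plus Brent refinement (xtol 1e−10 h);
  with γ = 0 the amount solver reduces exactly to the concentration solver.
- A threshold already satisfied at state entry yields crossing time 0 (the
  sequence only moves forward); a threshold on the wrong side of the
  asymptote ks/kd reports "unreachable" and aborts the simulation with a
  diagnostic naming the state and parameters.
- δ is clipped to (0.1, 0.9) — a ~24σ event at the default SD, so the window
  never binds in practice.
- Negative measured values after instrument noise are kept (they are
  vanishingly rare at σ ≤ 0.15 on positive signals) and counted in the event
  table's metadata.
- All randomness flows from one `numpy` Generator (CLI: a single master
  seed); the fully deterministic variant (`ModelConfig.deterministic()`)
  consumes no random numbers at all, so its output is byte-identical across
  seeds.

## What the simulations do and do not show

Every quantity in this package is generated by the model itself; there is no
experimental input. Agreement of the simulated flow scatters with published
cytometry patterns is therefore a statement about the model's structure and
its calibrated defaults, not a fit to data shipped here. Known limitations:
the Boolean sequence is fixed (no checkpoint re-routing, so no drug or
mutant perturbations); G1a↔quiescence is the only density-sensitive step;
there is no cell death or 4C→8C cycling; the population seed for the
contact-inhibition run starts synchronized in G1a, which produces damped
division waves over the first days (visible as a 2.0–2.5× daily count ratio
rather than a smooth 2.3×, and a plateau-detection day of 7 rather than 6
under the <5 %-increase rule); and instrument emulation stops at
multiplicative Gaussian noise (no gating, compensation or doublet
artifacts).
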