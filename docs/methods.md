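# Methods

This note documents the models implemented in `dynswitch`, the
numerical choices behind them, and the limits of what the test suite
demonstrates.

## Core model and conventions

A single protein interconverts between active (`X`) and inactive form,
with total concentration `X_T = X + X_inactive`:

```
dX/dt = f(X)(X_T − X) − g(X) X,
f(X) = a + b Xⁿ/(Kⁿ + Xⁿ),   g(X) = a′ + b′ K′ᵐ/(K′ᵐ + Xᵐ).
```

The Hill terms stand in for whatever molecular mechanism produces
ultrasensitivity (multisite phosphorylation, substrate competition, …);
with the standard constants (`b = K = b′ = K′ = 1`, `n = m = 5`,
`a′ = 0.1`) the steady state of `X` versus `X_T` is an S-shaped curve
with two folds for basal rates roughly `a ∈ (0.02, 0.4)`.  All slow
drives are scaled by `ε = 0.05`, so activation/inactivation is fast
against production, degradation and transport.

Conventions derived from the static switch at `a = ā` and used
everywhere else:

- `X_c` — midpoint of the two fold `X_T` coordinates (1.9594 at
  `ā = 0.3`); the center of the tanh modulation law.
- up/down thresholds — the `X` coordinates of the left and right folds
  (1.2034 and 0.6198 at `ā = 0.3`); a cycle is only counted if `X`
  crosses the up level upward *and* the down level downward, so
  small-amplitude wiggles near one branch never count as oscillations.
- transition threshold — the average of the two (0.9116); first upward
  crossing defines the transition time.

The modulation `a(X_T) = ā + Δa tanh(κ(X_T − X_c))` is evaluated either
instantaneously, with a lag (`a(t) = a(X_T(t − τ))`), or as a third
state variable relaxing at rate `1/δ`.  A single code path receives the
current `a` value, so the four modes cannot drift apart.

## Continuation

Response curves are traced by pseudo-arclength continuation: secant
predictor, Newton corrector on the augmented system, initial step 1e-2
adapting within [1e-5, 1e-1].  Two robustness measures matter with
exponents this steep:

- the corrector carries a trust radius (a solution further than 3× the
  step from the predictor is rejected and the step halved), because
  near the sharp left fold Newton can otherwise jump between branches
  or onto the spurious negative-`X` root family;
- when the parameter window ends before a distant right fold, the
  upper/middle branches form a second piece inside the window; a second
  segment is traced downward from the top of the window whenever the
  brute-force root count there exceeds the first segment's coverage.

Stability is the sign of ∂F/∂X (the system is scalar, so no eigenvalue
machinery).  Folds are bracketed where the direction of travel of the
continued parameter reverses and refined by a two-variable Newton
iteration on (F = 0, F_X = 0) to residuals below 1e-8.

Because the steady-state branch is single-valued in `X`, the closed
form `X_T(X) = X (f + g)/f` gives folds exactly by locating the
interior extrema of that map (`switch_folds_exact`).  This serves as an
independent oracle for the continuation and as the fast path in the
parameter survey.  A dense sign-change scan plus bisection
(`steady_states_bruteforce`) is the second oracle.  Edge case: at
`a = 0` exactly the activation threshold diverges, so only one fold
exists in any finite window; fold-count invariants are therefore stated
for `a > 0`.

## Deterministic integration

Runs without delay use LSODA with rtol 1e-8 / atol 1e-10 (the `ε⁻¹`
terms make the fast variable moderately stiff).  Delay runs, the
three-equation model and all large sweeps use a compiled fixed-step RK4
(numba).  Its step comes from the analytic stiffness bound: the maximum
of |∂F/∂X|/ε over the reachable region (worst-case basal rate `2a`,
`X_T` capped at max(5, 1.5× the right fold)) is kept at ≤ 1.2 per step,
with a cap of 4e-3; at the standard parameters this step reproduces the
adaptive integrator's period to 5e-7 relative.  A blow-up guard retries
once at one fifth of the step if the state goes non-finite.

The delayed basal rate is evaluated from a cubic-Hermite interpolation
of the stored `X_T` history with constant pre-history (the history
before `t = 0` equals the initial state).  `τ = 0` short-circuits to
the instantaneous branch, so the zero-delay reduction is exact; as
`τ → 0+` the delay path converges to the instantaneous one at the
stage-discretization level, O(dt²) (measured 2.5e-4 sup-norm at
dt = 1e-3 over 30 time units), which is the tolerance the reduction
tests use.

Period detection follows the two-threshold convention above with
alternation enforcement; amplitude detection smooths with a zero-phase
low-pass Butterworth filter (order 4, cutoff at 5× the dominant FFT
frequency — the filter family is fixed, the cutoff is the one free
choice and any envelope-preserving value behaves the same) and pairs
each maximum with the following minimum.

## Stochastic models

**Langevin.** Additive noise of magnitude σ on the fast variable only;
`X_T` evolves deterministically.  The integrator is stochastic Heun
(predictor–corrector drift, additive noise), chosen over plain
Euler–Maruyama because its deterministic order-2 limit meets the σ = 0
consistency bound (1e-3 sup-norm against the ODE) through the sharp
jump, where first-order drift does not.  `X` is clipped at zero; no
compensation noise is added.  Default dt = 1e-3.

**Gillespie.** Molecule counts `n_X`, `n_Y` with system size Ω
(concentration × Ω = count).  Reactions: activation at `ε⁻¹ f(n_X) n_Y`
with `f` using the Ω-scaled threshold `ΩK`; inactivation at
`ε⁻¹ g(n_X) n_X`; production of inactive protein at `k_X Ω`; and, for
the oscillator only, degradation of inactive protein at `n_X n_Y/Ω` and
of active protein at `n_X(n_X − 1)/Ω`.  Each degradation event removes
one molecule of the degraded species with the active protein acting
catalytically — this reproduces the mean-field `dX_T/dt = −X·X_T`
exactly, whereas consuming both reactants would double the degradation
flux.  The modulated basal rate uses `κ/Ω` and `Ω X_c`.  Default
initial condition: no molecules (`n_X = n_Y = 0`), matching the
deterministic transition setup.  Propensities are re-evaluated after
every event; no tau-leaping.

Per-replicate seeds are spawned from one master seed via
`SeedSequence`, so identical configuration + seed gives byte-identical
outputs.

A known structural limit, documented rather than hidden: the
*ensemble-mean* count trajectory cannot converge to the ODE in sup-norm
faster than the transition-timing jitter allows.  At Ω = 200 the
Poisson jitter of the crossing time (≈ 0.1 time units) is comparable to
the jump duration, so the mean smears the near-vertical jump and
deviates from the ODE by ≈ 15% of the peak there even though the error
decreases monotonically in Ω (36% → 22% → 15% for Ω = 10/50/200).
Agreement to a few percent in sup-norm would require Ω in the
thousands.

## Spatial model

Active and inactive protein diffuse (`D_X = D_Y = 5` by default) and
react with the same kinetics; `X_T` is the pointwise sum.  Forward
difference in time, centered second difference in space, zero-flux
(mirrored-node) boundaries.  The step obeys dt ≤ dx²/(2 max D) with a
0.4 safety factor, and a user step violating the bound is refused with
the admissible value reported.  Default grid dx = 0.2 on a domain of
length 100 — chosen so fronts travel far from the boundaries; the
stall-point estimate moves by < 0.005 when dx is halved.

Fronts start as a step between the two stable branch values at the
given `(a, X_T)`.  The front position is the interpolated crossing of
`X` through the midpoint of the branch values; the velocity is the
slope of a least-squares line through (t, position) after discarding
the first 10% of the window as relaxation transient and any snapshots
where the front sits within 2 length units of a boundary (fast fronts
can exit the domain before the window ends).  Positive velocity means
the active state advances; the zero crossing of velocity versus `a`
sits at a* ≈ 0.157 for the standard kinetics at `X_T = 2`.

The pinning protocol uses a tanh profile of `a` in space (high 0.27 on
the left, low 0.13 on the right, steepness 0.2 around the domain
center — the profile shape is fixed, its steepness and extent are free
defaults); the front launched on the left stalls where the profile
crosses a*, and a smoothstep blend to the mirrored profile at
t = 25 releases it.

## Random-parameter survey

Each set draws `a ∈ [0.05, 0.6]`, `a′ ∈ [0.01, 0.5]`,
`b, b′, K, K′ ∈ [0.5, 2]`, `n, m ∈ [2, 8]`, `k_X ∈ [0.5, 3]` uniformly
and `ε` log-uniformly on [0.01, 1].  These intervals bracket the
standard constants; they were fixed once, before any acceptance run.
Sets whose static switch at the sampled `a` is not bistable (exact fold
finder) are counted as non-oscillatory without simulation.  Bistable
sets are integrated for T = 200 per condition (`Δa = i·a` for
multipliers i, κ ∈ {1, 5, 10}, τ ∈ {0, 0.1, 0.2}) and classified
oscillatory when the detected mean period exceeds 0.01.  The default
run size in the acceptance suite is 500 sets — large enough that the
static-versus-dynamic comparison is strict in every (κ, τ) cell, small
enough to finish in a few minutes on one CPU.

## Mitotic-entry model

Six ODEs: total Cyclin B–Cdk1, active Cdk1 and Cdc25 level in nucleus
and cytoplasm.  Activation scales with the compartment's Cdc25 level
times a steep Hill activity in Cdk1 (basal 0.16, max 0.8, EC50 35 nM,
exponent 11); inactivation with the fixed Wee1 level (1.3 nuclear, 1.0
cytoplasmic) times a shallower decreasing Hill activity (basal 0.08,
max 0.4, EC50 30 nM, exponent 3.5) — the classic Cdk1-oscillator
parameterization, in nM and minutes.  Synthesis (`k_s = 1.5` nM/min)
is cytoplasmic only and complexes are born active.  Import multipliers
are linear in active Cdk1: `I_Cyc = 0.1 + Cdk1_n/30` for Cyclin B–Cdk1
and `I_Cdc = 1 + Cdk1_c/60` for Cdc25 (the coefficient denominators are
exposed as `c_cyc`, `c_cdc`).  Transport rates
(`kn_cyc = 0.2, kc_cyc = 0.1, kn_cdc = 0.05, kc_cdc = 0.1` /min) are
slow against activation and were chosen so that (i) the initial Cdc25
distribution (1 nuclear : 2 cytoplasmic) is stationary before any
activation (`kn_cdc·I_Cdc(0) = 0.5·kc_cdc`) and (ii) the canonical
sequence holds: cytoplasmic activation (t ≈ 51 min) precedes nuclear
activation (t ≈ 72 min), Cdc25 import pulls the nuclear threshold from
88 to below 60 nM, and after the nuclear jump Cdk1_n keeps rising while
Cdk1_c plateaus.

Total Cdc25 is conserved and total Cyclin grows exactly at `k_s`, both
by construction of the equations (verified to 1e-8 over full runs).
Jump thresholds are each compartment's instantaneous response-curve
convention (average of the fold Cdk1 coordinates) at t = 0.  The
instantaneous response curve reuses the generic continuation by mapping
the compartment's kinetics onto the `f/g` form with rescaled constants.

In the control with symmetric Wee1 and no import feedback the
compartments are still not mirror images — synthesis is cytoplasmic
only, so the nucleus sees protein only through weak basal import and
never activates within the window.  The control test therefore asserts
that the ordering *guarantee* is lost, not that the jumps tie.

## What the tests do and do not show

The synthetic experiments emulate the study conditions (standard
constants, σ = 0.6, Ω = 10–200, T = 200–4000, 100–200 replicates,
500-set survey); stochastic assertions are trend-level with bootstrap
error bars, not printed-value comparisons.  Passing them shows the
mechanisms — threshold motion tightening transition timing, modulation
widening the oscillatory regime, gradient pinning of fronts, ordered
compartmental activation — operate in these models as described.  It
does not show that real mitotic switches have these parameter values:
the mitotic transport rates are illustrative by design, the Langevin
noise enters only the fast variable, and the tanh coupling of `a` to
`X_T` is a stand-in for whatever biochemistry actually reshapes a
cell's response curve.

## Known limitations

- One spatial dimension only; no curvature effects, no explicit
  nuclear compartments in the PDE.
- No limit-cycle continuation or Hopf detection; oscillatory regions
  are mapped by direct simulation, so their boundaries inherit the
  period detector's amplitude convention.
- The Gillespie implementation is exact but unaccelerated; large Ω and
  long horizons cost proportionally.
- Delay is supported in the deterministic variants only; the
  stochastic models modulate instantaneously.
- For strongly negative Δa the survey can report small-amplitude
  oscillations whose character depends on the modulation
  implementation itself; they are reproduced qualitatively only.
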