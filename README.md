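# dynswitch

Simulation and analysis of bistable biochemical switches whose response
curve changes in time, modeled on the Cdk1/Wee1/Cdc25 switch that
drives mitotic entry.

Many cell-cycle transitions are read off a bistable response curve: the
steady-state activity `X` of a self-activating protein is bistable in
its total concentration `X_T`, and the transition fires when slow
accumulation of `X_T` carries the system past a saddle-node (fold)
point.  In real cells the *shape* of that curve is itself dynamic —
protein levels that set the thresholds change by synthesis, degradation
and nucleocytoplasmic transport while the transition is underway.  This
package is for modelers who want to explore what such dynamic switches
buy the cell: sharper timing of noisy transitions, wider oscillatory
regimes, and spatial control of traveling activity fronts.

## The model

The core kinetics are

```
dX/dt = f(X) (X_T − X) − g(X) X
f(X) = a + b Xⁿ / (Kⁿ + Xⁿ)          (autocatalytic activation)
g(X) = a′ + b′ K′ᵐ / (K′ᵐ + Xᵐ)       (self-suppressed inactivation)
```

with standard constants `b = K = b′ = K′ = 1`, `n = m = 5`,
`a′ = 0.1`, and a timescale separation factor `ε = 0.05` multiplying
the slow drive.  Model variants built on this scalar switch:

- **transition** — `dX_T/dt = k_X` (linear accumulation towards the
  activation threshold);
- **oscillator** — `dX_T/dt = k_X − X_T X` (production balanced by
  activity-driven degradation; a relaxation oscillator between the two
  folds);
- **dynamic switch** — the basal rate follows total protein,
  `a(X_T) = ā + Δa·tanh(κ(X_T − X_c))`, optionally with a lag τ or as
  a third ODE `da/dt = δ⁻¹(H(X_T) − a)`;
- **stochastic** — a Langevin version (additive noise σ on the fast
  variable) and an exact Gillespie version with system size Ω;
- **spatial** — a 1-D reaction–diffusion model of active/inactive
  protein supporting bistable traveling fronts;
- **mitotic entry** — a two-compartment (nucleus/cytoplasm) Cdk1 model
  in which Cdc25 translocation reshapes each compartment's response
  curve on the fly.

A pseudo-arclength continuation traces response curves through their
folds; the fold coordinates define the event thresholds and the
modulation midpoint `X_c` used by every detector.

## Worked example

```python
from dynswitch import STANDARD_PARAMS, trace_response_curve, run_timing_experiment

curve = trace_response_curve(STANDARD_PARAMS, "X_T", fixed_value=0.3, p_range=(0, 5))
for sn in curve.saddle_nodes:
    print(f"fold at X_T = {sn.parameter:.4f}, X = {sn.X:.4f}")

df = run_timing_experiment(
    "langevin", STANDARD_PARAMS, delta_a_values=[0.0, 0.3],
    kappa=5.0, k_X=1.0, sigma=0.6, replicates=100, seed=42,
)
print(df[["delta_a", "mean", "sd", "cv"]].to_string(index=False))
```

prints

```
fold at X_T = 1.6579, X = 1.2034
fold at X_T = 2.2609, X = 0.6198
 delta_a     mean       sd       cv
     0.0 2.408964 0.134605 0.055877
     0.3 2.121843 0.031772 0.014974
```

The folds bracket the bistable band of total protein: accumulation at
`k_X = 1` crosses the activation fold near `t ≈ 2.26`, and with noise
`σ = 0.6` the measured transition times scatter around `t ≈ 2.4`.
Making the switch dynamic (`Δa = 0.3`) drops the coefficient of
variation of that timing from 0.056 to 0.015 — the moving threshold
holds activity down until the last moment and then forces a sharp,
well-timed jump.

The `examples/` directory has one short script per capability
(response curves, transition timing, oscillations, fronts and pinning,
mitotic entry, the random-parameter survey).  A thin CLI wraps the same
functions:

```sh
dynswitch curve --a 0.3 --out out/curve
dynswitch oscillate --k-x 1.7 --out out/osc
dynswitch spatial --mode pinning --out out/pin
```

Each run directory receives the tables, a JSON summary, the resolved
configuration and a log, so any run can be reproduced exactly.

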