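"""Timing robustness of a noisy activation transition.

Total protein accumulates at rate k_X while noise (sigma = 0.6) rattles
the fast activity variable, so the moment X first crosses the
transition threshold varies between runs.  Coupling the basal rate a to
X_T (a dynamic switch, delta_a > 0) keeps activity low until the last
moment and sharply reduces the spread of transition times.
"""

from dynswitch import STANDARD_PARAMS, run_timing_experiment

df = run_timing_experiment(
    "langevin",
    STANDARD_PARAMS,
    delta_a_values=[0.0, 0.3],
    kappa=5.0,
    k_X=1.0,
    sigma=0.6,
    replicates=100,
    seed=42,
)
print(df.to_string(index=False))
print()
cv0 = df.loc[df["delta_a"] == 0.0, "cv"].iloc[0]
cv3 = df.loc[df["delta_a"] == 0.3, "cv"].iloc[0]
print(f"CV drops from {cv0:.3f} (static switch) to {cv3:.3f} (dynamic):")
print("the moving activation threshold makes the transition time more precise.")
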