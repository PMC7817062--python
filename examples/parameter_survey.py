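"""Random-parameter survey: dynamic switches promote oscillations.

Hill-kinetics constants, the timescale factor epsilon (log-uniform) and
the production rate k_X are drawn at random; each bistable set is
simulated with the basal rate either static (i = 0) or coupled to total
protein with amplitude delta_a = i*a.  The oscillating fraction rises
when the switch is dynamic, the more so for steeper (kappa) and lagged
(tau) coupling.  (Run here at a small size for speed; the acceptance
suite uses 500 sets.)
"""

from dynswitch import random_survey

df = random_survey(
    n_sets=60,
    i_multipliers=(0.0, 1.0),
    kappas=(5.0, 10.0),
    taus=(0.0, 0.2),
    seed=42,
)
print(df.to_string(index=False))
print(f"\nbistable sets: {df.attrs['n_bistable']} of {df.attrs['n_sets']}")
print("Rows with i = 1 (delta_a = +a) oscillate at least as often as the")
print("static rows, and the advantage grows with kappa and tau.")
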