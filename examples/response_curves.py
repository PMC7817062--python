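"""Trace the bistable response curve and derive the switch conventions.

The steady-state activity X of the self-activating protein is bistable
in the total concentration X_T: between the two saddle-node (fold)
points a low- and a high-activity branch coexist.  The fold coordinates
define the activation/inactivation thresholds and the modulation
midpoint X_c used by every other experiment.
"""

from dynswitch import (
    STANDARD_PARAMS,
    event_thresholds,
    midpoint_Xc,
    trace_response_curve,
)

params = STANDARD_PARAMS  # b = K = b' = K' = 1, n = m = 5, a' = 0.1

curve = trace_response_curve(params, "X_T", fixed_value=0.3, p_range=(0.0, 5.0))
print(f"continued {len(curve)} points; {len(curve.saddle_nodes)} saddle nodes:")
for sn in curve.saddle_nodes:
    print(f"  fold at X_T = {sn.parameter:.4f}, X = {sn.X:.4f}")

up, down, trans = event_thresholds(params, a_bar=0.3)
print(f"X_c (modulation midpoint)      = {midpoint_Xc(params, 0.3):.4f}")
print(f"up / down crossing thresholds  = {up:.4f} / {down:.4f}")
print(f"transition-time threshold      = {trans:.4f}")
print()
print("The folds bracket the bistable band of total protein; their X")
print("coordinates are the levels the period and transition detectors use.")
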