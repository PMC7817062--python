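"""Traveling fronts in space: velocity, stall point and pinning.

With diffusion, a boundary between high- and low-activity regions moves
at a velocity set by the basal rate a: the dominant state advances.
Near a ~ 0.15 the two states balance and the front stalls, so a spatial
a-gradient pins an incoming front where the gradient crosses that
value; flipping the gradient releases it.
"""

import numpy as np

from dynswitch import STANDARD_PARAMS, pinning_experiment, stall_point, velocity_scan

params = STANDARD_PARAMS

scan = velocity_scan(params, [0.12, 0.15, 0.18, 0.21, 0.24], X_T=2.0)
print(scan.to_string(index=False))
a_star = stall_point(params, np.round(np.arange(0.12, 0.2001, 0.01), 3))
print(f"\nstall point: front velocity crosses zero at a* = {a_star:.3f}")

fields, positions, pinned = pinning_experiment(
    params, high_a=0.27, low_a=0.13, flip_time=25.0, t_end=40.0
)
a0 = fields[0]
print(f"front pinned at x = {pinned:.1f}, where the a profile is "
      f"{np.interp(pinned, a0.x, a0.a):.3f} (close to a*)")
released = positions[(positions['t'] > 28)].dropna()
if len(released):
    print(f"after the profile flip at t = 25 the front resumes: "
          f"x = {released['position'].iloc[0]:.1f} at t = {released['t'].iloc[0]:.0f}")
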