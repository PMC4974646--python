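"""The mountain-top scenario: short trajectories, positive exposure.

Two cool ridges separated by a warm valley 0.5 °C above the source ridge.
The only future analogues of ridge pixels lie on the far ridge, so every
trajectory must cross the valley — one 5-km pixel in the second
dissimilarity cost band — and accrues MCE = 2.5 °C at penalty p = 2.
"""

import numpy as np

from climtraj import MethodParams, compute_mce, make_ridge_valley, run_forward

for valley_width in (1, 2):
    current, future, truth = make_ridge_valley(valley_width=valley_width)
    result = run_forward(current, future, MethodParams())
    src = truth["source_rows"]
    mce = result.mce[src, :]
    r, c = src[-1], current.shape[1] // 2
    traj = result.trajectories[(r, c)]
    print(f"valley width {valley_width} pixel(s): "
          f"MCE = {np.unique(mce[np.isfinite(mce)])} °C "
          f"(expected {truth['expected_mce_at_defaults']}), "
          f"MED = {traj.med:.0f} km, accumulated cost = "
          f"{traj.accumulated_cost:.0f}")
    assert compute_mce(traj) == truth["expected_mce_at_defaults"]

# MCE tallies the °C of dissimilarity met along the path regardless of its
# length: a 10-km trajectory over a warm valley is more exposed than a
# 100-km trajectory over climatically homogeneous terrain.
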