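"""Sensitivity of velocity and MCE to resolution, bin width and penalty.

Reruns the full pipeline on the ridge-valley landscape across parameter
combinations and prints the summary table (geometric means over positive
values and 5/50/95th percentiles), illustrating the documented trends:
velocities and MCE fall as the analogue bin widens and rise as the data
are coarsened.
"""

import pandas as pd

from climtraj import make_ridge_valley, sweep

current, future, _ = make_ridge_valley(shape=(24, 12))
table = sweep(current, future,
              resolutions=(1, 2),
              bin_widths=(0.5, 1.0),
              penalties=(2.0, 4.0))

cols = ["resolution_km", "bin_width", "penalty",
        "gmean_velocity_med", "gmean_velocity_ed", "gmean_mce",
        "frac_mce_zero", "p50_mce"]
with pd.option_context("display.width", 120):
    print(table[cols].to_string(index=False, float_format="%.3f"))

# Doubling the penalty p halves MCE on unchanged paths (the integer cost
# surface does not depend on p); widening the bin from 0.5 to 1.0 °C makes
# the warm valley an analogue, dropping MCE to zero.
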