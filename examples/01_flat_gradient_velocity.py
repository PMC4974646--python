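"""Climate velocity on flat terrain: long paths, zero exposure.

Builds a flat landscape with a pure latitudinal temperature gradient
(0.05 °C per 5-km pixel, i.e. 0.01 °C/km) warming uniformly by 1 °C over
90 years, then routes every pixel to its future climate analogue.
"""

import numpy as np

from climtraj import make_flat_gradient, run_forward

current, future, truth = make_flat_gradient(
    shape=(50, 20), pixel_size=5.0, gradient=0.05, warming=1.0)
result = run_forward(current, future)

valid = result.valid_mask
r0 = truth["reference_row"]
print(f"exact-match analogue displacement: {truth['displacement_km']:.0f} km "
      f"({truth['displacement_pixels']:.0f} pixels poleward)")
print(f"nearest analogue (bin edge):       "
      f"{truth['nearest_analogue_displacement_km']:.0f} km")
print(f"MED at row {r0}:        {result.med[r0, 10]:.1f} km")
print(f"velocity_MED there:   {result.velocity_med[r0, 10]:.3f} km/yr")
print(f"velocity_ED there:    {result.velocity_ed[r0, 10]:.3f} km/yr")
print(f"max MCE over grid:    {np.nanmax(result.mce[valid]):.2f} °C")

# On flat terrain the least-exposure path IS the straight line (MED = ED) and
# every traversed pixel warms through the source temperature, so the
# cumulative exposure is exactly zero: high velocity, no climatic resistance.
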