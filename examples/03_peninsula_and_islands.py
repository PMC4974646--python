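"""Northward peninsula: southward trajectories and island exclusion.

A north-pointing land tongue is surrounded by water on three sides; the
only analogues of its cool tip sit on a cold highland on the southern
mainland.  Trajectories from the tip must run south through warmer rows
(positive MCE) because the poleward route is open water.  A one-pixel
island in the water is flagged by the island policy and dropped from
statistics.
"""

from climtraj import make_peninsula, run_forward

current, future, truth = make_peninsula()
result = run_forward(current, future)

tr = truth["tip_row"]
c = sum(truth["tip_cols"]) // 2
print(f"tip pixel ({tr},{c}):  MCE = {result.mce[tr, c]:.1f} °C, "
      f"MED = {result.med[tr, c]:.1f} km, "
      f"destination row {result.dest_row[tr, c]} (tip row {tr}: southward)")
print(f"island pixel {truth['island_pixel']} excluded: "
      f"{bool(result.island_excluded[truth['island_pixel']])}")

# Control: fill the water with land continuing the gradient; the tip regains
# a monotone poleward route and its exposure vanishes.
cur_land, fut_land, _ = make_peninsula(all_land=True)
control = run_forward(cur_land, fut_land)
print(f"all-land control:    MCE = {control.mce[tr, c]:.1f} °C, "
      f"destination row {control.dest_row[tr, c]} (poleward)")
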