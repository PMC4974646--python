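"""Forward exposure vs reverse accessibility on the same landscape.

Forward trajectories route a pixel's current climate to its future
analogue (what organisms there will experience).  Reverse trajectories
route a pixel's future climate back to a current analogue (how accessible
the site is to colonisers).  Under a symmetric flat gradient the two are
mirror images.
"""

from climtraj import make_flat_gradient, run_forward, run_reverse

current, future, _ = make_flat_gradient(shape=(30, 10), pixel_size=5.0,
                                        gradient=0.1, warming=1.0)
fwd = run_forward(current, future)
rev = run_reverse(current, future)

r, c = 15, 5
print(f"pixel ({r},{c}) current {current.values[r, c]:.1f} °C, "
      f"future {future.values[r, c]:.1f} °C")
print(f"forward: destination row {fwd.dest_row[r, c]} "
      f"({r - fwd.dest_row[r, c]} px poleward), MED {fwd.med[r, c]:.0f} km")
print(f"reverse: source-analogue row {rev.dest_row[r, c]} "
      f"({rev.dest_row[r, c] - r} px equatorward), MED {rev.med[r, c]:.0f} km")
print(f"both zero-exposure: MCE fwd {fwd.mce[r, c]}, rev {rev.mce[r, c]}")
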