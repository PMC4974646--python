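# Methods

## Model

`climtraj` treats climate-change exposure as a routing problem on a raster
temperature field. A *climate analogue* of a source pixel with (rounded)
current mean annual temperature *T* is any pixel whose temperature in the
target period lies within *T* ± *h*, with half-width *h* = 0.25 °C by
default (bin width 0.5 °C). One routing problem is solved per 0.1 °C
isotherm increment: the increments partition the sources, every 0.1 °C
value present among land pixels is evaluated, and the 0.5 °C bin is wider
than the increment deliberately, so that pixels at 4.9 and 5.1 °C count as
analogues of the 5.0 °C isotherm rather than falling into separate bins.

### Cost surfaces

The dissimilarity cost of pixel *i* against increment *T* is an integer
band:

    cost_i = 1                                   if |T − T_i| ≤ h
    cost_i = 1 + ⌈(|T − T_i| − h) / (2h)⌉        otherwise

The +1 exists because least-cost algorithms cannot route over zero cost and
because it makes accumulated cost equal path distance along fully-analogue
paths — the property the MCE formula relies on. At the defaults this yields
0.5 °C-wide bands: dissimilarity (0.25, 0.75] costs 2, (0.75, 1.25] costs
3, and so on.

Band boundaries are closed above: |ΔT| exactly equal to *h* is an analogue,
and a dissimilarity of exactly 0.75 °C falls in the cost-2 band. Boundary
hits are rare because inputs are rounded to 0.1 °C on ingest (half away
from zero), but the convention is defined and guarded by a 1e-9 epsilon
against float representation of decimal values.

The integer banding is the canonical form. A continuous alternative,
cost = p·|ΔT| + 1, is available via `MethodParams(cost_form="continuous")`
for sensitivity work; in the banded form the penalty *p* enters only the
MCE conversion below, which keeps "double *p* ⇒ halve MCE" exact on
unchanged trajectories.

### Temporal compositing

Temperature grids are linearly interpolated between the current and future
periods (*n* = 31 steps by default, ≈3-year increments over 90 years;
endpoints are the input grids exactly, intermediates are not re-rounded to
0.1 °C since re-rounding would only create avoidable bin-boundary
artefacts). The final cost surface for an increment is the elementwise
*minimum* of the per-step costs: a pixel is charged at whichever time its
climate is most similar to the isotherm. This lets trajectories follow the
climate as it warms and keeps the accounting honest — the destination, an
analogue by definition in the final period, costs 1 rather than reflecting
start-of-period dissimilarity, and a poleward path on a monotone gradient
under uniform warming has zero exposure.

Water pixels are overridden to `water_cost` = 5000 *after* the composite
(the penalty is a property of the final surface, not of individual time
steps), which heavily penalises but does not forbid crossings. Water is
routable; it is never a source or an analogue. Land nodata is unroutable.

### Routing

Pixels are nodes of a grid graph (8-connected by default, 4 available);
the edge between adjacent pixels *a*, *b* weighs
((cost_a + cost_b)/2) · length, with length = pixel size for cardinal moves
and √2 × pixel size for diagonals. Accumulated cost is exact Dijkstra
(scipy.sparse.csgraph; all weights positive). The destination is the
analogue with least accumulated cost; ties are broken by smaller
straight-line distance to the source, then row-major pixel order, making
runs bitwise reproducible. Sources whose analogue set is empty or
unreachable are flagged (`no_analogue`), not fatal.

The extracted trajectory assigns each pixel *i* a traversal length *l_i*:
half the summed lengths of its incident path edges, endpoints carrying one
half-edge. Two identities then hold exactly (to float summation, checked at
1e-9 relative tolerance in tests): Σ l_i = MED, and Σ cost_i·l_i =
accumulated cost. The arithmetic-mean edge weight was chosen over
conductance-style means precisely because it preserves this accounting,
which the exposure metric requires.

### Metrics

* velocity = distance / elapsed time. Elapsed time defaults to 90 years
  (midpoint-to-midpoint of 1981–2010 and 2071–2100; a helper derives it
  from period strings).
* MCE = (Σ cost_i·l_i − MED) / p, computed as Σ (cost_i − 1)·l_i / p so
  that all-analogue paths give exactly 0.0 rather than a rounding residue.
  Units: °C (the penalty *p* = 2 cost units per °C converts excess cost
  back to temperature).
* The MED/ED ratio is 1 when MED = ED = 0 (self-analogues) and undefined
  (NaN) if ED = 0 with MED > 0, which cannot occur under the shared
  analogue definition but is guarded.
* Reverse (accessibility) mode swaps grid roles — sources are future-grid
  pixels, analogues are drawn from the current grid — and reverses the
  interpolated series; everything else is identical.

### Classification and islands

The bivariate scheme crosses velocity_MED, split at its median over valid
(unflagged) pixels, with MCE split at zero: classes 1–4 =
{low,high}-velocity × {zero,positive}-MCE. MCE = 0.0 is "low" regardless of
velocity. Islands — 8-connected land components other than the largest
(optionally, smaller than a minimum area) — are excluded: a source on an
island, or routed to an island, is flagged and dropped from medians, maps
and summaries, because its accumulated cost is dominated by the arbitrary
water penalty. Exclusion happens before the median is computed.

## Synthetic landscapes

Three deterministic generators provide ground truth:

* **flat gradient** — latitudinal gradient + uniform warming. The
  exact-match analogue sits warming/gradient pixels poleward; the *nearest*
  analogue sits at the near edge of the ±h bin, i.e. roughly
  (warming − h)/gradient pixels away, and the truth dict reports both (the
  nearest via an independent 1-D scan of the rounded lattice). MED = ED and
  MCE = 0 everywhere.
* **ridge/valley** — an elevation profile (°C-equivalent units via a lapse
  rate) building a source ridge, a warm valley of configurable width and
  ΔT, and a destination ridge whose future temperature equals the source
  ridge's current temperature. With ΔT = 0.5 °C the valley sits in the
  cost-2 band at every interpolation time, so MCE =
  valley_width × pixel_size × (band − 1)/p exactly (2.5 °C for one 5-km
  pixel, 5.0 °C for two, at p = 2).
* **peninsula** — a north-pointing land tongue flanked by water, with the
  tip's only analogues on a cold highland on the southern mainland;
  trajectories run south through warmer-than-bin rows (MCE > 0) and the
  all-land control restores the zero-exposure poleward route. The
  default warming keeps the poleward displacement inside the water frame
  so the control has an on-grid analogue. A one-pixel island exercises the
  exclusion policy.

These landscapes emulate the geometric and thermal structure the metrics
respond to — gradients, barriers, warm gaps, water — but not spatially
correlated warming fields, interannual variability, coastlines with
realistic fractal structure, or multi-variable climate spaces. Passing
tests therefore demonstrate the correctness of the machinery and the
qualitative behaviours (orderings, monotonicities, zero/positive exposure
regimes), not quantitative agreement with any real-world dataset.

## Sensitivity analysis

`sweep` reruns the pipeline over combinations of resolution (integer
block-mean coarsening; pixel size scales, partial edge blocks dropped,
aggregated values re-rounded to 0.1 °C, a block is water when at least half
its pixels are), analogue bin width, and penalty, and reports geometric
means and 5/50/95th percentiles of velocity_MED, velocity_ED, their ratio
and MCE. Geometric means are taken over strictly positive values; zero
counts are reported separately (`n_zero_*`), and MCE percentiles are given
over the MCE > 0 subset together with the MCE = 0 fraction. The block
statistic is mean; other resampling statistics would shift bin membership
near boundaries and are not offered.

## Numerical and design choices

* Ingest rounding: nearest 0.1 °C, halves away from zero, idempotent.
* All distances are planar in the projected grid's km units; geographic
  (degree) rasters are rejected at read time.
* Problem sizes: the test-suite and acceptance fixtures use grids between
  12×6 and 50×50 pixels — large enough to contain every geometric feature
  the metrics respond to while the full suite runs in seconds.
* Trajectories are stored per source on request (`store_trajectories`),
  exportable as GeoJSON LineStrings with MED/ED/MCE properties.

## Known limitations

* Single climate variable (temperature); no multivariate dissimilarity.
* Planar distances only; no geodesic correction, reprojection or
  multi-band I/O.
* Per-increment Dijkstra from every source is exact but scales with
  (sources × pixels); continental grids would need the tiled/multi-source
  optimisations deliberately left out here.
* The reverse-mode definition (role swap + reversed series) is declared
  rather than taken from an external formal specification; forward/reverse
  symmetry on symmetric inputs is verified in tests.
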