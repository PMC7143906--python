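# Methods

## Model

The package implements a weighted-overlay pressure index for groundwater
monitoring design. The study area — a polygon in a projected metric CRS —
is tiled with axis-aligned square cells of side `cell_size` (default
10 000 m), anchored at the lower-left corner of the area's bounding box
(configurable offset). Each nonempty cell∩area intersection is a block.
Cells are half-open, `[x0+j·d, x0+(j+1)·d) × [y0+k·d, y0+(k+1)·d)`, so
every point of the plane belongs to exactly one cell and boundary points
are never double-counted.

Clipping an irregular coastline leaves undersized fragments. A block with
`actual_area < min_area_fraction × cell_size²` (default fraction 0.5) is
unioned into the neighbor with which it shares the *longest boundary*,
iterating until no block is undersized; an undersized block with no
positive-length neighbor is kept and flagged. The longest-shared-boundary
rule is a reproducible, purely geometric proxy for "nearest"; ties break
by smallest block id. Merging conserves total area and is idempotent.

Each pressure layer *i* is a set of point sources with a weight
*wᵢ* ∈ [0, 1]. A block's score is Σᵢ nᵢwᵢ with nᵢ the in-block point
count. The score is additive, monotone in added points, and conserved:
block scores sum exactly (to float addition, asserted at 1e-9) to
Σᵢ (in-area points of layer i)·wᵢ. Facilities are modeled as single
representative points, even areal sources (landfills, quarries): the index
counts containment only, with no distance decay or cross-block influence.

Scores rounded to one decimal are binned into K classes by upper edges
(default 10.0, 20.0, 30.0, ∞ for K = 4; intervals `(edgeₖ₋₁, edgeₖ]`).
Class 1 extends down to zero so every block is monitored. Wells per class
default to 1/2/3/4 and must be non-decreasing in class — heavier pressure
never means fewer wells.

## Default registry

12 layers: urban waste-water discharges (0.3), IPPC industrial plants
(0.8), potentially contaminated sites (1.0), waste storage/management
companies (0.8), authorized atmospheric emitters (0.5), PCB treatment
plants (1.0), livestock farms (0.1), active quarries (0.2), urban solid
waste landfills (1.0), major-accident-hazard activities (0.2), disused
quarries (0.6), sinkholes (0.8). Weights reflect expert judgment on
potential groundwater impact and are taken as fixed inputs; the package
does not calibrate them. Sinkholes are the single *natural* pressure: in
karst terrain they are direct recharge points of the aquifer.

## Synthetic data

The generator emulates the study conditions so the pipeline is testable
without institutional GIS data:

* **Area** — a rectangle (default 60 km × 55 km, giving ~30 blocks at
  10 km cells) or a shipped synthetic coastal-peninsula outline
  (~2 670 km², comparable to a mid-size Mediterranean province). The
  peninsula grids into 39 raw cells of which 12 are undersized at the
  default merge fraction, leaving 27 blocks after merging — deliberately
  exercising the merge step. The outline is synthetic, not real
  cartography.
* **Points** — per-layer counts default to the published 12-layer
  inventory (34, 37, 28, 69, 164, 7, 770, 222, 10, 4, 22, 224; 1 591
  total), so whole-layer score totals are count×weight products and
  reproduce the published per-layer totals regardless of the spatial
  process. Two processes: `uniform` (bbox rejection sampling inside the
  polygon) and `clustered` (Thomas-type: default 25 uniform parents,
  Gaussian offspring displacement σ = 3 000 m, resampled until inside).
  The real data's clustering is unknown; both are provided because class
  membership — unlike layer totals — depends on spatial concentration.
  The cluster defaults are a plausible industrial-district scale, chosen
  once as realistic rather than fitted to anything.
* **Seeding** — one root seed; each layer draws from a substream derived
  from (seed, layer index), so changing one layer's count leaves the
  others' coordinates untouched.

What passing tests on synthetic data show: the geometric, counting,
scoring, binning and allocation machinery is exact and deterministic.
What they cannot show: whether the weights, the 10 km cell, or the class
edges are appropriate for any particular aquifer — those are domain
judgments the package takes as inputs. Per-block scores of the original
study are not reproducible because its georeferenced layers are
unpublished; only the count-and-weight arithmetic and the allocation rule
are checkable, and are.

## Numerical choices

* Point-in-block assignment uses the half-open cell index as a fast path,
  verified against the final (clipped/merged) block polygon; any point not
  resolved that way (exactly on a clipped boundary, or with externally
  built tessellations) falls back to testing blocks in ascending block id
  and taking the first whose geometry covers it, guaranteeing each in-area
  point is counted exactly once. Points outside every block are excluded
  from scores and reported per layer as a warning, not an error.
* Declared-CRS mismatch between a layer and the study area is an error;
  geographic (degree) CRS identifiers are rejected outright since meter
  cell sizes would be meaningless. There is no reprojection.
* Class binning rounds scores to one decimal with an explicit half-up rule
  rather than float banker's rounding, so bin membership near an edge is
  representation-independent (10.05 → 10.1 → class 2).
* Grid construction drops slivers below 1e-9 of a cell area (numerical
  noise of the polygon intersection); tiling is asserted to cover the area
  within 1e-6 relative error.
* Reported tables print one decimal; full-precision values are kept in a
  JSON sidecar and in the `raw_total` fields. Outputs are byte-identical
  across runs for the same config and seed.

## Problem sizes

Tests and the acceptance script run the full pipeline on the peninsula
fixture (39 raw / 27 merged blocks, 1 591 points), the conservation suite
over 20 seeded scenarios (2 areas × 2 processes × 5 seeds), and the
assignment oracle over 10 seeds × 2 000 points against a naive all-pairs
point-in-polygon loop — sizes at which the brute-force oracles are exact
and fast.

## Known limitations

* Containment-only counting: a large source sitting on a block edge
  influences only the block holding its representative point.
* The merge rule is one defensible reading of "absorb small coastal
  fragments into the nearest block"; other proxies (centroid distance,
  largest neighbor) would yield slightly different merged layouts.
* Well siting inside a block (`centroid`, `pressure_weighted`) is a
  presentation convenience, not an optimization against hydrogeological
  flow; the default leaves coordinates unset.
* Uniform/Thomas processes do not emulate real settlement geography
  (coastal concentration, road networks, zoning).
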