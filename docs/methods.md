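# Methods

## Model and assumptions

The package scores the *potential* for lake-ecosystem degradation from
watershed characteristics, not observed water quality.  The underlying
assumptions are those of the WRASTIC/DRASTIC family of multi-criteria
indices: each land-use pressure in the reception basin contributes
additively to degradation potential, the contribution is adequately captured
by a small integer grade times a fixed weight, and the physical setting
(slope, aspect toward the lake, soil permeability) modulates how much of
that pressure actually reaches the lake.  The Hazard Index does not enter
the classified value itself; it selects which threshold set applies, so a
physically vulnerable lake (steep, clay-soiled, draining toward the water)
is held to stricter WRASTIC bounds.

All tabular arithmetic is integer, so classifications are bit-exact and
platform independent.

## Scoring rubrics

Interval rubrics (irrigation share, agricultural share, watershed area,
vegetation cover) are left-closed, right-open with the final bin closed, so
contiguous printed intervals such as 10–25% / 25–50% form a partition; a
value exactly on an edge falls in the upper bin.  Categorical
multi-source indicators (wastewater, recreation, transport, industry)
combine sub-grades by maximum, the only combiner we found consistent with
every reference grade we could cross-check against the narrative
descriptions of individual lakes; it also makes the rubrics monotone (an
added pressure source never lowers a grade).

Two rubric ambiguities required a decision:

* **Agricultural land.**  The printed 3-bin scale (`<20 → 1`, `20–40 → 2`,
  `>40 → 3`) cannot produce the grades up to 5 present in the reference
  table.  The default is a 5-bin extension with 20%-wide bins; the printed
  scale remains available (`scale="printed_3bin"`).
* **Wastewater.**  The printed scale grades treatment plants
  (primary 3 / secondary 2 / tertiary 1) and population "aggregation
  nuclei" (natural-breaks classes 1–4), but never states how the two
  combine into the single 0–3 wastewater grade of the results table.  We
  keep them separate: the lake's W grade is the maximum stage grade over
  plants in the watershed (0 when there are neither settlements nor
  plants), while the nuclei surface (nearest-point allocation of settlement
  population + Jenks reclassification) is produced as a raster-mode
  diagnostic only.

Slope is graded by quartile of a reference slope distribution
(`<p25 → 1`, `p25–p50 → 3`, `p50–p75 → 4`, `≥p75 → 5`; the published scale
skips grade 2 and is implemented as printed).  Percentiles use linear
interpolation between order statistics; the left-closed convention breaks
ties upward.  Aspect is operationalised as angular proximity between the
downslope direction and the bearing from the cell to the lake centroid:
within 45° the slope drains toward the lake (grade 5), beyond 135° it drains
away (grade 1), otherwise neutral (grade 3); the cutoffs are configurable.
Soil permeability maps texture to hazard: clay 5, sand 3, gravel 1.

Natural-breaks (Jenks) classification is an exact dynamic program
minimising within-class sum of squared deviations; a brute-force
partition-enumeration oracle verifies it in the tests for n ≤ 12, k ≤ 4.

## Weights, hazard typing and calibration

The published weight table and the qualitative three-type definition leave
two rules under-specified, which `calibrate()` resolves against the 30-lake
reference (indicator grades, hazard grades and printed states):

* **Agricultural sub-weights.**  The printed assignment (land-use 5,
  irrigation 3) misclassifies at least one reference lake — it pushes the
  Oltina row to 65, past the highest semi-degraded bound of any type — while
  the transposed assignment (land-use 3, irrigation 5) reproduces all 30
  printed states.  The transposed scheme is the default; the literal one is
  available as `LITERAL_WEIGHTS` and is reported infeasible by the
  calibration search.
* **HI-type rule.**  Lake types are defined only qualitatively.  The default
  is the simplest monotone sum-threshold rule in the feasible set:
  HI ≤ 9 → type 1, 10–12 → type 2, ≥ 13 → type 3.  `calibrate()` returns
  the full feasible set (35 threshold pairs under the default weights) so
  users can select alternatives; the reference data constrain the rule only
  loosely.

WRASTIC values above 100 (possible at extreme grades) clamp into the
degraded bin.  One reference lake carries a slope grade 2 that the quartile
rubric cannot produce; `HazardScores` therefore accepts slope grades 1–5,
and the geospatial path can reach grade 2 through the rounded-mean zonal
aggregation (below).

## Geospatial workflow

Per lake: treatment plants, settlements, roads/railways, industrial and
exploitation sites are selected by intersection with the watershed polygon;
tourist infrastructure by a 50 m buffer around the lake; land-cover
fractions by counting cells whose centres fall strictly inside the
watershed; watershed area from the polygon in the projected CRS.  Slope and
aspect come from Horn's 3×3 method on the DEM (cells whose window touches
nodata or the edge are nodata; flat cells have undefined aspect and take the
neutral grade 3 in the hazard surface).  Soil-texture polygons are
rasterised by cell-centre containment.  Any arithmetic with nodata yields
nodata; zonal statistics ignore nodata cells; the mode statistic breaks ties
toward the lowest grade.

Per-cell slope grades are computed against the **whole-scene** slope
distribution by default (`slope_reference="scene"`), mirroring a workflow
that pre-processes country-scale layers before iterating over lakes.
Grading cells against the watershed's own distribution (the alternative
`"watershed"` setting) puts ~25% of cells in each grade by construction, so
a watershed-level grade aggregated from it by mode would be meaningless —
this is why the scene-wide reference is the default for the lake-level
grade, while the 25%-per-grade property of the rubric itself is tested
directly.

The lake's single hazard grade per factor is the **mode** of the per-cell
grades over the watershed (options: max, and mean rounded half-up with
snapping to the factor's valid grade set, ties downward).  The per-pixel
index surface (weighted sum × HI sum, cell-wise) and its three-class state
surface are also produced; the percentages of all state classes over the
watershed are recorded alongside the single classified state, which comes
from the aggregated grades.

Rasters are plain-text ESRI ASCII grids and vectors GeoJSON, with CRS
handled as an opaque identifier over projected metre coordinates; layers
with mismatched CRS fail fast, and reprojection is out of scope.

## Synthetic scenes

The generator builds, for any feasible grade combination, a 160×160-cell
landscape whose full-pipeline evaluation returns exactly the requested
grades:

* **Terrain.**  An eastward-dipping ramp whose gradient steps across four
  equal-width vertical strips (2°, 8°, 14°, 20° by default).  The surface is
  continuous, so the scene-wide slope distribution has clean quartiles and a
  watershed placed inside strip *q* receives per-cell grade *q* exactly.
  Zero-relief specifications are rejected as degenerate.
* **Watershed and lake.**  The watershed is an axis-aligned 30×30-cell
  rectangle; the cell size defaults to 25 m (EU-DEM-like) and scales as
  √(area/900 cells) when a watershed-area target is given, since areas up to
  thousands of km² cannot fit a 25 m grid of this size.  The lake (4×4
  cells) sits at the watershed's eastern, western or northern edge to
  realise aspect grades 5, 1 or 3 respectively — with an east-dipping
  terrain, the bearing from the bulk of the cells to the lake then lies
  within 45°, beyond 135°, or near 90° of the downslope direction.
* **Slope grade 2.**  Not reachable by the quartile rubric; the watershed is
  straddled across the first two strips (half the cells grade 1, half
  grade 3) and the scene's manifest flags the rounded-mean hazard
  aggregation, which yields exactly 2.
* **Land cover.**  A bit-flag legend (agricultural / natural vegetation /
  irrigated) lets the three fractions be controlled independently, realised
  by deterministic sorted-noise thresholding of cell counts (exact to
  1/900 ≈ 0.11%).  Independence is required: reference grade combinations
  such as irrigation 50–75% together with vegetation >50% cannot coexist in
  a single partition, and mixed agriculture/vegetation classes exist in real
  land-cover nomenclatures.  Fraction targets for a requested grade are
  representative in-bin values (e.g. agricultural grade 5 → 85%).
* **Features.**  Roads/railways of the requested categories cross the
  watershed (plus one decoy road outside it); treatment plants carry the
  stages implied by the wastewater grade; tourist infrastructure is placed
  at a requested distance from the lake shore; a single soil polygon covers
  the scene with the texture matching the permeability grade.

One seeded generator per scene drives the only random draws (land-cover
noise), in fixed order, so identical specifications give byte-identical
layers.

What the scenes do **not** emulate: realistic hydrology, watershed shapes,
terrain texture, or land-cover spatial autocorrelation.  Passing round-trip
tests therefore demonstrates that the derivation chain (layers → grades →
index → state) is correct and self-consistent, not that the index itself is
ecologically validated on real landscapes; the 30-lake reference table is
the only real-data anchor.

## Problem sizes and numerical choices

The test suite and the acceptance checks use 160×160-cell scenes (the 30
round-trip evaluations complete in about a second) and ≤64×64 grids for
brute-force oracle comparisons.  Percentile and mean computations are
floating point, but every grade, weight, index value and threshold is
integer, so classification outcomes carry no floating-point sensitivity.
Reported percentages round half-up to integers (17/30 → 57%).

## Known limitations

* The reference table's one out-of-rubric slope grade is representable but
  only reachable geospatially via the rounded-mean aggregation.
* The wastewater nuclei surface and the lake's W grade are deliberately not
  fused (no published combiner); the nuclei grade is diagnostic output.
* The classification thresholds are treated as exact integer bounds; no
  interpolation is applied between class bounds.
* One reference lake is described in the source narrative as protected but
  flagged unprotected in its inventory table; the fixture follows the
  inventory table.
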