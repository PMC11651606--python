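# Methods

## Containment model

The unit of analysis is a pair (fuel-break network, library of simulated
fires). Each fire *j* carries its final footprint polygon, its ignition
point, and its simulated size; each break *i* is a polyline with length
*L<sub>i</sub>* and treatment cost *C<sub>i</sub>* (defaulting to
*L<sub>i</sub>*). All geometry is Euclidean in one projected CRS (meters);
geographic coordinates are rejected at the I/O layer rather than silently
mis-measured.

The footprint boundary (exterior plus hole rings) is noded with every break
polyline clipped to the footprint, and the noded linework is polygonized
into faces. The face containing the ignition point is the ignition polygon.
A fire is *fully split* when the subdivision has more than one face and the
ignition face is a proper subset of the footprint; only fully split fires
can ever be contained. The set *S<sub>j</sub>* contains each break whose
linework contributes more than a minimum arc length (default 10⁻⁶ × the
footprint bounding-box diagonal — this excludes single-point touches) to
the ignition-face boundary. Footprint-perimeter arcs never enter
*S<sub>j</sub>*: a fire cannot spread past its own simulated footprint, so
those edges need no treatment.

Containment of a fully split fire is assumed to succeed iff (a) every break
in *S<sub>j</sub>* is treated and (b) the maximum flame length along the
*S<sub>j</sub>* arcs does not exceed the escape threshold *FL* (non-strict
pass, strict fail). Success protects the footprint outside the ignition
polygon: the avoided area AFB, and the avoided WUI value AWB (zonal sum of
the WUI raster over that region). Failure of either condition means the
fire burns its whole footprint; there is no partial containment credit.

## Geometric and numerical choices

- **Snapping.** All linework entering a subdivision is snapped to a
  precision grid of 10⁻⁹ × the footprint bounding-box diagonal
  (`shapely.set_precision`). Real GIS layers rarely share exact vertices;
  one shared grid guarantees that face boundaries and break arcs carry
  identical coordinates, which makes break-arc attribution exact. The
  induced area perturbation is orders of magnitude below the 10⁻⁶ relative
  conservation tolerance asserted in the tests.
- **Ignition on an arc.** If the ignition point lies on a noded arc (within
  the snap tolerance), all adjacent faces are candidates and the smallest
  face wins — the conservative, deterministic reading of "smallest polygon
  enclosing the ignition point". Ties beyond area are broken by face bounds.
- **Multi-part footprints.** The part holding the ignition point is
  subdivided; other parts are carried as whole faces, so face areas always
  sum to the footprint area and disconnected parts count toward AFB when
  containment succeeds. Holes are preserved; face areas are hole-exclusive.
- **Flame screening cell rule.** Any raster cell whose square geometrically
  intersects the *S<sub>j</sub>* arcs counts (the worst flame adjacent to
  the control line), the conservative choice. A `mode="boundary"` switch
  instead scans the entire ignition-polygon boundary, including perimeter
  arcs, for sensitivity analysis. If the arcs touch only nodata (or
  off-grid) cells the flame maximum is unknown and the fire is treated as
  not containable, even at *FL* = ∞.
- **AWB cell rule.** Center-in-region zonal sum — the unbiased standard
  convention, chosen deliberately different from the flame rule because AWB
  is an area account, not a worst-case screen.
- **Flame units** are whatever the raster carries (feet in the intended
  use); thresholds are compared in raster units with no conversion.

## Selection models

The exact model keeps both *x<sub>i</sub>* (treat break *i*) and
*y<sub>j</sub>* (fire *j* contained) binary. The linking row
*y<sub>j</sub>* ≤ (1/*M<sub>j</sub>*) Σ<sub>i∈S<sub>j</sub></sub>
*x<sub>i</sub>* forces *y<sub>j</sub>* = 0 unless the whole bounding set is
treated; relaxing *y<sub>j</sub>* to [0, 1] would award fractional credit
for partially treated polygons and contradict the all-or-nothing
containment assumption, so integrality is kept. Fires with
*S<sub>j</sub>* = ∅ are excluded from the matrix and retained for
reporting. One budget row charges either costs (Σ *C<sub>i</sub>x<sub>i</sub>* ≤ B)
or lengths (Σ *L<sub>i</sub>x<sub>i</sub>* ≤ B); scenario budgets default to
fractions of total network length.

Solves run through `scipy.optimize.milp` (HiGHS) at relative gap 0. HiGHS
also stops at a fixed *absolute* gap of 10⁻⁶, so the objective vector is
scaled to magnitude ~10⁶ inside `build_mip`; the tolerance then corresponds
to ~10⁻¹² relative and returned solutions are exact for any practically
distinguishable instance. Contained-fire sets are always recomputed from
the selected breaks by set inclusion and cross-checked against the solver
objective — solver variable values are never trusted directly. An
enumeration oracle (`brute_force`, guarded to ≤ 20 breaks, ties broken
toward the lexicographically smallest selection) provides the independent
correctness check; solver tie-breaking among equal-objective optima is
deliberately left to the back end, so oracle tests compare objectives, not
selections.

The rule-based baseline scores each break under full-network treatment
(*E<sub>i</sub>* = Σ *V<sub>j</sub>* over incident containable fires ÷
*C<sub>i</sub>*; zero-cost breaks are rejected as undefined), ranks
descending with ties broken by ascending id, and selects greedily. The
default walk is first-fit (skip an unaffordable break, continue down the
ranking), which lands as close to the budget as the ranking allows; a
stop-at-first-violation variant is available via `rule="stop"` for
sensitivity checks. The fixed selection is then evaluated under the same
objective, which yields the provable dominance OPT ≥ RBS tested across all
scenario grids.

## Scenario grid

Preprocessing is staged so the expensive work is done once: fires disjoint
from the network are dropped (with logged counts), geometry and flame
maxima are computed per retained fire, and FL screening is re-applied
cheaply per threshold. The large-fire filter removes exactly
⌊0.20 *n*⌋ of the *retained* (network-intersecting) fires from the largest
size down, ties at the cutoff dropped larger-id-first — a deterministic
percentile convention. The filter operates on the retained population
because excluded fires cannot influence any solution.

The default factorial crosses 2 objectives (AFB, AWB) × 2 fire samples
(all, no-large) × 3 escape thresholds (4, 8, ∞ — hand-tool control, heavy
equipment, and the optimistic no-escape scenario) × 10 budgets (10%–100% of
network length): 120 exact and 120 rule-based solves. Cell failures are
recorded as error rows without stopping the grid. Reports carry objective,
spend, containment counts and proportions, selected ids, gap and wall time;
the CSV written by the CLI omits the wall-time column so fixed-seed runs
are byte-reproducible.

## Synthetic landscapes

The generators emulate the statistical structure of the intended inputs —
a large-fire simulator's footprints/ignitions/flame grids, a WUI raster,
and a break network — at desk scale, from a single integer seed (one
independent substream per generator, so changing the fire count leaves the
network unchanged):

- **Network**: a (jittered) lattice, one break per lattice edge, default
  spacing 1.5 km on a 12 × 12 km extent with 15% edge dropout. Jitter
  displaces interior nodes by up to 0.15 × spacing so arcs are not axis
  aligned; boundary nodes stay fixed so the network spans the extent.
- **Fires**: buffered correlated random walks scaled about their centroid
  to an exactly lognormal area (median ≈ 44 ha, log-σ = 1, heavy tail to
  km² scale), 150 per landscape, ignitions rejection-sampled strictly
  inside. Random walks, unlike ellipses, cross several breaks irregularly
  and exercise the noding and multi-break *S<sub>j</sub>* logic.
- **Rasters**: flame length exp(μ + σZ) with Z a smoothed unit-variance
  Gaussian field (270 m cells, correlation length 800 m, median 3.5,
  log-σ 0.5 — a realistic mix around the 4/8 thresholds); WUI as
  clustered Gaussian patches on 30 m cells clipped to the 0.09 ha per-cell
  area cap, mimicking the patchy development pattern of real
  wildland–urban interfaces.

Defaults were fixed once to produce a non-trivial mix of excluded, unsplit,
screened-out, and containable fires (asserted in the tests). What the
synthetic landscapes do **not** reproduce: fire-spread physics and
weather/fuel correlations between footprint shape and flame length
(footprints and flame fields are independent here), per-fire flame rasters
(one shared field per landscape; the interface accepts per-fire rasters),
realistic network topology (roads/ridgelines), and the empirical magnitudes
of any particular region. Passing tests therefore certify the geometry,
screening, valuation and optimization machinery — not landscape-specific
management conclusions.

The hand-built `toy_fixture()` (4 breaks, 4 fires, explicit costs 2/2/3/1,
budget 5 in cost mode) is constructed so both solvers are auditable by hand
and the greedy ranking provably underperforms the optimum (4.5 vs 5.0); at
full budget both saturate at 12.5.

## Problem sizes and limitations

Default test and reproduction runs use landscapes of ~100–150 breaks and
40–200 fires, where the full 120-cell grid solves in seconds; the MIP
formulation itself is compact (one row per containable fire plus one budget
row) and scales far beyond that. Known limitations: no partial containment
or suppression resource/cost/time modeling; no construction of new breaks
(the candidate network is fixed); rasters must share the vector CRS (no
resampling/reprojection); GeoJSON and ESRI ASCII grids are the supported
formats; alternate optima are solver-dependent (only objectives are
guaranteed stable across back ends).
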