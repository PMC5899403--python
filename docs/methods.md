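# Methods

## Scope and outputs

`metroaccess` estimates door-to-door travel times from residential
addresses to the nearest health service of each of eight types, by
private vehicle and by walk-plus-public-transport, and summarises them
per metropolitan area typology (inner, middle, outer established, outer
growth, outer fringe).  Outputs are descriptive: quartile summaries,
public-vs-private mode gaps and ratios, gaps relative to the inner
typology, and the share of addresses within a 20-minute journey.
Inferential statistics are deliberately out of scope: with tens of
thousands of origins any between-group test is trivially "significant",
so the medians themselves are the deliverable.

## The synthetic city

The generator emulates the statistical structure a metropolitan
accessibility audit assumes, on a planar Cartesian plane in metres.

- **Typologies.** Five concentric annuli over a disc; default outer
  radii 3, 6, 9, 12, 15 km.  Real metropolitan typologies are irregular
  polygons; only the five-way classification matters downstream, so
  rings suffice.
- **Roads.** A polar lattice with 1 km radial pitch and 48 radial
  lines.  Every sixth radial is a major spoke, alternating freeway /
  arterial; infill radials alternate collector / local block-wise; every
  orbital ring road is sub-arterial.  Consequently all five hierarchy
  classes are present in every annulus.  Ring-road edge lengths are arc
  lengths (the road follows the circle), so no edge is shorter than the
  straight line between its endpoints.
- **Transit.** Trains (60 km/h) run the full length of the four freeway
  spokes, stopping at every ring crossing; one orbital bus loop
  (25 km/h) serves each annulus at the ring road nearest its radial
  midpoint, stopping at major-spoke crossings.  Each physical line is
  emitted as two one-directional routes.  Headways lengthen outward
  (train 10 min; buses 10/15/20/30/40 min inner → fringe), encoding the
  outward-thinning transit infrastructure of real metropolitan areas.
  The service window is 10:00–15:00, bracketing the off-peak noon
  departure used by the analysis; departures repeat every headway,
  with the count rounded down when the headway does not divide the
  window.  Stop-to-stop run times are rounded to whole seconds with a
  1 s floor, keeping stop times strictly increasing.
- **Facilities.** Counts per service type and ring are configuration;
  the defaults place count-per-area densities that decline outward for
  every type and most sharply for the referral-based specialist types
  (the outer fringe has no endocrinologist at all).  Positions are
  uniform within each ring.
- **Addresses.** Uniform over each annulus, 200 per typology by default
  (10,000 per typology — the full study scale, ~50,000 points — is a
  configuration change).  Uniform-over-area is an explicit assumption;
  real residential parcels cluster, which would tighten inner-city
  times and widen fringe variance.
- **Determinism.** One root seed; addresses and facilities draw from
  fixed numpy `SeedSequence` substreams (spawn keys 1 and 2), and the
  lattice and timetable are deterministic, so identical configurations
  produce identical cities and adding a component never perturbs
  earlier draws.

What the generator does **not** emulate: real street topology and
one-way streets, parcel-weighted population, demographic structure,
congestion, transit delays/capacity, and park-and-ride journeys (a
deliberate exclusion: mixed drive-to-station trips are a different
model).  Passing tests therefore demonstrate correctness of the
estimation machinery and the qualitative centre-periphery gradient, not
numerical agreement with any real city's medians.

## Private-vehicle model

Estimated off-peak speed per class is the mean of the observed inner-
and outer-region speeds when both exist (freeway 75, arterial 37.75,
sub-arterial 33 km/h) and half the sign-posted limit otherwise
(collector 25, local 20 km/h), half being the ratio the measured classes
exhibit.  The two-value mean reproduces every published estimate
exactly; a five-region mean would not.  If exactly one observation is
ever supplied the implementation falls back to the half-rule rather
than trusting a single region.  The m/s column is km/h ÷ 3.6, rounded
to two decimals only at the reporting layer.

Edge time = length / speed.  OD times are exact shortest paths
(multi-source Dijkstra per service type over the undirected graph), so
time(a→b) = time(b→a) and adding a facility can only lower a cell.
Door-to-vehicle time, parking, signals, turn penalties and congestion
are all zero — consistent with near-zero minima when an address adjoins
a facility.  Origins and destinations attach to the nearest network
node by Euclidean distance (ties to the lowest node id).  Nearest-node
snapping was chosen over nearest-edge projection for exact testability
against all-pairs oracles; with the default 1 km lattice it bounds the
positional error by about half a cell at every endpoint.  Cells whose
origin cannot reach any facility of a type are reported as +inf in
memory and as empty cells (with a logged count) on export — never
dropped.

## Public-transport model

A journey is any alternation of network walking legs (default 5 km/h —
the conventional assumption; the value is configurable and recorded in
the run manifest) and vehicle legs boarded no earlier than their
scheduled departure, with boarding allowed at the exact departure
second and no transfer penalty beyond walking and waiting.  The
quantity computed is the earliest arrival from a fixed departure
instant (Wednesday noon), minus the departure instant.

The solver scans ride connections (consecutive stop pairs within each
trip active on the departure weekday) in departure order, keeping the
earliest-known arrival at every road node; a connection whose boarding
node has been reached by its departure time relaxes, through a
precomputed all-pairs walking-time matrix, every node walkable from its
alighting stop.  A single pass is sufficient because any connection
able to feed another departs strictly earlier.  Staying aboard is the
special case of re-boarding the same trip at the next stop
(departure ≥ arrival, zero penalty).  The earliest-arrival *value* is
the contract; the test suite pins it to an independent round-based
exhaustive enumeration on small feeds.  Initialising with the walk
matrix and taking the final minimum over walking guarantees
journey ≤ pure-walk time, and an emptied timetable reduces the public
OD matrix exactly to walk-only times.

Walking distance to stops is uncapped by default (`max_access_walk_m`
caps every walking leg when set, which can legitimately disconnect an
OD pair).  Fares, capacity and real-time deviations are not modelled.
OD queries are memoised per snapped origin node, which is what keeps
the 10,000-origin configuration cheap.

## Summaries

Quantiles use linear interpolation between order statistics (numpy's
default); the convention is fixed here because published tables rarely
state one.  Unreachable cells are excluded from statistics and counted
in a separate `n_unreachable` column.  Travel times are not truncated:
extreme public-transport journeys are part of the phenomenon being
audited.  The 20-minute audit uses an inclusive threshold (≤ 20 min)
over reachable cells.  The public/private median ratio is null (and
logged) where the private median is exactly zero.

## Numerical choices and degenerate inputs

- All times are float64 minutes internally; GTFS times are integer
  seconds after midnight (hours may exceed 24 in the text format).
- Parallel edges collapse to the fastest (driving) or shortest
  (walking) representative.
- Snapping ties break toward the lowest node id; facility ids tie-break
  nothing because the minimum over facilities is order-invariant.
- Zero-length edges, non-increasing ring radii, negative counts,
  non-positive headways and malformed files are rejected with typed
  errors naming the offending object (ring, trip, row, class).
- Coordinate round trips are exact to 1e-6 m and times to 1e-9 min
  (full-precision repr on write).

## Problem sizes

Defaults were chosen so the full default analysis (721 network nodes,
~5,300 stop-time rows, 1,000 origins, 8 service types, both modes) runs
in a few seconds, and the scaled configuration of 2,000 addresses per
typology (10,000 origins) — one fifth of the full ~50,000-point study
scale — completes in well under a minute on a single CPU, making the
end-to-end bookkeeping checks routine rather than exceptional.

## Known limitations

- The ring-city geometry has perfect radial symmetry; it cannot probe
  direction-dependent effects (coastlines, corridors).
- Nearest-node snapping adds up to ~½ lattice cell of positional error
  per endpoint; at walking speed that is a few minutes and it dominates
  the inner-city public-transport medians.
- The nearest facility is assumed to be the one visited; provider
  choice, opening hours and capacity are out of scope.
- A single departure instant is analysed; no departure-time sampling or
  peak-period speeds.
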