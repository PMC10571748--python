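# Methods

## The measure

The virtual walking distance (VWD) of one animal on one calendar day is the
sum of center-to-center Euclidean distances between consecutively visited
antenna locations, in visiting order.  It is computed in three steps:

1. **Ingestion.** Readings (timestamp at 1 s resolution, animal, antenna
   location, pen) are sorted by (animal, timestamp, location) and exact
   duplicate triples dropped.  Rows naming an unregistered location are
   rejected and counted in the log; a malformed timestamp or a missing
   column is a hard error.  Timestamps are naive local clock time — no
   timezone or daylight-saving handling (the source data are barn-local
   wall clock; a DST shift would mis-bin at most one hour twice a year).
2. **Run collapsing.** Consecutive readings at the same antenna are one
   visit; only the visiting order matters because d(x, x) = 0.  Collapsing
   is therefore a pure optimisation, and the test suite checks it against a
   brute-force pairwise sum over the uncollapsed sequence.
3. **Summation.** Distances between consecutive visits are summed per
   calendar day.  Days are scored in isolation: the first reading of a day
   opens a new path and no transition spans midnight.  Cross-midnight moves
   are rare (the cohort rests roughly 22:00–06:00) and attributing such a
   move to either day would be arbitrary.

Conventions that follow from what the measure means:

* A **single detection counts** — one reading proves presence; there is no
  minimum visit duration.
* A day with **no readings is missing**, not zero.  Zero is a statement
  about behavior; absence of data is not.
* **Hour bins.** Each transition is credited to the hour of the *arrival*
  visit's first detection — the earliest second at which the movement is
  known to be complete.  (The destination's first reading is the only
  timestamp guaranteed to postdate the move; the departure time is only an
  upper bound on when the move began.)  Bins sum to the daily total by
  construction, and the pipeline asserts it to 1e-9 m.
* **Fattening day** 1 is the pen's move-in day; stages are the closed bins
  1–30, 31–60, 61–90 and >90 (boundaries configurable).

VWD is a lower bound on true distance walked, with one caveat inherited
from the hardware: an antenna's reading area has horizontal extent, so a
reading can occur some decimeters from the center point and individual
transitions can be slightly over-counted.  The bound is therefore "virtual"
rather than strictly minimal; nothing in this package estimates the true
distance, which is not identifiable from proximity data.

## Geometry

Distance matrices come from 2-D antenna center coordinates or are supplied
explicitly (when both are given the explicit matrix wins, with a
consistency warning beyond 0.05 m).  `validate_matrix` checks symmetry,
zero diagonal, nonnegativity and the triangle inequality exhaustively over
all triples with 1e-9 m slack for float error.  The triangle inequality is
load-bearing: it is what makes VWD monotone under detection dropout
(removing a reading replaces two legs by a direct leg that cannot be
longer).  Distances are carried at full float precision; the 0.1 m rounding
of the published matrix is a presentation choice of its source, not a
computational one.

## Aggregation

Stage means come in two variants: `all_days` (mean over observed pig-days;
animals weighted by coverage) and `per_pig_means` (mean of per-animal stage
means; one vote per animal).  They coincide on balanced data and diverge
toward over-represented animals otherwise.  All means are unweighted
arithmetic means over days with at least one reading.  Reading-free
pig-days are excluded everywhere, including the hourly profile: treating
them as zeros would require knowing the animal was actually housed (and the
system live) that day, and no defined input carries that roster.  No
inferential statistics are attached; the outputs are descriptive.

The health overlay is a left join of locomotion scores (0 = sound, 1 =
visible signs, 2 = lame with compensatory behavior, 3 = reluctant to walk)
onto the daily series by (animal, date).  Scores are sparse — inspection is
typically twice weekly — and are never imputed between observation days.

## The barn simulator

No distributional description of pen-location visits has been published, so
the simulator is an explicit artifact assumption: a semi-Markov process over
{trough, drinker1..3, playing device, rest}, built to reproduce the
structural features the pipeline relies on rather than to fit any dataset.

* **Rest departures** follow an inhomogeneous exponential clock with a
  piecewise-constant hourly rate: base rate 8e-4 s⁻¹, times a diurnal
  profile (×1.6 in the hour after each of six feedings at 06/09/12/15/18/22 h,
  ×1.8 through the late afternoon and evening 17–21 h, ×0.1 in the rest
  window 22:00–06:00), times a per-pig multiplier (lognormal, unit mean,
  σ = 0.35), a per-stage multiplier (1.0/0.8/0.6/0.5 — activity declines as
  pigs grow) and any lameness factor.
* **Visits** draw the location from fixed weights (trough 0.35, drinkers
  0.15 each, playing device 0.20) and an exponential dwell (means 60/15/30 s
  at trough/drinker/playing device), rounded to whole seconds, minimum 1 s.
  With probability 0.15 a visit chains directly into a visit at another
  location; otherwise the pig returns to rest.  Trajectories start and end
  in rest, so no visit spans midnight.
* **Detection** thins each visit second-by-second: every whole second in
  [entry, exit) is independently detected with the location's sensitivity
  (defaults 0.9 trough, 0.6 drinkers, 0.75 playing device).  Movement is
  instantaneous at the reading level — the measure only sees presence
  inside reading areas, so transit time is folded into rest.
* **Ground truth** per pig-day is the center-path length over the *actual*
  visit sequence, detected or not.  Perfect sensitivity recovers it
  exactly; any dropout can only shorten the computed path.
* **Lameness events** multiply the departure rate by an activity factor
  (default 0.3) from an onset day for a set duration, and emit locomotion
  scores (2 in the first week, 1 after) on twice-weekly inspection days.
* **Randomness.** One root seed spawns independent substreams per (pig,
  day) for trajectory and for detection.  Detection draws one uniform per
  visit-second in visit order, so runs differing only in sensitivities see
  nested detection sets on identical trajectories — the coupling used by
  the paired dropout tests.

The rate and dwell constants were chosen once, from a back-of-envelope
target of roughly 70 visits per day early in fattening, which puts default
cohorts in a realistic envelope: daily VWD roughly 20–750 m, early-stage
cohort means near 280 m falling below 150 m past day 90, an evening
activity peak and a nearly flat night.  They are scenario fields, not
hidden constants.

The pen geometry is the published five-location distance matrix; since no
coordinates were published, the simulator carries a synthetic planar
embedding (least-squares multidimensional scaling, frozen in
`data/synthetic_pen_coords.json`, max deviation 0.013 m).  Ground truth
uses matrix distances, so the embedding choice is immaterial.

What the simulator does **not** model — and hence what passing tests do not
demonstrate about real barns: spatially continuous movement between
antennas, reading-area geometry and overlap, social interaction and
synchrony between pen-mates, feed-intake behavior, weight-dependent
behavior change beyond the stage multipliers, seasonal or climate effects,
and any correlation between lameness and *which* locations a pig visits
(only the overall rate drops).  Recovery tests show the pipeline extracts
the structure that was put in; they cannot validate the behavioral model
itself.

## Numerical choices

* Distance comparisons use 1e-9 m tolerances (triangle check, hour-bin
  conservation, CSV round-trips).  Where an implementation sum and an
  independent oracle sum the same terms in different orders (numpy pairwise
  vs sequential), agreement is asserted at 1e-9 m rather than bit-exact.
* Sorting is stable (mergesort) everywhere ordering is part of the
  contract, so ties — e.g. the physically dubious but retained case of one
  animal read at two locations in the same second — resolve
  deterministically by location id.
* Degenerate inputs: an empty reading file yields empty tables; a
  single-reading day scores 0 m with 0 transitions; an empty daily table
  makes `report` print "no data" and exit 0.
* Output CSVs are written at full float repr precision and re-read within
  1e-9, with deterministic column and row order; rerunning any stage on the
  same inputs is byte-identical.

## Problem sizes

The test suite exercises cohorts up to 25 pigs × 120 days (3,000 pig-days,
~4.5 million readings, about half a minute end to end), the scale at which
the stage-decline and diurnal-recovery properties are asserted; unit-level
checks use 1,000-sequence oracle sweeps and 200 random subsampling pairs.

## Known limitations

* Naive local time; DST transitions are not handled.
* VWD compresses all unseen movement to straight lines between antenna
  centers; it is not comparable across pens with different antenna
  densities without care.
* The per-pig activity baseline varies several-fold; cohort means hide it,
  which is why per-pig summaries and overlays are first-class outputs.
* No lameness *detector* is included: the overlay visualises scores against
  activity, and the simulator can inject episodes, but classifying drops is
  out of scope.
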