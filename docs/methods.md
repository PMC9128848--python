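# Methods

This note documents the models, parameter choices and known limitations of
the `birdyear` analysis stages, and what the synthetic bird-year generator
does and does not emulate.

## GPS track processing

**Speed filter.** A forward pass from the first fix removes the *later*
member of any consecutive pair whose implied speed exceeds `vmax` (default
20 m s⁻¹ — well above sustained flapping flight for a small procellariiform
— so it removes only satellite-geometry artefacts), re-checking from the
same anchor until no violation remains.  Keeping the earlier fix preserves
the first anchor of the track and makes the filter idempotent.  The filter
runs on raw fixes only; interpolated positions are generated afterwards and
cannot violate the bound.

**Regularization.** Positions are linearly interpolated in plain lat/lon
onto a uniform grid anchored at the first fix (default interval: the
deployment programming, 20 min incubation / 10 min chick-rearing).  At
10–20-min steps over foraging-trip scales the difference from great-circle
interpolation is far below the GPS error and is accepted as a documented
simplification.  Grid times inside a raw gap longer than `max_gap` (default
4) intervals are emitted as missing rather than inventing positions across
long surface-rest gaps.

**Trips.** A fix within `colony_radius_km` (default 1.0 — the colony is a
point island and GPS error is ≪ 1 km) is "at colony"; maximal off-colony
runs are trips, complete iff flanked by at-colony fixes.  The flanking
at-colony fixes are included in the trip's fix sequence so the departure
and return legs count toward total distance, while the trip's start/end
(and hence duration) bound the off-colony run itself.  Incomplete trips
contribute only the maximum-range metric.  The short/long split for
chick-rearing trips is at 48 h, boundary inclusive.

## Movement-state clustering

Speed and absolute turning angle are clustered *independently* into
low/high regimes by a two-component univariate Gaussian mixture fitted with
EM.  This per-variable binary clustering with delimiter combination is a
deterministic simplification of the full bivariate reference algorithm: it
matches the binary-split semantics, is reproducible without random restarts
(components are initialized by splitting at the median; convergence when
the log-likelihood gain is below 1e-8, cap 500 iterations), and on
well-separated regimes attains near-Bayes misclassification rates (verified
in the tests against the exact Bayes boundary).  The delimiter is the
equal-posterior point between the component means — the root of the
quadratic `w₁N(x;μ₁,σ₁)=w₂N(x;μ₂,σ₂)` lying between the means, falling
back to the midpoint when no interior root exists.  Zero-variance variables
short-circuit to a degenerate delimiter with a warning.

Labels map by delimiter side — first letter speed, second turn — never by
cluster index, so LL/LH/HL/HH always mean rest / intensive search / travel
/ extensive search.  The model is fitted per deployment-stage pool (all
trips of a stage together), since stage-level behaviour summaries are the
target; per-bird fitting is available by calling `embc_fit` on subsets.
Turning angle uses the absolute value: the state definitions are symmetric
in turn direction.  Diel profiles bin steps by local solar hour (UTC +
lon/15) and flag bins as night when mean solar elevation < −6° (civil
twilight), which operationalizes "after last light / before first light".

## Light-level geolocation

The solar ephemeris uses the classic low-precision Fourier fits for
declination and the equation of time (≈0.1° / fraction-of-a-minute
accuracy) — far below the method's intrinsic error (~186 km on real
loggers).  Twilights are threshold crossings located by linear
interpolation between adjacent 5-min samples; dark runs shorter than
`min_dark` (default 30 min) flanked by light are treated as logger shading
and ignored.  The light threshold defaults to the midpoint of the observed
night floor and day ceiling (2nd/98th percentiles) per deployment, and the
sun elevation angle a₀ of that threshold is calibrated as the median solar
elevation at crossings detected during a span at a known site (≥ 7 days;
the median is robust to occasional shaded twilights).

Longitude follows from apparent local midday (sunrise→sunset pair) or
midnight (sunset→next-sunrise pair), corrected by the equation of time;
because the midpoint of a symmetric light curve is insensitive to the
threshold, longitude is robust to miscalibration of a₀.  Latitude solves
the sunrise equation by bracketed root-finding on φ ∈ [−89°, 89°]; the
equation can admit two roots, and ties are broken toward a latitude hint
(the colony, or the previous position) — with no hint ambiguous days are
dropped.  Days whose day length no latitude can reproduce yield a missing
latitude.  Near the equinoxes day length is ~12 h everywhere and latitude
is indeterminate: positions within ±14 d of either equinox (equinox
instants computed from the ephemeris as declination zero-crossings, not a
hardcoded calendar) are flagged, and flagged latitudes are excluded from
all spatial analyses.  No position smoothing is applied.

## Immersion phenology

30-s wet/dry samples are summarized into six 4-h blocks per UTC day; daily
wet fraction is the sample-weighted mean.  The moult window is the longest
run of days with wet fraction > 0.9, tolerating up to `gap_days` (default
2) consecutive sub-threshold days inside the run and requiring `min_days`
(default 5); the gap/min parameters are this package's own tolerance
choices around the >90% criterion.  Attendance requires *both* proximity —
the nearest usable position within ±2 d must lie within 200 km of the
colony, which prevents dry spells at the distal wintering site being read
as burrow visits — and either an all-dry block run of ≥ 8 h or continuous
darkness through an expected daylight period.  Because 4-h blocks truncate
the true dry span (flanking blocks are partly wet), an observed 8-h
fully-dry block run certifies a true dry period longer than 8 h, so the
block-run comparison is inclusive.  Overlapping evidence is merged; events
never overlap.  Breeding boundaries are the events flanking the largest
attendance gap (which must exceed 30 d); migration duration is whole days
between them and depends only on attendance dating, not positions.  Summed
great-circle legs between noisy positions systematically exceed the true
path length, so the reported total migration distance is an overestimate
whose bias grows with position noise; maximum range is likewise inflated
by the maximum over many noisy positions (typically one to a few hundred
km at geolocation accuracy).

## Space use

UDs are isotropic bivariate Gaussian kernels (sd = the smoothing parameter
h, in degrees) evaluated at cell centres and normalized to unit mass;
defaults h = 0.2° / 0.1° cells for GPS and h = 1.8° / 1° cells for GLS
(1.8° ≈ a 200-km search radius at these latitudes).  Evaluating at cell
centres rather than integrating over cells is accurate at these
grid-to-bandwidth ratios.  Contours are volume contours: cells sorted by
density, smallest prefix reaching the level; areas apply a cos(latitude)
correction.  BA is computed on full UDs over a shared grid (an option
truncates at the 95% contour first); `regrid` provides mass-conserving
aggregation/refinement between integer-related resolutions.  No
land-masking is applied.

## Isotopes

δX = (R_sample/R_standard − 1) × 1000, reported in ‰ (the ×1000 made
explicit).  Feather-to-blood tissue corrections are additive offsets that
**must be supplied by the caller** from the taxon-appropriate literature;
there is deliberately no default, outputs record the offsets applied, and
a provenance flag blocks double application.  The niche ellipse uses the
sample mean and covariance with the chi-square(2) quantile at the coverage
level (default 40%), area πq√detΣ; the hull is the exact convex hull.
Group-comparison statistics are out of scope — tables export cleanly to any
statistics environment.

## Synthetic bird-year generator

The generator's defaults are the study conditions used throughout the
tests: colony at (−39.25, 146.5), 10-min chick-rearing fixes, four-state
Markov switching (self-persistence 0.85, stationary occupancy ≈
35/12/46/7% for LL/LH/HL/HH), state speeds 0.3/1.0/10.0/6.5 m s⁻¹ (sd
0.15/0.3/1.2/1.0) and von Mises turn concentrations 30/−2/30/−2 (negative
κ concentrates turns near π, producing the high-turn searching states).
Movement is a discrete-time correlated random walk on a local tangent
plane re-projected to lat/lon — the simplest model exposing the speed/turn
structure the clustering assumes.  Trips are forced to start and end at
the colony by a homing pull once a duration budget (~30 h ± 40%) elapses,
plus an outbound guard within 8 km of the colony so mid-trip fixes never
re-enter the colony radius: trip ground truth is segmentable by
construction.  Light is logistic in solar elevation with inflection at the
calibration angle (−3.5°), making the threshold crossing analytically
invertible; the light-unit scale (max 64) is arbitrary and configurable,
as real devices vary.  The scripted non-breeding year departs in late
January after ten colony nights, migrates ~2000 km west-southwest at
250 km d⁻¹, winters ~75 d (with a 30-d moult starting 10 d after arrival),
returns, and resides ~100 km from the colony with five single-night burrow
visits.  Isotope groups are bivariate normal per tissue/period with means
in the observed range for a krill-feeding shelf forager.

What the generator does *not* emulate — and what passing tests therefore do
not establish about field data: oceanographic structure (currents,
bathymetry, prey fields), sensor clock drift, weather-driven light
interference beyond white noise and random shading, behaviour-dependent
twilight shading (birds in flight vs on water), and GPS measurement error.
Recovery rates on real deployments will be correspondingly worse,
especially for geolocation latitude in cloudy conditions.

## Numerical choices and degenerate inputs

Times are UTC throughout; coordinates signed decimal degrees (east/north
positive); distances use the haversine on a sphere of radius 6371.0088 km.
EM: median-split initialization, 1e-8 log-likelihood tolerance, sd floored
at 1e-4 of the data sd.  Latitude roots: 1°-grid bracketing + Brent to
1e-6°.  Empty fix sets, single fixes, all-identical cluster inputs,
collinear isotope samples and zero-position days all take explicit
degenerate branches (empty outputs, warnings, or errors naming the cause)
rather than crashing.  Problem sizes in the test-suite simulations (a
12–46-day GPS deployment, a 240-day GLS year, 10⁵-point Monte-Carlo
checks) were chosen so recovery statistics are well out of the noise while
the whole suite runs in well under a minute per module.
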