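# Methods

`reefrange` estimates home ranges of reef-associated sharks from passive
acoustic telemetry on essentially linear reef habitat, compares them across
sex × maturity groups and seasons with permutation statistics, and models the
probability that a marine protected area (MPA) of a given reef-slope area
fully covers individual home ranges. This note documents the models, the
parameter choices and the limits of what the synthetic-data tests demonstrate.

## Linear-habitat utilization distributions

Receivers moored along the outer slope of barrier reefs form a nearly
one-dimensional array: each receiver occupies a curvilinear position `s`
(km) along its reef axis. At the spatial resolution of such arrays
(kilometres between moorings) kernel UD estimators are not meaningful, so a
hull-based estimator is used:

1. The monitoring period is split into calendar days in study-local time
   (UTC+11 by default; timestamps are stored in UTC). A *daily occurrence*
   is the presence of at least one detection of an animal at a receiver
   within one local day; a day can contribute occurrences at several
   receivers.
2. Receivers are ranked by descending daily-occurrence count (ties broken by
   receiver id) and the **core subset** is the shortest prefix whose
   cumulative count reaches 95 % of the total. The boundary comparison is
   `≥` (a prefix exactly at 95 % qualifies).
3. On each reef, the 1-D convex hull of a receiver subset is the interval
   between its outermost receivers. The hull is mapped to habitat area
   through the reef's cumulative slope-area function `A(s)` (km² of outer
   reef slope from the reef origin to `s`; piecewise linear, non-decreasing,
   `A(0) = 0`). **UD100** uses all visited receivers, **UD95** only the core
   subset; per-reef areas are summed and inter-reef water contributes zero
   area (animals crossing between reefs are credited with the shortest
   great-circle distance in movement summaries, never with area).

An animal detected on a single receiver has a zero-extent hull and is
assigned `UD95 = UD100 = 0`; this deliberately under-estimates small ranges
at sub-spacing resolution. An animal with no occurrence in a season yields
an *absent* result (`None`), distinct from a present animal with `UD = 0`;
seasonal statistics by default use only animals present in that season.

Seasons are calendar months in local time: mating July–September, non-mating
October–June. The *exclusive mating-season fraction* is the area of the
mating-season hull minus the non-mating hull (interval difference per reef,
mapped through `A`), divided by the year-long UD100; it is 0 when the animal
has no mating-season detections or a zero year-long UD100.

## Telemetry cleaning and cohort rules

* **False detections.** Coded tags transmit every 30–90 s, so genuine visits
  leave clusters. A detection is removed iff no other detection of the same
  transmitter at the same receiver falls within ±3600 s (≈ 60× the mean
  transmission delay). The window is configurable; the rule is idempotent.
* **Post-capture window.** Detections earlier than 14 days after tagging are
  discarded; the window is closed–open, anchored at local midnight of the
  tagging date. Whether "two weeks" should count from the capture instant or
  from midnight is not observable at daily resolution; midnight anchoring
  keeps daily bins whole.
* **Exclusions.** Animals tagged at a receiver later lost are excluded first
  (their range cannot be anchored); among the remainder, animals with zero
  detections after the window are excluded as silent. The precedence makes
  the two exclusion sets disjoint, so
  `n_retained = n_tagged − n_silent − n_lost` always holds.

## Permutation and bootstrap statistics

UD areas are strongly right-skewed with a point mass at zero, so values are
transformed as `y = log10(1 + x)` and all inference is permutation-based:

* **Two-way permutation ANOVA** (sex, maturity, interaction) with sequential
  (type-I) sums of squares via successive orthogonalisation of the design
  blocks; the null distribution of each term's SS comes from unrestricted
  permutation of the responses. P-values use the add-one correction
  `(1 + #extreme)/(1 + m)`. The permutation stream stops early, per term,
  once the standard error of the p estimate drops below `0.1·p` (checked in
  blocks of 100, at least 50 permutations, at most 5000); the number of
  permutations actually used is reported per term. Early stopping follows
  the sequential-stopping idea used by permutation-ANOVA software; the rule
  here (relative-precision threshold 0.1) is this package's own choice.
* **Pairwise permutation Student tests** (999 permutations by default) on
  the same transformed scale, with pooled-variance t. When a pair is small
  enough that all label splits can be enumerated, the test switches to the
  exact exhaustive version automatically.
* **Bootstrap**: percentile bootstrap (200 runs) for group means, for the
  proportion of animals below a reporting threshold (10 km²; strict
  inequality), and for pointwise 95 % bands around cumulative UD curves
  (resampling individuals with replacement; the band is clipped to contain
  the point estimate, which matters only at extreme quantiles of small
  samples).

## MPA coverage model

For an MPA protecting `S` km² of reef slope, the habitat is discretised into
`n = ⌈S/dS⌉` intervals of width `dS = 1 km²` (the last interval truncated at
`S`; centres at interval midpoints). A shark `j` centred at centre `c_i` is
covered iff `[c_i − UD_j/2, c_i + UD_j/2] ⊆ [0, S]`. Averaging the indicator
over sharks gives `P_i`, and over intervals gives Π, the probability that a
shark placed uniformly in the MPA keeps its whole range inside it. Sharks
are placed homogeneously and intervals independently; habitat limits and
isolation (which make real MPAs on bounded reefs more effective) are outside
the model, so Π is conservative. The continuum limit
`Π = mean_j max(0, S − UD_j)/S` serves as an independent oracle: the
discretisation error is bounded by `dS/S`. The minimum size `S*` for a
target coverage is found by doubling-plus-bisection on the `dS` grid,
exploiting that Π is non-decreasing in `S`.

## MPA screening

WDPA-style polygon records are screened on: IUCN category in {I, Ia, Ib, II}
(subcategories count as I), a present designation year (WDPA encodes unknown
as 0), centroid inside the species-range box 26°S–26°N and 25°E eastwards to
150°W, and non-empty intersection with reef habitat. The longitude test and
all intersections run in a [0°, 360°) frame with per-ring unwrapping, so the
antimeridian needs no polygon cutting. Invalid geometries are repaired with
`make_valid`, keeping the polygonal part.

Areas are geodesic on the WGS84 ellipsoid, computed by mapping vertices
through the authalic latitude onto the authalic sphere and applying the
cylindrical equal-area shoelace formula. For polygons bounded by meridians
and parallels this is exact; for reef-scale polygons with oblique edges the
edge-path discrepancy is orders of magnitude below the 1 % tolerance used in
tests. Shapefile input is not supported; screening reads GeoJSON (RFC 7946).

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, with a
known ground truth for recovery tests. Defaults:

| parameter | default | rationale |
|---|---|---|
| reefs / lengths | 4 reefs, 100/72/52/44 km | four regions of a barrier-reef system |
| slope-area density | 0.5 km²/km | ~500 m wide outer-slope strip |
| receiver spacing | 4 km (71 receivers) | ~70-receiver array |
| group sizes | 66/24/24/33 (AM/AF/JM/JF), 147 total | tagged cohort composition |
| range spans (non-mating) | AM 20, JM 12, AF 9, JF 5 km | with the density, yields mean UD100 ≈ 12 km² and the ordering AM ≫ JM > AF > JF |
| adult-male mating expansion | +22 km in Jul–Sep | ≈ half the male year-round range used only in the mating season |
| detection radius | 2 km | half the spacing, so a daily position is always audible somewhere |
| detections logged per day | Poisson(12) | order tens of logged detections per day after detection losses |
| silent fraction | 29/147 | animals never heard after the post-capture window |
| false detections | 30 isolated pings | exercise the isolated-ping filter |
| study window | 2015-07-15 → 2016-12-31 | ~18 months; cohort counts and hull estimates are insensitive to longer windows, so the window is kept short enough for fast full-pipeline runs |

Each shark-day draws an independent position uniformly over the animal's
seasonal true range `[a, b]`. This is precisely the exchangeable-by-day
assumption the daily-bin UD estimator needs — the generator validates the
estimator, not any within-day movement model. Consequences worth noting:
with uniform use, the 95 % core subset covers almost the whole range, so
synthetic UD95 sits much closer to UD100 than in field data where space use
is concentrated; and cumulative-distribution shapes (e.g. the share of
animals below 10 km²) reflect the configured spans, not field skew. Passing
tests therefore demonstrate correctness of the estimators and rules, not
field-realism of detection behaviour (no tides, diel cycles, detection-range
decay, tag loss or battery death).

The frozen study-scale fixture (`paper_cohort()`) has 147 sharks of which 29
are silent, and the 3 animals tagged at subsequently-lost receivers are a
subset of the silent ones and sole users of their receivers — the only
configuration in which 147 tagged, 29 silent and 3 lost-receiver animals
leave exactly 118 retained with no bystander exclusions.

## Determinism and problem sizes

A single master seed is fanned out to per-stage seeds through
`numpy.random.SeedSequence.spawn` in a fixed order, so stages are
reproducible in isolation and full pipeline runs are byte-identical at a
fixed seed. Test problem sizes are chosen for thoroughness per unit time:
recovery tests use 40 sharks × ~300 days with receivers every 2 km;
permutation-calibration uses 500 null replicates (n = 24, up to 2000
permutations each); bootstrap calibration uses 1000 Gaussian samples of 30.

## Known limitations

* UD resolution is bounded below by receiver spacing; single-receiver
  animals get `UD = 0`.
* The coverage model treats the MPA as an isolated 1-D habitat segment with
  homogeneous use; no home-range overlap dynamics or habitat limits.
* The false-detection rule is a documented isolated-ping criterion, not a
  re-implementation of any proprietary vendor filter.
* Screening trusts WDPA-style attributes as given; multi-part MPA records
  are treated atomically by id.
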