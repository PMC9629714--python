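# Methods

`darkgaps` implements an end-to-end analysis of suspected intentional AIS
(automatic identification system) transponder disabling in fishing-vessel
position streams: detecting transmission gaps, separating deliberate
"going dark" from reception artefacts, mapping where the hidden time was
spent, and modelling the spatial drivers of disabling.  Because real
satellite-AIS feeds and labelled disabling events are proprietary, the
package ships a synthetic-data generator that emulates the statistical
structure of such a stream; every downstream stage is exercised, tested and
benchmarked against the generator's ground truth.

## 1. The synthetic world and fleet

**Grid.** All rasters live on regular lon/lat grids with half-open cells
`[west, west+Δ) × [south, south+Δ)`, row 0 at the south, 0.25° cells by
default.  Rasters are written as ESRI ASCII grids (plain text, EPSG:4326
implied); missing cells are NoData.

**Reception field.** Satellite reception quality — expected positions
received per vessel per day — is a background level plus isotropic Gaussian
bumps (`amplitude · exp(−d²/2σ²)`, d in planar degrees), clamped at zero.
Negative-amplitude bumps carve low-reception holes.  The default world is a
20°×20° open-ocean patch with background 35 positions/day, one deep hole
(amplitude −34, σ = 3.5°) and one mild high-reception lobe.  Shore is the
western extent edge by default; shore distance is great-circle distance to
the densified shoreline polyline on a sphere of radius 6 371 km.

**Movement.** Vessels follow a correlated random walk at hourly steps:
heading gets Gaussian turning noise (σ = 0.5 rad) plus a pull (weight 0.12)
toward a gear-specific fishing-ground center; step lengths are log-normal
with mean 0.04°/h (≈ 2.4 kn); the extent boundary reflects.  No real
movement model is being reproduced — any process that yields spatially
clustered tracks with realistic gap geometry suffices.

**Ping process.** Pings are an inhomogeneous Poisson process thinned by
reception: expected pings per vessel-day equal
`base_rate · min(1, reception/30)`, evaluated hourly along the track.
Class A transponders default to 100/day, class B to 13/day (A/B mix
0.7/0.3).  Each vessel additionally carries a log-normal broadcast-rate
multiplier (σ = 0.5, unit mean) representing antenna quality and
shadowing.  This heterogeneity matters: it is what produces genuine
reception-driven gaps in waters that pass the reception filter, giving the
classifier a non-trivial negative class.  These values are assumptions
chosen to produce a realistic mixture of gap causes, not calibrated
estimates of any real fleet.

**Intentional disabling.** Each vessel-day outside an existing dark period
starts a disabling event with probability
`logistic(β₀ + Σ βᵢ xᵢ)` on the driver covariates in the vessel's cell —
by default β₀ = −4.2 with positive weights on transshipment-vessel
loitering (0.06 per hour) and distance to shore (0.004 per km), the two
planted drivers.  Durations are log-normal (median 40 h, σ_log = 0.9), so
a tail of events exceeds the two-week cap.  The event is anchored at a real
ping (the last ping before), all pings strictly inside the interval are
deleted, and the truth log records the anchor and the first ping after.
Unintentional gaps are never planted; they arise implicitly where reception
is poor.  The generator's gap-cause mixture (roughly 4:1
intentional:reception among retained gaps on the bundled fixture) is an
assumption, not an estimate.

## 2. Reception maps

Observed reception per device class is the average number of received
positions per vessel per day: each vessel-day is attributed to the cell
holding the vessel's daily mean position (the attribution rule is isolated
in one function; alternatives are one-line changes), and the cell value is
total messages over total vessel-days.  Cells without vessel-days are
missing, never zero — no vessels is not no reception.  The predicted
surface interpolates observed 1° cell-center values to 0.25° with a
thin-plate-spline RBF, zero smoothing (exact at the nodes) and a degree-1
polynomial tail, which makes the interpolant exact for constant and linear
fields and commute with constant shifts; negative interpolants are clamped
to zero.  Interpolation quality is validated against the generator truth
only over fine cells whose parent coarse cell was observed — a global
thin-plate spline extrapolates poorly far outside its support, and the map
is only ever consumed at gap start positions, which lie where vessels
broadcast.

## 3. Gap detection and classification

A gap event is a pair of consecutive messages of one vessel spaced at least
12 h apart (boundary included).  Gaps are retained only when the start
position is **strictly** more than 50 nautical miles from shore and the
class-matched predicted reception **strictly** exceeds 10 positions/day;
both covariates are stored on every event regardless of outcome, and the
filters never see truth labels.

A retained gap is classified as suspected intentional disabling when the
vessel was broadcasting healthily just before going dark: at least `k`
positions in the lookback window `(start − L, start]` (half-open, so the
boundary ping at the gap start counts once) and predicted reception above a
rule-level threshold.  The default rule is L = 12 h, k = 14.  Rule models
are selected from a candidate grid (L ∈ {6, 12, 18, 24} h, k ∈ 2…30,
reception ∈ {10, 15, 20}) by mean F0.5 — precision weighted four times
recall — under 5-fold stratified cross-validation repeated 10 times; ties
break toward higher precision, then smaller k, then shorter L.  The rule
has no trained state, so pooled held-out confusion counts coincide with
full-data counts; the returned evaluation is computed over all retained
gaps.  Ground truth for evaluation: a gap is intentional iff a planted
interval of the same vessel is nested inside it (guaranteed by
construction), otherwise its cause is reception.

## 4. Allocating hidden time

Each suspected event's hidden hours (capped at 336 h for the lower-bound
estimate; uncapped for the upper bound) are spread over the grid two ways:

* **Linear** — traverse the great-circle segment between the bounding pings
  at constant speed; time per cell is proportional to arc length in the
  cell, computed by sampling the arc at ≤ 0.01° steps and binning segment
  midpoints (validated against 10⁻⁴° brute force).  Antipodal endpoints
  (undefined great circle) fall back to the start cell with a warning.
* **Probabilistic** — a reachability-bridge kernel: the feasible set is
  every cell center c with `d(start,c) + d(c,end) ≤ v_max · duration`
  (v_max = 10 kn); within it, weight is
  `(prior(c) + 10⁻⁹) · exp(−excess(c)/s)`, where excess is the detour
  beyond the direct route and `s = 0.5 kn · duration` — half a knot is a
  typical drift speed, so the slack grows with the time available.  The
  prior is a fishing-activity raster when supplied, uniform otherwise.
  Weights are normalised, so total time is conserved exactly.  A plain
  uniform-over-ellipse weighting was rejected: it is shape-mismatched with
  the linear method even for short gaps, while the two methods should and
  here do agree (per-cell Pearson r ≈ 0.85 on the bundled fixture) for
  events under two weeks, diverging for longer ones.

Broadcast activity uses inter-ping intervals shorter than 12 h, split
half/half between the two endpoint cells (longer intervals are gap
candidates and contribute nothing).  The fraction of activity obscured per
cell is `hidden / (activity + hidden)` — the denominator deliberately
includes the hidden time itself — missing where the denominator is zero.
Hot spots are cells jointly exceeding fraction and activity thresholds,
labelled by rook-adjacent connected components.

## 5. Drivers of disabling

The driver model asks where disabling happens relative to where fishing
happens.  Presences are cells with at least one suspected event; absences
are drawn uniformly without replacement, at an exact 1:1 ratio, from cells
with fishing activity and no disabling (no exclusion buffer).  Eight driver
rasters enter: distance to shore, to marine protected areas, and to
reported piracy (all clipped at 400 km to keep effects proximal),
transshipment-vessel loitering hours, chlorophyll-a, eddy kinetic energy,
sea-surface temperature and its temporal variability — consumed as static
period-mean rasters with no temporal matching.

The classifier is a gradient-boosted tree ensemble with binomial deviance,
tree depth 3, learning rate 0.01 and bag fraction 0.5 — the standard
ecological boosted-regression-tree settings.  Ensemble size is chosen by
internal 5-fold cross-validation over the staged deviance curve up to a
ceiling of 2 000 trees; at these desk-scale table sizes (10²–10³ rows) the
CV curve flattens well below the ceiling, so a larger cap only adds cost.
Relative importance is normalised split-gain per driver (sums to 100%);
partial dependence is the mean ensemble response over a 100-point grid per
driver spanning its observed range.  Evaluation follows the
presence/absence protocol: 50 iterations, each redrawing the absence set
(1:1 maintained) and splitting 75/25 stratified; held-out AUC and TSS
(sensitivity + specificity − 1 at the TSS-maximising threshold) are
averaged, and explained deviance (1 − residual/null) is reported for the
final training fit — a training-based quantity, stated as such.  Per-
iteration fits reuse a fixed ensemble size (the final fit's choice, or 500)
rather than re-running the internal CV 50 times.

## 6. Reproducibility and problem sizes

A single global seed derives per-stage seeds via SHA-256 of
`"<seed>:<stage>"` (truncated below 2³¹), so stages are individually
reproducible and fixing the seed fixes every byte of generator output.

The bundled study conditions are 100 vessels over 90 days on the default
world (≈ 4–6 × 10⁵ messages, ≈ 650 planted events, ≈ 400–600 retained
gaps); driver-model recovery experiments run on a 10°×10° world
(40×40 cells, ≈ 1 000–1 200-row tables).  These sizes give stable
statistics for every check while keeping the full test suite and the
acceptance script in the minutes range on a single CPU.

## 7. What passing tests do and do not show

The generator reproduces the *mechanisms* the pipeline exploits — reception
thinning, rate heterogeneity, anchored dark periods, covariate-driven event
placement — but not many features of real AIS data: no terrestrial
receivers, no message collisions in crowded waters, no gear-specific
diurnal fishing rhythms, no identity swapping, no temporal driver
variation, and planted truth is perfectly known whereas real labels are
themselves inferred.  Classifier precision/FPR and driver-recovery results
on synthetic data therefore demonstrate correctness of the machinery and
internal consistency of the method, not expected performance on a real
fleet.  Known limitations: the vessel-day cell-attribution rule and the
probabilistic-allocation kernel are this package's own constructions;
filters are evaluated at the gap start position only; and distance layers
saturate at 400 km by design.
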