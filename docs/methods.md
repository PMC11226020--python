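# Methods

## Scope and data model

`pamval` works on the *output* of an automated acoustic classifier, never on
audio. A detection is a fixed 3-s prediction window with a species label and
a confidence in [0, 1]; the canonical in-memory container is a pandas
DataFrame (site, recording, recording start, segment offsets, species,
confidence, absolute start time). Two tab-delimited dialects are read: the
per-recording result table produced by common analyzer GUIs (`Start (s)`,
`End (s)`, `Scientific name`, `Common name`, `Confidence`) and a combined
long table that adds `site_id`, `recording_id` and `recording_start`; the
combined table is the package's interchange format. Timestamps are naive
local civil time; no timezone conversion is ever applied automatically.

Malformed rows fail fast by default, with an opt-in skip-and-log mode:
silently dropping rows would bias every richness count downstream. All
confidence-threshold comparisons are inclusive (`confidence ≥ t`), so a run
with minimum confidence 0.10 retains detections reported at exactly 0.10.
Species identity is the scientific name after canonicalization through an
alias catalog (case/diacritic folding); common names are display-only.

## Performance metrics

Precision is validated per species on random samples of 60 detections, drawn
without replacement, independently at two strata (all detections at ≥ 0.10;
detections at ≥ 0.25). Samples are reproducible: each sample artifact stores
its seed, and the 5-s review-clip coordinates (3-s window plus 1 s of context
each side, clamped to the recording) are emitted so a human or an oracle can
label them identically. If a species has fewer than 60 eligible detections
the full pool is used and a shortfall warning recorded. The two strata are
drawn independently (not nested).

Recall is segment-level: 50 random 120-s segments are drawn uniformly from
the pooled recording time (a segment's start is uniform over each recording's
eligible measure). A detection belongs to a segment if its 3-s window
overlaps it by any amount. Recall = TP/(TP+FN) over segments; it is
*undefined* (missing) when the species was never manually recorded in any
segment. A species manually recorded but never matched by the classifier
yields recall 0 by default; an `undetected_missing` flag instead reports the
metric as missing when the classifier never detected the species at all,
reproducing a stricter published exclusion convention. The F-score is the
harmonic mean of the default-stratum precision and recall; a missing recall
propagates to a missing F.

The max false-positive confidence pools annotated false positives from both
strata's samples, since one value per species is reported and used. The SSC
decision rule is total and deterministic: 0.10 if `P_C10 ≥ 0.85`, else 0.25
if `P_C25 ≥ 0.85`, else the max-FP confidence (an error if the third branch
is reached with no false positive ever observed). Metrics are stored at full
precision and rounded half-away-from-zero to 3 decimals for presentation.

The bundled 20-species benchmark ships both the printed 3-decimal metrics
and the underlying integer counts. The counts matter: recomputing F from the
rounded decimals flips the last digit for two species, while the count-level
fractions reproduce every printed F exactly — the benchmark's F values were
evidently computed before rounding. One benchmark row (Western Meadowlark)
carries an SSC entry inconsistent with the decision rule as stated (both
precision strata are below 0.85, so the rule yields its max-FP confidence
0.598, not the listed 0.250); `pamval` implements the rule as stated, and the
test suite surfaces the discrepant row as a failing check rather than
special-casing it.

## Richness and method comparison

Short-duration richness is per survey visit: a visit is paired with every
same-site recording whose interval intersects the visit interval padded by
±60 min (interval intersection, not start-to-start distance, is the least
surprising reading of "within 1 hour"); visits with no qualifying recording
are excluded and reported. Long-duration richness is per site over an
inclusive date range. Accumulation curves use calendar days (day 1 = period
start, detections dated by segment start) and by construction end at the
whole-period richness. The top-N confirmation review ranks each species'
detections by confidence (ties broken by earlier timestamp, then recording
id, for auditability) and a species counts toward confirmed total richness
iff at least one of its top N (default 10) detections is confirmed.

Method comparison uses two-tailed Student paired t-tests on ARU − point-count
differences, aligned per visit (short) or per site (long), one test per
(period, threshold) cell. Degenerate difference vectors, routine on small
simulated fixtures, follow fixed conventions instead of erroring: all-zero
differences give t = 0, p = 1; zero-variance nonzero differences give
t = ±∞, p = 0. No multiple-testing correction is applied by default (matching
how threshold-ladder comparisons are conventionally reported); Holm-adjusted
p-values are available behind a flag.

## Simulator

The generator emulates the data-generating situation of a multi-site ARU
deployment with paired point counts:

- **Occupancy**: each species is present at a site with habitat-specific
  probability ψ (defaults 0.9 grassland, 0.6 row crop), drawn once per
  dataset.
- **Effort**: fixed clock blocks per day (default four 1-h blocks standing in
  for a dawn/dusk solar schedule — solar geometry would add a dependency
  without exercising any computation of interest), default 10 sites and a
  60-day season.
- **Detections**: at occupied sites true detections arrive per block as
  Poisson(λ_v · hours); false positives arrive everywhere as
  Poisson(λ_f · hours). Segments occupy distinct 3-s grid slots within a
  block (per species), matching a zero-overlap classifier run; over-capacity
  demands raise an error.
- **Confidences**: i.i.d. Beta draws rescaled to [0.10, 1] for true
  positives and [0.10, fp_cap] for false positives; `fp_cap` is the species'
  true maximum false-positive confidence, so threshold-recovery logic can be
  checked against a known bound. Default shapes Beta(1.5, 3) / Beta(1.2, 5)
  give right-skewed confidence distributions with false positives
  concentrated at low confidence, the qualitative shape practitioners see.
- **Point counts**: three visits per site, evenly spaced at 07:00; each
  occupied species is recorded per visit with probability `p_point_count`
  (default 0.5), independently across visits. An optional confusion mode
  attributes false positives to a source species for documentation examples.
- **Oracle annotation** replaces the expert: detection labels are copied from
  truth; a segment's manual species set is every species with a true
  vocalization overlapping it, optionally thinned by a manual-detection
  probability to emulate imperfect listeners.

Default species parameters derive from the bundled benchmark: per-species
total rates are proportional to the benchmark's detection totals over its
5,189 recorded hours, scaled down by 0.02 so that a full simulated season
stays around 3×10⁴ detections (desk-sized, seconds to generate); each rate is
split so the species' expected precision at the 0.10 stratum equals its
benchmark precision, and `fp_cap` equals its benchmark max-FP confidence.
All randomness flows from one integer seed through named child streams
(occupancy / detections / point counts / annotation), so outputs are
bit-identical across runs at the same seed.

What the simulator does *not* emulate — and hence what passing tests do not
show about field data: distance-dependent detectability and sound
propagation, weather and ambient-noise covariates, diel and seasonal
vocalization phenology, inter-annotator disagreement, and classifier
confidence miscalibration that correlates across time (confidences here are
i.i.d. given truth).

## Statistical validation performed

The suite checks parameter recovery, not just plumbing: on a species
engineered with expected precision ≈ 0.95, the 60-sample precision estimate's
exact (Clopper-Pearson) 95% interval covers the true value in ≥ 93% of 200
seeded replicates, and the SSC rule assigns the default 0.10 threshold in
≥ 95% of them; empirical precision and Poisson counts match their analytic
expectations within Monte-Carlo error; richness is monotone in threshold;
accumulation curves are non-decreasing with exact terminal values; and the
paired-t table equals an independently scripted closed-form computation to
6 decimals. Problem sizes in the tests (4–10 sites, 5–60 days, 200
replicates) were chosen to keep the full suite in the seconds-to-minutes
range while leaving expected counts large enough for the moment checks.

## Known limitations

- Segment placement is uniform within blocks; real vocalizations cluster.
- The SSC rule inherits the 60-sample design's granularity: precision
  estimates move in steps of 1/60, so species near the 0.85 cutoff are
  assigned thresholds with appreciable sampling variability.
- Recall from 50 segments is coarse for rare species (many are never
  manually recorded, leaving the metric undefined), which is faithful to the
  validation design rather than a defect of the implementation.
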