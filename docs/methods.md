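# Methods

## Problem setting

A single resident lives in a dwelling instrumented with passive-infrared
occupancy sensors (one area each) and a main-door entry sensor. The sensor
stack yields interval-level records — *the resident was at location L from
t0 to t1* — plus timestamped door open/close events. The task is to detect
days and hours on which the routine deviates (novelty detection against a
normal baseline, not supervised classification of anomaly types) and to
attribute each deviation to a visitor or to an irregular pattern of the
resident. The approach assumes the degree of *change* in the activity
pattern — not which activities occur — is the signature of abnormality, and
therefore quantifies each time window by its entropy.

## Encoding

Locations are mapped to positive odd integer codes. Five conventional
assignments are fixed (toilet = 1, bedroom-sleeping = 3, corridor = 5,
living room = 7, kitchen = 9); any other location takes the next unused odd
number in alphabetical order, so the map is deterministic for an arbitrary
home. Odd spacing keeps distinct codes at distance ≥ 2, which with the
default tolerance r = 1 makes "same room" the only template match — the
symbolic analogue the estimators expect.

A day is sampled at minute resolution: minute *t* (0-based, half-open
windows) carries the code of the interval containing the instant HH:MM:00.
Consequences, by design:

* dwell is rounded to whole minutes; a sub-minute interval containing no
  minute-start vanishes from the series;
* minutes covered by no interval repeat the last seen code (carry-forward);
  the resident being out of the home therefore appears as a constant
  stretch of the last location (typically the corridor by the door);
* minutes before the first interval of a day take a dedicated out-of-home
  code (largest assigned + 2), so every day is exactly 1440 samples.

Intervals may span midnight and contribute to each day they touch.
Overlapping intervals are rejected at ingest: with one resident,
simultaneous locations indicate a corrupt log, and clipping them silently
would fabricate transitions.

## Entropy measures

All seven estimators use the natural logarithm and return values in nats.

* **ShEn** `-k Σ_i p_i ln p_i` over the empirical symbol frequencies of the
  window (k = 1). Order-blind: any permutation of the window scores the
  same.
* **ApEn(m, r)** Template self-similarity with self-matches included:
  φ^m = mean_i ln C_i^m, ApEn = φ^m − φ^{m+1}, Chebyshev distance, match
  iff d ≤ r.
* **SampEn(m, r)** Self-matches excluded: −ln(A/B) over ordered pairs of
  the first N−m templates of lengths m+1 (A) and m (B). B = 0 raises an
  error (the statistic is undefined). A = 0 with B > 0 returns the finite
  ceiling −ln(1/((N−m)(N−m−1))) — the largest value the statistic could
  take with one more match — with a warning, so max-based thresholds stay
  finite.
* **FuzzyEn(m, r, n)** Templates are baseline-removed (own mean
  subtracted); pair similarity is the membership exp(−d^n / r); φ is the
  mean membership over self-excluded pairs; FuzzyEn = ln φ^m − ln φ^{m+1}.
  n = 2 by default. The self-pair diagonal is zeroed before averaging
  rather than subtracted afterwards — subtracting k from a sum dominated
  by k unit self-memberships cancels catastrophically when the remaining
  memberships are ~e^{−16}.
* **PerEn(m, τ)** Shannon entropy (unnormalised) of the ordinal-pattern
  distribution. Equal values are ranked by temporal order (stable sort):
  symbolic series are dominated by runs of equal codes, and temporal
  tie-ranking maps every run onto the "non-decreasing" pattern instead of
  scattering ties across patterns. Normalising by ln(m!) would rescale all
  thresholds uniformly and is omitted.
* **MPE / MFE** Coarse-grain the window at scales s ∈ {1, 2, 3} (block
  means, length ⌊N/s⌋), apply the base measure per scale, and aggregate by
  the arithmetic mean across scales. The scale set keeps a coarse-grained
  hourly window at ≥ 20 = 10·m samples. Both the scale set and the mean
  aggregation are package choices (configurable via `EntropyParams.scales`).

Parameter defaults m = 2, r = 1, τ = 1 follow the study design this package
operationalises. r is **absolute** on the code scale, not scaled by the
series SD (the conventional r ≈ 0.2·SD variant is available via
`r_scaled_by_sd` but off by default): on symbolic data the SD depends on
the arbitrary code assignment, whereas r = 1 has the crisp meaning
"identical codes only".

A caution on interpretation: template measures score *self-similarity*, not
transition count. A strictly periodic alternation of two codes is almost
perfectly self-similar and scores near zero on ApEn/SampEn/FuzzyEn even
though every sample is a transition. Irregularity requires aperiodic
variation; the simulator (below) respects this.

## Two-stage detection

Per measure, the daily threshold is the maximum daily entropy over the
labeled normal days, and the hourly threshold is the maximum over all
hourly windows of those days (one scalar per measure, not per hour-of-day —
matching the single-threshold design of the study and avoiding 24 separate
extreme-value estimates from 56 samples each). Days strictly above the
daily threshold are flagged; hours are then scanned only within flagged
days and flagged when strictly above the hourly threshold. Strict
inequality means calibration days can tie their own maximum but never flag
themselves — a structural safety property the suite verifies over 20 seeded
datasets. An exploratory `scan_all_hours` switch lifts the day gate.

Calibration requires explicit normal-day labels; no unsupervised split is
attempted.

## Attribution

An anomalous hour is *visitor-caused* iff at least one door event (open or
close — both count, since either indicates the door was used) falls within
[hour start − tolerance, hour end + tolerance]; tolerance defaults to 0
minutes (same clock hour), matching the hour-level alignment of the
detection stage. Other flagged hours are *irregular patterns*; the day
summary calls them *irregular sleep* when they fall in the night window
(default 22:00–07:00). Within a visitor hour, door events are paired in
order (1st–2nd, 3rd–4th, …) to bracket visits; a trailing unpaired event is
reported as an open-ended interval rather than guessed at. Door events
never create anomalies — attribution only labels hours the entropy stage
already flagged.

## Synthetic data

Real single-resident ADL recordings are privacy-sensitive and rarely
deposited, so the package ships a seeded simulator whose default profile
mirrors the study design end-to-end: 65 days, 56 normal and 9 anomalous
(days 16, 33, 52 visitor; 29, 38, 49 irregular sleep; 25, 42, 63 both),
carrying 13 abnormal hours in total — one per single-cause day, two on days
25 and 42, three on day 63 (two nocturnal + one visit).

A normal day is a fixed schedule — sleep with one nocturnal toilet
excursion, morning routine, lunch, a 15:00–17:00 outing (a coverage gap
bracketed by the resident's own door events), dinner, evening rest, bed —
with every block boundary jittered uniformly by ±5 minutes and 5–20 s
sensor gaps between consecutive intervals. Normal hours contain at most ~4
location transitions. Background door traffic is 4–6 events/day (outing
pairs plus an occasional evening opening), so door events alone cannot
indicate a visit.

Anomalous hours are filled with aperiodic bursts: dwells of 70–150 s in a
uniformly random room different from the previous one (visitor bursts move
among living room/corridor/kitchen; sleep bursts among
bedroom/toilet/corridor/kitchen, with no door events). Each visit emits
exactly one open/close pair inside its hour (open ≈ hh:03, close ≈ hh:47).
Burst hours contain ≥ 23 (typically ~30) transitions — at least 5× the
normal-hour maximum. This effect size is deliberately large: the fixture is
meant to be *separable*, so that perfect FuzzyEn/MFE recovery is an
achievable correctness check of the pipeline, not an empirical claim about
real recordings. What passing shows is that the implementation recovers a
known injected structure; real data will have smaller effects, drifting
baselines, sensor dropouts and multi-resident contamination that the
simulator does not model.

A separate `frequency_preserving` anomaly mode permutes the morning-routine
hour at one-minute granularity without changing its per-location minute
totals (the hour's schedule boundaries are frozen across days in this mode
so its composition is exactly constant). Symbol frequencies — hence ShEn —
are provably unchanged, while ordinal/template structure is scrambled; this
isolates the mechanism by which frequency-preserving anomalies evade
Shannon entropy but not PerEn/FuzzyEn.

All randomness flows from one `numpy` Generator; a seed fixes every output
byte-for-byte.

## Evaluation

Hour-level confusion matrix over *every* labeled hour (the packaged fixture
labels all 65 × 24 = 1560 hours; an unscanned hour counts as predicted
normal). Sensitivity, specificity, FPR, FNR and accuracy are reported in
percent; a ratio with zero denominator is NaN, never an exception.

## Problem sizes and numerics

The packaged fixture is the full 65-day design; profiling it with FuzzyEn
takes seconds (the O(N²) template distances for N = 1440 are vectorised).
Test ensembles that sweep many seeds or all seven measures use shortened
spans (6–26 days) of the same generator — the properties they check
(threshold safety, entropy ordering, oracle agreement) are scale-free.
Estimator correctness is established against independent double-loop
oracle implementations: exhaustively for all sequences of length ≤ 8 over
{1, 3, 5} and on 100 seeded random 60-sample windows, at 1e−10 absolute
tolerance.

## Known limitations

* Minute sampling erases sub-minute excursions; at PIR time resolution this
  is deliberate smoothing, but it caps the detectable burst rate at one
  transition per minute.
* The carry-forward rule cannot distinguish "out of home" from "sensor
  silent in the last room"; both render as a constant stretch.
* One hourly threshold per measure across all hours of day makes the
  quietest hours the easiest to flag and the busiest the hardest; per-hour
  baselines would need far more calibration days than a 56-day set offers.
* SampEn's finite ceiling in the no-match case is a convention (chosen so
  thresholding never sees infinity); comparisons of raw SampEn values near
  that ceiling are not meaningful.
* Attribution is correlational: a door event during a flagged hour is
  *called* a visit; a visitor who enters while the hour is not flagged, or
  irregular resident behaviour coinciding with door use, will be
  mislabelled.
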