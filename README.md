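# entroadl

Entropy-based anomaly detection for **activities of daily living (ADL)** in
single-resident smart homes instrumented with ambient sensors (PIR room
occupancy + a main-door entry sensor).

The package is aimed at researchers in ambient-assisted living who want to
flag days and hours on which a resident's routine was disturbed — by a
visitor, or by an irregular (e.g. nocturnal) activity pattern — using nothing
but interval-level sensor logs, and to tell those two causes apart.

## Method

1. **Encoding.** Each dwelling interval (start, end, location) is mapped to a
   positive odd integer code (toilet = 1, bedroom-sleeping = 3, corridor = 5,
   living room = 7, kitchen = 9, further rooms 11, 13, …). A day becomes a
   symbol series `A_N` of N = 1440 minute samples; each hour is a 60-sample
   window.
2. **Entropy profiling.** Seven irregularity measures are computed per day
   and per hour: Shannon entropy `-k Σ p_i ln p_i`, approximate entropy
   ApEn(m, r), sample entropy SampEn(m, r), permutation entropy PerEn(m, τ),
   fuzzy entropy FuzzyEn(m, r, n) with exponential membership
   `exp(-(d_ij^m)^n / r)`, and the multiscale variants MPE and MFE via
   coarse-graining. Defaults: m = 2, r = 1 (absolute, on the code scale),
   τ = 1, n = 2, scales {1, 2, 3}; all values in nats.
3. **Detection.** The threshold for each measure is the **maximum entropy
   over labeled normal days** — once on full-day vectors to flag anomalous
   days, then again on hourly windows (within flagged days) to localise the
   anomalous hours. Flagging is strict (`>`), so calibration days never flag
   themselves.
4. **Attribution.** A flagged hour containing main-door activity is labelled
   a *visitor*; one without is an *irregular pattern* of the resident,
   summarised as *irregular sleep* when nocturnal (22:00–07:00). Door events
   alone never create an anomaly.

Because frequency-based Shannon entropy ignores ordering, an anomaly that
merely re-orders activity (keeping per-room minute totals) is invisible to
ShEn but caught by the ordinal/template measures — the package ships a
synthetic anomaly mode that isolates exactly this mechanism.

## Worked example

Real recordings of this kind are rarely shareable, so the package includes a
seeded simulator of the study design: 65 days of a stable routine, of which
9 days (16, 25, 29, 33, 38, 42, 49, 52, 63) carry injected anomalies —
visitor episodes with door events, nocturnal activity bursts without them,
or both — totalling 13 abnormal hours.

```python
import entroadl as e
from entroadl import synthetic as syn

log, labels = syn.generate(syn.study_profile_config(seed=42))
series  = e.encode_log(log)
profile = e.compute_profile(series, e.EntropyParams(), ["ShEn", "FuzzyEn"])
model   = e.calibrate(profile, labels.normal_days())
result  = e.detect(profile, model)
print(sorted(result.anomalous_days["FuzzyEn"]))
print(e.metrics_table(result, labels, ["ShEn", "FuzzyEn"]).round(1))

report = e.attribute_hours(result, log.door_events, log.day_index_origin)
for day, summary in sorted(report.day_summaries.items()):
    print(f"day {day}: {summary}")
```

prints

```
[16, 25, 29, 33, 38, 42, 49, 52, 63]
         sensitivity  specificity  fpr   fnr  accuracy
measure
ShEn            46.2         99.9  0.1  53.8      99.5
FuzzyEn        100.0        100.0  0.0   0.0     100.0
day 16: visitor
day 25: irregular_sleep_and_visitor
day 29: irregular_sleep
day 33: visitor
day 38: irregular_sleep
day 42: irregular_sleep_and_visitor
day 49: irregular_sleep
day 52: visitor
day 63: irregular_sleep_and_visitor
```

FuzzyEn recovers every injected day and hour (sensitivity = specificity =
100%), while frequency-only ShEn misses over half of the abnormal hours —
the ordering-blindness the method is designed around. Attribution recovers
each day's injected cause; the day-16 visit is bracketed by its door events
(09:03–09:49).

The same pipeline is scriptable from the shell:

```bash
entroadl simulate --profile study --seed 42 --out data/
entroadl profile  --activity data/activity.csv --measure fuzzyen --out profile.csv
entroadl detect   --profile profile.csv --labels data/labels.csv --out detection.json
entroadl attribute --detection detection.json --door data/doors.csv \
                   --origin 2020-01-01 --out attribution.json
entroadl evaluate --detection detection.json --labels data/labels.csv --out metrics.csv
```

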