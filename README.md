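# whistlecee

Multi-scale analysis of common dolphin (*Delphinus delphis*) whistle
production during controlled exposure experiments (CEEs) with simulated
mid-frequency active sonar (MFAS), for bioacousticians and behavioral
response researchers working with passive acoustic monitoring data.

## The problem and the method

Free-ranging dolphin groups switch vocal state — bouts of intense
whistling, near silence, everything in between — on the order of once a
minute even undisturbed, so whether a sonar exposure changed their
calling depends heavily on the time window over which the comparison is
made.  This package implements an analysis chain that quantifies that
baseline variability first and then tests for a response at three nested
time scales:

1. **Geometry** — per-minute group-to-buoy distances from GPS fixes
   (haversine formula with linear interpolation), selection of the
   closest of up to three drifting recording buoys each minute, and
   exclusion of minutes where that distance exceeds 1.6 km.
2. **Counting** — whistle-detector export tables are cleaned of
   annotated sonar-harmonic detections, restricted to the selected buoy,
   and binned into per-second whistle counts `N_t` (detections *starting*
   in second `t`).
3. **Changepoints** — after a 5-s moving average, greedy binary
   segmentation locates changes in the mean and in the variance of the
   count series (Gaussian cost, MBIC-style penalty `3 log n`), giving
   per-period changepoint counts and the baseline switching rate.
4. **Response statistics** — `periodDiff = |median(N, exposure) −
   median(N, pre)|` at the 10-min scale, and `pingChange = mean(N,
   after-window) − mean(N, before-window)` in the 20 s and 5 s around
   each of the 24 pings (1.6 s long, every 25 s; controls use
   pseudo-ping timestamps).
5. **Models** — `periodDiff ~ ceeType + …` with a negative-binomial
   (NB2) likelihood; `pingChange ~ ceeType + medWhist + …` as a
   zero-inflated Gaussian, `P(y) = π·1{y=0} + (1−π)·N(y; μ, σ²)` with
   logit `π` driven by the baseline median whistle count, and with AR(1)
   correlation `φ^|Δt|` among the non-zero observations of an experiment
   at the 5-s scale.  Backward elimination by AIC with likelihood-ratio
   tests; pooled and Welch two-sample t-tests compare changepoint
   differences between control and sonar experiments.

A synthetic-experiment generator (`whistlecee.synthetic`) produces
complete CEEs — detection tables, buoy/group tracks, ping schedules —
from a Markov-modulated count process with known ground truth, so every
stage is testable without field data.

## Worked example

Simulate a sonar exposure with a 15-fold whistle burst in the ~5 s after
each ping (suppressed during the 1.6-s transmission), then run the
single-experiment analysis:

```python
from whistlecee.synthetic import SimConfig, simulate_cee
from whistlecee.pipeline import analyze_simulated_cee

cee = simulate_cee(SimConfig(
    cee_id="demo", cee_type="mfas", response_fold=15.0,
    suppress_during_ping=True, rl_max_db=152.0, seed=12,
))
r = analyze_simulated_cee(cee)
print("median whistles/s:", round(r.summary["med_whist"], 2))
print("mean-changepoints pre/exposure:",
      r.cpt_summary.mean_pre, r.cpt_summary.mean_exposure)
print("mean 5-s pingChange:", round(r.ping_short["pingChange"].mean(), 2))
print("first-ping fold change:", round(r.first_ping_fold, 2))
```

```
demo ping 21: fully masked window; record dropped
...
median whistles/s: 2.0
mean-changepoints pre/exposure: 13 78
mean 5-s pingChange: 17.48
first-ping fold change: 24.0
```

The group whistled about twice per second at baseline; counts jumped by
~17 whistles/s in the 5 s after a ping relative to the 5 s before, and
the first ping produced 24 times as many whistles in the 5 s after it
as in the 5 s before (one noisy realization of the injected 15-fold
burst).  The repeated bursts also inflate the exposure-period
changepoint count (78 vs 13 pre-exposure).  The log lines show the
1.6-km rule at work: a buoy drifted out of range late in the
experiment, so the last pings' windows were excluded.

The same chain is available from the shell
(`whistlecee simulate | geometry | count | changepoints | pingstats |
fit | report | all`), e.g.

```bash
whistlecee all --seed 1 --scenario response --out results/run1
```

which writes the per-experiment summary table, per-ping change series,
model-selection tables, a JSON report and a manifest recording every
parameter and seed.

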