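# echocage

Echogram-based behavioral analysis of a caged fish school exposed to acoustic
stimuli, together with a synthetic cage/echosounder scene simulator that
provides ground truth for every analysis stage.

The package covers the full chain used to quantify school reactions from an
upward-looking single-beam echosounder:

- **`echocage.io`** — the plain-text EGRAM echogram container (ping x range
  matrix of backscatter in dB with transducer metadata), event schedules and
  result tables, and the range/depth coordinate conventions.
- **`echocage.scene`** — the simulator: ~900 fish orbiting a 50 m x 28 m
  cage, a sinusoidal circadian depth rhythm, a Gaussian-beam renderer, and
  stimulus-triggered reactions (dive, vertical contraction, speed-up, tilt
  bias, direction reversal) with onset latency, recovery and habituation
  across repeats.
- **`echocage.envelope`** — per-ping school envelope: center of mass of the
  linear backscatter power, upper/lower school limits from the despeckled
  threshold mask, and hourly/event aggregation.
- **`echocage.traces`** — binarization, morphological cleanup (thickening,
  opening, closing with a 3x3 cross), 4-connected segmentation, size/level
  filtering, and per-trace length and tilt (OLS slope of the per-ping
  maximum-backscatter range, in m/ping).
- **`echocage.acoustics`** — calibrated hydrophone levels (exponential-RMS
  SPL, peak SPL), third-octave and narrowband spectra, and a harmonic
  distortion metric.
- **`echocage.stats`** — the per-event behavioral table, a PCA composite
  response score with B0/B1/B2 classes, Levene's test, unbalanced two-way
  ANOVA (Type III, sum-to-zero contrasts, empty-cell-aware interaction df),
  and Tukey–Kramer homogeneous subsets.
- **`echocage.pipeline` / `echocage.cli`** — one reproducible
  simulate → envelope → traces → events → stats run with a manifest.

## CLI

```sh
# end-to-end demo protocol (20-minute scene, tone + windmill events)
echocage run --out runs/demo --seed 1

# individual stages
echocage simulate --config scene.yaml --schedule events.csv --out scene/ --duration 3600 --seed 1
echocage envelope --in scene/scene.egram --threshold -70 --window 3600 --out envelope.csv
echocage traces   --in scene/scene.egram --min-size 6 --out traces.csv
echocage events   --in scene/scene.egram --schedule events.csv --out events.csv
echocage stats    --events events.csv --alpha 0.05 --out-prefix results/stats
echocage fixtures --out fixtures/

# hydrophone recordings (WAV + YAML calibration sidecar)
echocage noise spl --wav rec.wav --cal cal.yaml
echocage noise bands --wav rec.wav --cal cal.yaml --f-min 20
echocage noise thd --wav rec.wav --cal cal.yaml --f0 50
```

A scene config is YAML with a `scene:` section (any `SceneConfig` field) and
an optional `reactions:` list (any `ReactionSpec` field); `echocage run`
accepts a combined run config or uses the built-in demo when `--config` is
omitted.

## Conventions

- The canonical vertical coordinate is range from the transducer face; depth
  below the surface is a reporting conversion (`range_to_depth`), clamped at
  the surface.
- Missing samples are the sentinel −999 dB; all metrics ignore them.
- Event windows are half-open `[start, start + duration)`.
- Positive trace tilt = range increasing away from the transducer = upward
  swimming for an up-looking beam.
- SPL level classes: background < 120 ≤ low < 140 ≤ medium < 150 ≤ high
  < 170 ≤ very_high (dB re 1 μPa).
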