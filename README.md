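# puwarn

Analysis pipeline for pressure-ulcer (PU) early warning from wearable sensor
streams: per-minute tissue SpO2 / heart-rate / skin-temperature records with
validity flags, plus 5-minute pressure-grid frames recorded at a predilection
site.  Because clinical recordings of this kind are not freely
redistributable, the package ships a first-class synthetic generator that
reproduces the statistical structure the analysis assumes, so every stage is
fully testable offline.

## Components

| module | purpose |
| --- | --- |
| `puwarn.simulate` | synthetic cohorts: AR(1) vital signs around group levels, scheduled pressure-load events coupled into skin temperature, burst invalidity, gaps, SpO2-decline episodes |
| `puwarn.preprocess` | timeline gridding, out-of-range deletion, capped forward fill, per-timestamp data-quality factor, quality-thresholded section segmentation |
| `puwarn.events` | Butterworth smoothing, z-scoring, prominence/width-filtered peak detection, −5…+55 min event windows, k-means duration clustering with elbow selection, spike-triggered averaging with Pearson/Spearman scores |
| `puwarn.predictor` | 1-h rolling SpO2 mean with a 90 % validity gate, expanding patient mean, their difference, warn/normal states at a −3-point threshold, alarm merging |
| `puwarn.cohort` | per-subject mean vitals, patient-vs-control and condition-stratified comparisons with Welch's unequal-variances t-test (α = 0.001) |
| `puwarn.foot` | 4×12 insole grids: weight normalization, forefoot/midfoot/rearfoot loads, shoe-group summaries |
| `puwarn.io` / `puwarn.pipeline` / `puwarn.cli` | CSV schemas, YAML run configuration, stage orchestration, umbrella CLI |

## CLI

Each stage is a subcommand; `run-all` chains them:

```bash
puwarn simulate --n-patients 5 --n-controls 2 --duration 1440 --seed 7 --out-dir out/raw
puwarn preprocess --in-dir out/raw --out-dir out/pre --ffill-max 5 \
    --quality-threshold 0.667 --min-section-length 60
puwarn events --in-dir out/pre --pressure-dir out/raw --out-dir out/events --k 2:6 --seed 7
puwarn predict --in-dir out/pre --out-dir out/pred --window 60 --min-valid-frac 0.9 \
    --thres -3 --merge-gap 60 --warmup 120
puwarn cohort --in-dir out/raw --out-dir out/cohort --stratify prior_pu_surgery
puwarn foot --in-dir insoles/ --out-dir out/foot \
    --region-map forefoot=1-5,midfoot=6-8,rearfoot=9-12
puwarn run-all --config run.yaml --seed 7 --out-dir out
```

Timestamps are ISO 8601 UTC, blanks are empty cells, validity flags are 0/1;
all CSV round-trips are lossless.  A `run.yaml` may set any top-level key of
`puwarn.io.RunConfig` plus nested `quality`, `bounds`, `smoothing`, `peaks`,
`predictor` and `foot` sections; unknown keys are rejected.

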