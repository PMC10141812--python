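# facepulse

Deception-cue analysis from facial-landmark and pulse-rate time series.

The package implements a complete per-session pipeline:

1. **io_formats** — read per-frame facial landmark tables (OpenFace 2.0 CSV
   dialect: 68 face points, 56 eye-model points, gaze angles, head rotation),
   1 Hz pulse CSVs, and JSON utterance annotations; align the pulse series to
   the video frame rate (step repeat by default, linear optional).
2. **facial_geometry** — per-frame geometric features: eyebrow tilt
   (least-squares slope), brow–eye distances, inter-brow area, eye areas
   (shoelace formula), eye/mouth aspect ratios, iris offsets, mouth areas,
   mouth-corner raise, mouth angle, plus pass-through gaze / head pose /
   pulse. Distances are normalized by the nasal-bridge length `L`, areas by
   `L²`, making every feature image-scale invariant.
3. **temporal_features** — centered rolling variances (±3 s for facial
   features, ±10 s for pulse), first-quartile closure thresholds over the
   whole session, and trailing-window (3 s) blink / mouth-closure episode
   counts.
4. **labeling** — per-frame binary labels: positive from 3 s before to 5 s
   after the onset of a deceptive utterance, everything else negative.
5. **preprocess** — drop rows with missing features, remove per-feature
   outliers (Tukey fences by default; a literal `[Q1, Q3]` band is available
   as `literal_quartile`), then randomly undersample the majority class to
   exact balance.
6. **model_eval** — random forest with stratified, shuffled 10-fold
   cross-validation (optionally grouped by utterance/time block to avoid
   temporal leakage), pooled confusion matrices, accuracy / precision /
   recall / F1, holdout evaluation without refitting, and normalized
   impurity-based feature-importance rankings.
7. **synth_data** — a seeded synthetic session generator (landmark CSV,
   pulse CSV, annotation JSON plus a ground-truth log) with configurable
   deception-window effects on blink rate, mouth area, gaze, and pulse
   variance, so the whole pipeline is testable without human-subject data.

## CLI

Everything is reachable through one entry point:

```sh
facepulse simulate  --out session/ --seed 1 --duration 180
facepulse extract   --landmarks session/landmarks.csv --pulse session/pulse.csv \
                    --annotations session/annotations.json --out features.csv
facepulse label     --features features.csv --annotations session/annotations.json \
                    --out labeled.csv
facepulse preprocess --labeled labeled.csv --seed 1 --out clean.csv
facepulse train     --data clean.csv --seed 1 --out model.joblib
facepulse evaluate  --model model.joblib --data clean.csv --out metrics.json
facepulse importance --model model.joblib --out-csv importance.csv --out-png importance.png
```

or as a single run (simulate-or-read → extract → label → preprocess →
10-fold CV → importance), driven by a YAML config with CLI overrides:

```sh
facepulse pipeline --config config.yaml --out run/ --seed 1 \
    --outlier-mode tukey --fold-mode frame
```

The run directory receives `metrics.json`, `preprocess_report.json`,
`importance.csv`, `importance.png` and a `manifest.json` embedding the
config hash, seeds and versions. Reruns with an unchanged config are
byte-identical except for the manifest timestamp.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact
reproduction of the published worked metric examples, property suites for
geometry / temporal features / labeling / preprocessing (each against an
independent oracle), signal-recovery and null-generator behavior of the full
pipeline on synthetic sessions, and end-to-end determinism.

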