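# tapkin

Video-derived finger-tapping kinematics and severity prediction.

`tapkin` turns per-frame hand-landmark time series (21-point MediaPipe
schema) into a thumb–index angular displacement signal, segments the tapping
cycles, computes 13 per-trial kinematic features related to bradykinesia, and
predicts an ordinal severity score (0–3) with one of three classification
schemes — a single multiclass model, an ordinal-binary decomposition, or a
tiered binary cascade (control vs patient → score 1 vs {2,3} → 2 vs 3) in
which each stage selects its own features.  It also ships the accompanying
group-difference statistics (KS normality screening, ANOVA / Welch ANOVA,
Tukey HSD with Bonferroni correction) and a synthetic-data generator that
produces realistic quasi-periodic tapping traces, matching landmark streams,
and labeled feature cohorts so the whole pipeline is testable without videos.

## Library overview

| module                    | contents |
|---------------------------|----------|
| `tapkin.pose_io`          | `LandmarkSequence`, `DisplacementSignal`, CSV/JSON readers and writers, detection-gap filling/splitting |
| `tapkin.kinematics`       | `compute_angle_signal` (thumb–index angle), `lowpass` (7 Hz zero-phase Butterworth), `segment_cycles` (alternating peak/valley taps) |
| `tapkin.features`         | `extract_features` (13 features: amplitude/speed/opening/closing means + CVs, cycle-duration mean/CV/range, rate, amplitude decay), `batch_extract` |
| `tapkin.severity_models`  | class balancing (under-sample to median + SMOTE-style oversampling), CV-driven recursive feature elimination, logistic models for the three schemes, JSON-serializable bundles, PR-AUC/f1/per-class-accuracy reports |
| `tapkin.group_stats`      | per-feature normality screening, (Welch) ANOVA, Tukey HSD post-hoc with significance stars |
| `tapkin.synth`            | `simulate_signal`, `signal_to_landmarks`, `simulate_cohort`, severity presets 0–3 |

```python
from tapkin import (simulate_signal, lowpass, segment_cycles,
                    extract_features, SEVERITY_PRESETS)

signal = simulate_signal(SEVERITY_PRESETS[2].params)
filtered = lowpass(signal)
features = extract_features(filtered, segment_cycles(filtered))
print(features.mean_amplitude, features.amplitude_decay)
```

## CLI

```sh
tapkin simulate --preset 2 --n 30 --seed 1 --out trial.csv
tapkin extract  --landmarks trial.csv --fps 30 --out features.csv
tapkin train    --features cohort.csv --scheme tiered --seed 1 --out bundle.json
tapkin predict  --bundle bundle.json --features new.csv --out pred.csv
tapkin stats    --features cohort.csv --group-col score --out report.json
tapkin report   --bundle bundle.json
tapkin run      --config cfg.yaml --set n_per_class=50 --seed 1   # full pipeline
```

Landmark CSV dialect: header `frame,x0,y0,z0,…,x20,y20,z20` (wrist = 0,
thumb tip = 4, index tip = 8); displacement CSV: `time_s,angle_deg`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(closed-form sinusoid features, landmark roundtrip, generator parameter
recovery, metric/routing oracles, end-to-end tiered classification,
no-leakage, statistics calibration, balancing geometry).

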