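# drivewave

EEG spectral biomarkers of driving-induced mental workload, and
classification of the driver's neurological state.

Driving imposes a cognitive load that shows up immediately in the scalp
EEG: relative to rest, delta and theta power rise while beta and gamma
fall, and delta-derived ratios collapse. `drivewave` implements the full
analysis chain for a three-condition driving-simulator protocol —
pre-task **resting**, high-workload **city-roadway** driving and
low-workload **expressway** driving — recorded from four dry electrodes
(Fp1, Fp2 frontal; O1, O2 occipital) at 1000 Hz:

1. **Synthesis** (`drivewave.synth`) — a state-conditioned generator of
   multichannel EEG whose per-epoch band composition follows calibrated
   per-state logistic-normal distributions, with per-subject random
   effects, optional eye-blink/EMG/60 Hz artifacts (with ground-truth
   clean copies and reference channels), and deterministic seeding.
2. **Preprocessing** (`drivewave.preprocess`) — 60 Hz notch,
   anti-aliased downsampling to 250 Hz, reference-guided FastICA artifact
   removal, zero-phase 0.5–44 Hz band-pass, 30 s settle-period trim and
   non-overlapping 10 s epochs.
3. **Spectral features** (`drivewave.spectra`) — Welch PSDs (Hamming,
   2 s segments, 50% overlap) and, per band δ 0.5–4, θ 4–8, α 8–13,
   β 13–30, γ 30–44 Hz: absolute/relative/mean power and the median,
   power-weighted mean, 90% spectral-edge and peak frequencies, with
   frontal/occipital/global channel aggregates.
4. **Biomarkers** (`drivewave.biomarkers`) — relative band power
   e_j = E_j / Σ E (0.5–44 Hz), per-subject resting baselines and
   baseline-relative changes Δe = (e − r̄)/r̄, frontal asymmetry
   (e_R − e_L)/(e_R + e_L), the delta–alpha ratio DAR = e_δ/e_α and
   delta–theta ratio DTR = e_δ/e_θ, assembled into the canonical
   149-column feature table.
5. **Statistics** (`drivewave.stats`) — per-state means with 95% CIs,
   paired t-tests on subject-level means, band-vs-band OLS regressions.
6. **Selection & classification** (`drivewave.select_train`) — one-way
   ANOVA-F feature importance (selected when 1 − p > 0.95), subject-wise
   train/test splits, inverse-frequency class weighting, and five model
   families (KNN k=3 with weighted votes, linear discriminant analysis,
   RBF-SVM, a gain-ratio/pessimistically-pruned tree and an
   ANOVA-split univariate tree) with stratified 10-fold CV, confusion
   matrices, ROC/AUC and Gini = 2·AUC − 1.

The intended audience is researchers in neuroergonomics and biosignal
processing who need a tested, reproducible reference pipeline for
band-power workload biomarkers — with a generator that provides ground
truth the real study cannot.

## Worked example

```python
from dataclasses import replace
from drivewave.synth import default_state_specs, synthesize_cohort
from drivewave.preprocess import preprocess, segment_epochs
from drivewave.spectra import extract_features
from drivewave.biomarkers import build_feature_table
from drivewave.select_train import (FTestSelector, class_weights,
                                    split_by_subject, train_classifier, evaluate)

# 8-subject cohort, reduced epoch counts, synthesized at the analysis rate
eps = {"resting": 3, "city_roadway": 12, "expressway": 12}
specs = {s: replace(sp, n_subjects=8, epochs_per_subject=eps[s])
         for s, sp in default_state_specs().items()}
rec = synthesize_cohort(specs, seed=1, fs=250.0)

table = build_feature_table(extract_features(segment_epochs(preprocess(rec))))
print(f"{table.shape[0]} epochs x {table.shape[1] - 3} features")

tidy = extract_features(segment_epochs(preprocess(rec)))
g = tidy[(tidy.channel == "global") & (tidy.band == "delta")]
print(g.groupby("state").rel_power.mean().round(3))
```

prints

```
216 epochs x 149 features
state
city_roadway    0.487
expressway      0.494
resting         0.389
```

— the recovered global delta relative power per state: driving raises
delta (≈0.49) over rest (≈0.39, pulled above its long-run mean of 0.344
by this particular 8-subject draw; at 17 subjects it recovers to within
±0.05). The global DAR per state comes out as ≈15.5 (resting) versus
≈4.1 (both driving states): delta-to-alpha dominance is a resting-state
signature, and collapses under load. Training an RBF-SVM on
ANOVA-selected features to separate rest from city driving,

```python
binary = table[table.state.isin(["resting", "city_roadway"])]
train, test = split_by_subject(binary, [f"S{i:02d}" for i in range(1, 7)],
                               ["S07", "S08"])
sel = FTestSelector().fit(train.drop(columns=["subject", "state", "epoch"]),
                          train["state"])
res = train_classifier("svm_rbf", sel.transform(train).to_numpy(float),
                       train["state"], class_weights(train["state"]),
                       cv_k=5, seed=1)
rep = evaluate(res.model, sel.transform(test).to_numpy(float),
               test["state"].to_numpy(), "svm_rbf")
```

yields `selected 49 features; cv accuracy 1.000; test accuracy 1.000;
AUC 1.000; Gini 1.000` — resting versus driving is near-perfectly
separable, while the two driving states are not (their band profiles
differ by at most 0.016 in relative power; expect ~0.55–0.75 accuracy).

## Command line

Every stage is also a `drivewave` subcommand driven by one YAML config:

```sh
drivewave simulate   --config cfg.yaml --out cohort.csv      # or .edf
drivewave preprocess --in cohort.csv --config cfg.yaml --out epochs.npz
drivewave features   --in epochs.npz --config cfg.yaml --out features.csv
drivewave biomarkers --in features.csv --out table.csv
drivewave stats      --in table.csv --out report/
drivewave train      --in table.csv --model svm_rbf --task multiclass --out report/
drivewave run        --config cfg.yaml --out run/             # all of the above
```

Artifacts carry a JSON sidecar with the package version, seed and config
hash; identical configs reproduce byte-identical feature tables.

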