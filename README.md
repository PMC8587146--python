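# fusionhar

Early-fusion human activity recognition from a wrist accelerometer and two
cardiac bio-signals.

`fusionhar` is for researchers studying whether bio-signals (ECG, PPG) add
recognition power to the inertial signal that dominates wearable HAR: it
implements the full comparison pipeline — multi-rate preprocessing,
windowed time/frequency feature extraction, correlation-based feature
selection, seven signal-fusion scenarios and random-forest evaluation in
both subject-specific and leave-one-subject-out (LOSO) setups — together
with a synthetic multi-subject cohort generator so every stage runs
offline, deterministically, with no data downloads.

## The analysis

Five activities (sitting, stairs, table soccer, cycling, walking) are
recognized from three channels: wrist 3D-ACC at 32 Hz, wrist PPG at 64 Hz,
chest ECG at 700 Hz. The ACC is up-sampled to 64 Hz by pairwise averaging
and all channels are cut into non-overlapping, label-pure 7 s windows.
Each window yields 7 time-domain and 8 frequency-domain features per
channel (75 columns). Features are standardized with train-only statistics,

    z_i = (f_i − μ) / σ,   0 ≤ i < m,

and pruned by correlation-based feature selection: of every feature pair
with |Spearman ρ| > 0.85 on the training rows, the member less correlated
with the activity labels is dropped. Seven fusion scenarios — ACC, ECG,
PPG, ACC+ECG, ACC+PPG, ECG+PPG, ACC+ECG+PPG — feed a random forest
(300 trees, depth 25), scored by support-weighted F1 and one-vs-rest AUC,
per subject (stratified 80/20 + 10-fold CV) and across subjects (LOSO).

The scientific question the scenarios answer: walking and stair climbing
have nearly identical wrist-motion signatures but very different heart
rates, so a cardiac channel should resolve exactly the confusion a pure
accelerometer model suffers — and ECG, being immune to motion artifacts,
should do so better than PPG. See `docs/methods.md` for conventions and
the generator's design.

## Worked example

```python
import fusionhar as fh

records = fh.simulate_cohort(10, seed=1)            # 10 subjects, 120 s/activity
feats   = fh.cohort_feature_matrix(records)         # 850 windows x 75 features
spec    = fh.ModelSpec(seed=1)                      # random forest, 300 trees

for sc in (1, 2, 3, 4):
    _, mean = fh.loso_eval(feats, sc, spec, seed=1)
    print(f"scenario {sc} ({'+'.join(fh.SCENARIOS[sc])}): "
          f"LOSO weighted F1 = {mean['weighted_f1']:.3f}")
```

prints

```
scenario 1 (ACC): LOSO weighted F1 = 0.859
scenario 2 (ECG): LOSO weighted F1 = 0.791
scenario 3 (PPG): LOSO weighted F1 = 0.528
scenario 4 (ACC+ECG): LOSO weighted F1 = 0.977
```

Read: the accelerometer alone is the strongest single signal (0.859) but
confuses walking with stairs across subjects; ECG alone is weaker (0.791)
and artifact-ridden PPG much weaker (0.528); fusing ECG with the
accelerometer resolves the walking/stairs ambiguity and lifts cross-subject
F1 to 0.977. The same experiment through the CLI:

```sh
fusionhar simulate --out cohort/
fusionhar features --in cohort/ --out features.csv
fusionhar evaluate --features features.csv --mode loso --scenarios 1-7 --out results.json
fusionhar report --results results.json --out report/
```

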