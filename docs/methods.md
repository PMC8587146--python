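# Methods

`fusionhar` implements a feature-level ("early") fusion pipeline for
recognizing five daily activities — sitting, ascending/descending stairs,
table soccer, outdoor cycling, walking — from three wearable signals: a
wrist triaxial accelerometer (3D-ACC, 32 Hz), a wrist photoplethysmogram
(PPG, 64 Hz) and a chest electrocardiogram (ECG, 700 Hz). This note
documents the model, the numerical conventions, the synthetic cohort the
package ships for offline testing, and the design choices made where the
design was genuinely open.

## Pipeline

**Up-sampling.** The 32 Hz accelerometer is brought to the PPG's 64 Hz by
pairwise averaging: originals are kept at even output indices and each odd
index `2i+1` receives `(x[i] + x[i+1]) / 2`. The last odd slot has no
successor pair and repeats the final sample — the simplest rule that
doubles the length while preserving the sample range. The ECG stays at its
native 700 Hz.

**Windowing.** Signals are cut into non-overlapping, label-pure windows of
7 s (configurable; a sweep utility covers 0.5–15 s). Tiling restarts at
every activity-interval boundary and tails shorter than the window are
discarded, so no window ever spans a label change; this purity-by-
construction replaces any window-label voting rule. Overlapping windows
are deliberately unsupported: adjacent windows of these signals are far
from i.i.d., and overlap inflates apparent performance. Window length in
samples is `round(window_seconds × rate_hz)` (448 at 64 Hz and 4900 at
700 Hz for 7 s); sweep sizes must give at least 8 samples per channel.

**Features.** Per channel per window, 7 time-domain statistics (mean, min,
max, median, population standard deviation, zero-crossing count, mean-
crossing count) and 8 frequency-domain features — 15 × 5 channels = 75
named columns `{signal}.{time|freq}.{feature}`. Conventions:

- Crossings use a single rule everywhere: strict sign changes between
  consecutive values, with a zero sample adopting the previous nonzero
  sign. They are reported as raw counts, not rates; at fixed window length
  the two differ by a constant factor, which is irrelevant downstream.
- The one-sided amplitude spectrum is normalized as `|X_0|/N` for DC and
  `2|X_k|/N` elsewhere (the Nyquist bin of an even-length window is not
  doubled), so the DC feature literally equals the window's time-domain
  mean. Windows are neither detrended nor tapered — the DC feature needs
  the raw mean, and gravity is signal, not nuisance.
- For accelerometer channels gravity makes DC the global spectral maximum,
  so the peak feature is the *second max* and the dominant frequency is
  the frequency of that bin. When DC happens not to be the global maximum
  the rule falls back to the true second-largest amplitude overall. For
  bio-signals (ECG, PPG) the peak feature is the plain global maximum.
- Spectral statistics (mean, min, std, median, mean-crossings) run over
  all bins including DC. Ties in any peak search resolve to the lowest
  frequency, making every feature deterministic.

**Standardization.** Per feature column, `z = (f − μ)/σ` with μ and the
population σ estimated from training rows only and applied unchanged to
test rows; constant columns (σ = 0) are flagged degenerate and map to
zero. Training/test separation is absolute: no statistic of any test row
ever enters a fitted parameter, and the test suite asserts this with
instrumented runs.

**Correlation-based selection (CFS).** All pairwise Spearman rank
correlations (average ranks on ties) are computed on the training rows;
every pair with |ρ| > 0.85 loses its member that is less relevant to the
target. Relevance is |Spearman| against the activity label coded as an
integer by the fixed alphabetical map (cycling=0, sitting=1, stairs=2,
table_soccer=3, walking=4); this ordinal coding is a pragmatic, documented
simplification — Spearman against an arbitrary class coding is not a
principled multiclass relevance measure, but it is deterministic and
monotone-invariant. Qualifying pairs are processed greedily from highest
|ρ| down (ties by column name), skipping pairs with an already-dropped
member; relevance ties drop the lexicographically later name. Selection is
fitted per training partition (per subject in the personal protocol, per
fold in LOSO) and applied to the corresponding test rows — fitting it once
globally would leak test information. Undefined correlations (degenerate
columns) are treated as zero.

**Scenarios and models.** Seven signal subsets are evaluated: ACC, ECG,
PPG alone; the three pairs; and all three together. Standardization and
selection run on the full 75-column training matrix, and the scenario
filter then projects the retained columns, so per-scenario feature sets
are nested inside one selection. The headline classifier is a random
forest with 300 trees of maximum depth 25 (remaining hyperparameters are
scikit-learn defaults, recorded in the run manifest); k-nearest-neighbours
(k = 5) and multinomial logistic regression (unit-strength ridge) sit
behind the same interface for the model-family comparison. k and the ridge
strength are this package's own defaults. Feature importance is the mean
decrease in impurity averaged over per-fold forests trained on a common
column set.

**Evaluation.** Two protocols:

- *Subject-specific*: per subject, a stratified, seeded 80/20 split;
  pipeline statistics fitted on the 80 %; stratified 10-fold CV scores on
  the training portion (folds degrade to the smallest class count with a
  warning) recorded as an overfitting diagnostic; the final model trains
  on the full 80 % and is scored on the 20 %. Both the CV mean and the
  hold-out scores are reported, clearly labeled, since either could be
  quoted as "the" personal-model number.
- *LOSO (leave-one-subject-out)*: for each held-out subject, everything is
  fitted on the remaining subjects' windows and scored on the held-out
  subject. Cohort numbers are plain means over subjects in both protocols.

Scores are support-weighted F1 and support-weighted one-vs-rest ROC AUC
(one-vs-rest is the documented multiclass choice); a class with no
positives or no negatives in a test set has undefined AUC and is excluded
from the weighted mean with a warning. Confusion matrices (true labels as
rows) are emitted per subject, and the scenario-1-vs-4 contrast pair is
the recommended diagnostic for the walking/stairs confusion.

Seed policy: one master seed; every split, fold, forest and simulated
subject receives a child seed derived from `SeedSequence([master, context…])`,
so a run is a pure function of its configuration. Evaluators sort rows
into a canonical (subject, window) order before fitting because forest
bootstrap sampling is positional; results are therefore invariant to how
input rows were stacked.

## Synthetic cohort

The generator emulates the structure of a multi-device daily-activities
recording campaign: ~14 subjects, multi-rate channels (32/64/700 Hz), an
activity-interval label track, class imbalance, activity-dependent motion
spectra and heart-rate signatures, and motion-corrupted PPG. Its defaults
define the package's study conditions; they are deliberately stylized:

- **ACC**: per activity, a constant 1 g gravity orientation vector (with a
  small per-subject placement perturbation) plus a fundamental sinusoid
  and one second harmonic (35 % amplitude) per axis, plus white noise.
  Fundamentals: walking 1.9 Hz, stairs 2.05 Hz, table soccer 2.8 Hz,
  cycling 1.2 Hz, sitting 0. Each subject carries a characteristic cadence
  multiplier (sd 4.5 %) per activity, so walking and stairs overlap across
  subjects — the designed accelerometer ambiguity.
- **ECG**: a train of Gaussian-shaped R peaks (σ = 20 ms) whose RR
  intervals jitter per beat around the activity's rate. Heart-rate means:
  sitting 65, table soccer 82, walking 95, cycling 108, stairs 120 bpm.
  A subject's rate is `65 + offset + (mean − 65)/fitness` with offset
  ~N(0, 4 bpm) and fitness lognormal (sd 0.10): fitter subjects respond
  less to exertion. Walking and stairs stay ≥ 20 bpm apart — the cue that
  fusion is designed to exploit. No P/T waves are modeled; the features
  only see rate and pulse statistics.
- **PPG**: a two-harmonic pulse wave at the same instantaneous heart rate
  (slowly varying control points every 5 s). Motion corrupts it three
  ways: a small deterministic tone proportional to instantaneous
  acceleration magnitude (gain 0.1 × coupling), dominant broadband noise
  whose amplitude saturates with motion intensity (tanh knee at 0.08 g rms,
  max sd 1.2 × coupling), and perfusion loss attenuating the pulse by
  `1/(1 + 12 × rms)`. At rest the PPG is a clean pulse; during any
  vigorous activity it is mostly scrambled — so PPG recognizes sitting
  well and little else, the designed "weakest signal" role.

Default cohort: 10 subjects, one 120 s bout per activity (the real
protocol's 2.5 h is scaled down for desk-scale runs; durations are
configurable). What passing tests on this cohort show is that the
*pipeline* recovers designed effects — bio-signal fusion resolving
motion-ambiguous activity pairs, ACC > ECG > PPG informativeness, personal
models beating cross-subject models. Because within-subject windows of the
stylized waveforms are highly self-similar, personal models saturate near
a weighted F1 of 1.0 for any accelerometer-containing scenario; the
subject-specific fusion *gain* is therefore compressed toward zero on
synthetic data, and the fusion benefit is best read from the LOSO
protocol. What passing tests cannot show is performance
on real recordings: real motion is nonstationary and aperiodic, real HR
drifts with time-on-task rather than switching per activity, real PPG
artifacts correlate with posture, and real class imbalance comes from
uneven bout durations rather than the generator's balanced protocol.

## Numerical and edge-case choices

- Population (ddof 0) standard deviation everywhere, consistent between
  the time features and the standardizer.
- A window too long for every label interval yields an empty window set,
  not an error; windows under 2 samples, spectra under 3 bins, single-class
  training labels, and mismatched columns raise `ValueError`.
- Text serialization uses 17 significant digits and round-trip float
  parsing, so write→read is bit-lossless; results JSON is sorted-key, and
  two runs with one config and seed are byte-identical.
- The feature matrix has 75 columns (5 channels × 15). One published
  description of this feature family quotes 77 without enumerating the
  extra two; the 75 enumerable features are implemented.

## Known limitations

- Spearman-vs-integer-coded-labels relevance depends on the alphabetical
  class order; a different coding could drop the other member of a
  correlated pair.
- MDI importance is biased toward high-cardinality features and is
  averaged over folds without variance reporting.
- The generator's per-activity constant heart rate ignores cardiac
  kinetics (onset/recovery lags), which would blur windows near activity
  boundaries in real data; label-pure windowing hides that effect here.
- No late/decision-level fusion, no deep sequence models, no HRV-parameter
  extraction — the scope is the hand-crafted-feature early-fusion design.
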