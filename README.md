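# painconn

Connectivity-based, subject-independent recognition of pain states from
multichannel fNIRS (functional near-infrared spectroscopy) recordings.

Pain has no reliable objective readout: clinical practice leans on
self-report, which fails for non-verbal or sedated patients.  Prefrontal
haemodynamics measured by fNIRS carry pain-related information, and
network-level *connectivity* between channels generalises across subjects
better than single-channel amplitudes.  `painconn` implements a complete,
reproducible pipeline for three-class pain decoding (No Pain / Low Pain /
High Pain) from 24-channel oxy- (HbO2) and deoxyhaemoglobin (HHb) signals
sampled at 50 Hz, evaluated strictly subject-independently.

The pipeline:

1. **Synthetic cohort** (`painconn.cohort`) — a generator that emulates the
   structure of a 65-participant pain study: interleaved HbO2/HHb columns,
   10 s stimuli, 40 s rests, a 6:12:12 initial class imbalance balanced
   from rest periods, two corrupted channels (19, 21), drift, cardiac and
   respiratory oscillations, motion spikes, and *planted* class-dependent
   directed couplings between channels so that recovery can be tested
   against ground truth.
2. **Preprocessing** (`painconn.preprocess`) — channel quality control via
   the coefficient of variation (CV = SD / mean |x|, faulty above the 95th
   percentile) with spatial interpolation of flagged channels; then, per
   channel: mean subtraction, 3-SD motion-artifact offset correction with a
   6 s local window, zero-phase 4th-order Butterworth band-pass
   (0.01–0.2 Hz), Daubechies-4 wavelet denoising with soft thresholding,
   and min–max scaling to [0, 1]; finally HbT = HbO2 + HHb and segmentation
   into 10 s labelled trials.
3. **Connectivity features** (`painconn.connectivity`) — per trial and
   haemodynamic modality, four 24×24 matrices:
   Pearson correlation `r_ij = cov(x_i, x_j)/(σ_i σ_j)`;
   partial correlation `ρ_ij = −P_ij/√(P_ii P_jj)` from the precision
   matrix `P = Σ⁻¹`; band-mean magnitude-squared coherence
   `C_ij(f) = |S_ij(f)|²/(S_ii(f) S_jj(f))`; and pairwise Granger causality
   `gc(j→i) = ln(RSS_restricted/RSS_full)` from lag-p autoregressions.
   The symmetric upper triangles plus all directed Granger entries give a
   named 1380-dimensional feature vector
   (3·24·23/2 + 24·23; names like `granger_ch05_to_ch20`).
4. **Evaluation** (`painconn.evaluation`) — leave-one-subject-out (LOSO)
   cross-validation with in-fold z-scoring, in-fold mutual-information
   feature ranking (k-NN estimator), and a sweep over the feature count k
   with SVM, KNN, Random Forest and XGBoost at library defaults.
5. **Reporting** (`painconn.reporting`) — per-class and macro metrics,
   cross-modality aggregation, accuracy-vs-k curves, fold-stability counts
   of top-ranked features, and a parsimony rule: the smallest k whose
   High-Pain recall stabilises at ≥ 50 % while accuracy and macro F1 stay
   within 1 percentage point of the full 1380-feature model.

## Worked example

```python
import painconn as pc
from painconn.evaluation import run_sweep
from painconn.reporting import summarise, stability_counts

cfg = pc.CohortConfig(n_subjects=5, effect_scale=3.0, seed=0)
trials = []
for session in pc.iter_sessions(cfg):
    trials.extend(pc.preprocess_and_segment(session, modalities=("hbo2",)))
table = pc.features_for_dataset(trials, "hbo2")
print("feature table:", table.shape)

sweep = run_sweep({"hbo2": table}, grid=[10, 100], classifiers=["rf"], seed=0)
print(summarise(sweep)[["classifier", "k", "accuracy_mean", "accuracy_sd",
                        "hp_recall_mean"]].round(1).to_string(index=False))
print(stability_counts(sweep).head(5).round(1).to_string(index=False))
```

Output:

```
feature table: (180, 1382)
classifier   k  accuracy_mean  accuracy_sd  hp_recall_mean
        rf  10           60.0          4.2            66.7
        rf 100           65.6          8.0            61.7
modality              feature  count  percentage
    hbo2      pcorr_ch05_ch10      5       100.0
    hbo2 granger_ch07_to_ch10      4        80.0
    hbo2        coh_ch17_ch24      3        60.0
    hbo2 granger_ch11_to_ch13      3        60.0
    hbo2 granger_ch22_to_ch13      3        60.0
```

Five subjects contribute 36 balanced trials each (180 rows, 1380 features
plus subject and label columns).  With a strong planted effect, Random
Forest at k = 100 reaches 65.6 % mean LOSO accuracy against a 33.3 %
chance level, and the features most often ranked in the MI top 10 across
folds include pairs carrying the planted couplings (7→10 appears both as a
directed Granger feature and through the partial correlation of an
involved channel pair) — the generator's ground truth is recovered by the
analysis stack.

A command-line interface mirrors the stages
(`painconn simulate | preprocess | features | sweep | report`); run
`painconn --help` for details.

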