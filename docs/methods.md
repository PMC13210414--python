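# Methods

This note documents the models, numerical choices and limitations behind
`painconn`, in the spirit of the methods documentation of packages such as
statsmodels or msprime.

## The decoding problem

The task is three-class, subject-independent classification of pain state
(No Pain / Low Pain / High Pain) from short windows of multichannel
prefrontal fNIRS signals.  Each subject contributes 12 balanced trials per
class; evaluation is leave-one-subject-out (LOSO), so every reported
metric measures generalisation to an unseen person.  Features are
inter-channel connectivity rather than channel amplitudes: three symmetric
functional measures (Pearson correlation, partial correlation, band-mean
coherence) and one directed effective measure (pairwise Granger
causality), vectorised into 1380 named features for 24 channels.

## Synthetic cohort model

Real recordings of this kind are not freely redistributable, so the
package ships a generator whose output has the statistical structure the
analysis assumes.  It is a test harness for the *method*, not a model of
neurovascular physiology.

**Latent signal.** Each channel follows an AR(2) process whose complex
pole pair (radius 0.99, angle 2π·0.06/50) concentrates spectral power
around 0.06 Hz — inside the canonical haemodynamic band — without any
post-hoc filtering.  Placing the band-limiting inside the autoregression,
rather than low-pass filtering a broadband VAR output, keeps the planted
lag-1 couplings exactly representable by a low-order VAR, which is what
the Granger estimator fits.  Class information enters through sparse
directed lag-1 couplings between channels ((7→10), (3→5), (14→16),
(6→13) by default) whose strength is monotone in pain intensity:
0.1 / 0.45 / 0.8 for NP / LP / HP, times a global `effect_scale`
(default 1).  The coupling graph is acyclic with one driver per target, so
(a) couplings of any strength cannot destabilise the VAR (the companion
matrix stays triangular under a topological ordering), and (b) no
"proxy" channel pair becomes mechanically class-dependent.  Planted
channels deliberately avoid the corrupted channels and their repair
neighbourhoods: channel repair overwrites corrupted channels with
neighbour means, which would either erase a planted coupling or
manufacture spurious class-dependent pairs.

**Nuisance structure.** On top of the unit-variance latent signal each
channel receives: a slow sinusoidal drift (amplitude 2, period 300–900 s,
plus a small linear trend), a cardiac oscillation (~1.1 Hz, amplitude
0.5), a respiratory oscillation (~0.25 Hz, amplitude 0.3), white noise
(SD 0.3), Poisson-placed rectangular motion spikes (1/min, 0.2–0.5 s,
4–8 channel SDs — guaranteed to exceed the 3-SD artifact threshold), and a
positive DC offset (HbO2 ≈ 100 ± 5, HHb ≈ 70 ± 5 arbitrary units).  The DC
offset matters: the quality-control statistic is CV = SD / mean |x|, which
is scale-free for zero-mean signals; realistic fNIRS signals ride on large
positive baselines, making CV sensitive to excess variance.  The two
corrupted channels (19, 21) receive large-amplitude white noise
(SD 10 on HbO2, 3 on HHb), which provably gives them the two largest CVs
in every session.  HHb is generated as −0.3 × HbO2 fluctuation plus
independent noise, reproducing the canonical anticorrelation so that
HbT = HbO2 + HHb is non-degenerate.

**Timing.** A session is: 6 pre-stimulus NP windows (60 s baseline), then
a per-subject random permutation of 12 LP and 12 HP stimuli, each 10 s
followed by a 40 s rest (1260 s, 63 000 samples at 50 Hz).  The 6 extra NP
windows that balance the classes are the final 10 s of the first 6 rest
periods that precede a further stimulation; the literature specifies only
that they come from rest periods, so the placement is this package's
choice.  Rest-period and baseline dynamics use the NP coupling level.

**Determinism.** One cohort seed drives everything; per-subject
generators are spawned as `default_rng([seed, 7919, subject_index])`, so
cohorts are bit-identical across runs and subjects are independent of how
many others are generated.

**What the generator does not emulate.** Optode geometry and light
transport, task-evoked haemodynamic response shapes, serially correlated
physiological noise, inter-subject variability in SNR, and non-stationary
artifacts.  Passing tests on this cohort therefore demonstrate that the
*pipeline* is correct and leak-free and that planted effects of known size
are recoverable — not that any particular accuracy is attainable on real
recordings.

## Preprocessing

Order: QC/repair → mean subtraction → artifact correction → band-pass →
wavelet denoising → min–max scaling → HbT.  QC runs on the raw session,
before the five steps.

* **QC and repair.** CV is computed per channel and modality; channels
  above the 95th percentile of the session's CV distribution are flagged
  (union over HbO2/HHb; an all-zero channel has undefined CV and is always
  flagged).  Flagged channels are replaced time-point-wise by the mean of
  their mapped spatial neighbours (19 ← {17, 18, 23}, 21 ← {20, 18, 22});
  a flagged channel without a map entry is an error rather than a silent
  drop, keeping the 24-channel network topology intact.
* **Artifact correction.** "Segments" are contiguous runs of samples
  deviating > 3 channel SDs from the channel mean, merged when separated
  by < 0.5 s.  The correction subtracts an offset so the run mean matches
  the mean of the surrounding 6 s window (run excluded, truncated at the
  record edges).  Offset subtraction is the least destructive reading of a
  windowed-mean correction: it preserves the within-run waveform.
* **Band-pass.** 4th-order Butterworth, 0.01–0.2 Hz, applied
  forward–backward (`sosfiltfilt`) for zero phase; the contract tested is
  the zero-lag property, not a particular padding recipe.
* **Wavelet denoising.** Multilevel `db4` decomposition (level 4, capped
  at the maximum valid level), soft thresholding of all detail levels with
  the universal threshold σ√(2 ln N), σ from the MAD of the finest detail
  level.  A zero threshold (noiseless input) leaves coefficients
  untouched.
* **Scaling.** Per-channel min–max to [0, 1]; constant channels map to the
  interval midpoint.  HbT is computed *after* scaling and is not rescaled,
  so its range is [0, 2].

## Connectivity estimators

* **Partial correlation** uses the sample covariance plus a ridge
  δ·tr(Σ)/n on the diagonal (δ = 1e−6 by default; δ = 0 reproduces the
  textbook precision-matrix formula exactly and is verified against a
  residualisation brute force at 1e−8).
* **Coherence** is Welch-estimated (Hann taper, 128-sample segments, 50 %
  overlap) and scalarised as the mean of C_ij(f) over bins in
  0.01–0.2 Hz.  At the default trial length (500 samples at 50 Hz) the
  Welch resolution is 0.39 Hz and no non-DC bin falls inside that band; in
  that case the lowest non-DC bin is used.  Fewer than two segments is an
  error (single-segment coherence is identically 1).
* **Granger causality** is pairwise-bivariate: restricted model = p own
  lags + intercept, full model adds p lags of the source, statistic
  ln(RSS_r/RSS_f) clipped at 0, with p = 2 by default.  A fully
  conditional 24-variable MVAR on 500 samples would be ill-posed at
  moderate lag order, and a continuous magnitude (rather than a p-value)
  is what mutual-information ranking needs.  Zero-phase filtering in
  preprocessing is non-causal and is known to attenuate and partially
  symmetrise Granger estimates; the direction-recovery guarantees are
  therefore stated (and tested) on unfiltered VAR data, while
  class-dependence of the statistic survives the full pipeline.
* All four measures are invariant to per-channel affine rescaling, so the
  min–max scaling step cannot distort them.

Vectorisation is row-major upper triangle for the symmetric measures and
row-major over (source, target) for Granger, with 1-based, zero-padded
channel names (`corr_ch01_ch02`, `granger_ch05_to_ch20`).  The directed
feature for source A → target B reads matrix entry `gc[B, A]`.

## Evaluation

Standardisation uses the training fold's mean and *population* SD
(divisor n); features constant in training map to exactly 0 in both train
and test.  Mutual information uses scikit-learn's k-NN estimator
(3 neighbours) with the fold's derived seed; ties break by canonical
feature order via a stable sort.  The ranking is computed once per
(modality, fold) and prefixed for every k — mathematically identical to
selecting per k.  Classifiers run at library defaults with pinned seeds:
SVC, KNeighborsClassifier, RandomForestClassifier, XGBClassifier (any
gradient-boosted tree implementation satisfies the "XGBoost" role; the
name is recorded in outputs).  Class encoding is ordinal: NP = 0, LP = 1,
HP = 2.  Per-(modality, fold, classifier) sub-seeds derive from the master
seed through `numpy.random.SeedSequence`, so the entire sweep is
bit-reproducible.

## Reporting conventions

Accuracy is trace/total of the 3×3 confusion matrix (equal to the binary
accuracy formula under micro-pooled one-vs-rest reduction up to the affine
map (100 + 2·acc)/3); precision/recall/F1 are one-vs-rest per class with
0/0 → 0, macro-averaged.  Fold summaries use the sample SD (n−1); the
three-modality aggregation also uses the sample SD.  The aggregation picks,
per modality and k, the classifier with the best mean accuracy (ties break
by the order svm, knn, rf, xgboost and are logged).  "Stabilises at or
above 50 %" in the parsimony rule is operationalised as: the HP-recall
condition holds at k and at every larger grid value.  If no k passes, the
decision object says so explicitly instead of raising.  Exported tables
round to one decimal; data files keep full precision.

## Problem sizes used in the shipped checks

Structural counts run at the full study geometry (65 subjects, 24
channels, 50 Hz).  Statistical properties run at reduced geometry chosen
to keep the whole suite quick while leaving comfortable margins: oracle
equivalence on 50 random 6-channel instances; direction recovery on 100
bivariate VAR(1) replicates of 500 samples; leakage on a 10-subject
mini-sweep; end-to-end recovery on 15 subjects with `effect_scale = 3`
(HP coupling 2.4, comparable to the diagonal AR coefficient — a strongly
planted effect) at k = 100 with Random Forest.

## Known limitations

* Pairwise (not conditional) Granger causality can attribute shared-input
  effects to direct edges.
* The coherence scalar at 10 s trial length reflects a single Welch bin
  near 0.39 Hz rather than a true in-band average; longer windows restore
  the intended band mean.
* The generator's class effect enters only through second-order structure
  (couplings); real pain responses also change means and waveform shapes.
* Accuracies obtained on the synthetic cohort are properties of the
  generator's effect size and are not comparable to results on real
  recordings.
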