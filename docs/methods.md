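# Methods

This note documents the models, defaults and numerical choices behind
`ecglvh`, and what the synthetic testbed does and does not show about real
recordings.

## Synthetic 12-lead generator

Each beat on each lead is a sum of five Gaussian-shaped waves (P, Q, R, S,
T). The T wave is asymmetric by default (ascending half-width 60 ms,
descending 45 ms); all other waves are symmetric. Timing relative to the R
peak is shared across leads (P −170 ms, Q −40 ms, S +40 ms, T +300 ms);
amplitudes follow population-typical per-lead values (e.g. R: 1.0 mV in II,
1.5 mV in V5, −0.6 mV in aVR; S: −0.9 mV in V1). Records default to 10 s at
500 Hz and 60 bpm.

Wave onsets and offsets are *defined* at the point where the wave reaches
1% of its peak amplitude — for a Gaussian of half-width w that is
±w·√(2·ln 100) ≈ ±3.03 w from the centre. This gives a reproducible,
threshold-stated analytic ground truth for every landmark.

**LVH class.** The `lvh` class applies the voltage/strain pattern that the
clinical criteria target: +0.8 mV on R in V5, V6, I and aVL; −0.8 mV on S
in V1 and V2 (deeper); T amplitude sign flip in V5/V6; and a 20 ms wider
QRS. The widening is implemented by shifting the Q centre 10 ms earlier and
the S centre 10 ms later rather than broadening the waves: the
onset-to-offset duration grows by exactly 20 ms while wave shapes, overlaps
and therefore the analytic ground truth stay clean. (Broadening the
Gaussians instead buries the small Q under the R upstroke and detaches the
composite-signal extrema from the per-wave centres.)

**Stochastic terms.** Four independent, seedable sources:

| term | default | emulates |
| --- | --- | --- |
| additive white noise | 0.02 mV sd | measurement noise |
| RR jitter | 0.01 s sd per interval | sinus variability |
| per-record amplitude scale | lognormal, σ = 0.25 | between-subject voltage variability (body habitus, electrode placement) |
| per-lead/wave amplitude jitter | multiplicative, sd 0.10 | electrode-level variation |

The between-record amplitude variability matters: without it every record
of a class is identical up to noise, classifiers separate the classes
trivially, and each voltage criterion fires on all or none of a class.
A ~25% voltage coefficient of variation is typical of adult cohorts and
reproduces the clinically observed behaviour that individual voltage
criteria are specific but insensitive, while their "any-of" combination
gains sensitivity. Amplitude randomization multiplies amplitudes only;
timing, widths and signs are untouched, so fiducial ground truth is exact
under any variability setting.

**What the generator does not emulate:** baseline wander is off by default
(a sinusoidal term is available), and there are no ectopic beats, conduction
abnormalities, alternative LVH phenotypes, muscle artifact or powerline
interference. Passing tests on synthetic cohorts therefore demonstrate the
pipeline's correctness and its behaviour under the configured class
contrast — not clinical performance, which depends on real morphological
diversity. The generator's configured contrast (in particular the
deterministic lateral T inversion and QRS widening) makes the two classes
nearly separable for a multivariate classifier; held-out AUCs near 1.0 are
a property of those conditions.

## Delineation

R peaks are detected on lead II: band-pass 5–18 Hz, differentiate, square,
150 ms moving-window integration, adaptive threshold (20% of the 90th
percentile of candidate peak heights), 200 ms refractory period, then
refinement to the extremum of the raw signal. The squared transform makes
detection polarity-invariant.

Lead II's R indices anchor the per-lead searches. Per lead and beat:

* R is the anchor-proximal local extremum of |signal − baseline| within
  ±40 ms (proximity, not amplitude, decides — in rS leads like V1 the deep
  S must not capture the R label);
* Q and S are opposite-polarity extrema within ±80 ms before/after R;
* QRS onset and J point are found by walking outward from Q/S until the
  signal *stays* within a tolerance band of the baseline for 3 consecutive
  samples — the persistence requirement walks through brief notches between
  overlapping waves instead of mistaking them for baseline;
* P peak is the extremum in [R−300, R−100] ms; T peak the
  largest-|amplitude| extremum in [J+80, J+420] ms (sign preserved, so an
  inverted T has a negative amplitude);
* onsets/offsets use the same 1%-of-peak rule as the generator, with a
  noise floor of 1.5× the robust noise estimate (1.4826 × MAD of the
  Savitzky-Golay smoothing residual).

The isoelectric reference per lead is the median over windows 320–240 ms
before each R (between the previous T offset and the P onset at usual
rates); the whole-signal median is biased by wave tails and is not used.
The per-beat baseline for amplitude measurement is the median of the 40 ms
PR-segment window ending 20 ms before QRS onset. Waves whose amplitude
stays below 0.025 mV are flagged absent, never fabricated. A landmark set
violating temporal order is pruned (optional landmarks dropped first);
beats whose search windows cross the record edge are skipped.

On zero-noise synthetic cohorts of both classes, 100% of landmarks are
recovered within 2 samples (4 ms at 500 Hz) of the analytic truth — the
suite asserts ≥ 99%.

**Templates and QC.** Beats are aligned on R over a window from the median
QRS onset − 150 ms to the median T offset + 50 ms. Beats with Pearson
correlation to the per-lead median beat below `min_corr` (default 0.90) are
dropped; if fewer than `min_beats` (default 5) remain on any lead the
record is excluded with a reason code. These two thresholds are declared
defaults, not literature values, and are configurable.

## Morphological features

Amplitudes are measured per beat relative to the beat baseline and
aggregated by the median; ratios use the median amplitudes with
|denominator| < 0.01 mV treated as missing. Interval endpoint definitions
(conventional readings of the names, configurable): PR = P_on→QRS_on,
PS = P_on→S, PT = P_on→T_off, QT = QRS_on→T_off, QRS = QRS_on→J,
RS = R→S, ToT = T_on→T_peak, TTe = T_peak→T_off. T slopes are two-point
secants (onset→peak, peak→offset) in mV/s — deterministic and faithful to
how the quantity is read off a trace; a regression slope would depend on a
window choice. The negative-QRS percentage is the per-beat fraction of
samples in [QRS_on, J) strictly below baseline, ×100, median-aggregated.
Missing landmarks propagate to missing features, never zeros.

## Hermite decomposition

The averaged QRS (window QRS_on − 20 ms to J + 20 ms, baseline-subtracted,
time axis centred on R) is fit by least squares on the first N_q = 4
orthonormal Hermite functions

φᵢ(t) = (σ 2ⁱ i! √π)^(−1/2) Hᵢ(t/σ) e^(−t²/2σ²),

with Hᵢ the physicists' Hermite polynomials. The basis carries the
continuous-time normalization, so its quadrature-weighted Gram matrix on a
±6σ grid is the identity to ~1e−12 and the dilation identity
φᵢ^{2σ}(2t)·√2 = φᵢ^{σ}(t) holds exactly. The time scale σ is chosen per
fit by a grid search over {duration/k : k = 4…10}, keeping the smallest
RMSE; σ is stored on the fit so coefficients remain interpretable. Whether
to fix σ globally or adapt it per lead was an open design choice; the
per-fit search is the least arbitrary and is fully recorded. RMSE is
reported in µV over the fitted window. An all-zero window returns zero
coefficients and zero RMSE.

## V-index

T-wave segments (template T_on − 10 ms to T_off + 10 ms, baseline-
corrected) from the 8 linearly independent leads (I, II, V1–V6) are
resampled onto a common grid and stacked as rows of Ψ. The augmented limb
leads are linear combinations of the others and would bias the cross-lead
dispersions, so they are excluded by default (configurable). The dominant
T-wave T_d is the leading right singular vector of Ψ (unit norm, sign set
by positive correlation with the mean row). Each row is regressed on
[T_d, Ṫ_d]; the index is

v_index = std[w₂] / std[w₁] (reported in ms),

the cross-lead dispersion of the lag coefficients normalized by that of the
gains — the standard second-order dominant-T-wave estimate of
repolarization-time dispersion. It is non-negative, invariant to global
rescaling of Ψ, and undefined (missing, logged) when std[w₁] = 0.

Numerical choice: Ṫ_d is computed by Savitzky-Golay differentiation
(30 ms window, cubic), and the regression uses a smoothed copy of T_d.
Finite differences amplify the high-frequency part of the SVD estimation
noise by a factor of order f_s, which leaks gain variance into the lag
coefficients and inflates the index; with the local-polynomial derivative
the 30 ms model-recovery error stays below 5% median at 5% additive noise
(the suite asserts ≤ 10%). One index is computed per record from the
templates; beat-to-beat index trends are out of scope.

## Clinical criteria

All 22 rules are evaluated exactly as codified, on amplitude *magnitudes*
in mm at 10 mm/mV — thresholds are positive voltage sums, and under the
magnitude convention the Lewis formula reproduces the classical
(R_I + S_III) − (R_III + S_I) index. Strict inequality: a value exactly at
threshold is negative. "Any lead" clauses take the maximum over the named
options; "total 12-lead voltage" is Σ(|R| + |S|) over all leads; the two
voltage-duration products multiply by the QRS duration in ms against their
printed 2436 threshold. Two of the printed rules are knowingly unusual and
implemented as printed: the first Gubner rule subtracts |S(III)| where the
classical index adds it, and the second product rule shares the 2436
threshold with the first although it applies to the much larger total
12-lead voltage (making it positive for nearly all records). A missing
operand makes the criterion missing (not negative); combinations treat
missing members as negative votes.

## Classification

* **Labels**: `lvh` (positive) vs `control`; string or 0/1 accepted.
* **SFFS**: forward steps add the feature maximizing the mean AUC over
  `n_repeats` = 5 stratified 70/30 Monte-Carlo splits; floating backward
  steps remove features while removal strictly improves on the best AUC
  recorded for the smaller size; hard cap `max_features` = 30; the selected
  subset is the best visited. Constant columns are never candidates. All
  split seeds are recorded in the trace, so any run is reproducible.
* **Training**: stratified k = 10 folds; the majority class of each fold's
  training part is downsampled independently (all minority rows kept, an
  equal-size uniform majority subset); out-of-fold probability scores are
  pooled; the threshold θ̂ minimizes FPR² + (1 − TPR)² over the pooled
  out-of-fold ROC (candidates are midpoints of consecutive distinct scores
  plus sentinels; objective ties break toward the higher-specificity cut).
  Choosing θ̂ on pooled out-of-fold scores rather than the training fit is
  deliberate — it is the less optimistic of the two readings. The final
  learner refits on the full balanced data.
* **Learners**: logistic regression (L2, default strength), random forest
  with 150 trees, RBF SVM with logistic (Platt) score calibration fit on
  the training data — a monotone map to (0, 1) that leaves the ROC and the
  threshold geometry unchanged. Features are median-imputed; logreg/SVM
  inputs are standardized with training-part statistics only.
* **Ensemble**: `n_models` = 100 members by default (the acceptance-scale
  runs use 10 for speed), each a full re-run of the fold-balanced CV
  training with a derived seed, so members differ in their downsampling
  draws. Prediction is the majority of the members' thresholded votes; an
  exact tie returns the first member's vote, which is why member order is
  fixed and persisted.
* **Metrics**: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy,
  balanced accuracy (mean of the first two), and rank-statistic AUC.

## Degenerate inputs and edge rules

Flat signals raise a no-beats error; all-zero T-wave ensembles and
collinear regressors raise degenerate-ensemble errors; single-class label
vectors are rejected wherever a contrast is required; QC exclusion is a
reported outcome, not an exception. Seeds derived from a master seed stay
below 2³¹.

## Problem sizes used in the shipped runs

The test suite and `scripts/acceptance.py` use 200 + 200 training and
100 + 100 validation records with 10-member ensembles, 200 replicates for
the V-index recovery study, 100 instances for the threshold oracle, and
50/20 datasets for the SFFS checks — sizes at which every stochastic check
is stable across seeds while the full suite stays comfortably fast on a
single CPU.

## Known limitations

* The delineator is intentionally simple (single-lead anchoring, extremum +
  baseline-return rules); it has no notch/fragmentation handling and is not
  a clinical-grade delineator. External fiducials can be substituted via
  the CSV interface.
* Hermite fitting assumes the averaged QRS is well-centred on R; heavily
  fragmented complexes will show large RMSE (which is itself an informative
  feature).
* The V-index here is template-based and per-record; time-varying
  estimation is out of scope.
* Synthetic results quantify pipeline correctness under configured
  conditions, not clinical accuracy.
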