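# Methods

`wristhar` implements a two-phase pipeline for recognizing physical
activities (PA) from a single wrist-worn tri-axial accelerometer sampled at
100 Hz: a supervised laboratory phase that models each of 24 activity
classes in a low-dimensional wavelet feature space, and an unsupervised
free-living phase that discovers a session's activity structure and
identifies it against the laboratory models. This note records the model,
its assumptions, the tunable parameters, and the numerical and design
choices behind the implementation.

## Signals and windows

Recordings carry the three axis signals X, Y, Z in g plus the resultant
R = sqrt(X² + Y² + Z²), a rotation-invariant magnitude channel that removes
dependence on wrist orientation. All analysis operates on non-overlapping
10 s windows (1000 samples). Labels are half-open intervals `[start, end)`
of 1-based class ids; windows are tiled from each labeled interval's start
so a kept window never straddles an activity transition, and windows inside
unobserved stretches (class id −1) or partial windows at interval edges are
discarded. How edge windows were handled in the original protocol is not
recoverable; discarding is this package's choice.

## Feature space

The discriminative core is the "modified" wavelet coefficient feature:

1. a 3-level orthonormal Haar decomposition of the window's R signal
   (periodized filter bank; PyWavelets backend) gives 1000 coefficients
   ordered [A3 (125), D3 (125), D2 (250), D1 (500)], energy-preserving and
   exactly invertible;
2. for every coefficient position, the Kolmogorov–Smirnov distance between
   the within-class empirical distribution and a Gaussian with matched mean
   and variance, D = sup_x |F_n(x) − G(x)|, is computed per class; a
   position is scored by its **maximum** D across classes, so a coefficient
   strongly multimodal for *any single* activity is retained;
3. the 20 top-scoring positions (ties to the lower index) form the
   selector, shared by both pipeline phases;
4. a PCA fitted on the selected 20 coefficients of the training windows
   defines the classification space: its first 10 components for
   supervised model selection, the first 6 for the free-living phase (the
   dimensionality found best in the laboratory study design this package
   follows).

The intuition for step 2: an oscillatory signal's wavelet coefficient,
marginalized over gait phase, has a bimodal (arcsine-like) distribution,
while noise positions are near-Gaussian; deviation from normality is
therefore a signature of structured movement.

A full 130-name feature registry (time-domain moments and robust
statistics, sub-5 Hz spectral summaries, per-signal window-PCA scores, the
20 selected wavelet coefficients, subband energies, axis correlations,
jerk) is exposed for sequential forward selection. Only the wavelet-PCA
features feed classification; the registry's exact tail composition is
documented in `features.feature_registry` and versioned with the package.

## Classifiers

Each class is a full-covariance Gaussian mixture (2 components by default;
the per-class window counts in realistic protocols do not support more)
fitted by EM initialized with Linde–Buzo–Gray splitting k-means: starting
from the global mean, centroids are split by ±ε perturbation
(ε = 0.01 × per-dimension SD) and refined by Lloyd iterations; when a full
doubling would overshoot k, only the highest-distortion centroids split.
EM uses log-domain responsibilities, asserts a non-decreasing
log-likelihood every iteration, stops at relative improvement < 1e-6 or
200 iterations, and floors covariance eigenvalues at 1e-6 to keep
densities proper on near-degenerate windows.

Two classifiers share the per-class mixtures:

- **GMM** (static): per-window MAP class, log prior + mixture log-density,
  ties to the lower class id;
- **HMM** (dynamic): one hidden state per class, the class mixture as the
  emission density, transitions estimated from training label sequences by
  add-one-smoothed bigram counts, decoded with log-domain Viterbi (ties at
  each maximization resolve to the lower state id). The HMM exploits the
  temporal persistence of activities and dominates the GMM on non-stationary
  classes in our experiments, mirroring the phenomenon that motivates
  dynamic models in this field.

## Merging and evaluation

A single wrist sensor cannot separate some activity pairs (e.g. walking
variants differing only in the dominant hand's load). Specificity is
measured by a two-level scheme: after level-1 classification, any actual
class whose windows are predicted strictly more than 50% as one other class
is merged with it (union-find; transitively closed; the rule is re-applied
to the collapsed confusion matrix until a fixed point, so the merge map is
idempotent). The classifier is then refitted on the merged labels and the
final confusion matrix reported.

Two accuracy conventions are exposed deliberately:

- `mean_accuracy` — mean per-actual-class recall (trace of the
  column-normalized matrix), class-weighted and comparable across class
  counts; the headline metric;
- `overall_accuracy` — window-weighted trace/total; this is the quantity
  provably non-decreasing under *any* merge on fixed predictions (merging
  only moves off-diagonal mass onto the diagonal), so the merge-convergence
  diagnostic — greedily merging the most-confused pair and recording
  accuracy until one class remains — is defined on it. Mean per-class
  recall is not monotone under merges when class supports are unequal,
  which is why the two are kept distinct.

Model selection evaluates every (classifier kind, dimension) pair over
2-D..10-D leading-PC subspaces and ranks by mean accuracy, then by more
final classes (higher specificity), then by smaller dimension.

## Free-living phase

A free-living session is an unlabeled window sequence in the 6-D feature
space. The number of distinct activities K is estimated by fitting
LBG+EM mixtures over K = 1..8 and minimizing BIC; the raw maximized
log-likelihood is recorded per K but is monotone in K and cannot itself
select a finite model, so the penalized criterion is the operative choice.
Cluster assignments are temporally smoothed by an HMM whose states are the
K mixture components (transitions from hard assignments, add-one smoothed)
and decoded with Viterbi. Each cluster is then matched to the laboratory
class whose mixture means are nearest in Euclidean distance (minimum over
component-mean pairs; ties to the lower class id; several clusters may
match one class), by default with one Gaussian per cluster. Matched classes
carry MET values from the activity dictionary, banded as light (< 3.0),
moderate (3.0–5.9) and vigorous (≥ 6.0) and coded 1/2/3 on the timeline;
session summaries report percent of observed time per class and band.
Agreement with observed intensity is quantified by Pearson correlation of
the per-window codes (Spearman available); observed activity-type labels
map to codes as sitting/reclining/standing/squatting → 1, walking → 2,
jogging → 3, following the same Compendium bands.

## Synthetic data generator

No public dataset accompanies the 24-activity pool, so the generator
emulates its structure: each axis is a static gravity projection plus a
harmonic series at a class-specific fundamental (walking ≈ 1.1–2.0 Hz,
running ≈ 2.5–2.9 Hz, amplitudes growing with MET) plus white Gaussian
noise, with a shared random-walk phase drift (0.5 rad/√s) across harmonics
and axes. The drift matters: strictly phase-locked sinusoids make every
window of a bout identical in coefficient space, so nothing generalizes
across bouts, whereas drifting phase produces the phase-averaged,
multimodal within-class coefficient distributions the KS selector is
designed to detect. Stationary profiles differ in micro-movement noise
(seated laundry 0.02 g < brushing 0.03 < fidgeting 0.035 < driving
vibration 0.055); with resultant-only features, postures with equal
|gravity| are otherwise mathematically indistinguishable. Scripted sessions
concatenate labeled bouts, including ~8% "unobserved" gaps that carry
signal but no label, and default free-living scripts are majority
stationary with ≤10% ambulatory time.

What the generator does **not** model: sensor drift and calibration error,
non-wear, biomechanical coupling between axes beyond a fixed amplitude
ratio, inter-participant anthropometric variation, and activity
transitions inside a bout. Passing tests therefore demonstrate the
pipeline's correctness and its behavior under controlled class geometry,
not field performance on real wrist data.

## Problem sizes and test design

The verification suite runs the laboratory phase at 6 classes (two
stationary, three walking-like of which one pair is an exact duplicate,
one running-like), 120 train + 120 test windows per class split across six
bouts per class emulating different participants — small enough to run in
seconds, large enough that the duplicated pair reliably triggers the merge
rule while distinct classes stay separate. Free-living checks draw
block-structured sessions of ~1500–2800 windows (the 6–8 h regime) directly
from a synthetic bank of unit-covariance Gaussians placed 5σ apart; at much
smaller session sizes BIC with full 6-D covariances genuinely under-detects
K (the penalty outweighs the likelihood gain), which is a property of the
criterion, not of this implementation. Oracles are independent
constructions: a hand-written filter-bank recursion for the Haar transform,
brute-force sup-evaluation for the KS statistic, exhaustive path
enumeration for Viterbi, eigendecomposition for PCA, and
sklearn/hmmlearn fits as external cross-checks of EM and decoding.

## Known limitations

- Matching clusters by mixture-mean distance assumes class identity is
  encoded in feature-space location; classes distinguished mainly by
  covariance (e.g. two postures with equal mean R but different movement
  variance) can mis-match. The laboratory phase's classifiers do use the
  covariances; only the free-living matching step reduces to means.
- One shared 20-coefficient selector serves all classes; per-class
  selectors are a plausible alternative the original description leaves
  open.
- The HMM's states-as-classes topology is the standard reading; sub-states
  per activity or re-estimated emissions are not implemented.
- Pearson correlation on ordinal 1/2/3 intensity codes is the default
  convention here; Spearman is available where the ordinal reading is
  preferred.
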