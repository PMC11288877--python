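# Methods

`errpsim` studies whether a single-trial error-related-potential (ErrP)
decoder can be trained entirely on simulated EEG subjects and transferred to
unseen subjects without calibration. It couples a forward-model ERP
simulator with the standard ErrP decoding pipeline (windowed-mean temporal
features, class-weighted RBF SVM) and a statistical evaluation suite. This
note documents the model, its assumptions, the parameters that matter, and
the choices made where the design was genuinely open.

## Forward model

Scalp EEG is generated by the linear forward model `x(t) = G s(t)`, where
`G` is a lead field mapping dipolar source moments to electrode potentials.
The default head model is an analytic three-shell concentric-sphere
conductor — brain/skull/scalp radii 80/85/92 mm, conductivities in the
classical ratio 1 : 1/80 : 1. For each spherical-harmonic order the radial
boundary-value problem (potential and radial-current continuity at the two
interfaces, insulating scalp surface) is solved exactly as a 5x5 linear
system; the series is truncated at order 60. Sources are sampled uniformly
inside 92% of the brain-shell radius, which keeps the series tail below
~1e-5 relative. Two internal cross-checks pin the solution down: with equal
conductivities the per-order transfer coefficients reduce to the textbook
closed form (2n+1)/n, and the order-60 truncation agrees with an order-200
evaluation to well under 1% on random dipoles.

Electrode positions come from mne's bundled standard montages (BioSemi-64
by default), projected radially onto the scalp sphere. Externally computed
lead fields (e.g. an export of a realistic BEM model) can be supplied via a
documented HDF5 container (`/gains`, `/source_pos_mm`, `/orientations`,
`/channel_labels`, `/channel_pos_mm`).

Each source's gain column is rescaled so that its best-channel gain along
the default (radial) orientation is 1. Source amplitudes in microvolt are
then directly interpretable as best-channel scalp amplitude, which gives
the ERP component amplitudes below a concrete meaning under a head model
whose absolute gain scale is otherwise arbitrary.

## ERP classes

Conditions are peak mixtures. The error condition is a P200-N250-P320-N450
complex: peaks at 200/250/320/450 ms with source amplitudes +20/-40/+50/-40
uV and widths 50/50/120/150 ms, every peak generated on every trial. The
correct condition is a slow double positivity (270 ms / +20 uV / 200 ms and
350 ms / +10 uV / 250 ms) plus the same late negativity (450 ms / -40 uV /
150 ms); the two positive peaks' generation probabilities are drawn once
per subject, uniform on [0, 1], modelling how inconsistently these peaks
are reported across studies.

Peaks render as Gaussian pulses with sigma = width/6 (the stated width
spans +-3 sigma). Per trial, latency, width and amplitude each deviate by
up to 20% of their value, drawn from a zero-mean truncated normal with
sd = bound/3 capped at the bound — the stated deviation is the maximum, not
the standard deviation. A trial's components share no waveform: each
projects through its own dipole.

## Inter-subject variability

Five mechanisms make simulated subjects individual, and they are what makes
cross-subject transfer non-trivial:

1. **Whole-ERP latency shift.** One shift per subject, truncated normal
   with bound +-100 ms (sd 33 ms), shared by both conditions. The subject's
   ERP keeps its shape but is displaced in time. This is deliberately a
   subject-level (not trial-level) quantity: a per-trial shift of this size
   flattens every component out of the average and makes all simulated
   subjects temporally interchangeable, which collapses the
   subject-specific/generic/LOSO distinction entirely. A per-trial mode
   remains available (`shift_mode="trial"`).
2. **Source jitter.** Each component's dipole is re-drawn per subject,
   uniformly among sources within 10 mm of the component's nominal center.
3. **Orientation deviation.** Each component has one reference orientation,
   solved once from the gain tensor as the direction maximising the gain at
   Cz at the nominal center (standing in for orientations chosen by visual
   inspection of projection patterns); per subject, each Cartesian
   component of that orientation is scaled by an independent factor in
   [0.8, 1.2] and the result renormalised.
4. **Correct-peak probabilities**, per subject as above.
5. **Background-noise geometry.** 80 brown-noise sources, pairwise >= 25 mm
   apart, re-drawn per subject with random orientations.

The component source centers are configurable defaults placed in medial
fronto-central cortex (the late negativities slightly parietal) so that
projections peak at FCz/Cz; they are not literature coordinates.

## Background noise and calibration

Background activity is brown noise (PSD ~ 1/f^2): cumulative sums of white
Gaussian increments, linearly detrended, independently realised per source
and epoch, each scaled to a max-abs amplitude drawn uniformly from
37.5 +- 0.5 uV. A single scalar `noise_gain` multiplies the summed scalp
projection. Because the normalised spherical lead field does not preserve
the absolute signal-to-noise ratio a realistic head model would produce,
`noise_gain` is calibrated at the decoding level: grid over candidate
gains, simulate a few subjects, and pick the gain whose subject-specific
repeated-CV balanced accuracy is closest to 0.82 — the anchor level for
well-executed within-subject ErrP decoding. Three subjects are averaged
because single-subject difficulty varies by ~+-0.1 bACC (latency shift and
correct-peak probabilities dominate). The calibrated default is
`noise_gain = 0.5` (grid 0.25/0.35/0.5/0.7 gave mean bACC
0.895/0.871/0.815/0.750).

## Dataset assembly

Default study conditions: 250 Hz sampling, 1.5 s epochs including 0.5 s
pre-stimulus, 1200 epochs per subject with an exact 20% error rate
(240 error / 960 correct, shuffled), 15 training and 10 validation
subjects. Error counts are fixed, not Bernoulli-sampled, matching the fixed
error rate of the task and stabilising evaluation. All randomness descends
from one master seed through numpy SeedSequence spawning, with a documented
draw order (subject setup, trial parameters, noise, trial order), so
datasets are bit-reproducible per platform. Epochs are sampled on the
half-open interval [-0.5, 1.0) s; epochs are generated independently (no
inter-trial overlap).

## Preprocessing (real-data path)

Recorded EEG is brought to the same epoch representation by: polyphase
downsampling to 250 Hz; zero-phase Hamming-windowed sinc FIR filtering
(notch at 50 Hz — European mains — then 1-20 Hz band-pass; transition width
min(max(0.25 f_lo, 2 Hz), f_lo), one-pass linear phase with group-delay
compensation); a deliberately simple bad-channel step (robust log-variance
z-score > 5 or flatline, inverse-distance interpolation from the 4 nearest
good channels — no ICA); common-average re-referencing; and half-open
epoching on [-0.2, 0.6) s with optional [-0.2, 0] s baseline correction.
Applied to a concatenated simulated recording, the chain preserves the
class-average waveform at Cz with correlation >= 0.95 on [0, 500] ms.

## Decoding pipeline

Features are mean amplitudes in eight overlapping windows ([0,100],
[100,200], [150,250], [200,300], [250,350], [300,400], [350,450],
[400,500] ms, half-open on the sample grid) at the eight-channel reduced
montage FC1/FC2/C3/Cz/C4/CP1/CP2/Pz — 64 features per trial, channels
outer, windows inner. Per-feature z-scoring is always fit on training data
only; the looser reading "normalised over all trials" would leak test
statistics into training.

The classifier is an RBF SVM. Class imbalance is handled twice, as both
mechanisms are part of the protocol: class weights inversely proportional
to the pre-downsampling class frequencies, and random downsampling of the
majority class in every training split (test splits stay imbalanced, so
reported rates reflect deployment prevalence). Cost and gamma are selected
by exhaustive search — cost in 10^-6..10^6 (13 values), gamma in
10^-5..10^5 (11 values) — scored by mean balanced accuracy under inner
stratified cross-validation (5 folds by default, 3 at desk scale), with
downsampling and normalizer fitting repeated inside every inner training
fold. Exhaustive search replaces any sampler-based optimiser: over a finite
143-point grid it is strictly better. Ties break toward the smallest cost,
then the smallest gamma (prefer smoother models). A 7x6 desk-scale grid
(cost 10^-3..10^3, gamma 10^-4..10^1) covers the center of the ranges where
the optimum empirically lies. For very large training pools the
hyperparameter search may be bounded to a stratified subsample
(`max_search_trials`); the final model is always refit on the full pool.

Three regimes: **subject-specific** — 10-times repeated stratified 10-fold
CV within a subject, the full search nested inside every training fold;
**leave-one-subject-out** — pool all other subjects, fit, test on the full
held-out subject; **generic** — fit once on all pooled simulated training
subjects, freeze, apply without any adaptation.

## Statistics

Balanced accuracy is the arithmetic mean of the true positive rate (error
class) and true negative rate; chance is 0.5 regardless of prevalence.
Significance of a decoder is assessed by label permutation with the
plus-one estimator p = (#{null >= observed} + 1)/(n_perm + 1); within
permutations the already-selected hyperparameters are reused (re-searching
143 points inside every permutation is disproportionate; full re-search is
available). Paired regime comparisons use the Wilcoxon signed-rank test,
zero differences dropped, exact null for n <= 25. Pointwise error-vs-correct
waveform differences use Welch's t per timepoint with Benjamini-Hochberg
FDR over timepoints. Peak picking reports the maximal signed amplitude per
search interval ([50,250]/[200,400] ms positive, [200,400]/[400,600] ms
negative); a monotone segment therefore yields the interval endpoint.

QC diagnostics mirror standard signal-quality analyses: permuted
distributions of 200 ms pre-stimulus baseline RMS (averaged over
electrodes, then trials, then subjects), averaged single-trial FFT
amplitude spectra, and ERP images (correct-average-subtracted error trials,
moving-averaged over 5 consecutive trials, window truncated at the
trial-sequence edges).

## Desk-scale problem sizes

The test suite and the acceptance script run the full generative study
conditions (15 + 10 subjects, 1200 epochs, 20% error rate) but reduce the
evaluation cost where the protocol allows: the 7x6 grid with 3 inner folds;
hyperparameter search on a 6000-trial stratified subsample for the generic
pool (final refit on all trials); LOSO training pools capped at 2400
trials; the subject-specific regime on 3 subjects x 2 repeats; 200
permutations; validation subjects at 600 epochs where only evaluation (not
training) uses them.

## What the simulation does and does not capture

The generator reproduces the component structure, trial-to-trial parameter
variability, subject-level latency/topography/probability variability, and
1/f^2 background of feedback ErrP data, and it produces realistic
inter-subject spreads in decodability. It does not model ocular or muscular
artifacts, electrode drift/pops, habituation or fatigue, inter-trial
overlap, or cortical-geometry-driven orientation variability (a smooth
sphere under-disperses scalp patterns relative to a realistic head — the
decoding-level noise calibration compensates for SNR, not for pattern
diversity). Passing tests therefore demonstrate that the pipeline recovers
the intended structure under these idealised conditions, not that decoding
accuracies transfer unchanged to recorded EEG.

## Known limitations

- The spherical model's absolute gains are not physical; only the
  normalised, calibrated combination is meaningful.
- Grand-average peak latencies inherit Monte-Carlo noise from the 15
  subject-level latency shifts; the early positivity is a small deflection
  (~1-3 uV) and its latency is the least stable reported quantity.
- The correct-condition parameterisation is the weakest part of the
  underlying protocol (few studies report it); the true-negative rate is
  correspondingly the most parameter-sensitive metric.
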