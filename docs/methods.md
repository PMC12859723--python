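# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `nirsdetect`, in the spirit of
a statistical software appendix.

## Study design being emulated

A double-blind crossover: each participant receives oral THC (dronabinol)
and placebo on separate visits in randomized order. Scans occur predose and
at ~100 and ~200 minutes postdose; heart rate and the five-item DEQ
(0–100 each) are sampled every ~20 minutes from −20 to 240 minutes; a
drug-recognition expert administers an expanded FST once per THC session
(~120 minutes). The population is regular cannabis users, so tolerance is
high and many dosed participants never become clinically impaired; some are
impaired at only one of the two postdose scans.

## Synthetic-data generator

**Latent state.** Per participant: a tolerance draw (Beta(2,2)), a dose
(N(35, 14) mg clipped to [5, 80] — metadata only, no mechanistic role), a
stable resting heart rate (N(70, 7) bpm), and a responder draw calibrated so
the latent impaired fraction of post-THC scans hits
`impairment_prevalence_target` (default 0.40). Responders are impaired at
both postdose timepoints or, with probability `inconsistent_fraction`
(default 0.4), at exactly one. Placebo sessions are never impaired.

**Hemodynamics.** Per channel, HbO(t) (µM) = linear drift + Mayer (~0.1 Hz)
+ respiratory (~0.25 Hz) + cardiac (~1.1 Hz) sinusoids + signal + white
noise (σ = 0.1 µM). The signal term is, for n-back scans, a boxcar of the
six 30-s 2-back blocks (12 alternating blocks in 6 minutes) convolved with
a double-gamma HRF (peak 6 s, undershoot 16 s, peak:undershoot 6), amplitude
0.4 µM × (1 + effect_size·impairment); for resting scans, a 0.02–0.08 Hz
band-limited Gaussian process whose *variance* scales with the same factor
and whose medial-PFC channels share a common component whose weight rises
with impairment (elevated cross-channel correlation). The impairment factor
is attenuated by (1 − tolerance/2). HbR = −⅓ × signal + in-phase cardiac
pulsation + independent noise. `effect_regions` can confine the effect to
named montage regions; `effect_size = 0` makes impaired and non-impaired
scans byte-identical in distribution (the multiplier reduces to 1).

**Forward optics.** ΔOD at each wavelength follows the modified
Beer–Lambert law with a 30 mm source–detector separation, DPF 6.0 at both
wavelengths, and base-10 extinction coefficients (cm⁻¹ mM⁻¹) 0.586/1.5485
(HbO/HbR at 760 nm) and 1.058/0.6913 (850 nm), recorded in the config;
correctness is enforced by round-trip tests, not by treating any tabulation
as ground truth. Intensities are I₀·10^(−OD) with multiplicative log-normal
instrument noise. Motion artifacts are injected in OD space: Gaussian-bump
spikes (<2 s, Laplace amplitudes) and persistent step shifts, shared across
channels with per-scan probabilities.

**Physiology and assessors.** Impaired timepoints raise heart rate by
N(18, 4) bpm over the predose baseline and set the "feel drug" DEQ item to
N(70, 12); non-impaired THC timepoints get N(4, 3) bpm and N(22, 10). The
drug-effect time course is flat within ±20 min of each scan so that windowed
means recover the injected values exactly in expectation. Each clinical
rater is Bernoulli with the configured sensitivity (0.95) and specificity
(0.97) against the latent state. The FST is Bernoulli at the configured
operating point (recall 0.84, false-positive rate 0.34) with an ordinal 0–4
failed-component score consistent with the binary call (positive ⇔ ≥2
components failed).

**Attrition.** A per-scan missingness rate (default 0.17) emulates scan
attrition, bringing a 180-participant cohort to ≈890 resting scans with
≈100–120 labeled impaired — the intended ≈1:7 class imbalance.

**What the generator does not emulate.** Pharmacokinetics, dose–response,
scalp/optode optics, short-separation channels, rater drift, serial
correlation of physiology across sessions, and demographic structure.
Passing recovery tests therefore shows the *pipeline* extracts an embedded
signature of this hemodynamic form at realistic SNR and class imbalance; it
does not validate the neurobiology of any particular real signature.

## Preprocessing

OD uses the whole-scan column mean as reference (first-30-s and explicit
baselines available). PCA motion correction removes the leading spatial
principal components that cumulatively explain ≥ `variance_fraction`
(default 0.8) of cross-channel variance; 0 removes nothing. The band-pass is
a 3rd-order zero-phase (forward–backward) Butterworth, default 0.01–0.2 Hz;
in-band sinusoids pass within 5% amplitude and the chain is linear to ~1e−7
(IIR round-off). MBLL inversion solves the per-channel 2×2 extinction system
exactly; with artifacts and noise disabled and the true baseline supplied,
the forward→inverse round trip is exact to <1e−9 µM. Quality screening
flags channels whose cardiac-band (0.8–1.5 Hz) peak-to-median PSD
prominence falls below 5 or whose variance exceeds a ceiling; scans with >5
bad channels are excluded. These screening constants are our own, tuned on
synthetic data only; at study-scale defaults ordinary scans pass and only
rare artifact-dominated scans are excluded. For classification the filtered
series are decimated to 1 Hz (content sits below 0.2 Hz).

## Impairment labeling

Ground truth at a postdose scan = rater A ∧ rater B ∧ algorithm. The
algorithm is a composite standardized score: ΔHR/σ_hr + DEQ_feel/σ_deq ≥ τ
with defaults σ_hr = 10 bpm, σ_deq = 30 points, τ = 2, where ΔHR is the
±20-minute windowed mean minus the predose mean. The exact clinical
algorithm behind the original two-step definition is not public; this
composite-z rule is our stand-in, with constants chosen once so study-scale
cohorts reproduce the ≈111:782 class ratio, and all three surfaced in the
API. Training classes: impaired = labeled post-THC scans; non-impaired
pools post-placebo, predose, and post-THC-without-impairment scans (the
three subtypes are counted and reported). An empty impaired class aborts.

## Classifiers

**Kernel model.** Default 2000 kernels (1000 in the study-scale runs below);
lengths {7, 9, 11}, standard-normal mean-centered weights, log-uniform
dilations bounded by the series length, 50% padding, channel subsets
log-uniform up to 8 channels. Features are PPV (strict >0) and max over
valid positions. The ridge head is the closed-form solution on standardized
features with leave-one-out-selected λ from a 10-point log grid and
balanced class weights. Sequential detachment prunes the fraction p
(default 0.05 standalone; 0.1 inside CV) of active features with smallest
|w|·SD per step, refits, and selects the step maximizing holdout accuracy −
c·(fraction retained), c = 0.05, holdout = 25% stratified split; pruning
floors at `min_fraction` of the features.

**Parallel model.** Four feature blocks per scan — per-channel
mean/SD/skew/kurtosis of HbO and HbR; bandwidth-normalized band powers in
0.01–0.04/0.04–0.08/0.08–0.15 Hz; the upper triangle of the HbO
cross-channel correlation matrix (zero-variance channels contribute 0 by
convention); a small random-kernel pool — feeding an L2-penalized logistic
head (deterministic lbfgs, tol 1e−10). The identity of the original four
submodels is not public; these blocks are our definition.

## Evaluation protocol

Participants (never scans) are dealt into 5 outer folds, stratified by
ever-impaired status (round-robin after a seeded shuffle keeps per-stratum
counts within ±1); each outer fold's training participants are dealt into 6
inner folds the same way. Per inner fold: train on the other five, fit an
isotonic (PAVA) map from raw scores to [0,1] on the held-out fold (clamping
outside the fitted range), and pool the calibrated validation scores across
the six folds to select the F1-optimal threshold (candidates = midpoints
between distinct sorted probabilities plus {0,1}; prediction is prob ≥ t;
ties go to the smallest threshold). Outer-fold test scans get the mean of
the six calibrated probabilities. Pooling the threshold across validation
folds is a choice the protocol description leaves open; metrics are
reported both pooled over concatenated out-of-fold predictions and as
per-fold means, since either convention is defensible. A leakage audit
asserts participant-disjointness on every run and raises on violation.
Robustness mode assigns participants never impaired during THC exclusively
to test folds. Undefined metrics (empty denominators, single-class AUC) are
reported as None with a reason, never silently 0.

## Inference

The paired bootstrap draws, per resample, exactly n₊ positive and n₋
negative indices with replacement (class proportions preserved exactly),
recomputes all six metrics for both classifiers (AUC via the tie-corrected
rank statistic), and summarizes paired differences by percentile 2.5/97.5
CIs, the bootstrap SD as SE, and p = proportion of differences ≤ 0 —
kept verbatim as the one-sided convention; because it is misleading for
smaller-is-better metrics (FPR), the mirrored proportion ≥ 0 is also
reported, labeled. Resamples where a metric is undefined are dropped for
that metric and counted. BCa corrections are deliberately not used
(percentile CIs match the described procedure).

Condition contrasts (predose / placebo / THC-impaired / THC-not-impaired)
use complete-pair differencing: every participant observed in both
conditions contributes the difference of their condition means, the
contrast is the across-participant mean, and CIs come from a 2000-resample
cluster bootstrap over participants. This equals within-participant
centering restricted to complete pairs and is unbiased where plain
centering is not when participants contribute unequally across conditions;
it replaces REML mixed-model machinery by design. Channel importance
trains the kernel model (no detachment) on each HbO channel alone and
reports the mean validation-fold AUC, ordered by montage.

## Problem sizes and numerical notes

Study-scale experiments use 180 participants, 6-minute resting scans at
5 Hz, 1000 kernels, and detachment with p = 0.1 down to 15% of features;
null experiments use ten 60-participant, 3-minute cohorts with 200 kernels.
The test suite's desk fixtures are smaller (36 participants, 4-minute
scans). Because pooled AUC on a null cohort has sampling SD ≈ 0.05 at these
sizes, null behaviour is asserted on the across-seed mean (each seed is
also required to stay within a wider band). Seeds thread through a single
`numpy` Generator per cohort and explicit seeds for fold plans, model
fitting, and bootstraps; identical configs reproduce cohorts exactly.

## Known limitations

The generator's impairment signature is stylized (variance/coupling shifts,
not fitted to real spectra); the labeling algorithm and the four parallel
feature blocks are stand-ins for non-public components; pretrained
time-series foundation models are out of scope (trained weights are not
reproducible content); the SNIRF reader ingests amplitude data only. Real
printed performance tables from trial data are not reproducible without
those data; the package instead verifies internal-consistency identities
(precision/recall → F1) and full-pipeline recovery on cohorts with known
ground truth.
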