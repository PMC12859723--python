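# nirsdetect

Detecting acute Δ9-tetrahydrocannabinol (THC) impairment from prefrontal
functional near-infrared spectroscopy (fNIRS) time series.

Roadside and clinical assessment of cannabis impairment is hard: THC blood
levels correlate poorly with functional impairment in regular users, and
behavioral field sobriety tests (FSTs) have high false-positive rates.
`nirsdetect` is a research package for biostatisticians and neuroimaging
methodologists studying whether prefrontal hemodynamics can do better. It
provides, end to end and fully synthetic (no participant data required):

1. **Cohort simulation** — a double-blind THC/placebo crossover: per
   participant, two sessions with predose and two postdose 20-channel
   dual-wavelength (760/850 nm) fNIRS scans, serial heart rate and Drug
   Effects Questionnaire (DEQ) ratings, two clinician raters, and an
   expanded FST per THC session, all driven by a latent impairment state.
2. **Preprocessing** — optical density, PCA-based motion correction,
   zero-phase band-pass, modified Beer–Lambert inversion to ΔHbO/ΔHbR (µM),
   and cardiac-band channel quality screening.
3. **Labeling** — impairment ground truth as the conjunction of *both*
   clinical raters and a composite heart-rate/DEQ algorithm.
4. **Classification** — a random convolutional-kernel transform (PPV + max
   pooling per kernel) with a ridge head and *sequential feature
   detachment*, plus a four-block parallel feature ensemble with a
   cross-entropy head.
5. **Evaluation** — participant-level 5-outer × 6-inner nested
   cross-validation with isotonic calibration, k-model ensemble averaging,
   and F1-optimal thresholding.
6. **Inference** — stratified paired bootstrap comparison against the FST,
   within-subject condition contrasts with cluster-bootstrap CIs, and
   per-channel importance.

## The statistics at the core

For scan *i* with multichannel series **x**ᵢ, each random kernel *k*
(mean-centered weights, log-uniform dilation, random channel subset) yields
two features of its dilated convolution output *u* = *w*ₖ ∗ **x**ᵢ + *b*ₖ:

    PPV_k(i) = #{t : u(t) > 0} / |u|,   MAX_k(i) = max_t u(t)

A ridge classifier on the standardized features is pruned by sequential
detachment: repeatedly drop the fraction *p* of active features with the
smallest |wⱼ|·SD(fⱼ), refit, and keep the step maximizing (holdout accuracy
− c·fraction retained). Inside each outer fold, six submodels are trained on
inner-fold complements, each calibrated by isotonic regression (PAVA) on its
held-out fold; a test scan's probability is the mean of the six calibrated
outputs, thresholded at the F1-optimal cut found on the pooled validation
scores. Two classifiers A and B are compared on shared test scans by a
stratified paired bootstrap: each of 1000 resamples redraws exactly n₊
impaired and n₋ non-impaired scans, and the difference distribution gives
percentile 95% CIs, SEs, and p = P(diff ≤ 0).

## Worked example

`examples/03_nested_cv.py` simulates a 40-participant crossover with a
strong hemodynamic effect, preprocesses every scan, labels impairment, and
runs the calibrated nested CV:

```
238 scans; class counts: {'predose': 79, 'postplacebo': 79, 'post_thc_not_impaired': 52, 'impaired': 28}
pooled out-of-fold: AUC=0.847  F1=0.542  precision=0.650  recall=0.464  accuracy=0.908  FPR=0.033
per-fold thresholds: [0.336, 0.386, 0.417, 0.292, 0.417]
inconsistently-impaired subset: n=47, AUC=0.732
```

The class counts show the three non-impaired scan types (predose,
post-placebo, post-THC without clear impairment) beside the impaired class.
The pooled row is computed only on out-of-fold scans — no model ever saw its
test participants — so AUC 0.85 means the hemodynamic signature generalizes
across people. The subset row repeats the evaluation on participants
impaired at exactly one postdose timepoint, where classification must track
the onset/offset of impairment within a session. The other examples cover
simulation (`01`), preprocessing (`02`), the FST bootstrap comparison
(`04`), and contrasts/channel importance (`05`).

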