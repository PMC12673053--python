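# coughvision

Automated cough detection from ambulatory audio recordings.

Objective cough monitoring matters clinically — cough frequency is one of
the few quantifiable measures of symptom burden in chronic cough, COPD,
asthma, ILD and related conditions — but counting coughs in 24-hour
recordings by ear is prohibitively labour-intensive. `coughvision`
implements a complete, model-agnostic detection pipeline for
contact-microphone recordings (mono WAV, 8 kHz, 16-bit, silence-removed):
it slices recordings into fixed windows, labels them against annotated
cough events, renders each window as a spectrogram image, splits the data
subject-wise under demographic and cough-density balancing rules, trains a
class-weighted image classifier, and reports sensitivity, specificity,
precision and F1 overall, per subject and per diagnostic category. A
synthetic cohort generator makes every stage reproducible and testable
without access to clinical recordings.

## Method

**Segmentation and labelling.** A sliding window of 500, 750 or 1000 ms
with 50% overlap cuts each recording into fixed-length segments. Every
annotated cough event defines a 500 ms *reference window*; a segment is
labelled cough iff its overlap with some reference meets the
duration-specific threshold — ≥250 ms (500 ms windows), ≥375 ms (750 ms),
or the full 500 ms (1000 ms windows). Overlap arithmetic is exact, in
integer samples at 8 kHz.

**Spectrogram images.** Eighteen STFT parameterisations are supported:
segment duration × frame length *N* ∈ {64, 128, 256} samples × hop ∈
{N/2, N/4}, with a periodic Hann window and DFT length equal to *N*
(radix-2, no zero-padding). Framing is non-centred, so the image geometry
is

    width  = ⌊(segment_samples − N) / hop⌋ + 1   frames
    height = N/2 + 1                              bins

e.g. configuration `750_128_32` yields a 65 × 184 array. The magnitude
|STFT| is mapped to dB (20·log₁₀, per-image maximum as the 0 dB
reference), clipped to [−80, 0] dB, normalised, quantised to 8 bits,
coloured with the jet colormap and bicubically resized to 224 × 224 RGB
PNG, laid out as
`Spectrograms/<Category>/<Subject>/{positives,negatives}/<index>.png`.

**Subject-wise split.** Whole subjects go to train/validation/test at
60/20/20 (largest-remainder rounding per diagnostic category, every
category guaranteed in all three splits when it has ≥3 subjects). Among
valid assignments, a seeded random-restart hill-climbing search balances
per-category sex ratios and mean cough counts per hour across splits.

**Training.** Class-weighted cross-entropy with w_i = N/(2·N_i), AdamW
(β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), batch 128, linear warm-up to the peak
learning rate over the first 10% of steps then cosine decay to zero, at
most 20 epochs with patience-5 early stopping on validation F1 and
best-checkpoint restore. The classifier is a pluggable backend behind a
small contract; the shipped reference backend is a logistic model on
block-averaged pixels that trains on a CPU in minutes. A two-stage
protocol is provided: a pilot sweep over spectrogram configurations on a
~10% subset drawn from the same underlying events, ranked by test F1,
then a full-scale run with the winner.

**Evaluation.** Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
precision = TP/(TP+FP), F1 = harmonic mean of precision and sensitivity,
computed from confusion matrices pooled overall and per subject/category.
Undefined ratios (e.g. a subject with zero coughs) are flagged and
excluded, never coerced to 0 or 100. Sample-based and subject-based
k-fold cross-validation are both available; the sample-based mode warns
about the intra-subject leakage it introduces.

## Worked example

```
$ coughvision synth --out cohort --subjects-per-category 3 --duration 120 --seed 5
wrote 27 recordings to cohort
$ coughvision segment --cohort cohort --segment-ms 750 --out segments.csv
8613 segments (282 cough) -> segments.csv
$ coughvision split --cohort cohort --seed 5 --out splits
split written to splits (balance score 18.1122)
$ coughvision train --cohort cohort --config 750_128_32 --seed 5 --max-epochs 12 --out run
test F1: 68.77
```

The synthetic cohort holds 27 two-minute recordings (9 diagnostic
categories × 3 subjects) with per-category cough densities spanning the
clinically observed ~9–450 events/hour, so coughs are a rare class: 282
of 8613 windows (3.3%). The split step prints the balance-search
objective (sum of per-category sex-ratio and cough-rate deviations across
splits; lower is better — with one subject per category per split it
cannot reach zero). Training the reference backend and scoring the
held-out subjects gives a test F1 of 68.77% against a permuted-label
baseline near the 3% positive prevalence. Per-category breakdowns land in
`run/per_category.csv`:

```
group,tp,fp,tn,fn,sensitivity,specificity,precision,f1,undefined
Asthma,2,9,308,0,100.0,97.16,18.18,30.77,
Bronchiectasis,17,11,290,1,94.44,96.35,60.71,73.91,
COPD,5,3,311,0,100.0,99.04,62.5,76.92,
...
```

Low-density categories (here Asthma, with only two cough windows in its
test subject) show exactly the precision instability that per-category
reporting is meant to surface.

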