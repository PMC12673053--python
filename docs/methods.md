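# Methods

This note documents the models, conventions and design choices behind
`coughvision`, in the order the pipeline runs.

## Recording contract and time arithmetic

The pipeline assumes contact-microphone ambulatory recordings: mono RIFF
PCM WAV, 8 kHz, 16-bit, with silence largely removed upstream, so
non-cough audio still dominates but recordings are dense in sound events.
Off-contract sample rates are rejected unless resampling is explicitly
requested (polyphase, then re-quantised to int16); stereo input requires
an explicit channel selection. Annotations are per-recording cough event
intervals in seconds. Intervals are half-open `[onset, offset)` and all
overlap computations are performed in integer samples at 8 kHz, so
threshold comparisons (e.g. "overlap ≥ 250 ms" = 2000 samples) are exact
with no floating-point drift. Overlapping raw annotation events are
merged into interval unions with a warning, because the labelling rule
requires non-overlapping references; abutting events stay distinct.
Annotation CSVs carry millisecond precision (the generator places events
on whole milliseconds, so round-trips are exact).

## Synthetic cohort generator

Clinical cough corpora of this kind are private, so the generator
produces cohorts with the statistical structure the pipeline assumes
rather than clinically realistic audio:

- **Cough events** are two-phase: a band-limited broadband noise burst
  (30–100 ms, 2 ms attack, exponential decay) followed by a damped
  harmonic phonation tail (f₀ 140–420 Hz with three harmonics). Total
  duration is 250–500 ms, never exceeding the 500 ms that covers
  essentially all real coughs. Each subject draws a fixed f₀ and spectral
  tilt, giving subjects an identifiable acoustic character — this is what
  makes subject-held-out evaluation harder than sample-held-out and lets
  the cross-validation leakage effect appear in synthetic data.
- **Distractors** (non-cough events, default 120/hour) are pure tones,
  speech-like formant sweeps and low-frequency thuds; they are
  deliberately separable from coughs by a learnable margin, since the
  generator's job is to test pipeline mechanics, not cough acoustics.
- **Counts** are Poisson with mean `rate × duration / 3600`. Default
  per-category rates span ~9–450 events/hour (healthy volunteers at the
  bottom, bronchiectasis/paediatrics at the top), matching the published
  per-category densities of the clinical cohort this pipeline targets;
  per-subject rates get lognormal jitter (σ = 0.3) so subjects within a
  category differ. Default per-category sex ratios likewise follow the
  published demographics.
- **Placement** is rejection sampling with no overlap between any two
  events; each cough reserves its full 500 ms reference extent so
  labelling reference windows never collide. Failure to place an event
  raises rather than silently truncating.
- **Background** is stationary Gaussian noise (default RMS 0.005 full
  scale). Event amplitudes are 0.15–0.7, so every annotated interval
  carries energy well above background.

What passing tests on this data do *not* show: robustness to real cough
acoustics, room reverberation, overlapping speech, device transfer
functions, or annotation noise. They do show that the segmentation,
labelling, imaging, splitting, weighting, training and evaluation
machinery is correct and leak-free.

## Segmentation and the overlap-threshold labelling rule

Sliding windows of 500/750/1000 ms with 50% overlap; trailing partial
windows are dropped (never zero-padded), so each configuration's
fixed sample count (4000/6000/8000) holds for every segment and the
segment count is `⌊(L − seg)/hop⌋ + 1`. Each annotated event defines a
500 ms reference window; a segment is cough iff its maximal overlap with
any reference meets the threshold {500→250 ms, 750→375 ms, 1000→500 ms}.
The threshold ≥ at equality; for 1000 ms windows the threshold equals the
reference length, i.e. the entire reference must lie inside the segment.

Open choice — reference anchoring: nothing in the labelling rule fixes
where the 500 ms reference sits relative to an annotated event. The
default anchors it at the event onset, extending 500 ms (consistent with
a reference duration chosen to cover a whole cough from its onset); a
centre anchor is available via `reference_anchor="center"`. Events
shorter than 500 ms still get a full reference — the rule is defined on
the reference, not the raw event. References clipped at the recording
end are flagged; for 1000 ms windows a clipped reference can never reach
its threshold, which is accepted behaviour at recording edges. A segment
overlapping two references takes the maximum overlap (binary labels, one
per segment).

## Spectrogram images

DFT length equals the frame length (64/128/256 → bin spacings 125/62.5/
31.25 Hz), periodic Hann window, non-centred framing with no padding —
this framing is what makes the image widths come out as
`⌊(seg − N)/hop⌋ + 1` (30–497 across the 18 configurations) and is
deliberately chosen over library-default centred/padded STFTs, which
would change the frame counts.

Conversion order is fixed: dB → clip [−80, 0] → normalise [0, 1] →
quantise 0–255 → jet colormap → bicubic resize to 224 × 224 → PNG.
Numerical choices, each configurable:

- **dB reference**: the per-spectrogram maximum magnitude maps to 0 dB.
  The [−80, 0] clip range presupposes a 0 dB ceiling, and a per-image
  maximum is the convention that achieves it; it also makes images
  invariant to absolute recording gain.
- **Amplitude convention**: 20·log₁₀ (magnitude), with 10·log₁₀ (power)
  selectable via `log_factor`.
- **Jet colormap**: the canonical 256-entry piecewise-linear jet (each
  channel a clipped tent function), computed in closed form so output
  never drifts with plotting-library versions.
- **All-zero segments** map to the uniform floor colour, never NaN.
- **Resize** uses Pillow bicubic on the RGB image (colormap first, then
  resize). Pre-resize arrays are exact and tested exactly; post-resize
  pixels depend on the resize kernel and are treated as
  implementation-defined within small tolerances.

## Subject-wise splitting

Hard rules: subjects are atomic; per-category sizes follow
largest-remainder apportionment of (0.6, 0.2, 0.2); any category with ≥3
subjects appears in all three splits (a seat moves from the largest split
if rounding left one empty — a 3-subject category becomes 1/1/1);
categories with 1–2 subjects degrade to a warning. Remainder ties break
toward the later split (test, then validation) — a single deterministic
rule where any "simple rounding" convention would do; for a 67-subject
category it yields (40, 13, 14).

Soft objective: summed over categories and splits,
`|male_fraction(split) − male_fraction(category)|` plus
`|mean_rate(split) − mean_rate(category)| / max(mean_rate(category), 1)`.
The rate term is normalised so a 400/hour category does not drown out the
sex term. Minimised by seeded random restarts (default 8) each refined by
same-category pairwise-swap hill-climbing; ties broken by subject id
order, so the assignment is a deterministic function of (cohort, seed).
The search is compared against 1000 random valid assignments in tests and
is required to match or beat their minimum in ≥95% of cohorts.

## Training regime

Class weights `w_i = N/(2·N_i)` equalise the total loss mass of the two
classes (Σ w_i·N_i = N); both classes must be present. Optimiser AdamW
with decoupled weight decay 0.001 (0.01 in the pilot stage, where the 10%
subset raises overfitting risk). Learning rate: linear ramp from 0 to the
peak over the first 10% of total steps, then cosine decay to exactly 0 —
continuous at the junction. Batch 128, max 20 epochs, early stopping with
patience 5 and best-checkpoint restore.

Early-stopping monitor: validation F1 by default, validation weighted
loss selectable (`monitor="loss"`). F1 is the default because it is the
quantity the pilot ranking and the final model selection optimise; with
heavy class imbalance a weighted loss can improve while the operating
point's F1 degrades.

The backend contract (feature preparation, init, per-batch weighted-CE
gradient step, score prediction, state snapshot/restore) keeps the
classifier pluggable. The reference backend block-averages each RGB
channel to 28 × 28 (channels kept separate — jet is non-monotone in
luminance, so a grayscale average would destroy the intensity ordering)
and trains a single logistic layer. Its natural peak learning rate is
~1e-2; the 5e-5 default in `TrainConfig` is the fine-tuning scale for
large pretrained vision backends plugged in through the same contract.
The 86M-parameter pretrained-transformer backend used in large-scale work
is out of scope here; the contract and the training loop are what this
package provides.

Pilot sweep: each configuration trains on a ~10% subset drawn from the
same underlying events — cough events are chosen per subject with a
shared seed (so every configuration sees segments of the same coughs) and
non-cough segments are sampled per subject with subject-derived seeds;
configurations sharing a segment duration therefore see identical sample
identities. Rows report train/validation/test F1, the train-test gap, and
test precision/recall; aggregation helpers average by duration, frame
length or hop fraction, and the best configuration by test F1 is flagged.

## Evaluation

Metrics are computed from integer confusion counts and rounded half-up to
two decimals (percentages) only at presentation. Zero-denominator ratios
are reported as absent with a reason; per-subject summaries state how
many subjects were excluded (zero-cough subjects have undefined
sensitivity/F1). Per-group matrices sum exactly to the overall matrix.
Category summaries give pooled-overall, median, IQR and SD of per-subject
F1.

Cross-validation: sample-based k-fold shuffles segments, which places
highly similar same-subject segments on both sides of a fold boundary;
the runner emits an explicit leakage warning whenever this applies, and
the subject-based mode (grouped folds) is the unbiased alternative. The
test suite checks the qualitative consequence — sample-based mean F1 at
or above the subject-based mean on the same data.

## Problem sizes and defaults in tests

The test suite runs the full chain on a synthetic cohort of 9 categories
× 3 subjects with 10-minute recordings (≈43 000 segments at 750 ms), the
leakage comparison on a 9-subject cohort with 3-minute recordings, and
the split-invariant checks on 100 random cohorts of 3–5 categories × 3–12
subjects. These sizes were chosen as the smallest at which every
qualitative property (rare-class learning, subject heterogeneity,
balance-search quality) is comfortably expressed. Feature extraction
streams images in chunks so full-resolution 224×224×3 arrays are never
all held in memory.

## Known limitations

- The generator's distractors are far cleaner than real-world non-cough
  sounds; absolute F1 values on synthetic data say nothing about clinical
  performance.
- Event-level cough counting (merging segment detections back into
  events) is out of scope; the unit of evaluation is the segment.
- The labelling rule cannot mark a cough whose reference window is
  clipped below threshold at the recording edge.
- Single-subject split cells (unavoidable in small categories) make
  per-category balance targets unreachable; the balance score reports,
  but cannot remove, this deviation.
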