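# Methods

## Problem and model

`pcgseg` segments single-channel phonocardiograms (PCG) into the first and
second primary heart sounds (S1, S2) and the systolic and diastolic intervals
between them. The method rests on three physiological regularities: primary
heart sounds last under 250 ms; a physiologically split sound consists of two
sub-lobes less than 50 ms apart with clearly unequal energies; and the
systolic interval (S1 onset to S2 onset) is far more stable from beat to beat
than the diastolic interval. On top of the base segmenter sits a noise-robust
layer that detects bands of high-energy contamination (crying, stethoscope
motion) by their anomalously large envelope area and crops them before
segmentation.

## Pipeline

**Preprocessing.** Recordings are resampled to 4 000 Hz (polyphase rational
resampling with anti-alias filtering), bandpassed 40–500 Hz, and normalized
to [−1, 1]. The filter is a 4th-order Butterworth applied forward–backward
(zero phase) so group delay cannot shift sound onsets; the family and order
are a design choice — no published constraint fixes them — and are kept
behind `preprocess.bandpass`. Because the Butterworth magnitude is below
unity near the band edges, preprocessing is only idempotent up to residual
edge ripple (observed max ≈ 2·10⁻³ of full scale on synthetic signals), not
bitwise.

**Envelope.** The average Shannon energy (ASE) is computed over 20 ms windows
with 50% overlap: per frame E = −(1/N) Σ x²ln(x²), with 0·ln 0 := 0. The
natural-log base is arbitrary (it rescales the envelope; the zero threshold
below is invariant to it) but fixed for deterministic tests. The normalized
ASE (NASE) subtracts the envelope mean, and candidate lobes are maximal runs
of frames with NASE strictly > 0. A lobe's time extent is
[start_frame·hop, end_frame·hop + frame_len) — the full extent of its
contributing windows; single-frame lobes are retained and left to validation.

**Validation.** Lobes of duration ≥ 250 ms are removed. For adjacent lobes
with a gap (end-to-start) under 50 ms whose RMS ratio (weaker/stronger,
computed on the bandpassed signal within the lobe extent) is below 0.40, only
the stronger lobe is kept; otherwise both remain candidates (the weaker may
be a murmur, which identification passes over). Gap semantics are used for
the split rule and onset-to-onset semantics for cycle and systole lengths;
the distinction is deliberate and tested.

**Identification.** The anchor is the lobe pair bounding the longest
onset-to-onset gap (ties to the earliest), taken to straddle a diastole: the
lobe after the gap is the initial S1, its successor the initial S2. The chain
extends greedily forward then backward. Candidate next-S1 lobes must have
onsets within [0.5, 1.5] × the running cycle estimate (physiological
beat-to-beat variability bounds); each candidate pair is scored by the
equally weighted (1/3 each) sum of (a) the Pearson correlation between the
candidate's systolic-interval NASE stretch and the reference pair's, after
linearly resampling the shorter to the longer, (b) 1 − |Δcycle|/cycle and
(c) 1 − |Δsystole|/systole, both clipped to [0, 1]. A step is accepted only
above a 0.5 score floor; running cycle/systole estimates are cumulative means
of accepted values. Equal weights and the 0.5 floor are design choices
exposed in `SegmentationParams`.

**Success criterion.** A segmentation is flagged successful when at least one
complete S1–S2–S1 span was found *and* the accepted sounds account for at
least half of the validated lobes (`min_lobe_coverage = 0.5`). The coverage
gate exists because stationary broadband noise produces a dense lobe field
(~17 lobes/s at 10 s) through which the pair score can stitch a few spurious
pairs by chance; a labeling that leaves most candidate lobes unexplained is
not a plausible heart sound segmentation. On clean recordings nearly every
validated lobe is labeled, so the gate is inert there.

**Noise-robust layer.** With M lobe areas A_i (simple sums of ASE over lobe
frames), the population statistics Ā = (1/M)ΣA_i and
σ = √((1/M)Σ(A_i − Ā)²) give z_i = (A_i − Ā)/σ; lobes with z_i > 2.75 are
outliers (nothing is flagged when σ = 0). Population rather than sample
variance is intentional. Outlier lobes are cropped with a 50 ms guard margin
each side (the split-interval scale; the crop extent is otherwise a free
choice), remaining clean intervals shorter than 2.0 s are dropped (too short
to hold a full cycle at pediatric rates), and each surviving interval is
renormalized and segmented independently — the envelope mean is thus
recomputed per clean segment, so a cropped burst cannot inflate the NASE
threshold of the clean part. Labels are merged in time order with cropped
gaps carrying the noise state; alternation is not forced across a gap.
Outlier detection is a single pass by default; an iterative re-flagging pass
is available as `iterative_outlier_pass` but off, matching the one-shot
structure of the procedure.

## Evaluation metrics

Sensitivity: a ground-truth S1 (or S2) is a true positive when the midpoint
of some predicted sound of the same type falls inside it (half-open
[start, end)); otherwise a false negative; sensitivity = TP/(TP+FN).
Predictions wholly outside [first truth onset, last truth offset] are
disregarded, since the segmenter can find more cycles than the annotation
covers. Accuracy: mean absolute midpoint distance over truth/prediction
pairs matched greedily one-to-one by ascending distance (the pairing rule is
a design choice; an exhaustive oracle backs it in tests). Recording-level
success means every available truth sound was found, where sounds inside a
known noise window (± 150 ms pad, covering the crop margin and envelope
frame support) are not counted as available.

Note: for the published per-category cycle counts the TP/(TP+FN) ratio of
the "unsure" category equals 95.58%, while the figure printed alongside those
counts is 95.76%; the package reproduces the ratio definition and documents
the mismatch rather than matching the inconsistent figure.

## Synthetic data

The generator produces S1/S2 as Gaussian-windowed sinusoids (defaults: S1
100 ms at 80 Hz, amplitude 1; S2 80 ms at 140 Hz, amplitude 0.7 — inside the
passband, realistic durations), with the systolic interval fixed at 0.35 of
the nominal cycle and all cycle jitter applied to the diastole, enforcing the
systole-stability premise the identifier relies on. Optional features: split
S1 (sub-lobes < 50 ms apart, unequal amplitude), band-limited systolic
murmur, broadband noise bursts with RMS = gain × 0.1 (multiples of the
typical clean-signal RMS; gain 10 makes the burst dominate by > 5× RMS), and
background white noise at a configurable SNR (default 30 dB). The default
study suite is 100 recordings of 10 s, bpm drawn uniformly from 60–140
(pediatric-to-adult range) and relative cycle jitter from 2–8%; the
burst condition injects one 1 s, gain-10 burst per recording at a uniformly
random position. Problem sizes were chosen so the whole validation runs on a
laptop-class single core in well under a minute.

What the generator does **not** emulate: murmur spectra tied to specific
pathologies, S3/S4 gallops, holosystolic murmurs that obscure S1/S2 (known
failure modes of this algorithm family, deliberately out of scope),
respiration, sensor transfer functions, or clipping. Passing tests therefore
demonstrate correctness of the mechanism under the stated structural
assumptions, not clinical performance on real auscultation data.

## Numerical choices and degenerate inputs

* Interval convention: half-open [onset, offset), seconds, 0-based sample
  indices; annotation files round-trip at 1e-6 s precision.
* All-zero signals: normalization errors; the end-to-end segmenters catch
  this and return a failure-flagged empty segmentation instead of raising.
* Zero-variance envelope stretches score a correlation of 0.
* Score ties break to the earlier-onset pair; equal longest gaps break to
  the earliest.
* Multi-channel WAV input keeps the first channel with a logged warning;
  integer PCM is rescaled to [−1, 1]. These are package choices — no
  published handling exists for either case.

## Known limitations

* The identification chain stops at a long unexplained gap (e.g. an
  un-cropped noise region): the far side of the anchor is then lost. This is
  precisely the failure the noise-robust layer addresses, and the A/B
  comparison (`--no-noise-robust`) reproduces that direction: on the burst
  suite the base segmenter fully recovers ~1% of recordings while the
  noise-robust variant recovers ~50% (the rest fail because a clean side
  shorter than 2 s is dropped by design).
* Clean intervals shorter than 2 s are discarded even when they hold a full
  cycle at high heart rates; min_clean_duration is a parameter.
* Sensitivity/accuracy require ground-truth annotations in the supported
  TSV dialect; false positives / true negatives are not accounted, as the
  ground truth covers only annotated spans.
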