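# pcgseg — noise-robust Shannon-energy heart sound segmentation

`pcgseg` segments phonocardiograms (digital heart sound recordings) into the
primary heart sounds **S1** and **S2** and the **systolic** and **diastolic**
intervals between them. It is written for researchers and engineers building
automated auscultation pipelines — murmur classifiers, heart-rate and timing
analysis, stethoscope software — who need a fast, dependency-light segmenter
that survives the noise bursts (crying, stethoscope motion, speech) that
contaminate real, especially pediatric, recordings.

## Method

1. **Preprocess** — resample to 4 kHz, zero-phase Butterworth bandpass
   40–500 Hz, normalize to [−1, 1].
2. **Envelope** — average Shannon energy over 20 ms windows with 50% overlap,

       E_s = −(1/N) Σ_j x²(j) · ln x²(j),

   then mean-subtract (NASE); candidate sound lobes are the maximal runs
   with NASE > 0.
3. **Noise cropping** — with lobe areas A_i (simple sums of the envelope),
   flag lobes whose z-score z_i = (A_i − Ā)/σ_A exceeds 2.75 (population
   statistics) as noise, crop them with a 50 ms margin, and segment each
   remaining clean interval independently.
4. **Validate** — drop lobes ≥ 250 ms; merge split sounds (gap < 50 ms, RMS
   ratio < 40%) keeping the stronger lobe.
5. **Identify S1/S2** — anchor on the lobe pair bounding the longest
   inter-lobe interval (a diastole, since S2→S1 exceeds S1→S2), then extend
   forward and backward, scoring candidate pairs by systolic-envelope
   correlation plus agreement with the running cardiac-cycle and
   systolic-interval estimates.
6. **Evaluate** — midpoint-bracketing sensitivity TP/(TP+FN) and mean
   midpoint-distance accuracy against TSV ground-truth annotations
   (CirCor DigiScope dialect).

A synthetic phonocardiogram generator with exact ground truth
(`pcgseg.synth`) exercises every assumption above, including split sounds,
murmur bands, and injected noise bursts.

## Worked example

```python
from pcgseg import SynthConfig, generate, segment_noise_robust, sensitivity_eval

# 10 s at 80 bpm with 5% cycle jitter and a loud 1 s noise burst at 4 s
cfg = SynthConfig(duration_s=10, bpm=80, cycle_jitter=0.05,
                  bursts=((4.0, 5.0, 10.0),), seed=3)
rec, truth = generate(cfg)

seg = segment_noise_robust(rec)
print(seg.success, f"cycle {seg.cycle_length_s*1e3:.0f} ms, systole {seg.systole_s*1e3:.0f} ms")
print(sensitivity_eval(seg, truth))
```

prints

```
True cycle 766 ms, systole 262 ms
TP=22 FN=4 sensitivity=84.62% S1 midpoint error=0.95 ms S2 midpoint error=1.84 ms
```

The segmenter recovered the cardiac cycle (80 bpm ⇒ 750 ms) and systole on
both sides of the burst; the 4 missed sounds are the ones buried inside the
cropped 4–5 s noise window, which no segmenter is expected to label. With
`segment_base` (or the CLI flag `--no-noise-robust`) the burst breaks the
identification chain and everything before 5 s is lost.

The same pipeline is available from the shell:

```sh
pcgseg synth --bpm 80 --duration 10 --seed 3 -o rec.wav --truth truth.tsv
pcgseg segment rec.wav -o pred.tsv          # add --no-noise-robust for A/B
pcgseg evaluate pred.tsv truth.tsv
```

Output annotations are 3-column TSV (`onset<TAB>offset<TAB>state`) with
states 0 = noise/unlabeled, 1 = S1, 2 = systole, 3 = S2, 4 = diastole, so
PhysioNet CirCor DigiScope annotation files load directly.

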