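# Methods

This note documents the models, estimators, and design choices behind
`pdnet`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and the numerical decisions a
maintainer would want written down.

## 1. The representation: lag-shifted Pearson correlation images

Every feature series `x` (per-frame acoustic values, per-stroke geometry
values) is expanded into a *signal space* of 50 forward-shifted copies —
copy `k` is `x[k : k + L]` with common support `L = len(x) − 49` — and the
50×50 matrix of pairwise Pearson correlations is rendered as an image
(blue = correlation 0, yellow = 1, linear RGB ramp; negative values are
clipped for display but kept in the CSV). Shifts truncate rather than
wrap: circular shifting would fabricate periodicity at the series length.
The minimum series length is therefore 99 + the minimum support (50),
i.e. 149 samples.

Because each entry `M[i][j]` depends only on the relative lag `j − i`
(up to end effects), the matrix is essentially an image of the series'
autocorrelation function. Two consequences drive many choices below:

* **Scale and level invariance.** Multiplying a series by a constant or
  adding an offset leaves the matrix unchanged. A manifestation that only
  shrinks the *amplitude* of some modulation is invisible unless the
  amplitude falls to the estimator noise floor; a manifestation that
  changes the *timescale or periodicity* of the modulation changes the
  matrix directly.
* **Texture encodes dynamics.** Smooth slow modulation → broad yellow
  band around the diagonal; cycle-to-cycle perturbation → rapid decay to
  blue; quasi-periodic oscillation (tremor) → diagonal banding at the
  oscillation lag.

Composite ("SoC-style") images tile several blocks into one canvas with
region areas proportional to significance weights. The layout is a
deterministic guillotine: blocks sorted by descending weight (ties broken
by name), each block takes a strip across the current region's longer
axis, the last block absorbs rounding remainders, so regions tile the
canvas exactly and per-block area error stays within 2 %. Named recipes
(evenness, legibility, writing-combined, speech-combined) use
rank-proportional weights `w_i ∝ n − i + 1` over their declared
significance order; binary attributes (micrographia, progressive
micrographia, spacing) enter composites as solid panels (yellow =
present, blue = absent); nested composites are rendered and embedded.

## 2. Speech front end

Processing order: Wiener denoising → energy voice-activity detection →
concatenation of voiced samples → 50 ms frames with 50 % overlap
(window = `round(0.05·rate)` samples, hop = `floor(win/2)`, trailing
remainder dropped).

**Wiener filter.** Per 50 ms Hann frame (rounded up to an even length so
the 50 %-overlap-add is exactly unity), gain `H = S/(S+N)` with
`S = max(P − αN, 0)`, `P` the frame periodogram, `N` the noise PSD
(leading 250 ms by default, or a supplied profile), α = 2 (noise
oversubtraction; with α = 1 the expected residual energy of pure noise
filtered against its own PSD is ≈ 22 %, with α = 2 it is ≈ 6 %). Zero
noise PSD gives the identity to machine precision.

**VAD.** 25 ms non-overlapping frames; speech where energy exceeds
0.05 × the 95th-percentile frame energy (scale-invariant by
construction); segments shorter than 50 ms dropped.

**Pitch.** Biased autocorrelation via FFT; peak search in
`[rate/400, rate/60]` Hz with parabolic interpolation. The *biased* form
is used for the lag search (its taper breaks octave ties toward the
shorter period); the reported normalized peak is bias-corrected by
`N/(N−k)` and a frame is voiced when it reaches 0.45. Unvoiced frames
carry NaN and are dropped — never zero-filled — before imaging.

**HNR.** `10·log10(ACp/(1−ACp))` with `ACp` the bias-corrected
normalized autocorrelation peak, clipped to `[1e−6, 1−1e−6]` (≈ ±60 dB).

**Jitter/shimmer.** Glottal epochs by peak picking (minimum distance
0.7/f0, parabolic vertex refinement for sub-sample timing and amplitude);
`jitter_local = 100·mean|ΔT|/mean T` and analogously for amplitudes, over
sliding blocks (defaults: 30 periods, hop 5). When the autocorrelation
voicing decision fails on strongly irregular phonation, a coarse
pulse-rate estimate supplies the f0 hint. Periods outside
[0.55, 1.8] × the nominal period are discarded as octave/spurious marks.

**Formants.** Frames are decimated to ≈ 11 kHz, pre-emphasized (0.97),
Hamming-windowed, and fit with autocorrelation-method LPC of order
`2 + round(rate_eff/1000)`. Roots with bandwidth < 400 Hz above 90 Hz are
resonances; the two lowest are f1, f2. Two gates keep junk out: frames
whose LP prediction gain (signal/residual energy) is below 4 are skipped
(white noise measures ≈ 2, voiced speech ≥ 7), and when fewer than two
strict resonances survive (strong nasal coupling merging f1 with the
nasal pole, or high f0) the bandwidth cap is relaxed 1.5× before
skipping.

**Nasality.** Ratio of 200–500 Hz power to 0–4 kHz power of the
Hann-windowed frame spectrum, on voiced frames.

**Voice breaks.** Every VAD boundary is a transition; around each, pitch
and HNR trajectories over ±5 frames (default) are concatenated —
per transition pitch then HNR, transitions in temporal order — into one
series for imaging.

The six canonical manifestation series are: squared energy
(monoloudness), voiced f0 (monopitch), f2 (articulation), local jitter
(phonation tremor), voiced nasal ratio (hypernasality), and the
transition series (involuntary breaks).

## 3. Handwriting front end

Otsu binarization after affine luminosity/contrast adjustment (Otsu is
invariant to affine intensity shifts; if the dark class is the majority
the polarity is flipped so ink stays the minority class); specks < 9 px
removed. Strokes are 8-connected components; reading order is row-band
clustering (split the sorted centroid rows at gaps > 1.2 × median stroke
height) then left-to-right — a paper scan has no pen timeline, so this is
the only recoverable order. Baselines are centered moving averages
(window 9, symmetric shrinkage at line edges so a linear ramp is
reproduced exactly everywhere) of centroid rows per line.

Slant uses probabilistic Hough segments (seeded, hence deterministic) on
the ink mask, discarding segments shorter than half the median stroke
height or within 20° of the local baseline direction, and reports the
signed angle from the baseline normal in reading order. Flags use
empirical thresholds, all surfaced in output metadata: micrographia
(median height/page height < 0.009 ≈ 2.7 mm on A4), progressive
micrographia (first-to-last-third per-line median height decline > 25 %),
spacing (CV of within-line inter-stroke gaps > 0.9), baseline drift
(peak-to-peak baseline excursion > 1.5 × median height). The uniformity
series is heights normalized by the page median (median ≈ 1 by
construction); the tremor series is the per-stroke RMS residual of the
skeleton path around its moving-average smoothing (window 7 points).
Skeleton paths are ordered by a two-sweep BFS diameter walk, which
handles curved glyphs where a principal-axis projection would fold the
path onto itself.

The moving-average tremor residual is exact only for straight strokes:
on arcs the window's chord bias (sagitta ≈ W²/8r) inflates residuals,
and when the wobble's arc length stretches the path the filter starts
tracking the wobble itself. Recovery tests therefore measure staves
(aspect ratio < 0.45) with wobble wavelength comparable to the smoothing
window; in that regime the RMS residual matches the injected `a/√2`
within a few percent and doubles when the amplitude doubles.

## 4. The classifier

Five convolution blocks with 32→64→128→256→512 filters, ReLU, max
pooling, dropout (0.25); blocks 1–4 use 3×3 kernels with 2×2 pooling,
block 5 a 1×1 convolution with unit pooling (the all-unit-pooling
variant is selectable via `pool_sizes`, at the cost of a very wide
flatten); flatten → dense(64, ReLU) → dense(1, sigmoid). Everything is
float32 numpy with explicit seeded initialization, so a fixed seed
reproduces training exactly on one thread.

Training minimizes binary cross-entropy through the *fused* sigmoid
formulation (gradient `(p − y)/N` w.r.t. the logit). The naive
composition of a sigmoid layer with a probability-clipped BCE is not
just imprecise but unstable here: once outputs saturate, mismatched
clipping produces unbounded gradients and the network permanently
collapses onto the majority class. Adam (lr 1e−3 default), early
stopping on test loss (patience 5 default) with best-weights restore;
optional class-weighted loss (off by default).

Splits are subject-level: a held-out validation cohort (named subjects,
or an automatic pick of ≈ 20 % of each class, at least one subject per
class) plus a greedy 75/25 train/test assignment of the remaining
subjects by image count, **stratified by class** — an unstratified greedy
split can hand the test set an inverted class balance, which silently
inverts the early-stopping criterion. No subject ever straddles splits,
and the manifest checker enforces this.

## 5. The synthetic cohort

The generator exists because the clinical recordings are not available;
it emulates the *statistical structure* of the study cohort (20 patients,
10 controls; class-conditional manifestation presence probabilities
matching the published per-manifestation proportions, e.g. 75 % of
patients with non-uniform writing and none of the controls) with exact
per-subject ground truth. All randomness derives from one seed through
`SeedSequence.spawn`, so cohorts are byte-identical across runs.

**Voices** are source–filter synthesized: a glottal impulse train
(fractional-sample placement) with independent per-period frequency and
amplitude perturbations scaled so the *local* jitter/shimmer equal the
profile targets (`σ = target/1.128`, since `E|ε_i − ε_{i−1}| = 2/√π`),
slow prosodic f0 and intensity modulation (linear interpolation of
Gaussian control points), an optional 5 Hz phonatory tremor modulating
f0, a two-resonator vocal tract whose (f1, f2) targets are drawn from a
schematic vowel triangle (300, 800)–(800, 1200)–(400, 2400) Hz scaled
about its centroid, an additive 280 Hz nasal resonance, deterministic
silence insertions at the break rate, and a −50 dB noise floor. Leading
and trailing 0.35 s silences supply the denoiser's noise estimate and
make every VAD transition a full-context one.

Because of the representation's scale invariance (§1), hypokinetic
manifestations are injected as *timescale* changes with clinical
grounding, not just amplitude changes: monopitch and monoloudness lower
both the modulation depth (18→2.5 Hz f0 sd; 4→0.7 dB) and the inflection
rate (2.5→0.6 Hz); articulatory decay compresses the formant range
(0.95→0.35) and lengthens the vowel dwell (150→450 ms); phonation tremor
adds a 6 % f0 oscillation at 5 Hz, which bands the pitch matrix at the
tremor lag. Voice-break rate: 12/min affected vs 4/min controls.

**Pages** render pseudo-letter glyphs (65 % slanted staves, 35 %
arcs — parametric, so connected-component extraction is unambiguous) on
A4: per-line height schedule decaying by `height_decay_pct` across the
page; per-stroke height variation (`nonuniformity_pct`, half slow
oscillation, half white — slow so it survives Pearson normalization);
perpendicular sinusoidal wobble whose amplitude waxes and wanes across
strokes (wavelength ≈ 8 px along the stroke in cohorts); slant sampled
with a slow drift component; gamma-distributed gaps with the requested
CV; sinusoidal baseline drift. Ground-truth labels use thresholds placed
midway between the affected and normal parameter regimes and mirror the
pipeline's flag definitions.

**What the generator does not emulate:** real phonation (no glottal
pulse shape model, no aspiration noise, no language/phonetics), scanner
artifacts beyond additive grain, letter identity or orthography, pen
pressure/kinematics, and within-session variability of a real writer.
Passing tests therefore demonstrate that the pipeline recovers what it
claims from signals with known ground truth and that the representation
separates the injected pathology — not that the classifier would reach
the same scores on clinical recordings.

## 6. Problem sizes and run conditions

Cohort defaults: 20 s speech at 44.1 kHz per subject, 300-dpi A4 pages
with 11 lines × 25 strokes, three 149-sample windows per feature series
(so three combined images per subject), composites rendered at 64×64.
The cohort pipeline overrides two extraction defaults, recorded in its
config: transition context 10 frames (so every subject's break series
reaches imaging length) and jitter blocks of 12 periods, hop 2 (so 4–7 Hz
tremor modulation survives within-block averaging). The end-to-end
learnability check trains with batch 4, lr 2e−3, ≤ 20 epochs on the
seed-0 default cohort; on the held-out validation subjects it reaches
F1 ≈ 0.91 (speech combined) and ≈ 0.96 (writing combined), with
subject-disjoint splits verified. Validation scores at this cohort size
(6 held-out subjects) are quantized in steps of ~0.04 and noticeably
seed-dependent; robustness across seeds tracks how many informative
manifestations the sampled validation subjects happen to express.

## 7. Known limitations

* The involuntary-breaks correlation block carries little class
  information after windowing: the series is a concatenation of
  per-transition trajectories, so its structure is dominated by the
  deterministic pitch/HNR alternation and the break *count* is lost when
  the series is cut to a fixed window. The break information instead
  reaches the classifier through the composite indirectly (more, shorter
  voiced stretches alter other series).
* The jitter-block series carries phonatory tremor only weakly (the
  mean-absolute-difference statistic rectifies the oscillation); tremor
  cases are mostly detected through the banding they impose on the pitch
  matrix.
* Formant estimates carry a small positive bias (≈ 20 Hz at f1 = 500 Hz)
  from pre-emphasis and finite bandwidth; well within the tolerance used
  for articulation imaging.
* Hough slant yield depends on stroke geometry; pages are validated to
  produce ≥ 149 qualifying segments under all cohort parameter
  combinations, but extreme user-supplied profiles could under-produce,
  in which case the signal-space builder raises with the required length.
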