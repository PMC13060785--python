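# Methods

This note documents the models and procedures implemented in `audscene`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data-based tests do and do not
establish about real data.

## Auditory front ends

**Cochleagram.** The peripheral model is a 211-channel FIR gammatone
filterbank with center frequencies uniformly spaced on the ERB-number
scale between 40 Hz and 24 kHz, applied to 48 kHz audio. The ERB-number
scale uses the Glasberg–Moore formula E(f) = 21.4·log10(1 + 0.00437·f);
filters are 4th-order gammatones of bandwidth 1 ERB (b = 1.019·ERB(f)),
sampled in the time domain, truncated to 25 ms, and peak-normalized to
unit gain at their center frequency. Subbands are half-wave rectified,
compressed with a power of 0.3 (outer-hair-cell compression), lowpass
filtered at 4 kHz and downsampled to the output frame rate with a
Kaiser-windowed sinc filter (width 64 zero crossings, roll-off 0.94759,
beta 14.76965). The middle 2 s of the native 2.5 s input are excerpted to
discard edge artifacts, giving a 211 × 16,000 representation at the
default 8 kHz frame rate, or 211 × 400 at the 200 Hz modulation-pathway
rate.

*Numerical choices.* Filtering runs in single precision by default
(about an order of magnitude faster on typical hardware); the gain-scaling
law c(g·x) = g^0.3·c(x) then holds to ~1e-5 relative. A `dtype` switch
restores double precision (law holds to <1e-6) for precision-sensitive
use. Downsampling by large factors is cascaded through 8 kHz to keep the
anti-aliasing filters short. Negative excursions introduced by the
downsampling filter's ringing are clipped to zero so the representation
stays nonnegative. The channel count is configurable below 211 for
exploratory and test use; all shape-sensitive checks use the full size.

**Spectrotemporal modulation filterbank.** The cortical-stage features
use 2-D modulation filters on the 200 Hz cochleagram, cropped to the
central 1.95 s (390 frames). Spectral scales are
{0.0625, 0.125, 0.25, 0.5, 1, 2} cycles/ERB and temporal rates
{0.5, 1, 2, 4, 8, 16, 32, 64} Hz; each (scale, rate) pair yields an
upward- and a downward-selective filter (96 directional filters), plus 6
purely spectral and 8 purely temporal filters — 110 in total. The exact
analytic kernel family was an open choice: we use separable complex Gabor
carriers (constant-Q, envelope s.d. of one carrier period, truncated at
three s.d.) combined in quadrature, with direction set by the relative
sign of the spectral and temporal carriers; kernels are L2-normalized so
power is comparable across filters. Because cochleagram channels are
uniform in ERB number, cycles/ERB converts to cycles/channel through the
constant channel spacing. Filter outputs are squared and averaged over
time per frequency channel, giving a 110 × 211 (= 23,210-dimensional)
power representation.

## Distortion suite

The 68-condition grid comprises the original plus eleven families
(highpass/lowpass/bandpass Butterworth filtering, tempo change,
reverberation, local time reversal, peak clipping, noise vocoding, and
spectral/temporal modulation lowpass filtering) at the level values listed
in `audscene.distortions`. Every output passes a common post-chain:
truncation/padding to 1 s, 10 ms half-Hanning onset/offset windows, RMS
normalization to 0.01.

Open choices, as implemented:

- **Peak clipping** thresholds at the stated quantile of *absolute*
  amplitude, clipping magnitudes and preserving sign. This yields a
  monotone severity series from percentile 0.98 (mild) to 0 (extreme).
- **Vocoder**: 64 ERB-spaced gammatone analysis bands are grouped into
  contiguous channels of equal ERB span; Hilbert envelopes per channel;
  envelope division is guarded by an epsilon of 1e-8 × the maximum carrier
  envelope. The carrier is seeded Gaussian noise passed through the same
  channels.
- **Reverberation**: impulse responses are synthesized by passing pink
  noise through 32 cochlear subbands, imposing per-band exponential decay
  envelopes 10^(−3t/RT60(f)), and summing. RT60(f) equals the nominal
  value up to 4 kHz and shrinks linearly on a log-frequency axis to 0.5×
  at 20 kHz (a configurable stand-in for the faster high-frequency decay
  of real rooms). A direct impulse is prepended 5 ms before the tail and
  scaled so the direct-to-reverberant energy ratio matches the nominal DRR
  exactly; RT60 is verified by Schroeder backward integration of the tail.
- **Tempo** uses a WSOLA implementation with 25 ms Hann frames, 50%
  overlap, and a ±10 ms cross-correlation search for the best-aligned
  analysis frame; pitch is preserved, duration scales as 1/factor.
- **Modulation lowpass** filters the magnitude spectrogram's 2-D Fourier
  transform along the spectral (cycles/kHz) or temporal (Hz) modulation
  axis with a raised-cosine edge reaching zero at 1.4× the cutoff, then
  resynthesizes by alternating-projection phase recovery (≤50 iterations,
  initialized with the input's phase, stopping when the relative
  spectrogram change falls below 1e-4).

## Scenes

Sources are excerpted to their first second (onset preserved), windowed
with 10 ms half-Hanning ramps, RMS-equalized to 0.01, onset-jittered
uniformly in [0, 1] s at sample resolution, and summed, so mixtures span
up to 2 s; scene sizes are uniform on {1..5} with no category repeated
within a scene. Experiment-mode mixtures are RMS-normalized to 0.01.
Training mode replaces the plain sum with a monaural room simulation:
each source is attenuated by 1/distance (distance uniform in [1.4, 29] m
— the attenuation law was unspecified and inverse-distance is the
physical default), convolved with a synthesized impulse response, tagged
with a direction drawn from the 504-point grid (72 azimuths × 7
elevations), and padded to 2.5 s. The per-source RMS reference before
summation (0.01, the same as the final target) is a documented
convention.

## Trial design

Experiment-1 plans contain 408 trials in four blocks of 102; each block
probes each of 51 categories twice, present exactly once, with scene size
uniform per trial. Experiment-2 plans partition the 68 × 51 = 3,468
condition grid over 17 participants of 204 trials using the balanced map
participant = (distortion + category) mod 17, composed with seeded random
relabelings of distortions, categories and participants. This satisfies
the per-participant quotas (each distortion 3×, each category 4×) by
construction for every seed, which we preferred to a retry-based random
search with the same constraints. Half of each participant's trials are
randomly designated target-present; a complementary set of 17 inverts the
flags so every set of 34 covers each condition once present and once
absent. Exclusions: more than one failed headphone-check trial, or below
70% catch-trial accuracy (exactly 70% is retained).

## Signal-detection and reliability statistics

d′ = Φ⁻¹(H) − Φ⁻¹(FA), with rates of 0 or 1 replaced by 1/(2N) and
1 − 1/(2N) (the correction used was unspecified; this is the standard
one). Graded model scores are converted criterion-free via the rank AUC
(ties ½) and the equal-variance Gaussian identity d′ = √2·Φ⁻¹(AUC), with
AUC clamped to [1/(2n), 1 − 1/(2n)] before inversion. Per-condition human
d′ pools hit/FA counts across included participants (pooling vs.
averaging was unspecified; pooling is the lower-variance choice).

Split-half reliability correlates condition-wise aggregates across halves
of participants (or trials), Spearman by default, and is Spearman–Brown
corrected to the full sample; noise ceilings are geometric means of the
two reliabilities. The exact permutation test enumerates all C(10,4)
subsets with the mean-difference statistic T = mean(outside) −
mean(inside); when the designated values are the extreme set this reduces
to the "all four lowest" event (p = 1/210 ≈ .0048). A strict indicator
statistic is available as an option. Sample-size extrapolation subsamples
the pilot at each grid size, takes a pessimistic percentile (20th by
default) of the resampled reliabilities, fits a Spearman–Brown-form curve
and solves it for the criterion.

## Baseline recognition models

The baselines are independent per-category sigmoid readouts on a fixed
front end, trained with summed per-category binary cross-entropy and Adam
(lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-7, batch 32; the tests and examples use
larger learning rates appropriate to their much smaller feature spaces).
Weights initialize to zero-mean Gaussians (s.d. 0.01, seeded) with zero
biases; 10% of scenes are held out for validation; validation loss is
checked once per pass through a tenth of the training data and training
stops after 3 checks without improvement. Benchmark evaluation groups
probe trials by condition (scene size, category, or distortion) and
computes d′ per group from the AUC of probed-category scores; the harness
accepts any external score table, so models outside this package can be
evaluated identically.

## Voxelwise encoding and RSA

Each voxel's time-averaged response is predicted from time-averaged stage
features by ridge regression, w = (XᵀX + nλI)⁻¹Xᵀy, with X columns and y
demeaned on the training set only and columns deliberately not
norm-scaled (non-isotropic prior). λ is selected per voxel by
leave-one-out cross-validation over the training sounds on the grid
1e-50 … 1e49 (100 powers of ten); LOO residuals use the hat-matrix
identity e/(1−h), exact when the penalty nλI is held fixed at the full
training size, which is the convention adopted. Splits divide the sound
set into ⌈n/2⌉ training and the remaining test sounds (83/82 for 165).
Test-set Pearson correlations are zeroed when negative or when the
prediction is constant, squared, and corrected for attenuation by the
product of (a) the voxel reliability — Spearman–Brown-corrected median
pairwise scan correlation on the test sounds — and (b) the prediction
reliability — the analogous quantity over predictions from models fit on
single-scan training responses (re-using the λ selected on the
scan-averaged response). Both reliabilities are floored at the one-tailed
p < .05 critical Pearson r for their sample sizes (0.182 at n = 83, 0.183
at n = 82); corrected values above 1 are clipped to 1.

Model-level aggregation selects each voxel's best stage on a random half
of the splits and scores the held-out half (median), averaged over 10
repeats, then medianed across voxels within participant and averaged
across participants — avoiding the winner's-curse inflation of selecting
and scoring on the same splits. RSA uses representational dissimilarity
matrices (1 − Pearson r across units between sound pairs; Euclidean
available) with the same split discipline: best stage by Spearman ρ on
training-sound RDMs, scored on test-sound RDMs, median over splits, mean
over participants. All voxels are pooled into a single RDM per
participant.

## Synthetic data: what it does and does not show

Category exemplars are band-limited Gaussian noises (frequency-domain
construction, so out-of-band energy is negligible) mixed with a 4-harmonic
stack at half the center frequency and amplitude-modulated at the
category's AM rate (depth 0.9). Prototypes tile log-spaced center
frequencies 250–8000 Hz with bandwidth 0.5·cf, AM rates cycling through
{0, 2, 4, 8, 16, 32} Hz and harmonic weights {0, 0.3, 0.7}, so categories
differ in both spectral and temporal structure; exemplar jitter (default
0.1) perturbs center frequency and bandwidth multiplicatively in log space
and AM rate additively, with exemplar 0 kept as the unperturbed prototype.
The default bank mirrors the benchmark's 51-category label space.

Synthetic voxel sets are exact linear readouts of a chosen stage's
features plus independent Gaussian scan noise, with the ground-truth
weight matrix retained.

These generators support ground-truth recovery tests (corrected R² → 1,
permutation controls → 0, scene-size monotonicity of d′). They do not
emulate natural sounds' temporal syntax, harmonicity profiles, or
co-occurrence statistics, nor fMRI's voxel correlation structure and
nonlinearity; passing tests therefore validate the *machinery* — feature
extraction, distortion operators, designs, statistics — not claims about
human or cortical behavior on real recordings.

## Problem sizes used in tests

The test suite runs the full pipeline at reduced scale, chosen as the
smallest sizes at which the qualitative effects are stable: the scene-size
test uses a 51-category bank with 4 exemplars, 600 training scenes, a
48-channel cochleagram at a 200 Hz frame rate with time-averaged features,
and 70 evaluation scenes per scene size; encoding-recovery tests use 165
synthetic sounds, 20–25 voxels, 3 scans and 5 splits. The full-resolution
representations (211 channels, 8 kHz frames, 110-filter modulation bank)
are exercised where dimensions themselves are the claim.
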