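# Methods

## Overview

`mwppg` implements an image-based, multi-wavelength photoplethysmography
(MWPPG) pipeline for cuffless blood-pressure estimation.  A subject's
fingertip PPG is recorded simultaneously at four LED wavelengths
(660/730/850/940 nm, Channels 1–4) at 200 Hz for 60 s, with one cuff
reference (SBP, DBP) per recording.  The pipeline band-pass filters each
channel (0.5–8 Hz Butterworth, order 2, zero-phase), z-scores it, cuts all
four channels simultaneously into 5 s windows sliding by 1 s (56 windows
per minute), renders each window as a continuous-wavelet-transform (CWT)
scalogram image with the first-order complex Gaussian wavelet ("cgau1"),
maps each wavelength's scalogram to an RGB image through a fixed
colormap, stacks the four RGB images depth-wise into one H × W × 12
tensor, and regresses (SBP, DBP) jointly with an attention CNN +
bidirectional LSTM trained with Adam (learning rate 0.001) on the mean
absolute error.

Three input layouts mirror the experiment structure: Trial 1 uses one
wavelength's 3-channel image; Trial 2 feeds the four RGB images through
four weight-independent convolutional branches whose per-step features
are concatenated before the recurrent stage; Trial 3 feeds the fused
12-channel tensor through a single stack.

## Continuous wavelet transform

Coefficients follow the standard L2 convention

    WT_x(a, b) = |a|^{-1/2} ∫ x(t) ψ*((t − b)/a) dt,

discretised on the sample grid with the scale `a` in samples (the
PyWavelets convention; pseudo-frequency = f_c · f_s / a).  The transform
is evaluated by FFT cross-correlation with the sampled wavelet, which
matches a brute-force Riemann-sum evaluation of the integral to machine
precision; the test suite keeps that brute-force path as an independent
oracle and additionally cross-checks against PyWavelets' `cwt` (looser
tolerance, since its internal quadrature is coarser).

Numerical choices:

* **Centre frequency.** The "cgau1" spectrum |ω|·e^{−(ω−1)²/4} peaks at
  ω = 2, i.e. f_c = 1/π ≈ 0.3183.  The package locates f_c from a
  zero-padded FFT of the sampled wavelet rather than a coarse grid.
* **Scale grid.** 65 logarithmically spaced scales whose
  pseudo-frequencies span the 0.5–8 Hz filter passband — 16 scales per
  octave over 4 octaves, which puts the octave frequencies 0.5, 1, 2, 4
  and 8 Hz exactly on the grid.  Matching the passband avoids empty rows.
* **Scalogram rows.** The *image* uses amplitude (L1) row scaling,
  |WT|/√a, the usual display convention: a constant-amplitude tone then
  has scale-independent intensity and peaks at the scale matching its
  pseudo-frequency.  The complex wavelet's magnitude (not real part or
  squared magnitude) is used.
* **RGB rendering.** Per-window min–max normalisation to [0, 1] (hence
  invariance to positive rescaling of the window), the perceptually
  uniform `viridis` colormap, and bilinear resizing with no anti-aliasing
  (a fixed, bit-reproducible convention).  Default image size is 64 × 64
  (desk-scale experiments use 32 × 32).

## The regressor

Each conv block is convolution (3 × 3, stride 1, same padding) → batch
normalisation → SELU → squeeze-and-excitation channel attention → 2 × 2
average pooling.  The channel-attention description ("compute per-channel
importance scores from global information, then re-weight the feature
maps") is realised as squeeze-and-excitation: global average pool, a
bottleneck dense pair with reduction ratio 8, and a sigmoid gate, so every
channel weight lies strictly in (0, 1).  The "self-normalising" activation
is SELU, whose defining property is self-normalisation.

The CNN→recurrent bridge reads the final feature map's width axis as the
time sequence (scalogram columns are time steps) with height collapsed by
average pooling, giving one feature vector per step.  A two-layer
bidirectional LSTM follows, its outputs averaged over time, then two dense
layers emit (SBP, DBP) jointly.  Targets are standardised internally with
training-set statistics; predictions are returned in mmHg.

The network, its backpropagation and the Adam optimiser are implemented
in a compact numpy layer library (`mwppg.nn`), verified against finite
differences in the test suite.  Default sizes (conv widths 32/64/128,
LSTM hidden 128) stay under 2M parameters; the desk-scale preset
(16/32/64, hidden 48) has ≈130k.

## Training protocol

The window-level dataset is split 80/20; 10-fold cross-validation runs on
the training portion for assessment, the model is refit on the full 80%
and scored once on the untouched 20%.  The split is a pure function of
subject ids and the seed, so the four wavelength views of one cohort
receive identical index sets.  By default the split is **record-level**
(subject-disjoint): the 56 overlapping windows of one subject would
otherwise leak across the partition; `split_level="window"` preserves the
permissive alternative for comparison.  Optimiser Adam, learning rate
0.001, MAE loss; early stopping is off.  Epochs and batch size are
config-owned (desk preset: 60 epochs, batch 32, 2 folds).

## Evaluation

Errors are predicted − reference, in mmHg.  SD uses the *population*
form (divide by n), which makes RMSE² = ME² + SD² an exact identity —
the form under which published result tables of this kind are internally
consistent (e.g. √(0.58² + 8.72²) = 8.74).  R² is the standard
1 − SSE/SST with SST about the mean of the reference values.  The AAMI
verdict is |ME| < 5 mmHg and SD < 8 mmHg (strict).  BHS grading uses
cumulative percentages of |error| ≤ 5/10/15 mmHg with inclusive
thresholds — A = (60, 85, 95), B = (50, 75, 90), C = (40, 65, 85), D
otherwise.  Bland–Altman limits of agreement are ME ± 1.96·SD.

## Synthetic cohort generator

Real four-wavelength recordings cannot ship with the package, so the
generator emulates the acquisition protocol's statistical structure:
200 Hz, 60 s, four channels with correlated beat morphology, per-channel
amplitude gains, baseline wander (0.1–0.3 Hz) and white sensor noise,
and one (SBP, DBP) label pair per subject.

Each beat is a two-Gaussian pulse: a systolic wave plus a delayed
dicrotic wave.  Per subject, the latent draw is heart rate HR, base
dicrotic-to-systolic ratio d, notch delay, Gaussian widths, and a
*dicrotic gradient* s; channel k (0-based) renders dicrotic ratio
d·(1 + s·k), emulating deeper optical penetration at longer wavelengths.
Labels are a fixed affine link plus Gaussian noise (default SD 2 mmHg):

    SBP = 52 + 0.5·HR + 30·d + 100·s − 30·notch_delay + ε
    DBP = 0.55·SBP_det + 12 + ε′

The gradient s deliberately carries the largest share of label variance:
any single channel observes only the product d·(1 + s·k) and therefore
confounds d with s, while the four channels jointly identify both — this
is what gives fusion a genuine, structural information advantage over
every single wavelength, and it makes the parameter-recovery experiments
well-posed.  A configurable fraction of subjects (default 0.3) is
hypertensive (SBP ≥ 130 or DBP ≥ 90 mmHg); the two classes draw HR, d and
s from shifted sub-ranges and morphology is rejection-sampled until the
realised labels match the intended class.  One RNG stream per subject is
derived from (seed, subject index), so each record is reproducible
independent of cohort size.

What the generator does **not** emulate: real hemodynamics and
pulse-shape families, motion artifacts, arrhythmia, sensor drift,
between-session variability, or any true physiological coupling between
wavelength and blood pressure.  The wavelength gradient and the affine
label link are declared constructions.  Consequently, passing the
desk-scale experiments demonstrates that the pipeline's machinery —
preprocessing, fusion, architecture, protocol, metrics — can recover
structured multi-channel information end to end; it says nothing about
accuracy on real patients.

## Desk-scale problem sizes

The package's own experiments run at: 60-subject cohorts (24 for the
fusion-vs-single comparison), 14 windows per subject (10 for the
comparison), 32 × 32 images, the reduced-width model, 60 epochs (40 for
the comparison), 2 CV folds, one CPU.  These sizes are the package's
declared desk-scale conditions for the synthetic experiments.

## Degenerate inputs and tie-breaks

Constant signals cannot be z-scored (explicit degenerate-input error);
an all-equal scalogram renders as the uniform colormap(0) image; BHS
grading of an empty error set is an error; quality screening may reject
every window of a record, which is reported in the drop log rather than
raised.  A window is dropped for *all* channels if *any* channel violates
a quality rule, preserving four-channel alignment.

## Known limitations

* The reported full-scale accuracies of this method family require the
  real 162-subject recording set and full-scale training; the package's
  synthetic desk-scale results are not comparable to them.
* Quality-rule thresholds (flatline fraction, amplitude z-limit,
  autocorrelation periodicity) are pragmatic defaults, not validated
  against annotated artifact data.
* The numpy network trains on one CPU at desk scale only; there is no
  GPU path.
* Whether normalisation precedes or follows windowing, and the exact
  abnormal-segment rejection criteria, are open choices in this method
  family; both are configurable here (defaults: normalise per record
  after filtering, before windowing).
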