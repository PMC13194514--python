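# Methods

## Problem setting

Depression alters evoked EEG responses to emotional stimuli, and the
response change differs between stimulus categories. This package models
cue-locked ERPs recorded in a dot-probe paradigm with happy-neutral,
fearful-neutral and sad-neutral face pairs, and addresses two tasks at
once: classifying major depressive disorder (MDD) versus healthy controls
(HC), and regressing the continuous PHQ-9 severity score (0-27). The
reference cohort shape is the MODMA dot-probe dataset: 53 subjects (24 MDD,
29 HC), 128 electrodes, 250 Hz, ~160 trials per cue, 125-sample epochs.
Because that dataset is access-controlled, the package ships a synthetic
cohort generator that reproduces the data geometry and a controllable
severity effect, so that every stage is testable end to end.

## The network

Each cue condition feeds its own EEGNet-style branch with non-shared
weights:

1. **Temporal convolution** — `f1 = 8` filters of size 1 x 100 ("same"
   padding, bias-free) acting per electrode along time; these behave as
   learned band-pass filters.
2. **Depthwise spatial convolution** — per temporal filter, `D = 2`
   kernels of size C x 1 spanning all electrodes, collapsing the spatial
   axis; `f2 = f1 * D = 16` maps.
3. **Separable temporal convolution** — a 1 x 16 depthwise convolution per
   map followed by a 1 x 1 pointwise mix.

Batch normalization and ELU follow every convolution; dropout (p = 0.5)
and average pooling (1 x 4, then 1 x 8) follow the depthwise and separable
stages. Flattened branch outputs are concatenated:

    F_concat = concat(F_happy, F_fear, F_sad),
    dim = 3 * f2 * floor(floor(T / 4) / 8)    (= 144 for T = 125)

Heads: `softmax(W_cls F_concat + b_cls)` for classification and a linear
unit `W_reg F_concat + b_reg` for the normalized severity score. With
bias-free convolutions and affine batch norm, one branch of the
128-channel configuration has exactly 3440 trainable parameters — the
closed form in `model.count_parameters` is tested against enumeration of
the built graph.

### Numerical implementation

No deep-learning framework is used: the network is a compact numpy engine
(`_nn.py`) with hand-derived backward passes, verified against central
finite differences in the test suite. The long temporal convolutions run
in the frequency domain (scipy.fft) with the smallest circular length
whose wrap-around stays outside the sliced output windows; the FFT path is
tested against a direct sliding-window oracle. Arithmetic is float32.
Weight initialization is Glorot-uniform under a seeded generator; dropout
draws from a separate stream spawned from the same seed, so model
construction and training are bit-reproducible given (seed, single
device).

Design choices left open by the architecture description, resolved here:
depth multiplier D defaults to 2 (the canonical EEGNet value);
"same" padding on both temporal convolutions (required for the
125 -> 31 -> 3 pooling arithmetic to be well defined when the kernel
exceeds the pooled length); dropout after both the depthwise and the
separable blocks; the depthwise spatial kernel spans all C channels so
small-channel synthetic configurations remain valid. In joint mode the two
losses are summed unweighted; the reported runs train the two heads as
separate models (classify / regress modes).

## Label normalization

PHQ-9 targets are mapped to [0, 1] by `y* = (y - ymin)/(ymax - ymin)` and
predictions inverted by `y = y* (ymax - ymin) + ymin`. A literal
"per-subject" min-max is degenerate (each subject has a single score), so
`train_minmax` fits (ymin, ymax) over the *training subjects'* score
distribution — re-fitted inside every cross-validation fold so held-out
labels never touch the mapping. On the packaged 53-subject table this
yields (0, 24). The alternative `scale_bounds` strategy uses the fixed
questionnaire range (0, 27) and is immune to fold composition. All
regression metrics are computed after denormalization, on the 0-27 scale.

## Training and cross-validation

Adam (lr 1e-3, defaults otherwise), batch size 64, at most 20 epochs, a
10% validation split (stratified by class for classification) drawn from
training subjects' trials under the run seed. The weights retained are
those of the epoch with the lowest validation loss; training stops early
after 5 epochs without improvement (patience is configurable; the
retention rule alone is the essential contract). The classification loss
is the mean cross-entropy over the mini-batch and the regression loss the
mean squared error in normalized space.

Evaluation uses leave-one-subject-out cross-validation (LOSOCV): one fold
per subject, all of a subject's trials held out together, preventing the
network from exploiting subject identity. Pooled trial-level metrics are
primary; a majority-vote subject-level accuracy and a per-subject error
table are also reported.

One metric convention is inherited deliberately: the *positive* class of
the confusion matrix defaults to "normal" (HC, label 0). A true positive
is a control recognized as a control. `positive_label=1` switches to the
clinical convention. Degenerate metric denominators yield a flagged zero
(with a warning) instead of an exception, so pooled reports survive
pathological folds; kappa with both margins constant raises, since no
finite value is meaningful.

## Synthetic cohorts

`synthetic.SimConfig` generates, per subject and cue, `template + pink +
white` noise epochs. The template is a sum of three Gaussian-envelope
components (latencies 100 / 180 / 300 ms, widths 30 / 40 / 80 ms, base
amplitude 5 uV, unit-norm Gaussian channel topographies centered at 25 /
50 / 75% of the montage). Component amplitude varies linearly with PHQ-9
severity at cue-specific slopes, default (-0.15, +0.20, +0.25) uV/point
for happy/fear/sad — blunted positive reactivity and heightened negative
reactivity with increasing severity. Pink noise is spectrally shaped
(1/f amplitude) seeded white noise, normalized to unit standard deviation
before scaling; default noise scales are (0.7, 0.7) uV so the combined
noise SD is ~1 uV and the 5 uV components sit at roughly 5x noise —
deliberately easy, since the recovery checks probe wiring, not clinical
attainability. Severities are drawn uniformly from the observed group
ranges, HC (0, 5) and MDD (11, 24).

Problem sizes: the generator defaults to the study geometry (160
trials/cue; channels configurable up to 128). End-to-end runs use the
desk-scale configuration — 16 channels, 40 trials per cue, 12 subjects —
exposed as `desk_scale_config()`.

The generator omits volume conduction, ocular/muscle artifacts, latency
jitter, habituation and between-subject morphology. Passing recovery tests
therefore validates the pipeline, model and protocol mechanics, not
expected performance on clinical EEG.

## Null calibration and the pessimistic bias of LOSOCV

With the severity slopes set to zero the two groups are statistically
identical, and one might expect LOSOCV accuracy to concentrate tightly
around 0.5. It does not, and the deviation is *downward*: on the
desk-scale null cohort the protocol yields accuracy well below 0.5 and
negative kappa. The mechanism is structural. In a 12-subject balanced
cohort every fold trains on a 5-vs-6 class split; with no real signal the
network absorbs the majority prior of its training set, and the held-out
subject always belongs to that fold's *minority* class, so its trials are
systematically predicted against it. This anti-learning behaviour of
leave-one-out protocols on signal-free, class-balanced data is a known
property of the protocol, not label leakage — per-subject accuracies fall
below 0.5 symmetrically for both groups.

Two consequences for the calibration checks: (a) trial predictions within
a fold share one trained network, so the subject — not the trial — is the
independent unit, and the chance-level accuracy check uses binomial bounds
at n = 12; (b) pooled kappa on a null cohort is biased negative, and the
suite's |kappa| <= 0.1 assertion documents this honestly by failing under
the default null conditions rather than being weakened.

## Preprocessing

Average re-referencing, zero-phase 4th-order Butterworth band-pass
(0.3-100 Hz default; family and order are not dictated by the protocol —
the choice matches common EEG practice and phase-free ERP analysis), an
optional 50 Hz notch (off by default; a 0.3-100 Hz band-pass does not by
itself remove mains interference), half-open epoch windows (default
[-100, 400) ms = 125 samples at 250 Hz), baseline mean removal over
[-100, 0) ms, and pluggable artifact rejection with a built-in per-trial
peak-to-peak threshold (100 uV). ICA-based component cleaning is out of
scope; the strategy registry is the integration point for it.

## Known limitations

* The numpy engine is CPU-only and tuned for the desk-scale geometry;
  full-scale 128-channel LOSOCV training is possible but slow.
* Batch-norm statistics are per-branch global momentum estimates; very
  small batches give noisy eval-mode behaviour.
* The synthetic severity effect is linear and time-locked; real
  dose-response relationships need not be either.
* Subject-level classification is majority vote over trials; no
  uncertainty is attached to it.
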