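# Methods

## Problem and pipeline

`acticam` implements an end-to-end analysis that classifies a driver's
recent *sitting history* (a full workday seated vs sitting broken up by
3-min treadmill walks every 30 min) and *sleep history* (9-h vs 5-h
nightly sleep opportunity) from raw 20 Hz triaxial accelerometry recorded
by a thigh-worn monitor during 20-min simulated drives. The pipeline has
four phases: cohort simulation (data collection stand-in), CNN training,
CNN evaluation, and class activation mapping (CAM). Because the underlying
laboratory recordings are not publicly distributable, the package includes
a first-class synthetic cohort generator that reproduces the study design
and the qualitative movement signatures the classifiers must detect; all
statistical and architectural machinery operates identically on real CSV
exports of the same dialect.

## Synthetic cohort generator

**Design.** A 2x2 between-subjects factorial: activity {sitting, breaking
up sitting} x sleep {9-h, 5-h}, with default cell sizes 22/22/20/20
(84 participants). Each participant contributes two 20-min drives
(pre-shift 08:10, post-shift 17:30) on each of 5 experimental days — ten
drives in total — sampled at 20 Hz on a +-4 g scale.

**Signal model.** Each drive is the sum of four components:

1. *Gravity baseline.* The 1 g gravity vector projected onto body-fixed
   axes (x along the thigh, y mediolateral, z perpendicular to the
   anterior surface) by the thigh's pitch and roll:
   g = (sin p, cos p sin r, cos p cos r). A horizontal thigh with the
   device facing up reads (0, 0, 1). The projection has unit magnitude by
   construction wherever no event or noise is active.
2. *Pedal-movement bursts.* Onsets follow a Poisson process
   (default 8 events/min). Each burst is a sin^2-enveloped oscillation
   (default duration 0.8 s, frequency 1–2.5 Hz, amplitude ~|N(0.6, 0.2)| g)
   on the longitudinal axis with fixed-ratio coupling (0.35, 0.45) onto
   y and z. Inactivity bouts (default probability 0.3 per minute)
   redistribute events away from quiet minutes without thinning them, so
   the per-drive count remains exactly Poisson(rate x duration).
3. *Postural shifts.* A second Poisson process (default 0.5/min) of slow
   smoothstep ramps (2 s) that re-project the gravity baseline by
   N(0, 8 deg) pitch changes, plus a per-drive settling offset. When the
   shift rate is zero no posture randomness is drawn at all, so a
   zero-rate, zero-noise configuration produces the exact constant
   gravity projection.
4. *Sensor noise.* Additive white Gaussian noise (default sd 0.02 g).
   All samples are clipped to the +-4 g device range.

**Class structure.** Two non-negative effect sizes scale the separation
continuously; at zero both factors modulate nothing, making the
class-conditional distributions identical by construction (this exact
identity is enforced by short-circuiting the modulation, not by relying
on floating-point cancellation). With effect size e:

* activity — the resting thigh pitch mean separates as 15 +- 6e degrees
  (individual scatter sd 5 deg), and the postural-shift rate is multiplied
  by (1 + 0.8e) for the sitting class and divided by it for the
  breaking-up class (post-sitting restlessness vs recently-active calm);
* sleep — the 5-h class trades movement frequency for size and
  abruptness: event rate / (1 + 0.6e), amplitude x (1 + 0.8e) (capped at
  3 g), duration / (1 + 0.5e), inactivity probability
  1 - (1 - p0)^(1+e); the 9-h class moves more often at *unchanged*
  amplitude with less quiet time (rate x (1 + 0.6e), inactivity
  p0 / (1 + e)). The 9-h amplitude is deliberately not scaled down:
  shrinking it toward the noise floor would make the full-sleep class
  confusable with the quiet spells of the short-sleep class and
  separability would no longer grow monotonically with effect size.

Individual variation enters as per-participant lognormal multipliers
(sd 0.15 on event rate and amplitude, 0.2 on noise) and posture scatter,
so participants are identifiable from their signals — which is exactly why
split granularity matters below.

**Metadata.** Each participant receives a simulated mean total sleep time
per night (9-h class N(8.0 h, 40 min); 5-h class N(4 h 34 min, 18 min))
and a mean daily step count (sitting N(1231, 661); breaking-up
N(7016, 742)). A ground-truth verification step runs Welch two-sample
t-tests on both, mirroring the protocol's actigraphy/step-count
manipulation checks; on the default cohort both reject at p < 0.05.

**What the generator does not emulate.** Vehicle vibration and inertial
forces, steering-related movement, treadmill-walking segments outside the
drives, wrist actigraphy waveforms, clock drift, and any psychomotor
coupling between fatigue and driving performance. Passing tests therefore
demonstrate that the pipeline detects the encoded class structure under
controlled conditions, not that these effect sizes match real drivers.

## Data preparation

Raw CSVs (`time,x,y,z`, ISO-8601 ms timestamps) are parsed with strict
monotonicity and uniform-spacing checks. A configurable mapping
(`identity` or `linear(offset, gain)`) scales raw counts to g; values
beyond +-4 g are clipped with a logged count. Drives are isolated by
cross-referencing manifest start times against the time column; a slice
is the first sample at or after the start plus round(duration x rate)
samples (half-open, 0-based).

Task-specific exclusion: for sitting-history classification the pre-shift
drive of experimental day 1 is dropped (the activity manipulation had not
yet begun); for sleep-history it is kept (the first manipulated night
precedes it).

Windows of 4096 samples (~200 s; 512 at smoke scale) are cut from each
drive. Evaluation uses a deterministic fixed-stride enumeration (default
stride 1024). Cross-validation offers two granularities:

* `window_level` (default, matching the shuffled-window 80/20 regimen):
  the enumerated windows are shuffled and partitioned into k=5 folds.
  Epochs resample training windows uniformly from the fold's training
  pool — never from held-out windows, although overlapping neighbours of
  held-out windows can be trained on, and every participant appears on
  both sides of the split.
* `participant_level`: whole participants are assigned to folds
  (stratified by label, dealt as contiguous chunks of a class-interleaved
  shuffle so each validation fold covers both classes), and training
  windows are sampled at genuinely random offsets from training
  participants' drives. No participant ever spans both sides.

## Architectures

Both networks map a (3, L) window to a single pre-sigmoid logit and end
in global average pooling followed by one linear layer — the structural
prerequisite for CAM.

* **DixonNet**: conv(3→100, k16) + ReLU, conv(100→100, k16) + ReLU,
  max-pool(4), two more identical convolutions, GAP, dropout (p = 0.5),
  linear(100→1). Convolutions are length-preserving (same padding) so the
  last-conv map has length L/4 and CAM positions align with input samples
  by a constant factor of 4; valid padding is configurable. There are no
  normalization layers, which fixes the trainable parameter count at
  485,301 = (100·3·16+100) + 3·(100·100·16+100) + (100+1).
* **1D ResNet-18**: the standard 18-layer residual design with 1D
  convolutions — stem conv(3→64, k7, stride 2) + batch-norm + ReLU +
  max-pool(k3, stride 2, pad 1), then four stages of two basic units
  (two k3 conv+BN layers each) with 64/128/256/512 filters, stride-2
  transitions with 1x1 projection shortcuts, GAP, linear(512→1). At
  L = 4096 the last-conv map is 512 x 128
  (4096 → 2048 → 1024 → 1024 → 512 → 256 → 128). An abbreviated
  one-unit-per-stage variant (`resnet10_1d`) is available for comparison.

The engine is a self-contained NumPy implementation (per-tap BLAS
convolutions, explicit backpropagation, Adam); every layer's analytic
gradient is verified against central finite differences in the test
suite, and both architectures' parameter counts are checked against
independent layer-by-layer arithmetic.

With a single-logit binary head, a softmax over the two class scores
{z, 0} reduces to a sigmoid on z; the head is therefore evaluated as
sigmoid(logit) >= 0.5. For CAM, the positive class uses the head weights
w and the negative class -w.

## Training

Binary cross-entropy (numerically stable form), Adam (standard betas and
epsilon) stepping once per 64-window batch, initial learning rate 1e-4.
The learning rate is divided by 10 whenever the mean epoch training loss
fails to improve by more than 1e-4 (an explicit tolerance; none is
inherent to the rule) for 10 consecutive epochs. Training ends at
`max_epochs` (default 100) or when a reduction would cross `min_lr`
(default 1e-7). Epoch size defaults to
n_drives x (drive_samples // window_length) sampled windows. Accuracy,
F-score (harmonic mean of precision and recall, defined as 0 when
precision + recall = 0) and the 2x2 confusion matrix are computed per
fold on the fixed-stride validation windows; cross-validation reports
mean +- SD over the 5 folds, with per-window scoring (drive-level
aggregation is available separately).

## Class activation mapping

With S_k(x) the last-conv activation of channel k at position x, pooled
features f_k = mean_x S_k(x), and head weights w_k, the class score is
g = sum_k w_k f_k (equal to the logit minus the bias) and the map is
M(x) = sum_k w_k S_k(x). The mean pooling convention (rather than an
unnormalized sum) matches the pooling layer actually used; it rescales
w_k uniformly and changes neither classification nor the map's shape.
M is linear in both S and w, and mean_x M(x) = g exactly — both
identities are asserted in tests, alongside exact agreement with an
element-wise brute-force loop.

Maps are stretched to window length by linear interpolation (nearest-
neighbour optional), windows are ranked by |logit| (ties broken by drive
and offset for determinism), and the five highest- and five lowest-
magnitude *correctly classified* windows per predicted class are rendered
as three stacked panels (x, y, z), each spanning its channel mean
+- 0.5 g (a constant 1-g scale), with line colour encoding the per-window
min-max-normalized CAM (a constant map renders at the colour midpoint).

## Scaled-down validation study

The acceptance checks run the full pipeline on a reduced cohort chosen to
fit a single CPU: 8 participants (2 per cell), 2 experimental days, 2-min
drives, 512-sample windows, 10 training epochs, learning rate 1e-3 with
192–384 sampled windows per epoch. The larger step size is the package's
scaling choice for the smaller problem; the full-scale defaults remain
lr 1e-4 / window 4096, and the plateau schedule is unit-tested at those
values.

* **Null calibration** (both effect sizes 0) uses participant-level k=2
  folds pooled so each participant is validated exactly once. Held-out
  window predictions cluster strongly within participants — a CNN logit
  is dominated by each participant's posture baseline — so the 99%
  binomial band around 50% is computed over the independent units (the 8
  participants, giving [12.5%, 87.5%]), not over the correlated windows.
  Window-level splitting is not used here because, under the null, it
  would let the network recover labels by memorizing participant
  identity.
* **Class recovery** (both effect sizes 3) uses the window-level regimen
  and requires >= 90% validation accuracy from both architectures on the
  sleep task (the harder signature). A three-point effect-size sweep
  (0.25, 1.0, 3.0) on the sitting task checks that accuracy is
  non-decreasing within a 10-percentage-point Monte-Carlo tolerance that
  reflects single-fold training variability at fixed seeds.

## Numerical and reproducibility choices

Float32 forward/backward compute with float64 Adam moments and loss
accumulation; float64 throughout the gradient-check tests. All
randomness flows from a single seed through stable SHA-256-derived
per-stage seeds (all below 2^31), so any stage can be rerun independently
and an identical configuration reproduces every metric bit-for-bit on a
fixed platform. Checkpoints store the architecture tag, its
configuration, and named flat weight arrays (including batch-norm running
statistics).

## Known limitations

The generator's movement statistics per class are free parameters — the
source protocol reports none — so its defaults encode plausible
magnitudes, not measurements. Window-level splitting shares drives across
train/validation by design fidelity; participant-level results are the
generalization-relevant ones and are systematically lower. The CAM
analysis is visual and per-window; no population-level aggregation of
maps is attempted. Training at the full 84-participant, 4096-sample
scale is possible but slow on one CPU; the NumPy engine is tuned for the
smoke scale.
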