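# Methods

This note documents the models implemented in `fallsense`, the
parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical decisions a maintainer would want
written down.

## 1. Interrupt engine

### Register semantics

Three interrupt sources are defined on the accelerometer axes only
(gyroscope channels never participate):

| source | condition | threshold | duration |
|---|---|---|---|
| free fall | all three \|aᵢ\| < FF_THR | 0.563 g | 20 ms |
| motion | any \|aᵢ\| > MOT_THR | 2.0 g (configurable) | 20 ms (configurable) |
| zero motion | all three \|aᵢ\| < ZRMOT_THR | 0.5 g | 1000 ms |

A duration D at rate f demands `ceil(D·f)` *consecutive* qualifying
samples; the event fires at the sample completing the run (so 20 ms at
100 Hz = 2 samples, and an all-zero burst starting at index 100 fires
at index 101). After firing, a source is latched: it cannot re-fire
until its condition has been broken for at least one sample. This
matches latch-style hardware interrupt behavior and prevents per-sample
event storms.

The free-fall threshold's placement is geometric: minimized over
orientations, the largest absolute axis component of a 1 g gravity
vector is 1/√3 ≈ 0.57735 g (gravity at equal angles to all axes), so
any threshold above that value would let some resting orientation
permanently satisfy the free-fall condition. 0.563 g sits just below
the bound.

MOT_THR/MOT_DUR have no published reference values; the defaults
(2.0 g, 20 ms) exceed static gravity — so quiet standing cannot fire
the motion interrupt — and mirror the free-fall duration. Both are
plain config fields.

### The zero-motion tension

Taken literally, "all axes below 0.5 g" is unreachable for a resting
body: some axis must carry ~1 g of gravity. The engine implements the
literal rule as the default (fidelity to the stated register
semantics), and offers `zero_motion_gravity_compensated=True`, which
instead tests |‖a‖ − 1 g| < ZRMOT_THR so a motionless body at any
orientation can reach sleep. The synthetic fall's post-impact rest
phase reads near zero on all axes — emulating the gravity-suppressed
view such a detector effectively responds to — so the default pipeline
closes the wake→sleep loop end to end.

### F0/F1 state machine and FIFO

The FIFO holds `FIFO_CNT / (channels · 2 bytes)` sample sets — 50 at
the 600-byte default, i.e. 0.5 s at 100 Hz. In F0/F1 idle operation
samples stream into the FIFO with oldest-overwritten semantics and the
radio sleeps. A free-fall or motion event atomically flushes the
current FIFO contents (the pre-trigger context) to the transmitted log,
enables the zero-motion interrupt, and enters transmission mode, where
every FIFO fill is flushed until zero motion fires and the machine
returns to F0. Ties at one sample are processed free-fall first, then
motion, then zero motion. `duty_cycle` = transmitted samples / total
samples is the energy proxy; no absolute current modeling is attempted.

One spec-level invariant was corrected during implementation: the
number of *latched* free-fall events is **not** monotone in FF_THR — a
looser threshold can merge two qualifying runs into one, collapsing two
events into one. The property that does hold, and is tested, is that
the duration-qualified free-fall *coverage* (the set of samples inside
qualifying runs) grows monotonically with the threshold.

## 2. Synthetic IMU generator

The generator exists to exercise the interrupt logic and the
classification pipeline, not to be biomechanically faithful. Defaults:
100 Hz, 4 s traces, Gaussian per-channel noise (σ = 0.03 g accel,
2 deg/s gyro) added before clipping to the sensor ranges (±16 g,
±2000 deg/s).

Per-activity templates:

* **walking / stairs**: sinusoidal gait about 1 g on the vertical axis
  (1.5–2 Hz; amplitudes 0.18–0.28 g) with stair classes distinguished
  by pitch-rate bias sign (±18 deg/s) and cadence;
* **jogging**: rectified vertical profile (sharp upward contact peaks
  to ~1.9 g, dips no lower than ~0.8 g) so it never satisfies the
  free-fall condition;
* **jumping**: genuine airborne intervals (~120–180 ms, all axes
  ≈ 0.1 g) plus landing bumps. Jumps may legitimately fire the
  free-fall interrupt — interrupts gate transmission, not
  classification;
* **standing up / sitting down**: quiet 1 g trace with a ~1.2 s
  dip-then-overshoot vertical transient (amplitudes +0.30/−0.25 g,
  mirrored between the two classes) and opposite-signed pitch lobes.
  Amplitudes deliberately keep the vertical axis above ~0.7 g so
  postural transitions cannot fire the free-fall interrupt;
* **falling**: four phases — quasi-static stand (0.6–0.9 s, so the
  50-sample FIFO covers real pre-trigger context), free fall of
  100–400 ms with all axes ≈ 0.05 g (well past the 20 ms detection
  minimum), a 4–8 g impact half-sine (~50 ms), then near-zero rest
  that sustains the zero-motion condition.

Every generated fall triggers ≥ 1 free-fall interrupt under default
registers; walking never does (both are tested against a brute-force
scan). What passing tests show is that the *pipeline* behaves
correctly on signals with the right threshold structure; they say
nothing about accuracy on real human kinematics, soft-tissue artifacts,
device placement variation, or elderly-vs-young differences.

`generate_dataset` cuts traces into 2-s windows (stride 1 s), exactly
balanced per class, split 70/10/20 into train/validation/test (1200
windows per class reproduce the 840/120/240 reference arithmetic).
Seeds fan out deterministically via `numpy.random.SeedSequence`.

## 3. Preprocessing

Fixed order: axis remap → downsample → normalize → moving average →
window.

* **Axis map**: signed 3 × 3 permutation applied to both triplets;
  dataset-specific maps are user-supplied (the published mappings for
  SisFall/MobiFall-style frames were never printed).
* **Downsampling**: plain decimation (keep every k-th sample), e.g.
  200 → 100 Hz at factor 2. No anti-aliasing filter is applied, by
  scope.
* **Normalization**: per-channel min-max `y = (x − min)/(max − min)`.
  The default ranges are the nominal sensor ranges; an alternative
  constructor derives ranges from observed data (see §5).
* **Moving average**: causal mean of the last M samples; M defaults to
  5 (50 ms at 100 Hz — smooths noise without blunting the 20 ms
  free-fall signature). The first M−1 outputs average the shorter
  available history, keeping output length equal to input length and
  avoiding startup transients.
* **Windows**: 200 samples × 6 channels, stride 100 (50% overlap,
  standard HAR practice; the reference stride was unstated). A window's
  label is the majority per-sample label, ties broken toward falling —
  a conservative choice for a safety application; the original mixed-
  window rule was unstated.

## 4. FD-DNN

### Architecture conventions

Conv kernels are temporal: a "3 × 6" kernel spans 3 timesteps by all 6
input channels, which is what makes C1's parameter count
32 × (3 × 6) + 32 = 608. SAME stride-1 convolution preserves length;
SAME stride-2 pooling yields `ceil(L/2)`, which is what takes
25 → 13 at S4. The pooled (13, 200) map is handed to the LSTMs with the
pooled temporal axis as the recurrent axis. LSTM parameters are
4 · H · (D + H + 1); each 200-unit layer on 200-wide input has 320,800
parameters — reported per layer; the layers do not share weights
(weight tying between stacked LSTMs would be nonstandard).
`default_model_spec(conv_layers=k)` truncates the C1..C4 plan or
extends it by replicating C4, for depth-ablation studies.

### Training engine

Implemented in NumPy (float64) with hand-written backpropagation:
im2col convolution, argmax-cached pooling, full BPTT through both LSTM
layers (fused gate matmul, forget bias initialized to 1.0, zero initial
states), inverted dropout (default 0.5) on LSTM output sequences during
training only, Glorot-uniform weight init, and Adam (β₁ 0.9, β₂ 0.999,
lr 10⁻³, ε 10⁻⁸). Gradients of every layer type are verified against
central finite differences in the test suite (rel. tolerance 10⁻⁴).

Protocol: mini-batches of 128; training metrics logged every 5
iterations, validation every 25; checkpoints every 10 epochs; early
stopping on a validation-accuracy plateau (patience 20 checks,
min-delta 10⁻⁴). The harness restores the weights of the best
validation check at the end of training (`restore_best`, default on):
rare late-run Adam instabilities were observed to collapse an already-
converged model within a handful of batches, and best-weights
restoration is the standard guard. The recorded history still shows the
raw trajectory. A non-finite loss aborts with a diagnostic rather than
continuing.

Checkpoints are NumPy `.npz` archives of raw parameter arrays; they are
a convenience, not a portability surface — the auditor is.

## 5. Scaled-down end-to-end configuration

Full-size training (942k parameters, 300 epochs, thousands of real
windows) is out of desk scope. The end-to-end demonstration and
acceptance run use:

* dataset: 120 windows per class (960 total; 28 traces per class),
  split 84/12/24 per class;
* model: 2 conv blocks (32, 64 filters) + two 32-unit LSTMs + softmax;
* protocol: 30 epochs, batch 32 (the small set needs the extra
  optimizer steps per epoch), otherwise the standard settings above;
* normalization: ranges observed on the training windows
  (`NormalizationSpec.from_observed`). Against the nominal ±16 g /
  ±2000 deg/s ranges the synthetic signals' discriminative variation
  occupies ~1% of the unit interval and this short run cannot leave the
  uniform-probability plateau; observed ranges are the documented
  alternative for datasets that occupy a small fraction of the sensor
  range. Nominal ranges remain the default elsewhere.

At this configuration held-out accuracy was ≥ 99% across a 12-seed
sweep (~25 s per run on one CPU).

## 6. Evaluation

`confusion(y_true, y_pred)` builds the 8 × 8 actual-by-predicted count
matrix in the fixed label order. Accuracy = 100 · trace / total. Fall
metrics use the standard binary collapse (falls positive): sensitivity
= TP/(TP+FN), specificity = TN/(TN+FP), with zero denominators
reported as NaN rather than raised.

The bundled reference offline-test confusion matrix
(`REFERENCE_OFFLINE_CONFUSION`, 8 × 240 test windows) yields 99.17%
accuracy (1904/1920). Its binary fall metrics under the standard
definitions are 99.58% sensitivity (239/240) and 100.00% specificity
(no ADL predicted as a fall) — the 94.09%/99.94% figures historically
quoted alongside that matrix are not derivable from it under any
standard binary collapse, and the formula behind them was never stated.
This package reports the standard definitions and flags the mismatch
rather than reverse-engineering an undocumented one.

## 7. Known limitations

* Synthetic kinematics are threshold-accurate caricatures; no claim
  transfers to real recordings without retraining and revalidation.
* No anti-aliasing before decimation; no orientation estimation for
  randomly oriented devices.
* Energy is modeled as radio-on sample fraction only — no currents,
  packet overheads, or link-rate limits.
* The literal zero-motion rule cannot fire for a physically resting
  body carrying gravity on one axis; use the gravity-compensated mode
  for such streams.
* Training determinism is guaranteed per platform (fixed seed, fixed
  BLAS), not bit-exact across platforms.
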