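# Methods

## Problem and approach

Scratching in mice — rapid, repetitive hindlimb strokes toward an itchy
site — is a key behavioural readout in itch and dermatitis models, and is
conventionally scored by a human watching video. `scratchdetect`
implements an automated detector for top-view arena recordings (60 Hz) in
four stages:

1. **Motion images.** Consecutive frames are grey-scaled and subtracted;
   the absolute difference is cropped to a 300×300 px window around the
   animal's centre and binarized at a fixed intensity threshold
   (default 25 of 255, strict `>`). Background, lighting and the static
   body cancel; what remains is a sparse binary picture of what moved
   between the two frames. The first frame of a video has no difference
   image, so N frames yield N−1 motion images.
2. **Segments.** The classification unit at time t is the run of 21
   motion images from t−10 to t+10, labelled with the frame label at t
   only. Centre times whose window would leave the video are skipped
   rather than padded, keeping "21 consecutive images" literally true.
3. **Classifier.** A convolutional recurrent network: three blocks of
   32× 3×3 same-padded convolution (stride 1, ReLU) + 2×2/2 max pooling
   applied with shared weights to each of the 21 images (200→100→50→25,
   giving a 25·25·32 = 20 000-long feature per frame), two 256-unit LSTM
   layers (the first returning its full 21-step sequence, the second its
   final state), and a dense head of widths 128/128/32/8/1 with ReLU
   activations, 20 % dropout on the first two dense layers, and a sigmoid
   output read as the scratch probability.
4. **Events.** Segments with probability strictly above 0.5 are
   scratching; maximal runs of scratching segments are *events*, whose
   count per video and duration (segments / fps) are the behavioural
   readouts.

## Imbalance-aware training

Scratch frames are rare (a few percent), so an *epoch* is an upsampled
draw, not a data pass: 1500 segments sampled with replacement from all
segments plus 100 from the scratch segments, shuffled. Each sampled
segment receives one geometric transform — horizontal flip (p = ½),
vertical flip (p = ½), rotation uniform on [0°, 360°) — applied
identically to all 21 images, then a resize to 200×200. Optimisation is
Adam (lr 1e-4, β₁ 0.9, β₂ 0.999) on binary cross-entropy for 1000 epochs,
no early stopping, no validation split. The epoch's 1600 segments are
consumed in minibatches (default 32): a single 1600-segment gradient step
would be memory-prohibitive, and step granularity below the epoch level
is a free implementation choice.

One master seed fans out (via `numpy` `SeedSequence`) to the sampler, the
augmentation stream and dropout, so runs are bit-reproducible on a fixed
backend.

## Evaluation

Per-segment confusion counts give sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn), as
percentages; a zero denominator yields an explicit *undefined*, never an
exception or a silent 0. Event-level readouts are the per-video event
count (compared across videos by Pearson's r) and per-event durations,
matched observed-event-centrically: each observed event pairs with the
summed duration of all predicted events overlapping it, so a bout that
the detector fragments into several short events still compares against
its full observed duration.

Error segments (fp + fn) are classified three ways:

* **boundary** — the segment's enclosing event overlaps a counterpart
  event in the other track (a start/end disagreement);
* **false detection** — a predicted event overlapping no observed event;
* **oversight** — an observed event overlapping no predicted event.

The taxonomy is exhaustive and exclusive: boundary + false detection +
oversight = fp + fn, enforced by a fuzz test against a brute-force
implementation. Counting is per error *segment* (not per event).

## Numerical and design choices

* **Centroid.** The original centring method is cited but not described in
  the source; this package uses the motion-energy centroid — the mean
  coordinate of above-threshold difference pixels — exponentially smoothed
  (weight 0.5 on the current frame), falling back to the previous valid
  centre when fewer than 20 pixels moved (a resting animal produces an
  almost empty difference image). It tracks the animal without any
  segmentation model and is fully configurable.
* **Crop convention.** For centre (cx, cy) rounded half-up, the half-open
  window [cx−150, cx+150) × [cy−150, cy+150); out-of-bounds regions are
  zero-filled, so the output is always exactly 300×300.
* **Binarization is strict** (`> threshold`): a difference of exactly 25
  maps to 0.
* **Conv padding** is size-preserving ("same") so pooling halves
  dimensions exactly; without the original per-layer shape table this is
  the only choice that yields a clean 200→100→50→25 cascade.
* **LSTM activation.** The cell activation is ReLU as specified for the
  reference architecture, with `lstm_activation: tanh` as a configurable
  saturating escape hatch should ReLU recurrence diverge on other data;
  all shipped runs use ReLU.
* **Pool-before-ReLU fusion.** The conv blocks compute conv → maxpool →
  ReLU, which is exactly equivalent to the conventional conv → ReLU →
  maxpool because max commutes with a monotone function; it keeps cached
  activations at pooled resolution. Pooling-gradient ties are split
  evenly among tied inputs (a valid subgradient; ties are measure-zero
  for continuous activations).
* **Augmentation resampling.** Resizing is an anti-aliased affine
  bilinear resampling: a local average matched to the scale factor runs
  before the resample, because plain bilinear *sampling* of a sparse
  binary motion image at a 300→64 downscale drops most of a one-pixel
  trace (without it, a trained model detects nothing held-out). Resized
  images keep interpolated grey values in [0, 1]; nothing is
  re-binarized. In the training loop each video's motion images are
  downscaled once (cached) and the per-draw flip/rotation — one transform
  drawn per segment, applied identically to its 21 images — is a single
  bilinear affine at network resolution. Rotating after the anti-aliased
  resize is numerically near-equivalent to rotating at full resolution
  first and ~5× cheaper. The flip/rotation primitives remain available
  and are tested for their algebraic identities.
* **Probabilities** are clipped to [1e-6, 1−1e-6] so the output is
  strictly inside (0, 1) and the cross-entropy is finite in float32.
* **Weight init**: Glorot-uniform for dense/conv/LSTM input weights,
  orthogonal recurrent weights, zero biases with the forget gate at 1;
  recorded in every checkpoint's metadata.
* **Backprop** is hand-derived per layer and verified against float64
  central differences in the test suite (worst relative error ~1e-4).
* The network is implemented directly on numpy (float32, im2col GEMM
  convolutions with persistent workspace buffers, chunked over frames);
  the first conv block skips its input gradient. Inference encodes every
  motion image once and slides the 21-frame window over per-frame
  features, exploiting the 20-image overlap of consecutive segments.

## Synthetic data

Real recordings are not redistributable, so the generator emulates the
statistics the detector relies on, not mouse appearance: a bright ellipse
(body) on a dark noisy arena (default 480×480 rather than full HD, purely
for desk-scale runtime — preprocessing is size-agnostic), alternating
rest / locomotion / grooming / scratching episodes from a semi-Markov
script (exponential dwell, truncated to ≥ 5 frames; self-transition-free
switching weights). Grooming and scratching render as a small appendage
ellipse that rhythmically extends past the body outline and retracts
beneath it — slow (3 Hz) at the front for grooming, fast (12 Hz,
larger amplitude) at the rear flank for scratching — so per-frame motion
energy oscillates at the behaviour frequency and the two confusable
behaviours differ in both rhythm and vigour, which is exactly the
contrast the classifier must learn. Default dwell means and transition
weights were chosen once so that scratch frames make up roughly 2 % of
all frames, mirroring the strong class imbalance of real datasets.

What the generator does **not** model: limb kinematics, posture change,
fur texture, shadows, camera jitter, multiple animals, and the
full-resolution 1920×1080 format. Passing tests on synthetic data
therefore demonstrate that the pipeline's machinery — preprocessing,
segment bookkeeping, optimisation, event scoring — works end to end and
that the architecture can learn a frequency/amplitude motion signature;
they do not certify accuracy on real mice. A contrast-inversion flag
emulates the known failure mode on dark-coated animals qualitatively.

## The desk-scale benchmark

`scratchdetect.benchmark.run_benchmark(seed)` freezes a complete
experiment sized for one CPU: six 30 s synthetic videos, default
behaviour mix; the default architecture at 64×64 input; 30 epochs of
150 + 10 draws (a 10× scale-down of the full protocol in both input area
and sampling), consumed in minibatches of 8 so that the scaled epochs
keep a step granularity comparable to the full protocol's 50 optimiser
steps per epoch; videos ranked by scratch-segment count with the 2nd and
3rd richest held out — training keeps the richest video, and the held-out
pair is guaranteed to contain scratch events so sensitivity is defined.
Held-out segments are scored with the shared-encoder sliding-window path
and pooled into one confusion matrix. The acceptance thresholds
(sensitivity ≥ 60 %, specificity ≥ 90 %, decreasing loss) assert genuine
learning well above the all-negative baseline, not production accuracy.

## Known limitations

* Accuracy figures from the original full-scale study (trained on ~3 h of
  real video) are not reproducible here: neither the recordings nor the
  trained weights are public. The package reproduces the published
  percentages from the published confusion counts exactly, and
  demonstrates learning on synthetic data.
* ReLU LSTM recurrence can diverge on inputs far from the binarized
  motion statistics; the tanh switch is the documented escape hatch.
* Training at the full 200×200 scale on CPU is possible but slow; the
  implementation targets the scaled benchmark and full-scale inference.
* Video containers require an imageio codec plugin; directories of
  numbered PNG/TIFF frames are always supported.
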