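# Methods

## Problem setting

`corrseg` trains a binary semantic-segmentation network *while* an
annotator (human or simulated) works through an image set, labelling only
where the current model is wrong. Per-pixel labels are a trichotomy —
foreground, background, undefined — and everything downstream (loss,
validation F1, evaluation references) respects that partiality. The package
is organised as a file-based client/server protocol (sync directory,
JSON instructions, PNG annotations/segmentations) plus a library and CLI
around five stages: dataset construction, network, augmentation, the
training loop, inference, and measurements.

## Network

A fully convolutional residual U-Net variant with group normalization,
written as a self-contained NumPy engine: convolutions are stride-1 im2col
GEMMs (float32), gradients are hand-derived per layer (the input gradient
of a 3×3 convolution is a second GEMM against the 180°-rotated kernels),
and correctness is established by float64 finite-difference tests at layer
and whole-network level.

Architecture (canonical configuration):

| stage | operation | channels |
|---|---|---|
| down 1 | residual block (two padded 3×3 conv + GN) | 3 → 16 |
| down 2–5 | maxpool 2×2, 1×1 conv halving channels, two padded 3×3 conv + GN, residual 1×1 shortcut | 16→32→64→128→256 |
| up 1–4 | nearest-resize to the skip's size, concat, 1×1 reduce + padded 3×3 conv + GN, residual 1×1 shortcut | →96→64→48→32 |
| head | 1×1 conv | → 2 |

The logit map is cropped to its central valid core, 36 px per side, so the
output is always `input − 72` px per dimension: 572×572×3 in → 500×500×2
out. Total trainable parameters: 1,299,242 (1.3 M to one decimal). The
channel schedule is the free design variable; it was chosen to satisfy the
two checkable constraints (geometry and parameter count) while keeping
full-resolution layers narrow for CPU throughput. The first down-block has
no 1×1 halving convolution (the input has only 3 channels); halving applies
from the second block on. Group counts are the largest divisor of the
channel count ≤ 32. Weights are He-initialized (seeded). Pooling floors odd
sizes and each up-block resizes to its skip's exact shape, so any input
larger than the 72-px context works, 572 included.

Input images are scaled to [0, 1] per channel; greyscale sources are
replicated to three channels.

## Loss and optimization

Over annotated pixels only: unweighted sum of (a) `1 − soft-dice` of the
foreground probability against foreground labels, smoothing ε = 1, and
(b) mean two-class cross-entropy. The mask multiplies both terms, so the
loss value and the analytic gradient are *exactly* invariant to logits at
undefined pixels (asserted bitwise in tests). A crop with no annotated
pixels contributes zero. The implementation is saturation-safe in float32:
cross-entropy is evaluated in softplus form, its gradient as `p − t`
directly on the logit difference, and `1 − p` as `sigmoid(−d)` — naive
chain-rule forms lose the gradient entirely once `p` rounds to 1, which
permanently freezes training.

SGD with Nesterov momentum: lr 0.01, μ 0.99, weight decay exactly 0, no
learning-rate schedule (the dataset can grow indefinitely during training,
so a schedule keyed to a fixed horizon would be ill-posed).

## Training loop

An epoch is 612 subregions (network-input-sized random crops of training
images, sampled uniformly with replacement), growing to 2n when the
training set exceeds 306 images. Annotation folders are re-read every
epoch, so corrections enter training immediately. The annotation the loss
sees is the central crop matching the 500-px output footprint; annotated
pixels in the 36-px border of a crop contribute nothing (forced by the
geometry).

Validation F1 accumulates TP/FP/FN globally over all annotated pixels of
the validation set (per-image averaging is a plausible alternative; global
accumulation weights images by their annotated area). A checkpoint is
written exactly when F1 strictly exceeds the best seen so far — the gate
that prevents a transiently diverged model from overwriting a good one,
which matters in the corrective loop where training runs in short bursts.
Training stops after 60 consecutive epochs with neither an improvement nor
an annotation save/update; an annotation change resets the patience counter
(new labels restart the search), registered at the end of the epoch during
which the change appeared.

Assignment of new annotations: first → train, second → val, then val
exactly when train ≥ 5 × val. Iterating this from empty gives validation at
positions 2, 7, 13, 19, … (one validation image per five training images
after the bootstrap).

## Augmentation

Transforms: horizontal/vertical flip, 90° rotations (180° only for
non-square crops), elastic grid deformation, brightness/contrast jitter,
additive Gaussian noise, Gaussian blur. Each is applied independently with
probability 0.8, in a freshly shuffled order per crop. Geometric transforms
act identically on image and annotation (nearest-neighbour warping for
labels); photometric ones touch the image only. Elastic displacement fields
are i.i.d. Gaussians drawn at ⌈size/8⌉, lightly smoothed (σ 1.5 coarse
px), bilinearly upsampled, default amplitude 12 px. The 80% probability
applies uniformly to all transforms, the elastic one included.

## Inference

Reflect padding by 36 px gives every output pixel full context; 572-px
windows with 500-px valid cores tile the original image exactly, far-edge
windows shifted inward (later tiles overwrite — value-identical overlap for
a deterministic model whose receptive field stays inside the margin, which
the seam-freeness test asserts with a linear stand-in operator). For images
smaller than 500 px the window shrinks to image + 72 (single tile); the
network is fully convolutional so this is exact. Foreground probabilities
are averaged over {identity, horizontal flip} × all models, then
thresholded at 0.5, ties classified foreground. Averaging is on
probabilities, not logits.

## Measurements

* **Length**: pixel count of the scikit-image skeleton. The raw count is
  the reported value; a √2 diagonal correction exists behind a flag but is
  off by default. Note the thinning algorithm breaks ties asymmetrically,
  so flipping a blobby mask can change the count by a few percent —
  1-px-wide structures are exactly stable.
* **Region properties**: 8-connected components (diagonal neighbours join,
  so thin diagonal strands stay whole); centroid, area, equivalent
  diameter `2·sqrt(area/π)` (px, and mm when a px/mm calibration is given),
  perimeter, eccentricity, via scikit-image regionprops.
* **Counts**: regions surviving conjunctive filters — minimum equivalent
  diameter in mm (requires calibration; e.g. the 2 mm biopore convention)
  and/or minimum area in px (e.g. suppressing small false-positive nodule
  detections).
* **Metrics**: dice, recall, precision, accuracy per image, against any
  reference — typically the *corrected segmentation* (prediction with
  corrective labels overriding). Empty-denominator convention: 0/0 → 1.

## Synthetic scenes and the simulated annotator

Scenes are exact-ground-truth compositions on procedurally textured
backgrounds: random-walk tubes ("roots", with the walk's path length
recorded so skeleton length can be checked against it), non-touching dark
discs with diameters spanning the 2 mm counting threshold at 10 px/mm
("pores"), and bright blobs attached to tubes ("nodules"). Backgrounds are
low-frequency Gaussian-filtered noise plus per-pixel sensor noise. What
they deliberately do **not** emulate: occlusion, shadows, colour variation,
annotator inconsistency, class ambiguity at boundaries — so passing tests
demonstrate that the machinery learns and measures correctly, not that any
accuracy level transfers to field imagery.

The simulated annotator labels whole error components (prediction XOR
truth, 8-connected), dilated by a 1-px brush halo whose pixels take their
*true* class, truncated at a per-image pixel budget; disagreements within a
1-px boundary band are left undefined, mimicking a human's tolerance near
edges. Labels therefore never contradict the truth outside that band. The
first six images of a session get dense labels ("clear examples" — the
warm-up that stabilises training before corrections begin); later images
are corrected only where wrong, and an image without errors is accepted
without saving an annotation.

## Desk-scale configurations

The canonical configuration (572-px windows, 612-subregion epochs) is CPU
inference-friendly but too slow for CPU *training* test cycles, so the
test suite exercises the identical code path at reduced sizes, all plain
config values: 280-px scenes with 112-px training subregions and
64-subregion epochs for the convergence checks (six dense training scenes,
two validation scenes; F1 > 0.8 is typically reached within one or two
epochs), and 192-px scenes with 112-px subregions, 12 subregions per image
step, for the 30-image simulated corrective sessions. Session training
begins once the six clear-example images are saved, so the optimizer
always starts from a diverse dense set — beginning from one or two images
is exactly the unstable regime the clear-example warm-up exists to avoid —
and the desk-scale learning curve is spread over the session the way a
real session's is. The early-stopping checks run with learning rate 0 and
2-subregion epochs, which freezes the F1 trace and makes the patience
arithmetic exact. The network architecture is never reduced in these runs.

Training subregions below ~100 px supervise very few output pixels (the
output core is the crop minus 72 px), which makes gradients noisy enough
to stall optimization; 112 px (a 40×40 supervised core) is the practical
CPU minimum and is what the desk-scale runs use.

## Numerical and design choices

* Split planning scores a candidate grid by `max(pw,ph)/min(pw,ph) − 1 +
  (|pw−target| + |ph−target|)/(2·target)` — both terms dimensionless, zero
  exactly for square, target-sized pieces; ties break toward fewer pieces,
  then fewer rows. Images within 1.3× target on both sides are kept whole.
  Non-divisible dimensions: the last row/column absorbs the remainder.
* Annotation PNGs: pure opaque red = foreground, pure opaque green =
  background, transparent = undefined; any other pixel is rejected loudly.
* Instruction files are consumed exactly once, oldest first; malformed
  files are skipped (and removed) with a warning.
* Checkpoints are `.npz` archives embedding the architecture config, so
  loading needs no out-of-band information; names are zero-padded numbers
  plus a timestamp so lexical order is creation order.
* One master seed per run feeds dataset sampling, augmentation and weight
  init.

## Known limitations

* CPU-only NumPy training is orders of magnitude slower than a GPU
  framework; the canonical 612×572-px epoch is impractical on one core
  (the code path is identical at reduced sizes, which is how it is tested).
* Group normalization uses whole-image statistics at inference, so tiled
  and whole-image evaluation of the *network* can differ slightly near tile
  boundaries; the tiling contract is exact for translation-local operators
  and the 36-px context margin keeps the effect marginal in practice.
* The instruction queue assumes a single consumer; concurrent server
  processes would need locking that is deliberately out of scope.
* `validation_f1` accumulates globally over pixels; per-image averaging
  would weight small annotations more heavily and is not currently a
  config switch.
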