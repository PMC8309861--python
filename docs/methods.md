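# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `wscas`, in the spirit of a model-description
appendix. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and line conventions

Images are indexed `x` = column, `y` = row, origin top-left, 0-based; a
pixel covers the unit square around its integer centre. Straight lines
use the normal (ρ–θ) form `x·cosθ + y·sinθ = ρ` with θ canonicalised to
[0°, 180°) and ρ signed; a vertical line at column c is (ρ=c, θ=0°). The
*vertical-axis angle* of a near-vertical line is θ mapped to (−90°, 90°]
— positive when the top of the line leans right on screen. The "lowest
point" of a line is its intersection with the bottom pixel row
`y = H − 1`; the lateral error divides the offset between the predicted
and true lowest points by the image width.

## The synthetic scenes

The generator emulates the geometric structure of a harvester's
front-view camera: a background band above a horizon row, and below it a
field split by a near-vertical boundary (|angle| ≤ 30°) into uncut crop
(left) and harvested stubble (right). Per class the textures are built to
be separable by *local* colour/texture only — the single cue a
patch-level classifier can exploit: crop is a green-yellow base with
per-column hue jitter and short dark vertical stalk strokes; stubble is a
brown base with horizontal stripes and bright speckle; background is a
pale vertical gradient. Additive Gaussian pixel noise (default σ = 4 on
the 0–255 scale) is applied last. Identical spec + seed gives
bit-identical frames; in a sequence, frame i uses seed + i, and
per-frame drift moves the boundary's bottom intersection and angle
linearly, so the visible crop area shrinks monotonically the way it does
during a pass.

Ground truth is analytic: the class mask is rasterised from the boundary
line (a pixel is crop iff its centre lies strictly left of the line), the
crop polygon is the same region in pixel-centre coordinates, and the edge
line is stored exactly. One shared even-odd, pixel-centre polygon
rasteriser is used both to produce the masks and to compute IoU, so no
rasterisation bias enters the evaluation; the polygon reproduces the mask
pixel-for-pixel by construction.

What the scenes deliberately do **not** model: perspective distortion,
the harvester's header in-frame, illumination changes, weather, crop
species variation, occlusions, or curved edges. Tests passing on these
scenes therefore demonstrate the correctness of the pipeline's machinery
and its behaviour under controlled geometry/noise — not robustness to
real field footage.

## Patch dataset

Each frame contributes one patch per class: an axis-aligned window lying
(almost) entirely inside the class region and large enough to admit a
square training crop. The search finds the largest fully-pure rectangle
exactly (row-histogram stack algorithm over the class mask, enumerating
every maximal rectangle; ties by area resolve topmost-then-leftmost). For
the crop class the purity threshold is 0.95 rather than 1.0 — real crop
borders are ragged, and a segmentation model should see some border — and
the pure rectangle is then grown greedily (one row/column per side per
round, fixed direction order) while the window purity stays above
threshold. The greedy stage is deterministic but not guaranteed maximal;
maximality under a purity constraint is a combinatorial search that buys
nothing here. Reported purity is always the exact pixel count over the
final window.

Frames that cannot produce all three patches are skipped and logged.
Successfully processed frames alternate between the train and validation
halves (even position → train), making the half/half split reproducible
and per-class balanced to within one patch.

## Classifier

Backbone: 4 blocks of stride-1 same-padded 3×3 convolutions with ReLU,
channels 32→64→128→256, 2×2 max-pooling after blocks 1–3 only. This is
the only arrangement of four conv blocks that yields 256 final feature
maps at exactly 1/8 of the input resolution; a fourth pool would give
1/16. The head is global average pooling followed by a bias-free linear
layer to 3 logits — bias-free so that the spatial mean of each class
activation map equals the corresponding logit exactly (tested to 1e-5).

Training: MSE between the softmax output and the one-hot label (the
gradient is propagated through the full softmax Jacobian), Adam with
learning rate 1e-4, batch size 64, each sampled patch entering through a
fresh uniformly-random square crop (the only augmentation). Validation
uses deterministic centre crops. Early termination keeps the weights of
the epoch with the lowest validation loss and stops after `patience`
epochs (default 10, max 200) without improvement.

Everything is float32 numpy: convolutions are lowered to a single BLAS
matrix product via im2col, max-pooling routes gradients through cached
argmax indices, and weight init is seeded Kaiming-style fan-in scaling
(head: N(0, 0.01)). Non-finite loss aborts with a diagnostic. Given a
seed, training is bit-reproducible on a fixed BLAS.

## CAM segmentation

CAMs are computed exactly as `M_c = Σ_k ω_k^c f_k`. The per-pixel
categorical softmax is applied at the CAM's native resolution and the
resulting probabilities are bilinearly upsampled; since interpolation is
linear, per-pixel channel sums stay 1 (the reverse order —
upsample-then-softmax — is available behind a flag and differs slightly).
The crop mask is the per-pixel argmax with ties resolving to background,
then 8-connected components smaller than `min_area` (default 0.5% of the
frame pixels; no principled value exists, this suppresses isolated
misclassified blobs without touching the main region) are removed.

The network is fully convolutional, so full-frame inference runs at the
native frame size rounded down to the nearest multiple of 8 (bilinear
resize), capped at a maximum side of max(training input, 360); masks are
registered back to the original frame by nearest-neighbour scaling. For
the 180×180 desk-scale frames this means inference at 176×176 (22×22
CAMs) rather than shrinking every frame to the 80×80 training crop — the
training crop bounds what the classifier saw, not what the convolutional
features can cover.

## Edge detection

The mask contour is the exact inner morphological boundary
(`mask & ~erosion(mask)`, 3×3 footprint, image border treated as
background). On a two-level image this coincides with a Canny contour to
within one pixel (cross-checked in the tests) while behaving correctly in
the cases that matter here — masks touching the canvas border, where
gradient-based edge detectors suppress their outputs.

Trimming removes the top and bottom 10% of the contour's own row extent
(not of the image), then keeps the rightmost pixel per remaining row: the
right side of the crop region is the uncut edge. The Hough accumulator
uses 1 px × 1° bins with normals restricted to ±45° of the x-axis (the
edge is near-vertical by task geometry). All cells within 50% of the
accumulator peak are averaged — mean ρ, circular mean θ (period 180°) —
into the single reported line. The threshold is peak-relative rather
than a fixed fraction of the pixel count because quantisation spreads
the votes of a slightly wobbly but clearly linear contour across
neighbouring cells; a fixed 30%-of-pixels cut rejected contours whose
best cell held ~23% of the votes despite sub-pixel linearity. A line is
reported only if the peak itself gathers at least 10% of the pixels;
otherwise the pixel set has no linear consensus and `NoLineError` is
raised. An explicit `vote_threshold` argument overrides all of this.

## IPC baseline

The image-patch-classification baseline tiles the frame into 80×80
patches, classifies every complete tile with the *same* trained model
(the architecture is fully convolutional and the training crop equals the
tile size, so a separately trained tile classifier would be the identical
estimator), and labels residual border strips background. Its masks are
constant per tile, producing the characteristic step-shaped right
boundary and the IoU/lateral penalty the comparison is designed to show.

## Desk-scale study configuration

`RunConfig.demo()` is the study the acceptance script and the end-to-end
test run: 60 training frames and 20 held-out frames of 180×180 scenes
(horizon at row 88 so all three class regions admit 80 px patches),
80×80 training crops, batch 64, patience 5, at most 40 epochs. The
held-out pass drifts the edge over a wider position (100→77 px) and
angle (−8°→+5°) range than training. Problem sizes were chosen so the
whole study trains and evaluates in a few minutes on one CPU while
keeping every pipeline stage non-trivial (multiple batches per epoch,
patch windows near their admissibility limit, edges crossing tile
boundaries). The full-scale defaults (360×360 crops and scenes) remain
available and are exercised for inference in the tests.

## Known limitations

* The scene generator's simplifications listed above; in particular the
  linear boundary means curved or scalloped crop edges are untested.
* The greedy purity expansion can under-reach the truly largest
  0.95-pure window (see above).
* Hough quantisation limits angle resolution to about 1°; the averaging
  step recovers sub-degree accuracy only when several near-peak cells
  bracket the true line.
* Training cost scales with the square of the crop size; the full
  360×360 crop regime trains correctly but slowly on one CPU.
* Bit-level reproducibility assumes a fixed BLAS implementation; across
  different BLAS builds results agree only to floating-point tolerance.
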