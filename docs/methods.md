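# Methods

This note records the models implemented, the parameter choices that matter,
and what the synthetic fixtures do and do not establish.

## Illumination model and Retinex

A conveyor frame is treated as the product of reflectance and illumination,
`S = R · L`, with `L` smooth (lamp fall-off, the broad sheen of waxy fruit
skin). Single-scale Retinex estimates `L` as a Gaussian-surround weighted
average of the frame and returns `log(S + ε) − log(F ∗ S + ε)` per channel.

Choices:

* **Natural logarithm.** The base cancels in the affine display
  normalization, so nothing downstream depends on it.
* **ε = 1.0** on the 0–255 scale by default — it guards `log 0` and is
  negligible against typical intensities. The multiplicative-cancellation
  property (scaling the whole image leaves the output unchanged) holds
  exactly only at ε → 0; tests verify it at ε = 0.01 where the residual is
  below 10⁻³ for pixels ≥ 10.
* **σ = 80 px** default surround scale, truncation radius `⌈3σ⌉`, reflection
  padding, channels processed independently. The surround is applied as two
  1-D passes (the kernel is separable), which is exact and O(radius) per
  pixel.
* Display normalization clips to the (1, 99) percentile interval per channel
  before mapping to [0, 255], so isolated specular pixels cannot crush the
  contrast of the rest of the frame; a constant channel maps to mid-gray 128.

The corrected image feeds the neural detectors. The classical color
measurement deliberately reads the *raw* frame: per-channel log-ratios do
not preserve hue, and the red-coverage statistic is a hue statistic.

## Classical features

* **Otsu threshold** is computed from the 256-bin histogram by maximizing
  between-class variance, ties broken toward the smallest maximizing
  threshold; a constant image returns its own value flagged degenerate.
  Scene and crop segmentation threshold the per-pixel **maximum over
  channels**: fruit of any ground color is bright in at least one channel
  while the belt is dark in all three, so the max-projection stays bimodal
  regardless of red coverage (a mean projection lets the threshold split
  red from green-yellow fruit regions instead of fruit from belt).
* **Mask cleanup** fills interior holes and removes components below
  64 px; the operation is idempotent.
* **Perimeter** uses the Crofton formula with 4 projection directions,
  accurate to well under 1% on rasterized disks and ellipses. Naive
  boundary-step counting overestimates smooth outlines by ~5% and would
  push the circularity of a true circle down to ~0.90, silently demoting
  grade-1 fruit; any estimator here must reproduce disk circularity within
  5%, and this one does within 1%.
* **Circularity** `e = 4πS/L²`; **diameter** `2√(S/π) · mm_per_px`. The
  calibration `mm_per_px` is a required input (0.35 in the synthetic
  fixtures, i.e. a ~70 mm fruit spans ~200 px).
* **Red coverage**: HSI hue mapped linearly from 0–360° to 0–255 with red at
  the 0/255 wrap-around; a pixel counts as red if its hue lies in
  [0, 25] ∪ [245, 255] *and* its saturation is ≥ 0.15 (glare and washed-out
  pixels have no meaningful hue; zero-saturation pixels are flagged
  undefined and never counted). The denominator is always the full
  silhouette area. Defect area converts as `px · (mm_per_px/10)²` cm².

## Rule grading and multi-view decisions

Per-characteristic thresholds (GB/T10651-2008 as applied to Red Fuji):
color ≥ 0.80 / ≥ 0.55 for grades 1/2, else 3; shape index ≥ 0.85 / 0.80 /
0.75; diameter ≥ 70 / 65 / 60 mm; defects: none for grades 1–2, ≤ 3 cm² for
grade 3. The fruit's grade is the **worst** per-characteristic grade; any
characteristic below its grade-3 floor (or a defect over 3 cm²) rejects the
fruit. Rejected fruit are reported distinctly rather than folded into
grade 3, since sub-grade fruit is normally culled before grading.

Across views: a confident defect detection anywhere overrides everything
(grade 3, later evidence ignored); views with a confident stem/calyx
detection are discarded; remaining per-view grades are aggregated by
summing confidences per grade and taking the argmax, ties broken toward the
**worse** grade (the safe commercial choice). If every view is discarded,
all views are used and the decision is flagged low-confidence — a running
line must still emit a grade. Detection-confidence thresholds default
to 0.5. Tracks are associated frame-to-frame by greedy IoU ≥ 0.3 matching;
the conveyor keeps fruit in lanes, so overlap tracking suffices.

## Network architectures

All blocks run on an in-package reverse-mode autodiff tensor core (NumPy,
float32, im2col convolutions) — the networks here are small and only ever
smoke-trained, and a self-contained core keeps every forward/backward step
inspectable in the tests.

* **Skeleton**: YOLOv5s-scale — depth multiple 0.33, width multiple 0.50,
  SiLU activations, CSP (C3) stages, SPPF, FPN+PAN neck, three anchors per
  scale at strides 8/16/32.
* **ODConv**: `n` candidate kernels; a GAP → FC → ReLU trunk with four
  sigmoid heads produces per-sample attention over the spatial (k×k),
  input-channel, output-channel and kernel axes; the aggregated kernel is
  the attention-weighted sum and the sample is convolved with it. All four
  factors use the **sigmoid** (a deliberate choice here; softmax over the
  kernel axis is the other common normalization). In the reference
  detector the replaced "ordinary backbone convolutions" are the five
  strided stage convolutions plus the two SPPF projections; C3-internal
  convolutions are untouched.
* **GSConv**: dense convolution to half the output channels, a 3×3
  depthwise complement, concatenation, channel shuffle. The depthwise
  kernel is 3×3 so the cheap path stays cheaper than the dense convolution
  it displaces across the channel widths the necks use (a 5×5 complement
  would outweigh a 1×1 dense conv at small widths). **VoVGSCSP** is a
  cross-stage-partial block whose main path stacks two GSConv units
  (pointwise then 3×3), merged with a pointwise shortcut and fused 1×1.
* **Swin blocks**: the canonical pair — `z + W-MSA(LN(z))` then
  `+ MLP(LN(·))`, followed by the same with SW-MSA. Shifted windows use a
  cyclic roll plus an additive mask that sends attention between tokens of
  non-adjacent image regions to zero; relative position bias included.
  Token grids are padded to the window size when needed. The grader
  inserts one pair after each of backbone stages 3 and 4 (the /16 and /32
  stages).

### Reference configurations

The published parameter budgets pin several structural dials that the
architecture descriptions leave open. They were fixed once, by solving the
budget equations against exact counts, and are committed as the reference
configurations:

| build | budget | pinned dials |
|---|---|---|
| improved detector (ODConv + slim neck, 2 classes) | 6.78 M | ODConv n = 2, trunk hidden = max(C_in/56, 4); slim-neck channel scale 0.377 |
| same detector, standard neck | 9.32 M | follows from the above |
| slim-neck reduction | 2.54 M | follows from the above |
| grading network (SwinT stages 3–4, 3 classes) | 3.78 M | width multiple 0.24, window 8, shift 4, 8 heads, MLP ratio 293/64 |

Two structural facts force the less obvious values. First, a 0.50-width
standard neck holds only ~2.85 M parameters, so removing 2.54 M demands a
slim neck of ~0.31 M — far narrower than a same-width GSConv swap — hence
the 0.377 channel scale. Second, a 0.50-width skeleton plus Swin stages is
~3× the grading network's 3.78 M budget, so the grader is built at 0.24
width with the Swin MLP ratio as the fine dial. The counts are exact
integers (6 782 698; 9 320 314; 3 779 490) and are recomputed, never stored,
by `scripts/acceptance.py`.

* **Classes**: the detector has 2 (one merged stem/calyx class, one defect
  class — defect types are not subdivided); the grader has 3 (grades 1–3).
* **Smoke training**: a composite detection loss (BCE objectness over all
  anchor cells, BCE class + squared-error box terms at centre-cell-assigned
  positives) minimized by SGD with momentum on one fixed synthetic batch.
  This verifies that gradients reach every parameter and the objective
  decreases; it is a functional sanity check, not a training recipe, and
  nothing here claims detection accuracy.

## Synthetic scenes

The generator emulates the acquisition conditions the pipeline is designed
for: frames of 8–10 fruit (default 9) on a dark belt, smooth multiplicative
illumination (affine ramp, default falling to 0.6× across the frame,
composed with one broad Gaussian bump of amplitude 0.15), optional specular
highlights, ~0.35 mm/px at the fruit plane, frame 1296×1024 (half a
2592×2048 sensor). Fruit are axis-aligned ellipses with radial shading;
the red/ground partition is a sector in the elliptical parameter angle
(sector measure is exactly proportional to area, so coverage is controlled
analytically) perturbed by a smooth seeded ripple; defects are desaturated
dark patches of the requested physical area; top-pose fruit may carry a
stem mark. Placement uses a jittered lane grid — overlap-free by
construction, failing loudly when the frame cannot hold the requested
count. Ground-truth features are read from the generator's own label
rasters, so they are exact by construction. Illumination strengths default
to values under which direct Otsu segmentation still succeeds, keeping the
feature-stage tests independent of the enhancement stage.

What passing tests show: the measurement chain recovers controlled feature
statistics (coverage within 0.03, circularity within 0.05, defect area
within 10%) and the decision logic is correct over the ground-truth feature
space. What they do not show: performance on real fruit — real russeting,
bruise spectra, stem-vs-calyx appearance, soil, motion blur and camera
noise are all absent, and no claim about real-image detection accuracy is
made or tested.

## Numerical and degenerate-input conventions

* Boxes are half-open pixel intervals, origin top-left.
* Otsu ties → smallest maximizing threshold; constant image → flagged
  degenerate, segmentation refuses it.
* Objects under 16 px area are below the measurable minimum for contour
  metrics and are rejected.
* Weighted-vote ties → worse grade; empty view set → reject decision with a
  logged warning.
* Constant reflectance map → mid-gray 128 under display normalization.
* All randomness flows through explicit `numpy` generators seeded by the
  caller; identical seeds give byte-identical renders, manifests and model
  initializations.

## Known limitations

* The grading networks are architecture artifacts with exact parameter
  accounting and smoke-scale trainability; no trained weights ship with the
  package, and the multi-view pipeline therefore runs either on scripted
  (stub) detections or on the classical feature chain.
* The NumPy core is single-threaded and eager; a full-resolution 640×640
  detector forward takes seconds, fine for verification, unsuitable for
  throughput.
* HSI hue is undefined at zero saturation and numerically touchy near it;
  the saturation gate (0.15) makes the red count robust, but strongly
  desaturated genuine red (heavy glare) is deliberately not counted.
* Classical defect measurement in the end-to-end pipeline relies on the
  generator's defect mask or a scripted detector; a photometric defect
  segmenter is out of scope.
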