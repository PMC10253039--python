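# applegrade

Multi-view quality grading of dessert apples on a roller conveyor.

Automated fresh-apple grading judges each fruit on four characteristics from
the Chinese national standard GB/T10651-2008: red coloring coverage, shape
(circularity), fruit diameter and surface-defect area. A single camera view
is not enough — the top view hides defects behind the stem/calyx and biases
the color measurement — so fruit are rolled under the camera and several
views per fruit are combined. This package implements that whole chain as a
tested library plus CLI:

* **Retinex illumination correction** — the frame is modelled as
  `S(x,y) = R(x,y) · L(x,y)`; the slowly varying illumination `L` is
  estimated by a Gaussian surround and removed in the log domain,
  `log R = log S − log(F ∗ S)`, suppressing lamp fall-off and waxy-skin
  sheen before any measurement.
* **Classical grading features** — Otsu threshold segmentation with
  morphological cleanup; pixel area `S` → equivalent-circle diameter
  `d = 2√(S/π) · mm_per_px`; circularity index `e = 4πS / L²`
  (1 for a perfect circle); HSI red-coverage ratio: the fraction of
  silhouette pixels with hue in the wrap-around red band (0–25 ∪ 245–255 on
  an 8-bit hue scale) and enough saturation to exclude glare.
* **Lightweight network architectures** — the detection/grading networks as
  verifiable components on a compact NumPy autodiff core:
  omni-dimensional dynamic convolution (ODConv), whose effective kernel is
  an attention-weighted sum
  `Σᵢ αwᵢ · (αfᵢ ⊗ αcᵢ ⊗ αsᵢ ⊗ Wᵢ)` over `n` candidate kernels with
  sigmoid attention along the spatial, input-channel, output-channel and
  kernel axes; the GSConv / VoVGSCSP slim neck; window / shifted-window
  multi-head self-attention (W-MSA / SW-MSA) Swin Transformer blocks; and
  YOLOv5s-scale builders for a 2-class stem/defect detector and a 3-class
  grading network, with exact trainable-parameter accounting.
* **Multi-view decision logic** — any confident surface-defect detection
  sends the fruit straight to grade 3 (defect override); views showing the
  stem/calyx are discarded; the surviving per-view grades are combined by a
  confidence-weighted vote with ties broken toward the worse grade.
* **Synthetic conveyor scenes** — a seeded generator renders multi-fruit
  frames with exactly known ground-truth features (elliptical fruit,
  controlled red sectors, defect patches, stem marks, multiplicative
  illumination fields), plus PASCAL VOC XML / YOLO txt annotations, so the
  whole chain is testable without any external data.

## Worked example

Render one fruit with known ground truth and measure it:

```python
from applegrade.synthetic import AppleSpec, render_apple
from applegrade.features import extract_features, CalibrationConfig
from applegrade.pipeline import rule_grade

render = render_apple(
    AppleSpec(diameter_mm=72, aspect=0.95, color_coverage=0.85),
    mm_per_px=0.35, seed=7,
)
feats = extract_features(render["image"], CalibrationConfig(0.35))
print(feats)
print(rule_grade(feats))
```

prints

```
AppleFeatures(area_px=33240, perimeter_px=648.70, diameter_mm=72.00,
              shape_index=0.9926, color_ratio=0.8349, defect_area_cm2=0.0)
1
```

— a 72.0 mm, nearly circular (e = 0.99), 83% red fruit: grade 1 on every
characteristic (diameter ≥ 70 mm, e ≥ 0.85, coverage ≥ 0.80, no defect).

Build the two reference networks and report their sizes:

```
$ applegrade build-model --arch detector
detector: 6782698 parameters (6.78 M)
$ applegrade build-model --arch grader
grader: 3779490 parameters (3.78 M)
```

Other subcommands: `applegrade enhance` (Retinex on one image),
`applegrade features` (JSON feature record for one view),
`applegrade synth` (render an annotated dataset with a 3:1 train/test
split), `applegrade run` (grade every fruit track across a directory of
frames, classical or scripted-stub detections, YAML-configured).

## Layout

```
src/applegrade/
  retinex.py       illumination correction
  features.py      segmentation + shape/size/color features
  neural/          tensor core, blocks (ODConv, GSConv, VoVGSCSP, Swin),
                   model builders, smoke training
  pipeline.py      rule grading + multi-view decision logic
  synthetic.py     seeded scene generator
  annotations.py   PASCAL VOC XML / YOLO txt IO
  config.py, cli.py
docs/methods.md    model assumptions, parameter choices, limitations
```
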