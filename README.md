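# capest — coordinate-attention detection of small crop pests

`capest` is a CPU-friendly research toolkit for detecting **small, densely
distributed objects** — the crop-pest regime, where a typical instance
covers well under 1% of the image and several instances share a frame. It
implements, from the numerics up (a compact reverse-mode autodiff engine on
NumPy; no deep-learning framework required):

* **CAFPN** — a feature pyramid whose top-down fusion is modulated by
  *coordinate attention*: directional average pooling along height and
  width produces per-row and per-column sigmoid gates
  `o[c,i,j] = x[c,i,j] · gh[c,i] · gw[c,j]`, so the fused features keep
  position information that plain pooling destroys. A switch reverts to
  the plain pyramid `Y_i = C_i(X_i) + Up(Y_{i+1})` bit for bit.
* An **anchor-free three-branch head** (class scores, four boundary
  distances, centerness), decoded as `box = (x−l, y−t, x+r, y+b)` with
  score `√(p_cls · p_ctr)` and class-wise NMS.
* **Dynamic soft sample weighting** — positives are weighted by a
  *learnable category-specific Gaussian center prior*
  `G(d|μ_c,θ_c) = exp(−Σ_a (d_a−μ_a)²/θ_a²)`, normalized per object;
  negatives by `w⁻ = 1 − N(1/(1−k))` with `k` the best IoU of the point's
  predicted box against the ground truth. `μ, θ` (shape `(C,2)`) train by
  backpropagation and can recover systematic per-class annotation offsets.
* A **synthetic dense small-object scene generator** with COCO-format
  output, emulating field-trap statistics (21 classes, ≥1 instance per
  image, ~20% of images with >5 instances, relative scales 0.01–1%).
* A **COCO-protocol evaluator** (AP/AR, IoU 0.5:0.05:0.95, 101-point
  interpolation, size strata at 32² and 96²) and a trainable-parameter
  accountant.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Train the desk-scale detector (tiny backbone, 128×128 synthetic scenes) and
evaluate on held-out scenes:

```python
from capest.experiments import run_desk_experiment, parameter_budget

res = run_desk_experiment(seed=1, use_ca=True, dynamic=True,
                          out_dir="runs/demo")   # ~1 min on one core
print(res.report.summary())
```

which prints (seed 1):

```
        ap:   58.2%
      ap50:   91.7%
      ap75:   68.9%
  ap_small:   57.0%
 ap_medium:   66.9%
  ap_large:    n/a
  ar_small:   68.5%
 ar_medium:   71.0%
  ar_large:    n/a
```

`ap50 = 91.7%` is the COCO average precision at IoU 0.5 on 60 held-out
scenes after 12 epochs on 200 scenes; `ap` averages IoU thresholds
0.5–0.95; the size strata follow the COCO 32²/96² area cuts (these scenes
contain no "large" objects, hence `n/a`). Running the same seed with
`use_ca=False, dynamic=False` (plain pyramid + fixed center sampling)
lowers the held-out AP at IoU 0.5 by several points — the ablation the
package is built to probe.

Model-size accounting of the full-scale detector (ResNet-50 + CAFPN):

```python
print(parameter_budget()["reference"])
# {'cafpn_m': 32.19, 'baseline_m': 32.02,
#  'cafpn_exact': 32192376, 'baseline_exact': 32020122}
```

Coordinate attention adds 0.17 M trainable parameters (three blocks of
57,418) on top of the 32.02 M plain-pyramid baseline.

## Command line

```bash
capest synth --n 200 --out data/           # synthetic COCO dataset
capest train --config cfg.yaml             # SGD, momentum 0.9, lr drops ×10
capest eval  --config cfg.yaml --checkpoint runs/demo/last.npz \
             --ann data/annotations.json
capest detect --config cfg.yaml --checkpoint runs/demo/last.npz \
              --image data/images/scene_00000.png --out vis.png
```

`detect` draws predictions in green and (with `--gt`) annotations in red.

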