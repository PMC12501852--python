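# amodalfruit

Amodal RGB-D instance segmentation of occluded greenhouse fruit.

Fruit growing in dense greenhouse rows constantly hide one another and
disappear behind stems and leaves.  Ordinary instance segmentation only
labels the pixels a camera actually sees, so every downstream phenotyping
quantity — fruit size, shape, grasp point, ripeness coverage — is biased as
soon as occlusion appears.  *Amodal* segmentation predicts each object's
complete silhouette, hidden parts included.  This package is a toolkit for
building and evaluating such models when no public RGB-D amodal dataset
exists for the crop at hand:

* **`scene_synth`** — a procedural generator of greenhouse-like RGB-D scenes
  (1–10 spherical fruit plus stem/leaf occluders, hemispherical-shell camera
  and light sampling, three illumination regimes) rendered by an analytic
  z-buffer ray caster that yields *exact* amodal, visible and occlusion
  masks for free.
* **`amodal_masks`** — the mask algebra (`M_O = M_A \ M_V`, occlusion rate
  `|M_O| / |M_A|`, occlusion-rate strata) and the clone-fusion procedure
  that manufactures amodal ground truth for real photographs by pasting a
  cropped instance over another image.
* **`cga_asnet`** — a two-stream detection network with contextual and
  global attention: RGB and depth backbones whose residual blocks can use a
  convolutional attention block (CFT) and whose stage outputs can pass
  through channel + spatial attention (GAM); C3–C5 features are fused by
  1×1 convolutions into an FPN, and a four-branch head predicts box/class,
  visible mask, amodal mask and an occlusion flag with a hierarchical
  dependency `F_V → F_A → F_O`.
* **`amodal_metrics`** — pixel precision/recall/F1, Hungarian-matched
  **F@.75**, **mIoU**, and mask **AP50/AP75/mAP**.
* **`pipeline`** / CLI — the end-to-end generate → train → predict →
  evaluate workflow, fully seeded.

The network runs on a small numpy reverse-mode autodiff engine bundled with
the package (`amodalfruit.nn`), so the whole pipeline — including training —
is reproducible on a single CPU.

## The statistics at the core

For a predicted mask `P` and a ground-truth mask `G`,

    F1(P, G) = 2|P ∩ G| / (2|P ∩ G| + |P \ G| + |G \ P|).

Pairwise F1 scores between predictions and ground truths form a matrix; the
Hungarian algorithm picks the one-to-one assignment `M` maximising total F1
(greedy matching is *not* equivalent), and

    F@.75 = (1/N) Σ_{(i,j)∈M} 1{F1_ij ≥ 0.75}

over the `N` ground-truth instances.  mIoU averages matched-pair IoUs with
unmatched ground truths scored 0; AP integrates the 101-point interpolated
precision–recall curve at a mask-IoU threshold, and mAP averages AP over
thresholds 0.50:0.05:0.95.  The training loss is the unweighted sum

    L = L_cls + L_box + L_V + L_A + L_Ocls + L_rpn_cls + L_rpn_loc.

## Worked example

The pinned *tiny desk profile* (96×96 frames, 2–4 enlarged fruit, width-16
backbone, 300 iterations) exercises the identical code path as the
full-scale configuration, in minutes on a CPU:

```bash
amodalfruit generate --profile tiny --n-scenes 20 --seed 1 --out ds
amodalfruit train --data ds --out run --seed 1
amodalfruit predict --checkpoint run/checkpoint.npz --data ds --split test \
    --out-json preds.json
amodalfruit evaluate --pred-json preds.json --gt-json ds/annotations.json \
    --split test
```

which prints (seed 1, this exact configuration):

```
F@.75  43.8
mIoU   47.9%
AP50   32.3%  AP75 2.0%  mAP 12.9%
  bin  low: F@.75 66.7  mIoU 49.9%  (n=3)
  bin  mid: F@.75 42.9  mIoU 51.0%  (n=7)
  bin high: F@.75 33.3  mIoU 43.1%  (n=6)
```

Reading the output: after only 300 iterations of from-scratch training on
16 synthetic frames, the tiny model already matches ~44 % of unseen test
instances at pixel-F1 ≥ 0.75 and recovers about half of each instance's
full (amodal) area; accuracy degrades from the low- to the high-occlusion
stratum, as expected.  On its own training split the same model reaches
F@.75 57.8 / mIoU 61.2 % — the overfitting gap that the scaled-down
learning test exploits.  Training losses are logged per iteration and per
component in `run/losses.jsonl` (total falls 3.58 → 1.27 over the 300
iterations in this run).

The same workflow is available from Python:

```python
from amodalfruit.pipeline import tiny_profile, run_generate, run_train

config = tiny_profile(seed=1)
run_generate(config, "ds")
model, history = run_train(config, "ds", "run")
detections = model.predict(rgb, depth)   # list of Detection records
```

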