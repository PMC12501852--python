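# Methods

This note records the models, conventions and design decisions behind the
package, in the order the pipeline runs.

## Synthetic scene model

**Geometry.** A scene is a cluster of 1–10 spherical fruit (radius
0.03–0.05 m by default, centers within ±0.25 m of the world origin,
right-handed frame, z up) plus 0–4 occluders: stems as finite open
cylinders (radius 0.3–0.6×, length 2–5× the mean fruit radius, roughly
vertical axes) and leaves as discs (radius 0.8–1.6× the mean fruit
radius).  Occluder sizes scale with fruit radius so the occlusion-rate
distribution is stable across image resolutions.  Spheres are a deliberate
simplification: tomatoes are approximately round, and exact analytic
intersections are what make pixel-exact amodal ground truth and an
independent ray-casting oracle possible.

**Camera sampling.** The scene footprint is drawn as length l ∈ [1, 2] m
and width w ∈ [2, 4] m; the camera shell radii are

    r_view_lower = max(w/2, l/2),      r_view_upper = 1.7 · r_view_lower.

Positions are uniform over the *volume* of the upper hemispherical shell:
radius by inverse-CDF on r³ (so E[r³] is the midpoint of [r_lo³, r_hi³],
which the tests check), direction uniform over solid angle on the upper
hemisphere.  The camera always looks at the origin.  Intrinsics default to
a 60° horizontal-FOV pinhole with the principal point at the image center —
a conventional choice, since nothing downstream depends on the exact FOV.

**Lights.** 0–2 point lights (count uniform on {0, 1, 2}) are placed in an
outer shell.  The two printed shell equations are mutually circular as a
pair, so the package fixes the only self-consistent reading, anchored to
the camera shell: `r_light_lower = r_view_upper + 0.1 m` and
`r_light_upper = r_light_lower + 1 m`.  Three illumination regimes map to
(ambient, point-intensity) pairs — strong (0.35, 1.0), normal (0.25, 0.6),
weak (0.12, 0.25) — with a per-light ×U(0.8, 1.2) intensity jitter drawn
after the geometry, so two regimes with equal seeds share identical light
positions and differ only in intensity (an ordering the tests rely on).
The default regime mixture is 20 % strong / 60 % normal / 20 % weak.

**Renderer.** An analytic z-buffer: per primitive, a conservative
image-space rectangle is derived from its bounding sphere, and ray–
primitive intersections are evaluated vectorised inside it; the nearest
hit wins (ties go to the earlier-indexed primitive, deterministically).
Each fruit is additionally intersected in isolation to obtain its amodal
mask; visible = id-buffer ownership; occlusion = amodal \ visible.
Shading is Lambertian plus regime ambient, with no cast shadows or
reflections — cosmetic effects that do not alter any mask.  Depth is
distance along the optical axis, valid within 0.25–5.46 m (the working
range of the emulated time-of-flight sensor); values outside are written
as invalid (0).  Depth PNGs are 16-bit millimeters.  Equality with a
per-pixel brute-force closest-hit ray caster, written independently in the
test suite, is asserted pixel-for-pixel on 100 random sphere scenes.

**What the generator does not emulate:** texture, specularity, soft
shadows, non-spherical fruit, plant architecture, and sensor noise.
Passing tests therefore demonstrate that the algorithms are correct on
geometrically faithful occlusion patterns, not that a model trained here
transfers to real greenhouse imagery.

## Mask algebra and annotation

`M_O = M_A \ M_V` is a set difference on binary rasters (never signed
arithmetic); a visible pixel outside the amodal silhouette is a hard
error.  Occlusion rate is `|M_O| / |M_A|`; rate 1 (no visible pixels)
drops the annotation.  The occlusion strata are half-open —
[0, 0.10), [0.10, 0.30), [0.30, 1.00] — because printed stratum labels
with shared endpoints cannot partition instances for counting.
A dataset's stratification table counts instances by their own bins and
assigns each *image* to the bin of its most-occluded instance.

Clone fusion pastes the tight crop of a source instance's visible mask
onto a target image.  Every pre-existing instance's pre-paste visible
mask becomes its amodal ground truth; the paste footprint splits it into
new visible and occlusion parts, and fully covered instances are dropped.
Compositing is hard alpha with optional 1-px feathering: any blending
scheme yields identical derived masks, so gradient-domain blending is
out of scope.

## Network

Two residual backbones (3-channel RGB, 1-channel depth; depth normalised
as `(d − 0.25) / (5.46 − 0.25)` clipped to [0, 1], invalid → 0) produce
C3–C5 at strides 8/16/32.  Group normalisation is used throughout because
training runs at batch size 2.

**CFT block** (replaces the second 3×3 convolution of a residual block in
the configured stages, default C3–C5): key `K` from two stacked 3×3
convolutions, query `Q` and value `V` from 1×1 convolutions; attention
logits `θ` from two 1×1 convolutions of `K ⊕ Q`; `W = softmax(θ)` over
the *channel* axis at each position — the only axis whose normalisation
length is independent of image size; the attended value `W ⊙ V` passes
through a 3×3 dilation-2 convolution `M`, and `Y = Conv₁ₓ₁(K + M(W ⊙ V))`.
The placement of `W` (on `V`, before `M`) follows the block's stated data
flow; both the softmax axis and the CFT/GAM placements are configuration
axes so attention ablations (baseline / +CFT / +GAM / both) are
expressible by flags alone.

**GAM** (applied to stage outputs, default C3–C5): channel attention —
shared two-layer MLP (reduction r = 4) over global average- and max-pooled
descriptors, summed, sigmoid; then spatial attention — channelwise
average/max maps through a 7×7 convolution and sigmoid.

**Fusion and detection.** Per level, RGB and depth features are
concatenated on channels and reduced by a 1×1 convolution, then fed to an
FPN (P3–P5), a single-anchor-per-cell RPN (anchor sizes per level are
config), and RoIAlign (7×7 box, 14×14 mask, bilinear, 2×2 samples per
bin).  The box branch flattens the 7×7 feature through two FC layers into
class logits and box deltas.  The mask branches receive the 7×7 box
feature upsampled to 14×14 (`F_B`, taken *before* the FC layers — the
spatial map is what can be upsampled) together with the 14×14 RoI feature
(`F_RoI`).  Hierarchical fusion towers `h_V`, `h_A`, `h_O` each concat
their inputs and apply three channel-reducing 3×3 convolutions followed by
three more; the dependency order is strict: `F_A = h_A(F_B, F_RoI, F_V)`
and `F_O = h_O(F_B, F_RoI, F_V, F_A)` (an ablation hook zeroes `F_V` on
its way into downstream branches to test this isolation).  `P_V`/`P_A`
are a 2×2 stride-2 transposed convolution plus a 1×1 per-pixel classifier
producing 28×28 logits — a dense layer over a 28×28 map would be
parameter-explosive, so the "fully connected" pixel classifier is
implemented as the 1×1 convolution standard in mask heads.  `P_O` is an
FC binary classifier on the globally pooled `F_O`.  The occlusion target
is 1 iff the instance's occlusion mask has ≥ 1 pixel.

**Loss.** `L = Σ` of class CE, box smooth-L1, visible-mask BCE,
amodal-mask BCE (28×28, box-aligned nearest-crop targets), occlusion CE,
RPN objectness BCE and RPN smooth-L1 — weights default to 1 and are
config.  RoI sampling: proposals + ground-truth boxes + 8 random boxes
(so clear negatives exist even when all proposals sit on fruit);
foreground at IoU ≥ 0.5, background at IoU < 0.3, the ambiguous band
unsampled.  Amodal ⊇ visible is *not* enforced at inference; the optional
`union_visible` flag post-processes `A := A ∪ V`.

**Compute engine.** The package ships its own reverse-mode autodiff on
float64 numpy arrays (`amodalfruit.nn`): convolution as a sum of strided
tensordots over kernel offsets, an exact non-overlapping 2×2 stride-2
transposed convolution, RoIAlign with scatter-add backward, and the
detection losses with closed-form gradients.  All custom operators carry
finite-difference gradient checks.  Weights are He-initialised from a
single seeded generator; classification/RPN output layers use small-std
init plus a background-prior bias so an untrained network produces no
detections at the default score threshold (0.5).

## Training schedules

The full profile mirrors the published schedule (640×480 input, batch 2,
initial LR 0.00125, 90,000 iterations).  The pinned tiny desk profile —
96×96 frames, 2–4 fruit, backbone widths (16, 24, 32, 48), 300 iterations
— overrides LR to 0.03 with 20-iteration linear warmup and cosine decay,
and enlarges fruit radii to 0.12–0.20 m so instances subtend ~20 px and
28×28 mask targets stay informative at this resolution; everything else
keeps the default study conditions.  A single global seed fans out via
`SeedSequence` to dataset, network-init and training-loop generators;
checkpoints store weights, optimizer velocity, RNG state and a config
hash, so a resumed run reproduces an uninterrupted one bit-for-bit.

## Evaluation semantics

Matching maximises total pairwise pixel-F1 via the Hungarian algorithm
(cost 1 − F1); `scipy.optimize.linear_sum_assignment` is deterministic,
and the tests verify its optimum against exhaustive permutation
enumeration, including the 2×2 case where greedy matching loses half the
score.  F@.75 counts matched pairs with F1 ≥ 0.75 over all ground truths.
Empty-vs-empty masks score F1 = 1 (vacuous agreement).  mIoU defaults to
*instance* mode — matched-pair IoUs, unmatched ground truths as 0,
averaged per class then across classes — because the statistic is
reported alongside instance-level F@.75; a *semantic* mode (per-class
pixel pooling, background included as the k+1-th class) is provided since
either reading of a class-mean IoU is defensible.  AP uses 101-point
interpolation with greedy per-frame matching by descending score and no
score threshold; mAP averages AP over IoU thresholds 0.50:0.05:0.95.
Per-occlusion-bin reports assign each ground truth to its bin and reuse
the global within-frame matching.

## Problem sizes used by the checks

Shell-containment and radius-moment properties use 10,000 draws; the
renderer oracle compares 100 random ≤3-sphere scenes at 64×64; generator
bounds scan 200 default-scale scenes; Hungarian matching is fuzzed on
1,000 matrices up to 6×6; the learning check trains the tiny profile for
300 iterations on 20 scenes and requires the training loss (mean of the
first vs last 10 iterations, smoothing batch noise) to at least halve and
the amodal-mask IoU of the clearest-occlusion held-in instance to exceed
its visible-mask IoU against the amodal ground truth.  These sizes are the
package's pinned defaults and are deliberately small enough to rerun
anywhere.

## Known limitations

* The generator's photometric realism is minimal by design; sim-to-real
  transfer claims are outside what these tests can support.
* The tiny profile's absolute accuracy is limited by 300 from-scratch
  iterations; it demonstrates learnability and branch differentiation,
  not the ceiling of the architecture.
* The renderer models open cylinders (no end caps); grazing camera
  placements inside occluder bounding spheres fall back to full-frame
  intersection tests rather than being rejected.
* Uncompressed RLE keeps annotations plain-text and dependency-free at
  the cost of file size; large-scale exports would want compressed RLE.
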