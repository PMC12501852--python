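"""Occlusion-aware amodal instance segmentation network for RGB-D input.

Architecture, in the order data flows through it:

1.  Two residual backbones (one for RGB, one for the depth raster)
    whose residual blocks can swap their 3x3 convolution for a
    *contextual feature transformer* (CFT) block — attention weights
    derived by convolving the concatenated key/query context instead of
    dot products — and whose stage outputs can pass through a *global
    attention mechanism* (GAM: channel-attention MLP followed by a 7x7
    spatial-attention convolution).
2.  RGB-D fusion: per pyramid level (C3-C5) the two feature maps are
    concatenated on channels and reduced back with a 1x1 convolution.
3.  A feature pyramid network feeds a region proposal network; RoIAlign
    pools per-proposal features.
4.  A four-branch head: box/class branch (two FC layers), then visible
    mask, amodal mask and occlusion-classification branches fused
    hierarchically — the amodal branch sees the visible branch's
    features, the occlusion branch sees both — so prediction of hidden
    extent is conditioned on what is visible.
5.  The training loss is the unweighted (by default) sum of seven
    terms: class, box, visible mask, amodal mask, occlusion class, RPN
    objectness and RPN localisation.

Everything is width/depth-configurable; the pinned *tiny* configuration
trains on a CPU in minutes and is the one exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor
from .scene_synth import DEPTH_MIN, DEPTH_MAX

__all__ = [
    "NetworkConfig",
    "Detection",
    "LossBreakdown",
    "CFTBlock",
    "ChannelAttention",
    "SpatialAttention",
    "GAM",
    "Backbone",
    "RGBDFusion",
    "FPN",
    "CGAASNet",
    "combine_losses",
    "box_iou_matrix",
    "nms",
]

_STAGES = ("c2", "c3", "c4", "c5")
_LOSS_KEYS = ("cls", "box", "visible", "amodal", "occ_cls",
              "rpn_cls", "rpn_loc")


@dataclass
class NetworkConfig:
    """Width/depth and head configuration.

    Defaults are the CPU-trainable tiny profile; :meth:`full` gives the
    ResNet-50-scale variant matching the published training setup.
    """

    stage_widths: Tuple[int, int, int, int] = (16, 32, 48, 64)
    blocks_per_stage: Tuple[int, int, int, int] = (1, 1, 1, 1)
    cft_stages: Tuple[str, ...] = ("c3", "c4", "c5")
    gam_stages: Tuple[str, ...] = ("c3", "c4", "c5")
    gam_reduction: int = 4
    fpn_width: int = 32
    head_width: int = 32
    head_fc: int = 128
    roi_box_size: int = 7
    roi_mask_size: int = 14
    num_classes: int = 1                    # foreground classes
    loss_weights: Dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in _LOSS_KEYS})
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    anchor_sizes: Tuple[float, ...] = (16.0, 32.0, 64.0)   # per P3/P4/P5
    rpn_pre_nms: int = 200
    rpn_post_nms: int = 24
    roi_samples: int = 16
    union_visible: bool = False             # post-hoc A := A | V
    seed: int = 0

    @property
    def mask_out_size(self) -> int:
        # one 2x2 deconvolution doubles the mask RoI resolution
        return 2 * self.roi_mask_size

    @classmethod
    def full(cls, **over) -> "NetworkConfig":
        base = dict(stage_widths=(256, 512, 1024, 2048),
                    blocks_per_stage=(3, 4, 6, 3), fpn_width=256,
                    head_width=256, head_fc=1024,
                    anchor_sizes=(32.0, 64.0, 128.0))
        base.update(over)
        return cls(**base)


@dataclass
class Detection:
    """One predicted instance."""

    box: Tuple[float, float, float, float]   # [x0, y0, x1, y1] px
    class_label: int
    score: float
    visible: np.ndarray                       # (H, W) bool
    amodal: np.ndarray                        # (H, W) bool
    occluded: int                             # occlusion classification


@dataclass
class LossBreakdown:
    """The seven loss components and their weighted sum."""

    components: Dict[str, float]
    weights: Dict[str, float]
    total: float

    def __post_init__(self):
        for k, v in self.components.items():
            if v < -1e-9:
                raise ValueError(f"loss component {k} is negative: {v}")


def combine_losses(components: Dict[str, "Tensor | float"],
                   weights: Optional[Dict[str, float]] = None):
    """Weighted sum of the loss components.

    Accepts either scalars (returns a plain :class:`LossBreakdown`) or
    autodiff tensors (returns ``(total_tensor, LossBreakdown)``).
    """
    weights = dict(weights or {})
    for k in components:
        weights.setdefault(k, 1.0)
    tensors = {k: v for k, v in components.items() if isinstance(v, Tensor)}
    if tensors:
        total = None
        for k, v in components.items():
            term = (v if isinstance(v, Tensor) else Tensor(float(v))) * weights[k]
            total = term if total is None else total + term
        breakdown = LossBreakdown(
            components={k: float(v.data) if isinstance(v, Tensor) else float(v)
                        for k, v in components.items()},
            weights=weights, total=float(total.data))
        return total, breakdown
    total = sum(weights[k] * float(v) for k, v in components.items())
    return LossBreakdown(components={k: float(v) for k, v in components.items()},
                         weights=weights, total=total)


# ---------------------------------------------------------------------------
# Attention blocks
# ---------------------------------------------------------------------------

class CFTBlock(nn.Module):
    """Contextual feature transformer.

    Key K: two stacked 3x3 convolutions of the input (the second one
    locally enhances the key).  Query Q and value V: 1x1 convolutions.
    Attention logits: two 1x1 convolutions of the channel-concatenated
    (K, Q); softmax over channels at each position gives weights W.
    The weighted value W*V passes through a dilated 3x3 convolution M
    (receptive-field growth at constant resolution) and is fused with K
    by a final 1x1 convolution.  Output shape equals input shape.
    """

    def __init__(self, rng, channels: int):
        c = channels
        self.conv_k1 = nn.Conv2d(rng, c, c, 3, padding=1)
        self.conv_k2 = nn.Conv2d(rng, c, c, 3, padding=1)
        self.conv_q = nn.Conv2d(rng, c, c, 1)
        self.conv_v = nn.Conv2d(rng, c, c, 1)
        self.conv_t1 = nn.Conv2d(rng, 2 * c, c, 1)
        self.conv_t2 = nn.Conv2d(rng, c, c, 1)
        self.conv_m = nn.Conv2d(rng, c, c, 3, padding=2, dilation=2)
        self.conv_out = nn.Conv2d(rng, c, c, 1)

    def attention_weights(self, x: Tensor) -> Tensor:
        k = self.conv_k2(self.conv_k1(x))
        q = self.conv_q(x)
        theta = self.conv_t2(self.conv_t1(nn.concat([k, q], axis=1)))
        return theta.softmax(axis=1)

    def forward(self, x: Tensor) -> Tensor:
        k = self.conv_k2(self.conv_k1(x))
        q = self.conv_q(x)
        v = self.conv_v(x)
        theta = self.conv_t2(self.conv_t1(nn.concat([k, q], axis=1)))
        w = theta.softmax(axis=1)
        attended = w * v
        m = self.conv_m(attended)
        return self.conv_out(k + m)


class ChannelAttention(nn.Module):
    """GAM channel stage: shared two-layer MLP over avg- and max-pooled
    descriptors, summed and squashed to (0, 1)."""

    def __init__(self, rng, channels: int, reduction: int):
        if channels % reduction:
            raise ValueError(
                f"channels {channels} not divisible by reduction {reduction}")
        self.fc1 = nn.Linear(rng, channels, channels // reduction)
        self.fc2 = nn.Linear(rng, channels // reduction, channels)

    def attention(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        gate = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return gate.sigmoid()                 # (B, C) in (0, 1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        return x * self.attention(x).reshape(B, C, 1, 1)


class SpatialAttention(nn.Module):
    """GAM spatial stage: channelwise avg/max maps through a 7x7 conv."""

    def __init__(self, rng):
        self.conv = nn.Conv2d(rng, 2, 1, 7, padding=3)

    def attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(nn.concat([avg, mx], axis=1)).sigmoid()  # (B,1,H,W)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention(x)


class GAM(nn.Module):
    """Channel attention followed by spatial attention; shape preserving."""

    def __init__(self, rng, channels: int, reduction: int = 4):
        self.cam = ChannelAttention(rng, channels, reduction)
        self.sam = SpatialAttention(rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.sam(self.cam(x))


# ---------------------------------------------------------------------------
# Backbone / fusion / FPN
# ---------------------------------------------------------------------------

def _gn(channels: int) -> nn.GroupNorm:
    g = 8
    while channels % g:
        g //= 2
    return nn.GroupNorm(g, channels)


class ResidualBlock(nn.Module):
    """Basic residual block; the second 3x3 conv may be a CFT block."""

    def __init__(self, rng, in_ch, out_ch, stride=1, use_cft=False):
        self.conv1 = nn.Conv2d(rng, in_ch, out_ch, 3, stride=stride, padding=1)
        self.gn1 = _gn(out_ch)
        self.inner = CFTBlock(rng, out_ch) if use_cft else \
            nn.Conv2d(rng, out_ch, out_ch, 3, padding=1)
        self.gn2 = _gn(out_ch)
        self.proj = (nn.Conv2d(rng, in_ch, out_ch, 1, stride=stride)
                     if (stride != 1 or in_ch != out_ch) else None)

    def forward(self, x):
        h = self.gn1(self.conv1(x)).relu()
        h = self.gn2(self.inner(h))
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class Backbone(nn.Module):
    """Residual backbone with optional CFT blocks and per-stage GAM.

    Returns C3/C4/C5 feature maps at strides 8/16/32.
    """

    def __init__(self, rng, in_channels: int, config: NetworkConfig):
        w = config.stage_widths
        self.stem1 = nn.Conv2d(rng, in_channels, w[0], 3, stride=2, padding=1)
        self.stem_gn1 = _gn(w[0])
        self.stem2 = nn.Conv2d(rng, w[0], w[0], 3, stride=2, padding=1)
        self.stem_gn2 = _gn(w[0])
        self.stages = []
        in_ch = w[0]
        for si, name in enumerate(_STAGES):
            blocks = []
            stride = 1 if name == "c2" else 2
            for b in range(config.blocks_per_stage[si]):
                blocks.append(ResidualBlock(
                    rng, in_ch, w[si], stride=stride if b == 0 else 1,
                    use_cft=name in config.cft_stages))
                in_ch = w[si]
            self.stages.append(nn.ModuleList(blocks))
        self.gams = []
        for si, name in enumerate(_STAGES):
            self.gams.append(GAM(rng, w[si], config.gam_reduction)
                             if name in config.gam_stages else None)

    def forward(self, x: Tensor) -> Dict[str, Tensor]:
        h = self.stem_gn1(self.stem1(x)).relu()
        h = self.stem_gn2(self.stem2(h)).relu()
        feats: Dict[str, Tensor] = {}
        for name, stage, gam in zip(_STAGES, self.stages, self.gams):
            for block in stage:
                h = block(h)
            out = gam(h) if gam is not None else h
            feats[name] = out
            h = out
        return {k: feats[k] for k in ("c3", "c4", "c5")}


class RGBDFusion(nn.Module):
    """Per-level channel concatenation + 1x1 reduction of the two streams."""

    def __init__(self, rng, config: NetworkConfig):
        w = config.stage_widths
        self.convs = nn.ModuleList([
            nn.Conv2d(rng, 2 * w[i], w[i], 1) for i in (1, 2, 3)])

    def forward(self, rgb: Dict[str, Tensor],
                depth: Dict[str, Tensor]) -> Dict[str, Tensor]:
        fused = {}
        for conv, name in zip(self.convs, ("c3", "c4", "c5")):
            a, b = rgb[name], depth[name]
            if a.shape[2:] != b.shape[2:]:
                raise ValueError(f"spatial mismatch at {name}: "
                                 f"{a.shape} vs {b.shape}")
            fused[name] = conv(nn.concat([a, b], axis=1))
        return fused


class FPN(nn.Module):
    def __init__(self, rng, config: NetworkConfig):
        w, f = config.stage_widths, config.fpn_width
        self.lat = nn.ModuleList([nn.Conv2d(rng, w[i], f, 1) for i in (1, 2, 3)])
        self.out = nn.ModuleList([nn.Conv2d(rng, f, f, 3, padding=1)
                                  for _ in range(3)])

    def forward(self, feats: Dict[str, Tensor]) -> Dict[str, Tensor]:
        l3 = self.lat[0](feats["c3"])
        l4 = self.lat[1](feats["c4"])
        l5 = self.lat[2](feats["c5"])
        p5 = l5
        p4 = l4 + nn.upsample_nearest2(p5)
        p3 = l3 + nn.upsample_nearest2(p4)
        return {"p3": self.out[0](p3), "p4": self.out[1](p4),
                "p5": self.out[2](p5)}


# ---------------------------------------------------------------------------
# Boxes, anchors, proposals
# ---------------------------------------------------------------------------

def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU between two (N,4) / (M,4) box arrays, [x0,y0,x1,y1]."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    area_a = np.maximum(a[:, 2] - a[:, 0], 0) * np.maximum(a[:, 3] - a[:, 1], 0)
    area_b = np.maximum(b[:, 2] - b[:, 0], 0) * np.maximum(b[:, 3] - b[:, 1], 0)
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.maximum(x1 - x0, 0) * np.maximum(y1 - y0, 0)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> List[int]:
    order = np.argsort(-scores, kind="stable")
    keep: List[int] = []
    while len(order):
        i = int(order[0])
        keep.append(i)
        if len(order) == 1:
            break
        ious = box_iou_matrix(boxes[i][None], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thr]
    return keep


def _encode_deltas(anchors: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = (anchors[:, 0] + anchors[:, 2]) / 2
    ay = (anchors[:, 1] + anchors[:, 3]) / 2
    gw = np.maximum(boxes[:, 2] - boxes[:, 0], 1e-6)
    gh = np.maximum(boxes[:, 3] - boxes[:, 1], 1e-6)
    gx = (boxes[:, 0] + boxes[:, 2]) / 2
    gy = (boxes[:, 1] + boxes[:, 3]) / 2
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def _decode_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = (anchors[:, 0] + anchors[:, 2]) / 2
    ay = (anchors[:, 1] + anchors[:, 3]) / 2
    d = np.clip(deltas, -4.0, 4.0)
    cx = ax + d[:, 0] * aw
    cy = ay + d[:, 1] * ah
    w = aw * np.exp(d[:, 2])
    h = ah * np.exp(d[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


class RPN(nn.Module):
    def __init__(self, rng, config: NetworkConfig):
        f = config.fpn_width
        self.conv = nn.Conv2d(rng, f, f, 3, padding=1)
        self.obj = nn.Conv2d(rng, f, 1, 1)
        self.deltas = nn.Conv2d(rng, f, 4, 1)
        # small output init + background prior keep untrained objectness low
        self.obj.weight.data *= 0.05
        self.deltas.weight.data *= 0.05
        self.obj.bias.data[:] = -2.0

    def forward(self, pyramid: Dict[str, Tensor]):
        outs = {}
        for name, feat in pyramid.items():
            h = self.conv(feat).relu()
            outs[name] = (self.obj(h), self.deltas(h))
        return outs


def make_anchors(level_shapes: Dict[str, Tuple[int, int]],
                 sizes: Sequence[float]) -> Dict[str, np.ndarray]:
    anchors = {}
    for (name, (H, W)), size in zip(level_shapes.items(), sizes):
        stride = {"p3": 8, "p4": 16, "p5": 32}[name]
        ys, xs = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        cx = (xs.ravel() + 0.5) * stride
        cy = (ys.ravel() + 0.5) * stride
        half = size / 2.0
        anchors[name] = np.stack(
            [cx - half, cy - half, cx + half, cy + half], axis=1)
    return anchors


# ---------------------------------------------------------------------------
# Heads
# ---------------------------------------------------------------------------

class FusionTower(nn.Module):
    """Hierarchical fusion h_*: concat inputs -> three channel-reducing 3x3
    convolutions -> three more 3x3 convolutions."""

    def __init__(self, rng, in_ch: int, width: int):
        self.reduce = nn.ModuleList([
            nn.Conv2d(rng, in_ch, width, 3, padding=1),
            nn.Conv2d(rng, width, width, 3, padding=1),
            nn.Conv2d(rng, width, width, 3, padding=1)])
        self.refine = nn.ModuleList([
            nn.Conv2d(rng, width, width, 3, padding=1) for _ in range(3)])
        self.norms = nn.ModuleList([_gn(width) for _ in range(6)])

    def forward(self, inputs: List[Tensor]) -> Tensor:
        h = nn.concat(inputs, axis=1) if len(inputs) > 1 else inputs[0]
        for i, conv in enumerate(list(self.reduce) + list(self.refine)):
            h = self.norms[i](conv(h)).relu()
        return h


class MaskPredictor(nn.Module):
    """P_V / P_A: one 2x2 deconvolution then a 1x1 pixel classifier."""

    def __init__(self, rng, width: int, num_classes: int):
        self.deconv = nn.ConvTranspose2x2(rng, width, width)
        self.logits = nn.Conv2d(rng, width, num_classes, 1)

    def forward(self, f: Tensor) -> Tensor:
        return self.logits(self.deconv(f).relu())


class SegmentationHead(nn.Module):
    """Box branch + hierarchically fused V / A / O branches (Eq.-style
    dependency order: F_A needs F_V, F_O needs F_V and F_A)."""

    def __init__(self, rng, config: NetworkConfig):
        f, w = config.fpn_width, config.head_width
        k = config.num_classes
        box_in = f * config.roi_box_size ** 2
        self.fc1 = nn.Linear(rng, box_in, config.head_fc)
        self.fc2 = nn.Linear(rng, config.head_fc, config.head_fc)
        self.cls = nn.Linear(rng, config.head_fc, k + 1)
        self.box = nn.Linear(rng, config.head_fc, 4)
        self.cls.weight.data *= 0.05
        self.box.weight.data *= 0.05
        self.cls.bias.data[0] = 1.0     # background prior at init
        self.h_v = FusionTower(rng, 2 * f, w)
        self.h_a = FusionTower(rng, 2 * f + w, w)
        self.h_o = FusionTower(rng, 2 * f + 2 * w, w)
        self.p_v = MaskPredictor(rng, w, k)
        self.p_a = MaskPredictor(rng, w, k)
        self.p_o = nn.Linear(rng, w, 2)
        self.config = config

    def box_branch(self, f_box: Tensor):
        n = f_box.shape[0]
        flat = f_box.reshape(n, -1)
        h = self.fc1(flat).relu()
        h = self.fc2(h).relu()
        return self.cls(h), self.box(h)

    def mask_branches(self, f_b: Tensor, f_roi: Tensor,
                      ablate_visible: bool = False):
        """Returns (visible logits, amodal logits, occlusion logits).

        ``ablate_visible`` zeroes the F_V feature where it feeds the
        downstream branches (dependency-isolation testing); the visible
        branch's own output is untouched.
        """
        f_v = self.h_v([f_b, f_roi])
        v_logits = self.p_v(f_v)
        f_v_in = Tensor(np.zeros_like(f_v.data)) if ablate_visible else f_v
        f_a = self.h_a([f_b, f_roi, f_v_in])
        a_logits = self.p_a(f_a)
        f_o = self.h_o([f_b, f_roi, f_v_in, f_a])
        n, w = f_o.shape[0], f_o.shape[1]
        pooled = f_o.reshape(n, w, -1).mean(axis=2)
        o_logits = self.p_o(pooled)
        return v_logits, a_logits, o_logits


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class CGAASNet(nn.Module):
    """Two-stream RGB-D amodal instance segmentation network."""

    def __init__(self, config: Optional[NetworkConfig] = None):
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(self.config.seed)
        self.backbone_rgb = Backbone(rng, 3, self.config)
        self.backbone_depth = Backbone(rng, 1, self.config)
        self.fusion = RGBDFusion(rng, self.config)
        self.fpn = FPN(rng, self.config)
        self.rpn = RPN(rng, self.config)
        self.head = SegmentationHead(rng, self.config)

    # -- input handling ------------------------------------------------

    @staticmethod
    def normalize_inputs(rgb: np.ndarray, depth: np.ndarray):
        rgb = np.asarray(rgb)
        depth = np.asarray(depth, dtype=np.float64)
        if rgb.shape[:2] != depth.shape:
            raise ValueError("rgb and depth must be registered and equal size")
        x_rgb = rgb.astype(np.float64).transpose(2, 0, 1)[None] / 255.0
        valid = depth > 0
        d = np.where(valid,
                     np.clip((depth - DEPTH_MIN) / (DEPTH_MAX - DEPTH_MIN),
                             0.0, 1.0),
                     0.0)
        return Tensor(x_rgb), Tensor(d[None, None])

    def extract_pyramid(self, rgb: np.ndarray, depth: np.ndarray):
        x_rgb, x_d = self.normalize_inputs(rgb, depth)
        fused = self.fusion(self.backbone_rgb(x_rgb),
                            self.backbone_depth(x_d))
        return self.fpn(fused)

    # -- proposals -----------------------------------------------------

    def _proposals(self, pyramid, image_size):
        cfg = self.config
        rpn_out = self.rpn(pyramid)
        shapes = {name.replace("c", "p"): feat.shape[2:]
                  for name, feat in pyramid.items()}
        anchors = make_anchors({n: pyramid[n].shape[2:] for n in pyramid},
                               cfg.anchor_sizes)
        all_boxes, all_scores = [], []
        for name in pyramid:
            obj, deltas = rpn_out[name]
            score = 1.0 / (1.0 + np.exp(-obj.data[0, 0].ravel()))
            d = deltas.data[0].reshape(4, -1).T
            boxes = _decode_deltas(anchors[name], d)
            all_boxes.append(boxes)
            all_scores.append(score)
        boxes = np.concatenate(all_boxes)
        scores = np.concatenate(all_scores)
        W, H = image_size
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, W)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, H)
        wh = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
        ok = wh > 4.0
        boxes, scores = boxes[ok], scores[ok]
        top = np.argsort(-scores, kind="stable")[:cfg.rpn_pre_nms]
        boxes, scores = boxes[top], scores[top]
        keep = nms(boxes, scores, 0.7)[:cfg.rpn_post_nms]
        return boxes[keep], scores[keep], rpn_out, anchors

    def _roi_features(self, pyramid, boxes: np.ndarray, size: int):
        """RoIAlign with FPN level assignment by box scale."""
        if len(boxes) == 0:
            f = self.config.fpn_width
            return Tensor(np.zeros((0, f, size, size)))
        areas = np.maximum(boxes[:, 2] - boxes[:, 0], 1e-6) * \
            np.maximum(boxes[:, 3] - boxes[:, 1], 1e-6)
        levels = np.clip(np.floor(3 + np.log2(np.sqrt(areas) / 56.0)),
                         3, 5).astype(int)
        parts, order = [], []
        for lv, name, scale in ((3, "p3", 1 / 8), (4, "p4", 1 / 16),
                                (5, "p5", 1 / 32)):
            idx = np.flatnonzero(levels == lv)
            if len(idx) == 0:
                continue
            parts.append(nn.roi_align(pyramid[name], boxes[idx], size, scale))
            order.append(idx)
        order = np.concatenate(order)
        feats = nn.concat(parts, axis=0) if len(parts) > 1 else parts[0]
        inv = np.argsort(order, kind="stable")
        return feats[inv]

    # -- inference -----------------------------------------------------

    def predict(self, rgb: np.ndarray, depth: np.ndarray) -> List[Detection]:
        """Full detection pass on one registered RGB-D frame."""
        cfg = self.config
        H, W = np.asarray(rgb).shape[:2]
        pyramid = self.extract_pyramid(rgb, depth)
        proposals, _, _, _ = self._proposals(pyramid, (W, H))
        if len(proposals) == 0:
            return []
        f_box = self._roi_features(pyramid, proposals, cfg.roi_box_size)
        cls_logits, box_deltas = self.head.box_branch(f_box)
        probs = cls_logits.softmax(axis=1).data
        scores = probs[:, 1:].max(axis=1)
        labels = probs[:, 1:].argmax(axis=1) + 1
        boxes = _decode_deltas(proposals, box_deltas.data)
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, W)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, H)
        keep = scores >= cfg.score_threshold
        boxes, scores, labels = boxes[keep], scores[keep], labels[keep]
        if len(boxes) == 0:
            return []
        keep = nms(boxes, scores, cfg.nms_iou)
        boxes, scores, labels = boxes[keep], scores[keep], labels[keep]

        f_b = nn.upsample_nearest2(
            self._roi_features(pyramid, boxes, cfg.roi_box_size))
        f_roi = self._roi_features(pyramid, boxes, cfg.roi_mask_size)
        v_logits, a_logits, o_logits = self.head.mask_branches(f_b, f_roi)
        detections = []
        for i in range(len(boxes)):
            ci = labels[i] - 1
            vis = _paste_mask(v_logits.data[i, ci], boxes[i], (H, W))
            amo = _paste_mask(a_logits.data[i, ci], boxes[i], (H, W))
            if cfg.union_visible:
                amo = amo | vis
            occ = int(np.argmax(o_logits.data[i]))
            detections.append(Detection(
                box=tuple(float(v) for v in boxes[i]),
                class_label=int(labels[i]), score=float(scores[i]),
                visible=vis, amodal=amo, occluded=occ))
        return detections

    # -- training ------------------------------------------------------

    def compute_losses(self, rgb: np.ndarray, depth: np.ndarray,
                       gt_boxes: np.ndarray, gt_visible: Sequence[np.ndarray],
                       gt_amodal: Sequence[np.ndarray],
                       gt_occluded: Sequence[int],
                       rng: np.random.Generator) -> Dict[str, Tensor]:
        """The seven loss components on one frame (matched proposals).

        ``gt_boxes``: (G, 4) amodal boxes; masks are frame-sized binaries;
        ``gt_occluded``: 1 if the instance has a nonempty occlusion mask.
        """
        cfg = self.config
        H, W = np.asarray(rgb).shape[:2]
        pyramid = self.extract_pyramid(rgb, depth)
        proposals, _, rpn_out, anchors = self._proposals(pyramid, (W, H))
        gt_boxes = np.atleast_2d(np.asarray(gt_boxes, dtype=np.float64))
        losses: Dict[str, Tensor] = {}

        # ---- RPN losses over matched anchors
        anchor_cat = np.concatenate([anchors[n] for n in pyramid])
        obj_logits = nn.concat(
            [rpn_out[n][0].reshape(1, -1) for n in pyramid], axis=1
        ).reshape(-1)
        delta_pred = nn.concat(
            [rpn_out[n][1].reshape(1, 4, -1).transpose((0, 2, 1))
             for n in pyramid], axis=1).reshape(-1, 4)
        iou = box_iou_matrix(anchor_cat, gt_boxes)
        best_gt = iou.argmax(axis=1)
        best_iou = iou.max(axis=1)
        pos = best_iou >= 0.5
        for g in range(len(gt_boxes)):          # force-match each gt
            pos[int(iou[:, g].argmax())] = True
        neg = best_iou < 0.3
        neg &= ~pos
        n_pos = int(pos.sum())
        neg_idx = np.flatnonzero(neg)
        take = min(len(neg_idx), max(8, 2 * n_pos))
        neg_sel = rng.choice(neg_idx, size=take, replace=False) \
            if take < len(neg_idx) else neg_idx
        sel = np.concatenate([np.flatnonzero(pos), neg_sel])
        targets = np.zeros(len(sel))
        targets[:n_pos] = 1.0
        losses["rpn_cls"] = nn.bce_with_logits(obj_logits[sel], targets)
        if n_pos:
            pos_idx = np.flatnonzero(pos)
            t_deltas = _encode_deltas(anchor_cat[pos_idx],
                                      gt_boxes[best_gt[pos_idx]])
            losses["rpn_loc"] = nn.smooth_l1(delta_pred[pos_idx], t_deltas,
                                             beta=1.0 / 9.0)
        else:
            losses["rpn_loc"] = Tensor(0.0)

        # ---- RoI sampling: proposals + gt boxes, matched at IoU 0.5
        rois = np.concatenate([proposals, gt_boxes]) if len(proposals) \
            else gt_boxes.copy()
        # pad the negative pool with random boxes so clear background
        # examples exist even when all proposals sit on fruit
        n_rand = 8
        rw = rng.uniform(8, max(W // 2, 9), size=n_rand)
        rh = rng.uniform(8, max(H // 2, 9), size=n_rand)
        rx = rng.uniform(0, np.maximum(W - rw, 1))
        ry = rng.uniform(0, np.maximum(H - rh, 1))
        rand_boxes = np.stack([rx, ry, rx + rw, ry + rh], axis=1)
        rois = np.concatenate([rois, rand_boxes])
        iou_r = box_iou_matrix(rois, gt_boxes)
        match = iou_r.argmax(axis=1)
        max_iou = iou_r.max(axis=1)
        # fg >= 0.5, bg < 0.3; the ambiguous band is left unsampled
        fg_idx = np.flatnonzero(max_iou >= 0.5)
        bg_idx = np.flatnonzero(max_iou < 0.3)
        n_fg = min(len(fg_idx), cfg.roi_samples // 2)
        n_bg = min(len(bg_idx), cfg.roi_samples - n_fg)
        fg_sel = (rng.choice(fg_idx, size=n_fg, replace=False)
                  if n_fg < len(fg_idx) else fg_idx)
        bg_sel = (rng.choice(bg_idx, size=n_bg, replace=False)
                  if n_bg < len(bg_idx) else bg_idx)
        roi_sel = np.concatenate([fg_sel, bg_sel])
        if len(roi_sel) == 0:
            for k in ("cls", "box", "visible", "amodal", "occ_cls"):
                losses[k] = Tensor(0.0)
            return losses
        roi_boxes = rois[roi_sel]
        labels = np.zeros(len(roi_sel), dtype=int)
        labels[:len(fg_sel)] = 1

        f_box = self._roi_features(pyramid, roi_boxes, cfg.roi_box_size)
        cls_logits, box_deltas = self.head.box_branch(f_box)
        losses["cls"] = nn.cross_entropy(cls_logits, labels)
        if len(fg_sel):
            t_deltas = _encode_deltas(roi_boxes[:len(fg_sel)],
                                      gt_boxes[match[fg_sel]])
            losses["box"] = nn.smooth_l1(box_deltas[:len(fg_sel)], t_deltas)
        else:
            losses["box"] = Tensor(0.0)

        # ---- mask + occlusion branches on foreground RoIs
        if len(fg_sel):
            fg_boxes = roi_boxes[:len(fg_sel)]
            f_b = nn.upsample_nearest2(
                self._roi_features(pyramid, fg_boxes, cfg.roi_box_size))
            f_roi = self._roi_features(pyramid, fg_boxes, cfg.roi_mask_size)
            v_logits, a_logits, o_logits = self.head.mask_branches(f_b, f_roi)
            S = cfg.mask_out_size
            v_t = np.stack([_crop_mask(gt_visible[match[i]], rois[i], S)
                            for i in fg_sel])
            a_t = np.stack([_crop_mask(gt_amodal[match[i]], rois[i], S)
                            for i in fg_sel])
            losses["visible"] = nn.bce_with_logits(
                v_logits[:, 0], v_t)
            losses["amodal"] = nn.bce_with_logits(
                a_logits[:, 0], a_t)
            occ_t = np.array([int(gt_occluded[match[i]]) for i in fg_sel])
            losses["occ_cls"] = nn.cross_entropy(o_logits, occ_t)
        else:
            for k in ("visible", "amodal", "occ_cls"):
                losses[k] = Tensor(0.0)
        return losses


def _crop_mask(mask: np.ndarray, box: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour crop of a frame mask to a box-aligned size grid."""
    H, W = mask.shape
    x0, y0, x1, y1 = box
    xs = np.clip((x0 + (np.arange(size) + 0.5) / size * (x1 - x0)).astype(int),
                 0, W - 1)
    ys = np.clip((y0 + (np.arange(size) + 0.5) / size * (y1 - y0)).astype(int),
                 0, H - 1)
    return mask[np.ix_(ys, xs)].astype(np.float64)


def _paste_mask(logits28: np.ndarray, box: np.ndarray,
                frame_shape: Tuple[int, int]) -> np.ndarray:
    """Resize box-aligned mask logits into the frame, threshold at 0.5."""
    H, W = frame_shape
    x0, y0, x1, y1 = box
    bw = max(int(round(x1 - x0)), 1)
    bh = max(int(round(y1 - y0)), 1)
    prob = 1.0 / (1.0 + np.exp(-logits28))
    S = prob.shape[0]
    resized = ndimage.zoom(prob, (bh / S, bw / S), order=1, grid_mode=True,
                           mode="nearest")
    resized = resized[:bh, :bw]
    out = np.zeros((H, W), dtype=bool)
    ix0, iy0 = int(round(x0)), int(round(y0))
    sx0, sy0 = max(0, -ix0), max(0, -iy0)
    ix0, iy0 = max(0, ix0), max(0, iy0)
    h = min(bh - sy0, H - iy0)
    w = min(bw - sx0, W - ix0)
    if h > 0 and w > 0:
        out[iy0:iy0 + h, ix0:ix0 + w] = \
            resized[sy0:sy0 + h, sx0:sx0 + w] >= 0.5
    return out
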