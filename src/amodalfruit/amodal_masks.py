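"""Amodal / visible / occlusion mask algebra.

An *amodal* mask M_A is the full projected silhouette of an object,
including parts hidden behind occluders; the *visible* (modal) mask M_V
contains only the pixels actually seen from the viewpoint.  The
occlusion mask is their set difference

    M_O = M_A \\ M_V,

and the occlusion rate is |M_O| / |M_A| in [0, 1].  A rate of 1 means
the object is completely hidden, in which case its annotation is dropped
rather than saved.  Instances are stratified into three occlusion-rate
bins — [0, 0.10) low, [0.10, 0.30) moderate, [0.30, 1.00] high — a
half-open convention so the bins partition [0, 1].

The module also implements clone-fusion annotation: pasting a cropped
instance from one image onto another manufactures an occlusion whose
amodal ground truth is known exactly (it is the occludee's pre-paste
visible mask), which is how amodal labels are produced for real
photographs without guessing hidden shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "InstanceMasks",
    "OCCLUSION_BINS",
    "MaskConsistencyError",
    "DegenerateInstanceError",
    "occlusion_mask",
    "occlusion_rate",
    "bin_occlusion",
    "clone_fuse",
]


class MaskConsistencyError(ValueError):
    """Visible mask contains pixels outside the amodal mask."""


class DegenerateInstanceError(ValueError):
    """Amodal mask is empty — the instance has no extent."""


#: occlusion-rate strata: label -> [lo, hi) (last bin closed at 1.0)
OCCLUSION_BINS: Tuple[Tuple[str, float, float], ...] = (
    ("low", 0.0, 0.10),
    ("mid", 0.10, 0.30),
    ("high", 0.30, 1.00),
)


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


@dataclass
class InstanceMasks:
    """One instance's amodal / visible / occlusion masks plus metadata."""

    amodal: np.ndarray
    visible: np.ndarray
    occluded_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    occlusion_rate: float = field(default=None)  # type: ignore[assignment]
    category: str = "tomato"
    instance_id: int = 0

    def __post_init__(self):
        self.amodal = _as_bool(self.amodal)
        self.visible = _as_bool(self.visible)
        if self.occluded_mask is None:
            self.occluded_mask = occlusion_mask(self.amodal, self.visible)
        else:
            self.occluded_mask = _as_bool(self.occluded_mask)
        if self.occlusion_rate is None:
            self.occlusion_rate = occlusion_rate(self.amodal, self.visible)

    @property
    def occluded(self) -> bool:
        return bool(self.occluded_mask.any())

    @property
    def fully_occluded(self) -> bool:
        return not self.visible.any()

    def bin_label(self) -> str:
        return bin_occlusion(self.occlusion_rate)


def occlusion_mask(amodal, visible) -> np.ndarray:
    """Set difference M_O = M_A \\ M_V on binary rasters.

    Raises :class:`MaskConsistencyError` if any visible pixel lies
    outside the amodal silhouette (a corrupt annotation).
    """
    a, v = _as_bool(amodal), _as_bool(visible)
    if a.shape != v.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {v.shape}")
    if np.any(v & ~a):
        raise MaskConsistencyError("visible mask extends outside amodal mask")
    return a & ~v


def occlusion_rate(amodal, visible=None) -> float:
    """|M_O| / |M_A|.  Accepts (M_A, M_V) or a precomputed InstanceMasks."""
    if isinstance(amodal, InstanceMasks):
        a, o = amodal.amodal, amodal.occluded_mask
    else:
        a = _as_bool(amodal)
        o = occlusion_mask(a, visible)
    n_a = int(a.sum())
    if n_a == 0:
        raise DegenerateInstanceError("amodal mask is empty")
    return float(o.sum()) / n_a


def bin_occlusion(rate: float) -> str:
    """Assign an occlusion rate to its stratum label."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"occlusion rate {rate} outside [0, 1]")
    for label, lo, hi in OCCLUSION_BINS:
        if lo <= rate < hi:
            return label
    return OCCLUSION_BINS[-1][0]  # rate == 1.0


def clone_fuse(
    source_img: np.ndarray,
    source_visible_mask,
    target_img: np.ndarray,
    target_instances: Sequence[InstanceMasks],
    placement: Tuple[int, int],
    feather: bool = False,
) -> Tuple[np.ndarray, List[InstanceMasks]]:
    """Paste a cropped instance over a target image to manufacture occlusion.

    The source instance's visible pixels (tight crop of
    ``source_visible_mask``) are composited over ``target_img`` with the
    crop's top-left corner at ``placement = (row, col)``.  For every
    pre-existing target instance the pre-paste visible mask becomes the
    amodal ground truth, the new visible mask is what survives outside
    the paste footprint, and the occlusion mask is the overlap with the
    footprint.  Instances left with no visible pixels are dropped.  The
    pasted source becomes a new, unoccluded foreground instance.

    ``feather`` optionally averages the 1-px footprint boundary with the
    background to soften the seam; derived masks are unaffected.
    """
    smask = _as_bool(source_visible_mask)
    if not smask.any():
        raise ValueError("source visible mask is empty")
    rows = np.flatnonzero(smask.any(axis=1))
    cols = np.flatnonzero(smask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = source_img[r0:r1, c0:c1]
    crop_mask = smask[r0:r1, c0:c1]
    ph, pw = r1 - r0, c1 - c0
    py, px = placement
    H, W = target_img.shape[:2]
    if py < 0 or px < 0 or py + ph > H or px + pw > W:
        raise ValueError(
            f"placement {placement} puts the {ph}x{pw} paste outside the "
            f"{H}x{W} target frame")

    footprint = np.zeros((H, W), dtype=bool)
    footprint[py:py + ph, px:px + pw] = crop_mask

    fused = target_img.copy()
    region = fused[py:py + ph, px:px + pw]
    region[crop_mask] = crop[crop_mask]
    if feather:
        edge = footprint & ~_erode1(footprint)
        blur = fused.astype(np.float64)
        blur[edge] = 0.5 * blur[edge] + 0.5 * target_img.astype(np.float64)[edge]
        fused = blur.astype(target_img.dtype)

    updated: List[InstanceMasks] = []
    for inst in target_instances:
        pre_visible = inst.visible
        post_visible = pre_visible & ~footprint
        if not post_visible.any():
            continue  # fully occluded by the paste: annotation not saved
        updated.append(replace(
            inst,
            amodal=pre_visible,
            visible=post_visible,
            occluded_mask=pre_visible & footprint,
            occlusion_rate=None,  # recomputed in __post_init__
        ))
    new_id = 1 + max((i.instance_id for i in target_instances), default=0)
    updated.append(InstanceMasks(amodal=footprint, visible=footprint,
                                 instance_id=new_id))
    return fused, updated


def _erode1(mask: np.ndarray) -> np.ndarray:
    """4-neighbourhood binary erosion by one pixel."""
    out = mask.copy()
    out[1:] &= mask[:-1]
    out[:-1] &= mask[1:]
    out[:, 1:] &= mask[:, :-1]
    out[:, :-1] &= mask[:, 1:]
    return out
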