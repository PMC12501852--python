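"""Dataset serialization: PNG rasters and a COCO-style amodal JSON dialect.

Layout written by :func:`write_dataset`::

    out_dir/
      images/000123.png        8-bit RGB
      depth/000123.png         16-bit grayscale, millimeters, 0 = invalid
      annotations.json         COCO dialect (below)
      manifest.json            config echo, split lists, stratification
      stratification.tsv       regime x occlusion-bin table

The annotation dialect keeps standard COCO ``images`` / ``annotations``
/ ``categories`` keys; each annotation's ``segmentation`` is the
*amodal* mask as uncompressed column-major RLE, with additional
``visible_mask`` and ``occluded_mask`` RLEs, an ``occluded_rate`` float
and an ``occluded`` flag.  Everything is written deterministically
(sorted keys, rounded floats) so equal seeds give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from PIL import Image

from .amodal_masks import OCCLUSION_BINS, InstanceMasks, bin_occlusion

__all__ = [
    "DatasetConfig",
    "rle_encode",
    "rle_decode",
    "write_rgb_png",
    "read_rgb_png",
    "write_depth_png",
    "read_depth_png",
    "write_dataset",
    "load_annotations",
    "validate_annotations",
    "format_stratification",
    "manifest_hash",
]


# ---------------------------------------------------------------------------
# RLE (COCO uncompressed: column-major counts, starting with zeros)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Encode a binary mask as uncompressed column-major RLE."""
    mask = np.asarray(mask).astype(np.uint8)
    h, w = mask.shape
    flat = mask.flatten(order="F")
    # boundaries where the run value changes
    change = np.flatnonzero(np.diff(flat)) + 1
    idx = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(idx).tolist()
    if flat.size and flat[0] == 1:   # counts must start with a zero-run
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    if sum(counts) != h * w:
        raise ValueError("RLE counts do not cover the raster")
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------------------
# PNG rasters
# ---------------------------------------------------------------------------

def write_rgb_png(path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(path)


def read_rgb_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_depth_png(path, depth_m: np.ndarray) -> None:
    """Metric depth (meters, 0 invalid) as 16-bit PNG in millimeters."""
    mm = np.round(np.asarray(depth_m, dtype=np.float64) * 1000.0)
    if mm.max(initial=0) > 65535:
        raise ValueError("depth exceeds 16-bit millimeter range")
    Image.fromarray(mm.astype(np.uint16)).save(path)


def read_depth_png(path) -> np.ndarray:
    mm = np.asarray(Image.open(path), dtype=np.float64)
    return mm / 1000.0


# ---------------------------------------------------------------------------
# Dataset writing
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """Scene distribution plus dataset-level options."""

    n_scenes: int = 20
    seed: int = 0
    train_ratio: float = 0.8            # 8:2 split
    scene: "SceneConfig" = None  # type: ignore[assignment]

    def __post_init__(self):
        from .scene_synth import SceneConfig
        if self.scene is None:
            self.scene = SceneConfig()
        if self.n_scenes < 1:
            raise ValueError("n_scenes must be >= 1")
        if not 0.0 <= self.train_ratio <= 1.0:
            raise ValueError("train_ratio must lie in [0, 1]")


def scene_seed(global_seed: int, index: int) -> int:
    """Deterministic per-scene seed fan-out (< 2**31)."""
    state = np.random.SeedSequence([int(global_seed), int(index)])
    return int(state.generate_state(1)[0] % (2 ** 31))


def _round6(x: float) -> float:
    return float(round(float(x), 6))


def write_dataset(config: DatasetConfig, out_dir, seed: Optional[int] = None) -> dict:
    from .scene_synth import render_scene, sample_scene, allocate_regimes

    g_seed = config.seed if seed is None else int(seed)
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "depth").mkdir(parents=True, exist_ok=True)

    regimes = allocate_regimes(config.scene.regime_mix, config.n_scenes)
    n_train = int(round(config.n_scenes * config.train_ratio))

    images, annotations = [], []
    strat: Dict[str, Dict[str, List[int]]] = {
        r: {b[0]: [0, 0] for b in OCCLUSION_BINS}
        for r in config.scene.regime_mix}
    ann_id = 1
    for i in range(config.n_scenes):
        s_seed = scene_seed(g_seed, i)
        spec = sample_scene(config.scene, s_seed, regime=regimes[i])
        frame, records = render_scene(spec)
        name = f"{i:06d}.png"
        write_rgb_png(out / "images" / name, frame.rgb)
        write_depth_png(out / "depth" / name, frame.depth)
        W, H = config.scene.image_size
        images.append({
            "id": i + 1,
            "file_name": f"images/{name}",
            "depth_file_name": f"depth/{name}",
            "width": W, "height": H,
            "regime": spec.regime,
            "split": "train" if i < n_train else "test",
            "scene_seed": s_seed,
        })
        rates = []
        for rec in records:
            m = rec.masks
            x0, y0, x1, y1 = rec.bbox
            annotations.append({
                "id": ann_id,
                "image_id": i + 1,
                "category_id": 1,
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": int(m.amodal.sum()),
                "iscrowd": 0,
                "segmentation": rle_encode(m.amodal),
                "visible_mask": rle_encode(m.visible),
                "occluded_mask": rle_encode(m.occluded_mask),
                "occluded_rate": _round6(m.occlusion_rate),
                "occluded": bool(m.occluded),
                "ripeness": rec.ripeness,
            })
            ann_id += 1
            rates.append(m.occlusion_rate)
            strat[spec.regime][bin_occlusion(m.occlusion_rate)][1] += 1
        if rates:  # image stratum: bin of its most occluded instance
            strat[spec.regime][bin_occlusion(max(rates))][0] += 1

    coco = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "tomato", "supercategory": "fruit"}],
    }
    _dump_json(out / "annotations.json", coco)

    manifest = {
        "n_scenes": config.n_scenes,
        "seed": g_seed,
        "train_ratio": config.train_ratio,
        "image_size": list(config.scene.image_size),
        "regime_mix": {k: _round6(v) for k, v in config.scene.regime_mix.items()},
        "splits": {
            "train": [im["id"] for im in images if im["split"] == "train"],
            "test": [im["id"] for im in images if im["split"] == "test"],
        },
        "stratification": strat,
        "annotations": "annotations.json",
    }
    _dump_json(out / "manifest.json", manifest)
    (out / "stratification.tsv").write_text(format_stratification(strat))
    return manifest


def _dump_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, separators=(",", ":"))
                          + "\n")


def manifest_hash(out_dir) -> str:
    """SHA-256 over the dataset's JSON artifacts (determinism checks)."""
    h = hashlib.sha256()
    for name in ("annotations.json", "manifest.json"):
        h.update(Path(out_dir, name).read_bytes())
    return h.hexdigest()


def format_stratification(strat: Dict[str, Dict[str, List[int]]]) -> str:
    """Regime x occlusion-bin table, cells as images/instances."""
    bins = [b[0] for b in OCCLUSION_BINS]
    bounds = {"low": "[0,10)", "mid": "[10,30)", "high": "[30,100]"}
    regimes = list(strat)
    lines = ["occlusion_rate(%)\t" + "\t".join(regimes) + "\ttotal"]
    for b in bins:
        cells = [f"{strat[r][b][0]}/{strat[r][b][1]}" for r in regimes]
        ti = sum(strat[r][b][0] for r in regimes)
        tn = sum(strat[r][b][1] for r in regimes)
        lines.append(f"{bounds[b]}\t" + "\t".join(cells) + f"\t{ti}/{tn}")
    tot_cells = []
    for r in regimes:
        ti = sum(strat[r][b][0] for b in bins)
        tn = sum(strat[r][b][1] for b in bins)
        tot_cells.append(f"{ti}/{tn}")
    ti = sum(strat[r][b][0] for r in regimes for b in bins)
    tn = sum(strat[r][b][1] for r in regimes for b in bins)
    lines.append("total\t" + "\t".join(tot_cells) + f"\t{ti}/{tn}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def validate_annotations(doc: dict) -> None:
    """Structural validation with path-level diagnostics (raises ValueError)."""
    for key in ("images", "annotations", "categories"):
        if key not in doc or not isinstance(doc[key], list):
            raise ValueError(f"annotations: missing or non-list key {key!r}")
    image_ids = set()
    for k, im in enumerate(doc["images"]):
        for f in ("id", "file_name", "width", "height"):
            if f not in im:
                raise ValueError(f"images[{k}]: missing field {f!r}")
        image_ids.add(im["id"])
    for k, ann in enumerate(doc["annotations"]):
        for f in ("id", "image_id", "category_id", "segmentation"):
            if f not in ann:
                raise ValueError(f"annotations[{k}]: missing field {f!r}")
        if ann["image_id"] not in image_ids:
            raise ValueError(f"annotations[{k}]: unknown image_id "
                             f"{ann['image_id']}")
        seg = ann["segmentation"]
        if not (isinstance(seg, dict) and "size" in seg and "counts" in seg):
            raise ValueError(f"annotations[{k}]: segmentation must be an RLE "
                             "object with 'size' and 'counts'")
        if sum(seg["counts"]) != seg["size"][0] * seg["size"][1]:
            raise ValueError(f"annotations[{k}]: RLE counts do not cover the "
                             "raster")
        rate = ann.get("occluded_rate")
        if rate is not None and not 0.0 <= rate <= 1.0:
            raise ValueError(f"annotations[{k}]: occluded_rate {rate} "
                             "outside [0, 1]")


def load_annotations(path) -> dict:
    """Read + validate an annotation file; decode masks per image.

    Returns ``{"images": {...}, "by_image": {image_id: [InstanceMasks]},
    "raw": doc}`` where each InstanceMasks carries amodal/visible masks
    (visible falls back to amodal when the file has no visible_mask).
    """
    doc = json.loads(Path(path).read_text())
    validate_annotations(doc)
    images = {im["id"]: im for im in doc["images"]}
    by_image: Dict[int, List[InstanceMasks]] = {i: [] for i in images}
    for ann in doc["annotations"]:
        amodal = rle_decode(ann["segmentation"])
        visible = (rle_decode(ann["visible_mask"])
                   if "visible_mask" in ann else amodal)
        by_image[ann["image_id"]].append(InstanceMasks(
            amodal=amodal, visible=visible, instance_id=ann["id"],
            category=str(ann["category_id"])))
    return {"images": images, "by_image": by_image, "raw": doc}
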