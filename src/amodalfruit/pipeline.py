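"""End-to-end orchestration: generate -> train -> predict -> evaluate.

A single global seed fans out deterministically (via ``SeedSequence``)
to the dataset generator, the network initialisation and the training
loop, so a whole run is reproducible bit-for-bit.  Training defaults
mirror the published schedule (batch 2, initial learning rate 0.00125,
90,000 iterations at 640x480); the pinned *tiny desk profile* — 96x96
images, 2-4 fruit, backbone width 16, 300 iterations — exercises the
identical code path at a scale a CPU handles in minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import dataset_io, nn
from .amodal_masks import InstanceMasks
from .amodal_metrics import EvalReport, evaluate_dataset
from .cga_asnet import CGAASNet, NetworkConfig, combine_losses
from .dataset_io import DatasetConfig
from .scene_synth import SceneConfig

__all__ = [
    "TrainConfig",
    "RunConfig",
    "tiny_profile",
    "derive_seed",
    "run_generate",
    "run_train",
    "run_predict",
    "run_evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "load_training_set",
]


@dataclass
class TrainConfig:
    """Optimisation schedule; defaults follow the published setup."""

    batch_size: int = 2
    learning_rate: float = 0.00125
    momentum: float = 0.9
    max_iterations: int = 90000
    warmup_iterations: int = 0
    cosine_decay: bool = False
    log_every: int = 10


@dataclass
class RunConfig:
    """Complete configuration of one experiment."""

    seed: int = 0
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    miou_mode: str = "instance"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ds = dict(d.get("dataset", {}))
        if "scene" in ds and isinstance(ds["scene"], dict):
            sc = dict(ds["scene"])
            for k in ("n_fruits_range", "fruit_radius_range",
                      "n_occluders_range", "l_range", "w_range",
                      "image_size", "background"):
                if k in sc and isinstance(sc[k], list):
                    sc[k] = tuple(sc[k])
            ds["scene"] = SceneConfig(**sc)
        nt = dict(d.get("network", {}))
        for k in ("stage_widths", "blocks_per_stage", "cft_stages",
                  "gam_stages", "anchor_sizes"):
            if k in nt and isinstance(nt[k], list):
                nt[k] = tuple(nt[k])
        return cls(seed=d.get("seed", 0),
                   dataset=DatasetConfig(**ds),
                   network=NetworkConfig(**nt),
                   train=TrainConfig(**d.get("train", {})),
                   miou_mode=d.get("miou_mode", "instance"))

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def tiny_profile(seed: int = 0, n_scenes: int = 20,
                 **network_over) -> RunConfig:
    """The pinned CPU profile: 96x96 frames, 2-4 large fruit, width-16 net.

    Fruit radii are enlarged (0.12-0.20 m vs the realistic 0.03-0.05 m)
    so instances subtend ~20 px at this resolution and mask targets stay
    informative; everything else follows the default study conditions.
    """
    scene = SceneConfig(
        n_fruits_range=(2, 4),
        fruit_radius_range=(0.12, 0.20),
        n_occluders_range=(0, 2),
        image_size=(96, 96),
    )
    net = dict(stage_widths=(16, 24, 32, 48), fpn_width=24, head_width=24,
               head_fc=64, anchor_sizes=(16.0, 28.0, 48.0),
               seed=derive_seed(seed, "network"))
    net.update(network_over)
    return RunConfig(
        seed=seed,
        dataset=DatasetConfig(n_scenes=n_scenes,
                              seed=derive_seed(seed, "dataset"), scene=scene),
        network=NetworkConfig(**net),
        train=TrainConfig(batch_size=2, learning_rate=0.03,
                          max_iterations=300, warmup_iterations=20,
                          cosine_decay=True),
    )


def derive_seed(global_seed: int, role: str) -> int:
    """Stable fan-out of the global seed to a named component (< 2**31)."""
    tag = int.from_bytes(role.encode()[:4].ljust(4, b"\0"), "little")
    ss = np.random.SeedSequence([int(global_seed), tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Generate
# ---------------------------------------------------------------------------

def run_generate(config: RunConfig, out_dir) -> dict:
    """Write the synthetic dataset plus the serialized run configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dataset_io.write_dataset(config.dataset, out)
    config.save_yaml(out / "run_config.yaml")
    return manifest


# ---------------------------------------------------------------------------
# Train
# ---------------------------------------------------------------------------

def load_training_set(data_dir, split: str = "train") -> List[dict]:
    """Load frames of one split with decoded masks and amodal boxes."""
    data = dataset_io.load_annotations(Path(data_dir) / "annotations.json")
    frames = []
    for img_id, im in sorted(data["images"].items()):
        if im.get("split", split) != split:
            continue
        rgb = dataset_io.read_rgb_png(Path(data_dir) / im["file_name"])
        depth = dataset_io.read_depth_png(Path(data_dir) / im["depth_file_name"])
        insts: List[InstanceMasks] = data["by_image"][img_id]
        boxes = []
        for m in insts:
            ys = np.flatnonzero(m.amodal.any(axis=1))
            xs = np.flatnonzero(m.amodal.any(axis=0))
            boxes.append([xs[0], ys[0], xs[-1] + 1, ys[-1] + 1])
        frames.append({
            "image_id": img_id,
            "rgb": rgb, "depth": depth,
            "boxes": np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
            "visible": [m.visible for m in insts],
            "amodal": [m.amodal for m in insts],
            "occluded": [int(m.occluded) for m in insts],
            "instances": insts,
        })
    return frames


def run_train(config: RunConfig, data_dir, out_dir,
              resume_from=None) -> Tuple[CGAASNet, List[dict]]:
    """Seeded training loop with per-iteration loss decomposition logging."""
    frames = load_training_set(data_dir, "train")
    if not frames:
        raise ValueError(f"no training frames found under {data_dir}")
    frames = [f for f in frames if len(f["boxes"])]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = CGAASNet(config.network)
    opt = nn.SGD(model.parameters(), lr=config.train.learning_rate,
                 momentum=config.train.momentum)
    rng = np.random.default_rng(derive_seed(config.seed, "train"))
    start_it = 0
    if resume_from is not None:
        start_it = load_checkpoint(resume_from, model, opt, rng)

    history: List[dict] = []
    log_path = out / "losses.jsonl"
    mode = "a" if resume_from is not None else "w"
    with open(log_path, mode) as log:
        for it in range(start_it, config.train.max_iterations):
            warm = config.train.warmup_iterations
            scale = min(1.0, (it + 1) / warm) if warm else 1.0
            if config.train.cosine_decay and it >= warm:
                frac = (it - warm) / max(config.train.max_iterations - warm, 1)
                scale *= 0.5 * (1.0 + np.cos(np.pi * frac))
            opt.lr = config.train.learning_rate * scale
            idx = rng.choice(len(frames), size=min(config.train.batch_size,
                                                   len(frames)), replace=False)
            components: Dict[str, nn.Tensor] = {}
            for fi in idx:
                f = frames[fi]
                li = model.compute_losses(f["rgb"], f["depth"], f["boxes"],
                                          f["visible"], f["amodal"],
                                          f["occluded"], rng)
                for k, v in li.items():
                    components[k] = components.get(k, 0.0) + v * (1.0 / len(idx))
            total, breakdown = combine_losses(components,
                                              config.network.loss_weights)
            opt.zero_grad()
            total.backward()
            opt.step()
            entry = {"iteration": it, "total": breakdown.total,
                     **{k: round(v, 6) for k, v in
                        breakdown.components.items()}}
            history.append(entry)
            log.write(json.dumps(entry) + "\n")
    save_checkpoint(out / "checkpoint.npz", model, opt,
                    config.train.max_iterations, rng, config)
    return model, history


def _config_hash(config: RunConfig) -> str:
    import hashlib
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(path, model: CGAASNet, opt: nn.SGD, iteration: int,
                    rng: np.random.Generator, config: RunConfig) -> None:
    """Single-file checkpoint: weights + optimizer + RNG + config hash."""
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    arrays.update({f"vel_{i}": v for i, v in enumerate(opt.vel)})
    meta = {"iteration": iteration,
            "rng_state": rng.bit_generator.state,
            "config": config.to_dict(),
            "config_hash": _config_hash(config)}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, model: CGAASNet, opt: Optional[nn.SGD] = None,
                    rng: Optional[np.random.Generator] = None) -> int:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        n = len(model.parameters())
        model.load_state_arrays([z[f"param_{i}"] for i in range(n)])
        if opt is not None:
            opt.vel = [z[f"vel_{i}"].copy() for i in range(n)]
    if rng is not None:
        rng.bit_generator.state = meta["rng_state"]
    return int(meta["iteration"])


# ---------------------------------------------------------------------------
# Predict / evaluate
# ---------------------------------------------------------------------------

def run_predict(model: CGAASNet, data_dir, out_json,
                split: str = "test") -> dict:
    """Run detection on a dataset split and write a predictions file."""
    frames = load_training_set(data_dir, split)
    preds = []
    for f in frames:
        for det in model.predict(f["rgb"], f["depth"]):
            preds.append({
                "image_id": f["image_id"],
                "category_id": det.class_label,
                "score": round(det.score, 6),
                "bbox": [round(v, 2) for v in det.box],
                "segmentation": dataset_io.rle_encode(det.amodal),
                "visible_mask": dataset_io.rle_encode(det.visible),
                "occluded": det.occluded,
            })
    doc = {"predictions": preds}
    Path(out_json).write_text(json.dumps(doc, sort_keys=True,
                                         separators=(",", ":")) + "\n")
    return doc


def run_evaluate(pred_json, gt_json, use_mask: str = "amodal",
                 miou_mode: str = "instance", per_bin: bool = True,
                 split: Optional[str] = None) -> EvalReport:
    """Evaluate a predictions file against ground-truth annotations.

    ``split`` restricts evaluation to ground-truth images whose
    ``split`` field matches (e.g. ``"test"``); default is all images.
    """
    gt = dataset_io.load_annotations(gt_json)
    if split is not None:
        keep = {i for i, im in gt["images"].items()
                if im.get("split") == split}
        gt["by_image"] = {i: v for i, v in gt["by_image"].items()
                          if i in keep}
    doc = json.loads(Path(pred_json).read_text())
    preds = doc.get("predictions", doc if isinstance(doc, list) else [])
    preds_by_image: Dict[int, List[dict]] = {i: [] for i in gt["by_image"]}
    for k, p in enumerate(preds):
        if "segmentation" not in p or "score" not in p:
            raise ValueError(f"predictions[{k}]: needs 'segmentation' and "
                             "'score'")
        img = p.get("image_id")
        if img not in preds_by_image:
            if img in gt["images"]:
                continue            # image excluded by the split filter
            raise ValueError(f"predictions[{k}]: unknown image_id {img!r}")
        entry = {"amodal": dataset_io.rle_decode(p["segmentation"]),
                 "score": float(p["score"])}
        if "visible_mask" in p:
            entry["visible"] = dataset_io.rle_decode(p["visible_mask"])
        preds_by_image[img].append(entry)
    gts_by_image = {i: v for i, v in gt["by_image"].items() if v}
    preds_by_image = {i: preds_by_image[i] for i in gts_by_image}
    return evaluate_dataset(preds_by_image, gts_by_image, use_mask=use_mask,
                            miou_mode=miou_mode, per_bin=per_bin)
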