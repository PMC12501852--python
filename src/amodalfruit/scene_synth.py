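"""Synthetic greenhouse RGB-D scenes of mutually occluding fruit.

Scenes contain 1-10 sphere-shaped fruit clustered around the origin of a
right-handed world frame (z up), plus stem (cylinder) and leaf (disc)
occluders.  Camera viewpoints are sampled uniformly over the volume of a
hemispherical shell whose radii derive from the scene footprint,

    r_view_lower = max(w/2, l/2),      r_view_upper = 1.7 * r_view_lower,

with l in [1, 2] m and w in [2, 4] m.  Between 0 and 2 point lights are
placed on an outer shell 0.1 m beyond the camera shell and 1 m thick,
and one of three illumination regimes (strong / normal / weak) sets the
ambient and point-light intensities.

Rendering is an analytic z-buffer: per pixel, the nearest ray-primitive
intersection gives the instance id buffer and metric depth (valid range
0.25-5.46 m, 0 = invalid); shading is Lambertian plus ambient.  Each
fruit is additionally intersected in isolation to obtain its amodal
mask, from which the occlusion mask and occlusion rate follow exactly.
Fully occluded fruit are dropped from the annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .amodal_masks import InstanceMasks, bin_occlusion

__all__ = [
    "DEPTH_MIN",
    "DEPTH_MAX",
    "ILLUMINATION_REGIMES",
    "RIPENESS_COLORS",
    "ViewSamplingParams",
    "LightSamplingParams",
    "CameraPose",
    "Sphere",
    "Cylinder",
    "Disc",
    "PointLight",
    "SceneSpec",
    "SceneConfig",
    "RGBDFrame",
    "InstanceRecord",
    "sample_view_radii",
    "light_radii",
    "sample_camera",
    "sample_lights",
    "sample_scene",
    "render_scene",
    "generate_dataset",
]

#: valid metric depth range (m); values outside are written as invalid (0)
DEPTH_MIN = 0.25
DEPTH_MAX = 5.46

#: regime -> (ambient level, point-light intensity scale)
ILLUMINATION_REGIMES: Dict[str, Tuple[float, float]] = {
    "strong": (0.35, 1.0),
    "normal": (0.25, 0.6),
    "weak": (0.12, 0.25),
}

#: ripeness class -> base albedo (linear RGB in [0, 1])
RIPENESS_COLORS: Dict[str, Tuple[float, float, float]] = {
    "ripe": (0.85, 0.13, 0.10),
    "turning": (0.90, 0.55, 0.12),
    "unripe": (0.35, 0.62, 0.22),
}

_OCCLUDER_COLORS = {"stem": (0.30, 0.42, 0.16), "leaf": (0.22, 0.48, 0.18)}

_EPS = 1e-9
_T_NEAR = 1e-6


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Sampling geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewSamplingParams:
    """Camera-shell radii derived from the scene footprint."""

    l: float
    w: float
    r_view_lower: float
    r_view_upper: float


@dataclass(frozen=True)
class LightSamplingParams:
    """Light-shell radii, one shell thickness beyond the camera shell."""

    r_light_lower: float
    r_light_upper: float
    n_lights: int
    regime: str


def sample_view_radii(l: float, w: float) -> ViewSamplingParams:
    """Inner/outer camera radii from scene length l and width w (meters)."""
    if not 1.0 <= l <= 2.0:
        raise ValueError(f"scene length l={l} outside [1, 2] m")
    if not 2.0 <= w <= 4.0:
        raise ValueError(f"scene width w={w} outside [2, 4] m")
    r_lower = max(w / 2.0, l / 2.0)
    return ViewSamplingParams(l=l, w=w, r_view_lower=r_lower,
                              r_view_upper=1.7 * r_lower)


def light_radii(view: ViewSamplingParams, n_lights: int = 0,
                regime: str = "normal") -> LightSamplingParams:
    """Light shell sits 0.1 m beyond the outer camera radius and is 1 m thick."""
    lo = view.r_view_upper + 0.1
    return LightSamplingParams(r_light_lower=lo, r_light_upper=lo + 1.0,
                               n_lights=n_lights, regime=regime)


@dataclass(frozen=True)
class CameraPose:
    """Pinhole camera: world position, look-at target, intrinsics."""

    position: Tuple[float, float, float]
    target: Tuple[float, float, float]
    focal: float           # px (fx == fy)
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.focal <= 0:
            raise ValueError("focal length must be positive")


def _shell_point(rng: np.random.Generator, r_lo: float, r_hi: float) -> np.ndarray:
    """Uniform-in-volume point in the upper hemispherical shell [r_lo, r_hi]."""
    u = rng.uniform()
    r = (r_lo ** 3 + u * (r_hi ** 3 - r_lo ** 3)) ** (1.0 / 3.0)
    z = rng.uniform()                       # direction uniform over solid angle
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - z * z))
    return r * np.array([s * math.cos(phi), s * math.sin(phi), z])


def sample_camera(params: ViewSamplingParams,
                  seed: Union[int, np.random.Generator],
                  image_size: Tuple[int, int] = (640, 480),
                  hfov_deg: float = 60.0) -> CameraPose:
    """Camera uniformly in the view shell volume, looking at the origin."""
    rng = _rng(seed)
    pos = _shell_point(rng, params.r_view_lower, params.r_view_upper)
    W, H = image_size
    focal = (W / 2.0) / math.tan(math.radians(hfov_deg) / 2.0)
    return CameraPose(position=tuple(pos), target=(0.0, 0.0, 0.0),
                      focal=focal, cx=W / 2.0, cy=H / 2.0, width=W, height=H)


@dataclass(frozen=True)
class PointLight:
    position: Tuple[float, float, float]
    intensity: float


def sample_lights(view: ViewSamplingParams, regime: str,
                  seed: Union[int, np.random.Generator]) -> List[PointLight]:
    """0-2 point lights in the light shell; intensity scaled by the regime.

    With the same seed, all regimes produce identical light geometry; only
    the intensity scale differs (strong > normal > weak).
    """
    if regime not in ILLUMINATION_REGIMES:
        raise ValueError(f"unknown illumination regime {regime!r}")
    rng = _rng(seed)
    lp = light_radii(view)
    n = int(rng.integers(0, 3))
    positions = [_shell_point(rng, lp.r_light_lower, lp.r_light_upper)
                 for _ in range(n)]
    jitters = [rng.uniform(0.8, 1.2) for _ in range(n)]
    scale = ILLUMINATION_REGIMES[regime][1]
    return [PointLight(position=tuple(p), intensity=scale * j)
            for p, j in zip(positions, jitters)]


# ---------------------------------------------------------------------------
# Primitives and scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: Tuple[float, float, float]
    radius: float
    color: Tuple[float, float, float]
    ripeness: str = "ripe"


@dataclass(frozen=True)
class Cylinder:
    """Finite open cylinder (lateral surface): base point, unit axis, height."""

    base: Tuple[float, float, float]
    axis: Tuple[float, float, float]
    radius: float
    height: float
    color: Tuple[float, float, float]


@dataclass(frozen=True)
class Disc:
    center: Tuple[float, float, float]
    normal: Tuple[float, float, float]
    radius: float
    color: Tuple[float, float, float]


Primitive = Union[Sphere, Cylinder, Disc]


@dataclass
class SceneSpec:
    """Everything needed to render one view deterministically."""

    fruits: List[Sphere]
    occluders: List[Primitive]
    camera: CameraPose
    lights: List[PointLight]
    regime: str
    seed: int
    background: Tuple[float, float, float] = (0.10, 0.12, 0.08)

    def __post_init__(self):
        if not 1 <= len(self.fruits) <= 10:
            raise ValueError(
                f"scene must contain 1-10 fruit, got {len(self.fruits)}")


@dataclass
class RGBDFrame:
    """Registered color + metric depth + instance id buffer for one view."""

    rgb: np.ndarray                  # (H, W, 3) uint8
    depth: np.ndarray                # (H, W) float64 meters, 0 = invalid
    instance_id_buffer: np.ndarray   # (H, W) int32, 0 = background/occluder


@dataclass
class InstanceRecord:
    """One fruit's annotation: masks, occlusion statistics, box."""

    instance_id: int
    category: str
    ripeness: str
    bbox: Tuple[int, int, int, int]  # [x0, y0, x1, y1] half-open pixels
    masks: InstanceMasks

    @property
    def occlusion_rate(self) -> float:
        return self.masks.occlusion_rate

    @property
    def occluded(self) -> bool:
        return self.masks.occluded

    def bin_label(self) -> str:
        return bin_occlusion(self.occlusion_rate)


@dataclass
class SceneConfig:
    """Generator configuration; defaults are the study conditions."""

    n_fruits_range: Tuple[int, int] = (1, 10)
    fruit_radius_range: Tuple[float, float] = (0.03, 0.05)
    cluster_extent: float = 0.25         # fruit centers within +-extent of origin
    n_occluders_range: Tuple[int, int] = (0, 4)
    l_range: Tuple[float, float] = (1.0, 2.0)
    w_range: Tuple[float, float] = (2.0, 4.0)
    image_size: Tuple[int, int] = (640, 480)
    hfov_deg: float = 60.0
    regime_mix: Dict[str, float] = field(default_factory=lambda: {
        "strong": 0.2, "normal": 0.6, "weak": 0.2})
    ripeness_probs: Dict[str, float] = field(default_factory=lambda: {
        "ripe": 0.5, "turning": 0.25, "unripe": 0.25})
    background: Tuple[float, float, float] = (0.10, 0.12, 0.08)


def sample_scene(config: SceneConfig, seed: int,
                 regime: Optional[str] = None) -> SceneSpec:
    """Draw a full scene specification from the configured distributions."""
    rng = _rng(seed)
    l = rng.uniform(*config.l_range)
    w = rng.uniform(*config.w_range)
    view = sample_view_radii(l, w)

    n_fruit = int(rng.integers(config.n_fruits_range[0],
                               config.n_fruits_range[1] + 1))
    e = config.cluster_extent
    names = list(config.ripeness_probs)
    probs = np.array([config.ripeness_probs[k] for k in names], dtype=float)
    probs /= probs.sum()
    fruits = []
    for _ in range(n_fruit):
        center = rng.uniform(-e, e, size=3)
        radius = rng.uniform(*config.fruit_radius_range)
        ripeness = names[rng.choice(len(names), p=probs)]
        fruits.append(Sphere(center=tuple(center), radius=radius,
                             color=RIPENESS_COLORS[ripeness], ripeness=ripeness))

    r_mean = float(np.mean([f.radius for f in fruits]))
    n_occ = int(rng.integers(config.n_occluders_range[0],
                             config.n_occluders_range[1] + 1))
    occluders: List[Primitive] = []
    for _ in range(n_occ):
        center = rng.uniform(-1.3 * e, 1.3 * e, size=3)
        if rng.uniform() < 0.5:  # stem
            axis = rng.normal(size=3)
            axis[2] = abs(axis[2]) + 1.0   # mostly vertical
            axis /= np.linalg.norm(axis)
            occluders.append(Cylinder(
                base=tuple(center), axis=tuple(axis),
                radius=r_mean * rng.uniform(0.3, 0.6),
                height=r_mean * rng.uniform(2.0, 5.0),
                color=_OCCLUDER_COLORS["stem"]))
        else:  # leaf
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            occluders.append(Disc(
                center=tuple(center), normal=tuple(normal),
                radius=r_mean * rng.uniform(0.8, 1.6),
                color=_OCCLUDER_COLORS["leaf"]))

    if regime is None:
        reg_names = list(config.regime_mix)
        reg_p = np.array([config.regime_mix[k] for k in reg_names], dtype=float)
        reg_p /= reg_p.sum()
        regime = reg_names[rng.choice(len(reg_names), p=reg_p)]

    camera = sample_camera(view, rng, image_size=config.image_size,
                           hfov_deg=config.hfov_deg)
    lights = sample_lights(view, regime, rng)
    return SceneSpec(fruits=fruits, occluders=occluders, camera=camera,
                     lights=lights, regime=regime, seed=int(seed),
                     background=config.background)


# ---------------------------------------------------------------------------
# Analytic z-buffer renderer
# ---------------------------------------------------------------------------

def _camera_basis(cam: CameraPose):
    pos = np.asarray(cam.position, dtype=np.float64)
    fwd = np.asarray(cam.target, dtype=np.float64) - pos
    fwd /= np.linalg.norm(fwd)
    up_hint = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(fwd, up_hint)) > 0.999:
        up_hint = np.array([1.0, 0.0, 0.0])
    right = np.cross(fwd, up_hint)
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)
    return pos, fwd, right, down


def _ray_grid(cam: CameraPose):
    pos, fwd, right, down = _camera_basis(cam)
    u = (np.arange(cam.width) + 0.5 - cam.cx) / cam.focal
    v = (np.arange(cam.height) + 0.5 - cam.cy) / cam.focal
    uu, vv = np.meshgrid(u, v)
    dirs = (fwd[None, None, :] + uu[..., None] * right[None, None, :]
            + vv[..., None] * down[None, None, :])
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    return pos, fwd, dirs


def _intersect(prim: Primitive, origin: np.ndarray, dirs: np.ndarray):
    """Nearest positive hit distance per pixel; NaN where the ray misses."""
    t = np.full(dirs.shape[:2], np.nan)
    if isinstance(prim, Sphere):
        oc = origin - np.asarray(prim.center)
        b = dirs @ oc
        c = float(oc @ oc) - prim.radius ** 2
        disc = b * b - c
        ok = disc > 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t_near = -b - sq
        t_far = -b + sq
        cand = np.where(t_near > _T_NEAR, t_near, t_far)
        valid = ok & (cand > _T_NEAR)
        t[valid] = cand[valid]
    elif isinstance(prim, Cylinder):
        a = np.asarray(prim.axis, dtype=np.float64)
        a = a / np.linalg.norm(a)
        w0 = origin - np.asarray(prim.base)
        d_par = dirs @ a
        d_perp = dirs - d_par[..., None] * a
        w_par = float(w0 @ a)
        w_perp = w0 - w_par * a
        A = np.einsum("ijk,ijk->ij", d_perp, d_perp)
        B = d_perp @ w_perp
        C = float(w_perp @ w_perp) - prim.radius ** 2
        disc = B * B - A * C
        ok = (disc > 0) & (A > _EPS)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        for root in ((-B - sq) / np.where(A > _EPS, A, 1.0),
                     (-B + sq) / np.where(A > _EPS, A, 1.0)):
            s = w_par + root * d_par
            valid = ok & (root > _T_NEAR) & (s >= 0) & (s <= prim.height) \
                & np.isnan(t)
            t[valid] = root[valid]
    elif isinstance(prim, Disc):
        n = np.asarray(prim.normal, dtype=np.float64)
        n = n / np.linalg.norm(n)
        denom = dirs @ n
        num = float((np.asarray(prim.center) - origin) @ n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = num / denom
        hit = origin[None, None, :] + tt[..., None] * dirs
        dist2 = np.einsum("ijk,ijk->ij",
                          hit - np.asarray(prim.center), hit - np.asarray(prim.center))
        valid = (np.abs(denom) > _EPS) & (tt > _T_NEAR) & \
            (dist2 <= prim.radius ** 2)
        t[valid] = tt[valid]
    else:  # pragma: no cover
        raise TypeError(f"unknown primitive {type(prim)}")
    return t


def _normal_at(prim: Primitive, points: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    if isinstance(prim, Sphere):
        n = (points - np.asarray(prim.center)) / prim.radius
    elif isinstance(prim, Cylinder):
        a = np.asarray(prim.axis, dtype=np.float64)
        a = a / np.linalg.norm(a)
        rel = points - np.asarray(prim.base)
        n = rel - (rel @ a)[..., None] * a
        n /= np.maximum(np.linalg.norm(n, axis=-1, keepdims=True), _EPS)
    else:
        n = np.broadcast_to(np.asarray(prim.normal, dtype=np.float64),
                            points.shape).copy()
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
    # orient toward the camera
    flip = np.einsum("...k,...k->...", n, dirs) > 0
    n[flip] *= -1.0
    return n


def _bounding_sphere(prim: Primitive) -> Tuple[np.ndarray, float]:
    if isinstance(prim, Sphere):
        return np.asarray(prim.center, dtype=np.float64), prim.radius
    if isinstance(prim, Cylinder):
        a = np.asarray(prim.axis, dtype=np.float64)
        a = a / np.linalg.norm(a)
        center = np.asarray(prim.base) + a * (prim.height / 2.0)
        return center, math.hypot(prim.height / 2.0, prim.radius)
    return np.asarray(prim.center, dtype=np.float64), prim.radius


def _pixel_rect(cam: CameraPose, basis, center: np.ndarray, radius: float):
    """Conservative image-space rectangle covering a bounding sphere.

    Returns (r0, r1, c0, c1) slice bounds, the full frame when the
    camera is too close for a stable projection, or None when the sphere
    lies entirely behind the camera or outside the frame.
    """
    pos, fwd, right, down = basis
    rel = center - pos
    z = float(rel @ fwd)
    if z + radius <= _T_NEAR:
        return None
    if z - radius < 0.05:                      # grazing: no safe bound
        return (0, cam.height, 0, cam.width)
    u = cam.cx + cam.focal * float(rel @ right) / z
    v = cam.cy + cam.focal * float(rel @ down) / z
    pr = cam.focal * radius / (z - radius) * 1.2 + 2.0
    c0 = max(int(math.floor(u - pr)), 0)
    c1 = min(int(math.ceil(u + pr)) + 1, cam.width)
    r0 = max(int(math.floor(v - pr)), 0)
    r1 = min(int(math.ceil(v + pr)) + 1, cam.height)
    if r0 >= r1 or c0 >= c1:
        return None
    return (r0, r1, c0, c1)


def _camera_inside(prim: Primitive, pos: np.ndarray) -> bool:
    if isinstance(prim, Sphere):
        return bool(np.linalg.norm(pos - np.asarray(prim.center)) <= prim.radius)
    if isinstance(prim, Cylinder):
        a = np.asarray(prim.axis, dtype=np.float64)
        a = a / np.linalg.norm(a)
        rel = pos - np.asarray(prim.base)
        s = float(rel @ a)
        perp = np.linalg.norm(rel - s * a)
        return 0 <= s <= prim.height and perp <= prim.radius
    return False


def render_scene(spec: SceneSpec) -> Tuple[RGBDFrame, List[InstanceRecord]]:
    """Render a scene and derive exact amodal annotations.

    Returns the RGB-D frame (with fruit instance id buffer; occluder
    pixels are background id 0) and one :class:`InstanceRecord` per
    fruit that is at least partly visible; fully occluded fruit are not
    annotated.
    """
    if not spec.fruits and not spec.occluders:
        raise ValueError("cannot render an empty scene")
    cam = spec.camera
    basis = _camera_basis(cam)
    origin, fwd, dirs = _ray_grid(cam)
    prims: List[Primitive] = list(spec.fruits) + list(spec.occluders)
    for p in prims:
        if _camera_inside(p, origin):
            raise ValueError("camera lies inside a scene primitive")

    H, W = cam.height, cam.width
    zbuf = np.full((H, W), np.inf)
    idbuf = np.zeros((H, W), dtype=np.int32)        # fruit ids 1..n, else 0
    hit_prim = np.full((H, W), -1, dtype=np.int32)  # index into prims
    fruit_hits: List[np.ndarray] = []

    for k, prim in enumerate(prims):
        hit = np.zeros((H, W), dtype=bool)
        rect = _pixel_rect(cam, basis, *_bounding_sphere(prim))
        if rect is not None:
            r0, r1, c0, c1 = rect
            t_sub = _intersect(prim, origin, dirs[r0:r1, c0:c1])
            hit_sub = ~np.isnan(t_sub)
            closer = hit_sub & (t_sub < zbuf[r0:r1, c0:c1])
            zb = zbuf[r0:r1, c0:c1]
            zb[closer] = t_sub[closer]
            hp = hit_prim[r0:r1, c0:c1]
            hp[closer] = k
            ib = idbuf[r0:r1, c0:c1]
            ib[closer] = k + 1 if k < len(spec.fruits) else 0
            hit[r0:r1, c0:c1] = hit_sub
        if k < len(spec.fruits):
            fruit_hits.append(hit)

    # depth along the optical axis, clipped to the valid sensor range
    cosang = dirs @ fwd
    depth = np.where(np.isfinite(zbuf), zbuf * cosang, 0.0)
    depth[(depth < DEPTH_MIN) | (depth > DEPTH_MAX)] = 0.0

    # shading
    ambient, _ = ILLUMINATION_REGIMES[spec.regime]
    total_int = sum(l.intensity for l in spec.lights)
    bg = np.clip(np.asarray(spec.background) * (ambient + 0.3 * total_int),
                 0.0, 1.0)
    img = np.broadcast_to(bg, (H, W, 3)).copy()
    hit_any = hit_prim >= 0
    if hit_any.any():
        points = origin[None, None, :] + zbuf[..., None] * dirs
        for k, prim in enumerate(prims):
            sel = hit_prim == k
            if not sel.any():
                continue
            n = _normal_at(prim, points[sel], dirs[sel])
            shade = np.full(sel.sum(), ambient)
            for light in spec.lights:
                lvec = np.asarray(light.position) - points[sel]
                lvec /= np.linalg.norm(lvec, axis=-1, keepdims=True)
                shade += light.intensity * np.maximum(
                    0.0, np.einsum("ik,ik->i", n, lvec))
            img[sel] = np.clip(
                np.asarray(prim.color)[None, :] * shade[:, None], 0.0, 1.0)
    rgb = (img * 255.0 + 0.5).astype(np.uint8)

    frame = RGBDFrame(rgb=rgb, depth=depth, instance_id_buffer=idbuf)

    records: List[InstanceRecord] = []
    for i, fruit in enumerate(spec.fruits):
        amodal = fruit_hits[i]
        if not amodal.any():
            continue  # outside the frame entirely
        visible = idbuf == i + 1
        if not visible.any():
            continue  # occlusion rate 1: annotation not saved
        masks = InstanceMasks(amodal=amodal, visible=visible,
                              category="tomato", instance_id=i + 1)
        ys = np.flatnonzero(amodal.any(axis=1))
        xs = np.flatnonzero(amodal.any(axis=0))
        bbox = (int(xs[0]), int(ys[0]), int(xs[-1]) + 1, int(ys[-1]) + 1)
        records.append(InstanceRecord(instance_id=i + 1, category="tomato",
                                      ripeness=fruit.ripeness, bbox=bbox,
                                      masks=masks))
    return frame, records


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def allocate_regimes(mix: Dict[str, float], n: int) -> List[str]:
    """Deterministic largest-remainder allocation of n scenes to regimes."""
    names = list(mix)
    weights = np.array([mix[k] for k in names], dtype=float)
    weights /= weights.sum()
    exact = weights * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    out: List[str] = []
    for name, c in zip(names, counts):
        out.extend([name] * int(c))
    return out


def generate_dataset(config, out_dir, seed: Optional[int] = None) -> dict:
    """Render a full dataset to ``out_dir`` and return its manifest.

    ``config`` is a :class:`~amodalfruit.pipeline.DatasetConfig`; writes
    ``images/*.png``, ``depth/*.png`` (16-bit, millimeters) and
    ``annotations.json`` (COCO dialect with amodal/visible/occlusion
    RLE masks), plus a regime-by-occlusion-bin stratification table and
    a deterministic 8:2 (configurable) train/test split.
    """
    from . import dataset_io  # local import: keeps renderer importable alone
    return dataset_io.write_dataset(config, out_dir, seed=seed)
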