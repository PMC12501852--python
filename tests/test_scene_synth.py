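"""Sampling geometry and renderer correctness for the synthetic scenes."""

import math

import numpy as np
import pytest

from amodalfruit import scene_synth as ss
from amodalfruit.scene_synth import (CameraPose, SceneConfig, SceneSpec,
                                     Sphere, sample_camera, sample_lights,
                                     sample_scene, sample_view_radii,
                                     render_scene, light_radii)
from raycast_oracle import brute_force_masks


# ---------------------------------------------------------------------------
# Shell radii
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("l,w,lo,hi", [
    (1.0, 2.0, 1.0, 1.7),
    (2.0, 2.0, 1.0, 1.7),     # max() tie between l/2 and w/2
    (2.0, 4.0, 2.0, 3.4),
])
def test_view_radii_formulas(l, w, lo, hi):
    p = sample_view_radii(l, w)
    assert p.r_view_lower == pytest.approx(lo)
    assert p.r_view_upper == pytest.approx(hi)
    assert p.r_view_upper > p.r_view_lower > 0


@pytest.mark.parametrize("l,w", [(0.5, 2.0), (2.5, 2.0), (1.0, 1.0),
                                 (1.0, 5.0)])
def test_view_radii_domain_errors(l, w):
    with pytest.raises(ValueError):
        sample_view_radii(l, w)


def test_light_radii_offsets():
    view = sample_view_radii(1.0, 2.0)       # r_upper = 1.7
    lp = light_radii(view)
    assert lp.r_light_lower == pytest.approx(1.8)
    assert lp.r_light_upper == pytest.approx(2.8)


# ---------------------------------------------------------------------------
# Camera sampling
# ---------------------------------------------------------------------------

def test_camera_shell_membership_and_determinism():
    params = sample_view_radii(1.0, 2.0)
    for seed in range(500):
        cam = sample_camera(params, seed)
        r = np.linalg.norm(cam.position)
        assert params.r_view_lower <= r <= params.r_view_upper
        assert cam.position[2] >= 0
    a = sample_camera(params, 42)
    b = sample_camera(params, 42)
    assert a == b


def test_camera_radius_cubed_is_volume_uniform():
    # uniform-in-volume radius: r^3 ~ U[r_lo^3, r_hi^3], so
    # E[r^3] = (1 + 1.7^3) / 2 with SE = range / sqrt(12 n)
    params = sample_view_radii(1.0, 2.0)
    n = 10_000
    rng = np.random.default_rng(7)
    r3 = np.array([np.linalg.norm(sample_camera(params, rng).position) ** 3
                   for _ in range(n)])
    expected = (1.0 + 1.7 ** 3) / 2.0
    se = (1.7 ** 3 - 1.0) / math.sqrt(12 * n)
    assert abs(r3.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# Light sampling
# ---------------------------------------------------------------------------

def test_lights_count_shell_and_regime_ordering():
    view = sample_view_radii(1.0, 2.0)
    counts = set()
    for seed in range(300):
        lights = sample_lights(view, "normal", seed)
        counts.add(len(lights))
        for lt in lights:
            r = np.linalg.norm(lt.position)
            assert 1.8 - 1e-12 <= r <= 2.8 + 1e-12
    assert counts == {0, 1, 2}
    # same seed: identical geometry, strictly ordered intensity
    for seed in (3, 5, 11):
        weak = sample_lights(view, "weak", seed)
        strong = sample_lights(view, "strong", seed)
        assert len(weak) == len(strong)
        for lw, lst in zip(weak, strong):
            assert lw.position == lst.position
            if len(weak):
                assert lw.intensity < lst.intensity


def test_unknown_regime_rejected():
    view = sample_view_radii(1.0, 2.0)
    with pytest.raises(ValueError, match="regime"):
        sample_lights(view, "blinding", 0)


# ---------------------------------------------------------------------------
# Renderer
# ---------------------------------------------------------------------------

def _camera(position, size=64):
    focal = (size / 2) / math.tan(math.radians(30.0))
    return CameraPose(position=position, target=(0.0, 0.0, 0.0), focal=focal,
                      cx=size / 2, cy=size / 2, width=size, height=size)


def _spec(fruits, occluders=(), camera=None, lights=()):
    return SceneSpec(fruits=list(fruits), occluders=list(occluders),
                     camera=camera or _camera((0.0, -2.0, 0.5)),
                     lights=list(lights), regime="normal", seed=0)


def test_single_sphere_unoccluded():
    spec = _spec([Sphere((0, 0, 0), 0.3, (0.8, 0.1, 0.1))])
    frame, recs = render_scene(spec)
    assert len(recs) == 1
    r = recs[0]
    assert (r.masks.visible == r.masks.amodal).all()
    assert r.occlusion_rate == 0.0
    assert not r.masks.occluded_mask.any()


def test_fully_hidden_far_sphere_dropped():
    cam = _camera((0.0, -2.0, 0.0))
    near = Sphere((0, 0, 0), 0.3, (0.8, 0.1, 0.1))
    far = Sphere((0, 1.0, 0), 0.15, (0.2, 0.6, 0.2))  # same axis, smaller
    frame, recs = render_scene(_spec([near, far], camera=cam))
    assert [r.instance_id for r in recs] == [1]


def test_partial_overlap_occlusion_is_projected_intersection():
    cam = _camera((0.0, -2.0, 0.0))
    near = Sphere((0.12, 0.0, 0.0), 0.25, (0.8, 0.1, 0.1))
    far = Sphere((-0.12, 1.0, 0.0), 0.25, (0.2, 0.6, 0.2))
    frame, recs = render_scene(_spec([near, far], camera=cam))
    by_id = {r.instance_id: r for r in recs}
    assert by_id[2].occluded
    overlap = by_id[1].masks.amodal & by_id[2].masks.amodal
    assert (by_id[2].masks.occluded_mask == overlap).all()
    assert overlap.sum() > 0


def test_empty_scene_and_camera_inside_errors():
    with pytest.raises(ValueError):
        _spec([])  # SceneSpec enforces 1-10 fruit
    inside = Sphere((0.0, -2.0, 0.5), 0.4, (0.8, 0.1, 0.1))
    with pytest.raises(ValueError, match="inside"):
        render_scene(_spec([inside]))


def test_renderer_matches_brute_force_oracle():
    """z-buffer masks equal per-pixel closest-hit masks, pixel for pixel."""
    rng = np.random.default_rng(99)
    for _ in range(10):
        n = int(rng.integers(1, 4))
        fruits = [Sphere(tuple(rng.uniform(-0.3, 0.3, 3)),
                         float(rng.uniform(0.1, 0.3)), (0.8, 0.1, 0.1))
                  for _ in range(n)]
        cam = _camera(tuple(rng.uniform(-2, 2, 2)) + (rng.uniform(0.5, 2),))
        spec = _spec(fruits, camera=cam)
        frame, recs = render_scene(spec)
        idbuf, amodal = brute_force_masks(cam, [(f.center, f.radius)
                                                for f in fruits])
        np.testing.assert_array_equal(frame.instance_id_buffer, idbuf)
        rec_by_id = {r.instance_id: r for r in recs}
        for k in range(n):
            if k + 1 in rec_by_id:
                np.testing.assert_array_equal(
                    rec_by_id[k + 1].masks.amodal, amodal[k])
            else:  # dropped: fully occluded or out of frame
                assert not (idbuf == k + 1).any()


def test_mask_consistency_and_depth_bounds():
    cfg = SceneConfig(image_size=(96, 96), n_fruits_range=(2, 5),
                      fruit_radius_range=(0.1, 0.2))
    for seed in range(8):
        frame, recs = render_scene(sample_scene(cfg, seed))
        union = np.zeros(frame.depth.shape, dtype=bool)
        for r in recs:
            assert not (union & r.masks.visible).any()
            union |= r.masks.visible
        assert (union == (frame.instance_id_buffer > 0)).all()
        valid = frame.depth[frame.depth > 0]
        if valid.size:
            assert valid.min() >= ss.DEPTH_MIN
            assert valid.max() <= ss.DEPTH_MAX


def test_scene_and_render_determinism():
    cfg = SceneConfig(image_size=(64, 64))
    s1 = sample_scene(cfg, 5)
    s2 = sample_scene(cfg, 5)
    assert s1 == s2
    f1, r1 = render_scene(s1)
    f2, r2 = render_scene(s2)
    np.testing.assert_array_equal(f1.rgb, f2.rgb)
    np.testing.assert_array_equal(f1.depth, f2.depth)
    assert len(r1) == len(r2)
    for a, b in zip(r1, r2):
        np.testing.assert_array_equal(a.masks.amodal, b.masks.amodal)


def test_scene_spec_fruit_count_bounds():
    cam = _camera((0.0, -2.0, 0.5))
    too_many = [Sphere((0, 0, 0), 0.1, (1, 0, 0))] * 11
    with pytest.raises(ValueError):
        SceneSpec(fruits=too_many, occluders=[], camera=cam, lights=[],
                  regime="normal", seed=0)
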