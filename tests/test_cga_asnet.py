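"""Architecture contracts: attention blocks, fusion, heads, losses."""

import numpy as np
import pytest

from amodalfruit import nn
from amodalfruit.cga_asnet import (CFTBlock, CGAASNet, ChannelAttention,
                                   FPN, GAM, LossBreakdown, NetworkConfig,
                                   RGBDFusion, SpatialAttention,
                                   combine_losses)
from amodalfruit.nn import Tensor
from amodalfruit.scene_synth import render_scene, sample_scene


def _zero_params(module):
    for p in module.parameters():
        p.data[:] = 0.0


@pytest.fixture(scope="module")
def frame_and_records(tiny_config):
    spec = sample_scene(tiny_config.dataset.scene, 7)
    return render_scene(spec)


class TestCFT:
    def test_shape_preserved(self, rng):
        blk = CFTBlock(rng, 8)
        x = Tensor(rng.normal(size=(1, 8, 16, 16)))
        assert blk(x).shape == (1, 8, 16, 16)

    def test_attention_normalised_over_channels(self, rng):
        blk = CFTBlock(rng, 8)
        x = Tensor(rng.normal(size=(2, 8, 6, 6)))
        w = blk.attention_weights(x).data
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-5)

    def test_zero_parameters_give_uniform_weights_and_zero_output(self, rng):
        blk = CFTBlock(rng, 8)
        _zero_params(blk)
        x = Tensor(rng.normal(size=(1, 8, 5, 5)))
        w = blk.attention_weights(x).data
        np.testing.assert_allclose(w, 1.0 / 8.0)
        np.testing.assert_allclose(blk(x).data, 0.0)


class TestGAM:
    def test_channel_attention_shapes(self, rng):
        cam = ChannelAttention(rng, 16, 4)
        assert cam.fc1.weight.shape == (16, 4)   # hidden width C/r
        x = Tensor(rng.normal(size=(2, 16, 5, 5)))
        m = cam.attention(x)
        assert m.shape == (2, 16)
        assert ((m.data > 0) & (m.data < 1)).all()

    def test_channel_attention_constant_map_identity(self, rng):
        """On spatially constant maps avg- and max-pooling coincide, so
        the gate is sigmoid(2 * MLP(v))."""
        cam = ChannelAttention(rng, 8, 2)
        v = rng.normal(size=8)
        x = Tensor(np.broadcast_to(v[None, :, None, None],
                                   (1, 8, 4, 4)).copy())
        got = cam.attention(x).data[0]
        h = np.maximum(v @ cam.fc1.weight.data + cam.fc1.bias.data, 0)
        mlp = h @ cam.fc2.weight.data + cam.fc2.bias.data
        np.testing.assert_allclose(got, 1 / (1 + np.exp(-2 * mlp)),
                                   atol=1e-12)

    def test_zero_mlp_gives_half(self, rng):
        cam = ChannelAttention(rng, 8, 4)
        _zero_params(cam)
        x = Tensor(rng.normal(size=(1, 8, 3, 3)))
        np.testing.assert_allclose(cam.attention(x).data, 0.5)

    def test_reduction_must_divide(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            ChannelAttention(rng, 10, 4)

    def test_spatial_attention_shape_and_zero_init(self, rng):
        sam = SpatialAttention(rng)
        x = Tensor(rng.normal(size=(1, 8, 32, 32)))
        m = sam.attention(x)
        assert m.shape == (1, 1, 32, 32)
        assert ((m.data > 0) & (m.data < 1)).all()
        _zero_params(sam)
        np.testing.assert_allclose(sam.attention(x).data, 0.5)

    def test_composition_preserves_shape(self, rng):
        gam = GAM(rng, 8, 4)
        x = Tensor(rng.normal(size=(2, 8, 7, 9)))
        assert gam(x).shape == (2, 8, 7, 9)


class TestFusion:
    def test_shape_contract(self, rng):
        cfg = NetworkConfig(stage_widths=(8, 16, 24, 32))
        fuse = RGBDFusion(rng, cfg)
        rgb = {n: Tensor(rng.normal(size=(1, c, s, s)))
               for n, c, s in (("c3", 16, 12), ("c4", 24, 6), ("c5", 32, 3))}
        dep = {n: Tensor(rng.normal(size=t.shape)) for n, t in rgb.items()}
        out = fuse(rgb, dep)
        assert [out[n].shape for n in ("c3", "c4", "c5")] == \
            [(1, 16, 12, 12), (1, 24, 6, 6), (1, 32, 3, 3)]

    def test_identity_kernel_passes_rgb_through(self, rng):
        """A 1x1 kernel equal to identity on the RGB half and zero on the
        depth half reproduces the RGB features exactly."""
        cfg = NetworkConfig(stage_widths=(8, 16, 24, 32))
        fuse = RGBDFusion(rng, cfg)
        for conv, c in zip(fuse.convs, (16, 24, 32)):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
            conv.weight.data[np.arange(c), np.arange(c), 0, 0] = 1.0
        rgb = {n: Tensor(rng.normal(size=(1, c, s, s)))
               for n, c, s in (("c3", 16, 12), ("c4", 24, 6), ("c5", 32, 3))}
        dep = {n: Tensor(np.zeros(t.shape)) for n, t in rgb.items()}
        out = fuse(rgb, dep)
        for n in rgb:
            np.testing.assert_allclose(out[n].data, rgb[n].data)

    def test_spatial_mismatch_rejected(self, rng):
        cfg = NetworkConfig(stage_widths=(8, 16, 24, 32))
        fuse = RGBDFusion(rng, cfg)
        rgb = {"c3": Tensor(rng.normal(size=(1, 16, 12, 12))),
               "c4": Tensor(rng.normal(size=(1, 24, 6, 6))),
               "c5": Tensor(rng.normal(size=(1, 32, 3, 3)))}
        dep = dict(rgb)
        dep["c3"] = Tensor(rng.normal(size=(1, 16, 10, 12)))
        with pytest.raises(ValueError, match="mismatch"):
            fuse(rgb, dep)


class TestForward:
    def test_blank_frame_yields_no_detections(self, tiny_config):
        net = CGAASNet(tiny_config.network)
        rgb = np.full((96, 96, 3), 20, np.uint8)
        depth = np.zeros((96, 96))
        assert net.predict(rgb, depth) == []

    def test_detection_output_contract(self, tiny_config, frame_and_records):
        frame, _ = frame_and_records
        cfg = NetworkConfig(**{**tiny_config.network.__dict__,
                               "score_threshold": 0.01})
        net = CGAASNet(cfg)
        dets = net.predict(frame.rgb, frame.depth)
        assert dets, "low threshold should yield candidate detections"
        H, W = frame.depth.shape
        for d in dets:
            assert d.visible.shape == d.amodal.shape == (H, W)
            assert d.occluded in (0, 1)
            assert 0.0 <= d.score <= 1.0
            x0, y0, x1, y1 = d.box
            assert 0 <= x0 <= x1 <= W and 0 <= y0 <= y1 <= H

    def test_unregistered_inputs_rejected(self, tiny_config):
        net = CGAASNet(tiny_config.network)
        with pytest.raises(ValueError, match="registered"):
            net.predict(np.zeros((96, 96, 3), np.uint8), np.zeros((64, 96)))


class TestBranchDependencies:
    def test_ablating_visible_changes_amodal_not_visible(self, rng,
                                                         tiny_config):
        net = CGAASNet(tiny_config.network)
        f = tiny_config.network.fpn_width
        s = tiny_config.network.roi_mask_size
        f_b = Tensor(rng.normal(size=(3, f, s, s)))
        f_roi = Tensor(rng.normal(size=(3, f, s, s)))
        v0, a0, o0 = net.head.mask_branches(f_b, f_roi)
        v1, a1, o1 = net.head.mask_branches(f_b, f_roi, ablate_visible=True)
        np.testing.assert_allclose(v0.data, v1.data)   # V untouched
        assert not np.allclose(a0.data, a1.data)       # A depends on F_V
        assert not np.allclose(o0.data, o1.data)       # O depends on F_V


class TestLoss:
    def test_weighted_sum_of_units(self):
        comps = {k: 1.0 for k in ("cls", "box", "visible", "amodal",
                                  "occ_cls", "rpn_cls", "rpn_loc")}
        bd = combine_losses(comps)
        assert bd.total == pytest.approx(7.0)

    def test_linearity_in_weights(self):
        comps = {"cls": 0.3, "amodal": 0.8, "box": 0.1}
        base = combine_losses(comps).total
        doubled = combine_losses(comps, {"amodal": 2.0}).total
        assert doubled - base == pytest.approx(0.8)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            LossBreakdown(components={"cls": -0.1}, weights={"cls": 1.0},
                          total=-0.1)

    def test_perfect_logits_drive_losses_to_zero(self):
        z = Tensor(np.array([[20.0, -20.0], [-20.0, 20.0]]))
        assert float(nn.cross_entropy(z, np.array([0, 1])).data) < 1e-6
        logits = Tensor(np.full((2, 4), 20.0))
        assert float(nn.bce_with_logits(logits, np.ones((2, 4))).data) < 1e-6
        assert float(nn.smooth_l1(Tensor(np.zeros(4)), np.zeros(4)).data) == 0


class TestDeterminismAndLearning:
    def test_seeded_init_reproducible(self, tiny_config):
        a = CGAASNet(tiny_config.network)
        b = CGAASNet(tiny_config.network)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_one_step_decreases_fixed_batch_loss(self, tiny_config,
                                                 frame_and_records):
        frame, recs = frame_and_records
        net = CGAASNet(tiny_config.network)
        boxes = np.array([r.bbox for r in recs], float)
        args = (frame.rgb, frame.depth, boxes,
                [r.masks.visible for r in recs],
                [r.masks.amodal for r in recs],
                [int(r.occluded) for r in recs])

        def loss_total(seed):
            losses = net.compute_losses(*args, np.random.default_rng(seed))
            return combine_losses(losses, tiny_config.network.loss_weights)

        t0, bd0 = loss_total(0)
        opt = nn.SGD(net.parameters(), lr=0.01)
        opt.zero_grad()
        t0.backward()
        opt.step()
        t1, bd1 = loss_total(0)       # same sampling rng -> same batch
        assert bd1.total < bd0.total
        assert all(v >= 0 for v in bd0.components.values())

    def test_equal_seeds_equal_first_losses(self, tiny_config,
                                            frame_and_records):
        frame, recs = frame_and_records
        boxes = np.array([r.bbox for r in recs], float)
        totals = []
        for _ in range(2):
            net = CGAASNet(tiny_config.network)
            losses = net.compute_losses(
                frame.rgb, frame.depth, boxes,
                [r.masks.visible for r in recs],
                [r.masks.amodal for r in recs],
                [int(r.occluded) for r in recs], np.random.default_rng(5))
            totals.append(combine_losses(losses)[1].total)
        assert totals[0] == totals[1]


class TestBaselineMode:
    def test_attention_free_backbone_is_plain_residual(self, tiny_config,
                                                       frame_and_records):
        frame, _ = frame_and_records
        base_cfg = NetworkConfig(**{**tiny_config.network.__dict__,
                                    "cft_stages": (), "gam_stages": ()})
        baseline = CGAASNet(base_cfg)
        full = CGAASNet(tiny_config.network)
        n_base = sum(p.data.size for p in baseline.parameters())
        n_full = sum(p.data.size for p in full.parameters())
        assert n_base < n_full
        # forward still works end to end
        pyr = baseline.extract_pyramid(frame.rgb, frame.depth)
        assert set(pyr) == {"p3", "p4", "p5"}
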