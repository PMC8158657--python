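import numpy as np
import pytest

from comodseg import autograd as ag
from comodseg import network as net
from comodseg.network import (NetworkConfig, SegmentationNetwork,
                              binarize_prediction, co_attention_average,
                              forward_segment, reverse_attention)
from comodseg.volume_io import split_modality_pairs


@pytest.fixture(scope="module")
def model():
    return SegmentationNetwork(NetworkConfig(base_filters=4, seed=0))


class TestEncoder:
    def test_pyramid_shapes_and_channels(self, model, rng):
        x = ag.Tensor(rng.normal(size=(1, 2, 32, 32, 32)))
        pyr = model.encoder(x)
        for lvl, (res, ch) in enumerate(zip((32, 16, 8, 4, 2), (4, 8, 16, 32, 64)), 1):
            f = pyr.level(lvl)
            assert f.shape == (1, ch, res, res, res)

    def test_parameter_sharing_identity(self, model):
        # one parameter set serves both pairs: the encoder object is shared
        assert model.encoder is model.encoder
        x = np.random.default_rng(0).normal(size=(1, 2, 16, 16, 16))
        a = model.encoder(ag.Tensor(x)).f5.data
        b = model.encoder(ag.Tensor(x.copy())).f5.data
        np.testing.assert_array_equal(a, b)

    def test_gradients_flow_from_both_pairs(self, model, rng):
        stacks = {p: rng.normal(size=(1, 2, 16, 16, 16)) for p in ("g1", "g2")}
        out = model(stacks)
        model.zero_grad()
        out.prediction.sum().backward()
        w = model.encoder.stages[0].layers[0].conv.weight
        assert w.grad is not None and np.abs(w.grad).sum() > 0

    def test_divisibility_error(self, model, rng):
        with pytest.raises(ValueError, match="divisible"):
            model.encoder(ag.Tensor(rng.normal(size=(1, 2, 30, 30, 30))))


class TestPartialDecoder:
    def test_global_map_at_level3_resolution(self, model, rng):
        pyr = model.encoder(ag.Tensor(rng.normal(size=(1, 2, 32, 32, 32))))
        f_dp, m_g = model.partial_decoder(pyr)
        assert m_g.shape == (1, 3, 8, 8, 8)  # 3 region logit channels
        assert f_dp.shape[2:] == pyr.f3.shape[2:]

    def test_region_channels_is_three(self, model):
        assert model.partial_decoder.head.weight.shape[0] == 3


class TestReverseAttention:
    def test_zero_logits_give_half(self):
        r = reverse_attention(ag.Tensor(np.zeros((2, 3, 4)))).data
        np.testing.assert_allclose(r, 0.5, atol=1e-12)

    def test_saturation(self):
        assert reverse_attention(ag.Tensor(np.full((2,), 20.0))).data.max() < 1e-8
        assert reverse_attention(ag.Tensor(np.full((2,), -20.0))).data.min() > 1 - 1e-8

    def test_scalar_loop_oracle(self, rng):
        m = rng.normal(size=(4, 4, 4)) * 3
        r = reverse_attention(ag.Tensor(m)).data
        for idx in np.ndindex(m.shape):
            expected = 1.0 - 1.0 / (1.0 + np.exp(-m[idx]))
            assert abs(r[idx] - expected) < 1e-6

    def test_open_interval_and_monotone(self, rng):
        m = rng.normal(size=(10,))
        r = reverse_attention(ag.Tensor(m)).data
        assert ((r > 0) & (r < 1)).all()
        bumped = reverse_attention(ag.Tensor(m + 0.1)).data
        assert (bumped < r).all()  # increasing logit decreases R


class TestCoAttention:
    def test_idempotent_average(self, rng):
        r = ag.Tensor(rng.random((3, 3)))
        np.testing.assert_allclose(co_attention_average(r, r).data, r.data)

    def test_constants(self):
        a = ag.Tensor(np.full((2, 2), 0.2))
        b = ag.Tensor(np.full((2, 2), 0.6))
        np.testing.assert_allclose(co_attention_average(a, b).data, 0.4, atol=1e-12)

    def test_elementwise_oracle(self, rng):
        a, b = rng.random((5, 5)), rng.random((5, 5))
        out = co_attention_average(ag.Tensor(a), ag.Tensor(b)).data
        for idx in np.ndindex(a.shape):
            assert abs(out[idx] - (a[idx] + b[idx]) / 2.0) < 1e-7

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            co_attention_average(ag.Tensor(np.zeros((2, 2))),
                                 ag.Tensor(np.zeros((3, 2))))


class TestAttendFeatures:
    def test_identity_attention(self, rng):
        f = rng.normal(size=(1, 4, 2, 2, 2))
        out = net.attend_features(ag.Tensor(f), ag.Tensor(np.ones_like(f)))
        np.testing.assert_allclose(out.data, f + 1.0, atol=1e-12)

    def test_annihilation_plus_bias(self, rng):
        f = rng.normal(size=(1, 4, 2, 2, 2))
        out = net.attend_features(ag.Tensor(f), ag.Tensor(np.zeros_like(f)))
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_scalar_oracle_per_pair(self, rng):
        f = rng.normal(size=(2, 3, 3, 3))
        r = rng.random((2, 3, 3, 3))
        out = net.attend_features(ag.Tensor(f), ag.Tensor(r)).data
        for idx in np.ndindex(f.shape):
            assert abs(out[idx] - (f[idx] * r[idx] + 1.0)) < 1e-6

    def test_map_residual_mode_drops_plus_one(self, rng):
        f = rng.normal(size=(1, 2, 2, 2, 2))
        r = rng.random((1, 2, 2, 2, 2))
        out = net.attend_features(ag.Tensor(f), ag.Tensor(r), "map_residual")
        np.testing.assert_allclose(out.data, f * r, atol=1e-12)


class TestForward:
    def test_shapes_and_range(self, model, normalized32):
        study, _ = normalized32
        out = forward_segment(study, model)
        assert out.prediction.shape == (1, 3, 32, 32, 32)
        assert out.prediction.data.min() > 0.0
        assert out.prediction.data.max() < 1.0
        assert out.side_maps["m3"].shape == (1, 3, 8, 8, 8)
        assert out.side_maps["m4"].shape == (1, 3, 4, 4, 4)
        assert out.side_maps["m5"].shape == (1, 3, 2, 2, 2)
        assert set(out.global_maps) == {"g1", "g2"}

    def test_inference_deterministic(self, model, normalized32):
        study, _ = normalized32
        a = forward_segment(study, model).prediction.data
        b = forward_segment(study, model).prediction.data
        np.testing.assert_array_equal(a, b)

    def test_pair_swap_invariance_with_symmetric_weights(self, rng):
        # tie the per-pair branches together, then swapping the two pairs'
        # inputs must leave the output unchanged (the co-attention average and
        # the symmetric fusion see an identical multiset of inputs)
        model = SegmentationNetwork(NetworkConfig(base_filters=2, seed=5))
        for blk in model.fuse_blocks.values():
            a, b = blk.pair_mix
            for pa, pb in zip(a.parameters(), b.parameters()):
                pb.data = pa.data.copy()
            w = blk.fuse.conv.weight
            half = w.data.shape[1] // 2
            w.data[:, half:] = w.data[:, :half]
        stacks = {"g1": rng.normal(size=(1, 2, 16, 16, 16)),
                  "g2": rng.normal(size=(1, 2, 16, 16, 16))}
        out_ab = model(stacks).prediction.data
        out_ba = model({"g1": stacks["g2"], "g2": stacks["g1"]}).prediction.data
        np.testing.assert_allclose(out_ab, out_ba, atol=1e-9)

    def test_forward_under_five_seconds(self, model, normalized32):
        import time
        study, _ = normalized32
        t0 = time.time()
        forward_segment(study, model)
        assert time.time() - t0 < 5.0

    def test_single_pair_mode(self, normalized32):
        study, _ = normalized32
        m = SegmentationNetwork(NetworkConfig(base_filters=2, pairs=("g2",), seed=1))
        out = forward_segment(study, m)
        assert out.prediction.shape == (1, 3, 32, 32, 32)
        assert set(out.global_maps) == {"g2"}

    def test_residual_map_mode_runs(self, normalized32):
        study, _ = normalized32
        m = SegmentationNetwork(NetworkConfig(base_filters=2, seed=1,
                                              residual_mode="map_residual"))
        out = forward_segment(study, m)
        assert np.isfinite(out.prediction.data).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(levels=4).validate()
        with pytest.raises(ValueError):
            NetworkConfig(residual_mode="bogus").validate()
        with pytest.raises(ValueError):
            NetworkConfig(pairs=("g3",)).validate()


class TestBinarize:
    def test_threshold(self):
        probs = np.zeros((3, 2, 2, 2))
        probs[0] = 0.6
        probs[1, 0] = 0.6
        probs[2] = 0.4
        m = binarize_prediction(probs)
        assert m.wt.all()
        assert m.tc[0].all() and not m.tc[1].any()
        assert not m.et.any()

    def test_tie_goes_to_one(self):
        probs = np.full((3, 2, 2, 2), 0.5)
        m = binarize_prediction(probs)
        assert m.wt.all() and m.tc.all() and m.et.all()

    def test_nesting_enforced_constructively(self, rng):
        probs = rng.random((3, 6, 6, 6))
        m = binarize_prediction(probs)
        m.validate()

    def test_range_check(self):
        with pytest.raises(ValueError):
            binarize_prediction(np.full((3, 2, 2, 2), 1.5))
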