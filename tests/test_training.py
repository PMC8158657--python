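import dataclasses

import numpy as np
import pytest

from comodseg import training as tr
from comodseg.network import NetworkConfig
from comodseg.phantoms import generate_cohort
from comodseg.volume_io import map_labels, normalize_study


@pytest.fixture(scope="module")
def tiny_cohort(tiny_spec):
    return generate_cohort(4, spec=tiny_spec, master_seed=9)


def tiny_config(seed=9, steps=5, **kw):
    cfg = tr.TrainConfig(learning_rate=3e-3, patch_size=(16, 16, 16),
                         batch_size=1, steps=steps, master_seed=seed,
                         network=NetworkConfig(base_filters=2, seed=seed), **kw)
    cfg.validate()
    return cfg


class TestSplit:
    def test_80_20_reproducible(self):
        ids = [f"s{i}" for i in range(10)]
        a = tr.split_dataset(ids, 0.8, seed=3)
        b = tr.split_dataset(ids, 0.8, seed=3)
        assert a == b
        assert len(a[0]) == 8 and len(a[1]) == 2
        assert sorted(a[0] + a[1]) == sorted(ids)

    def test_half_of_two(self):
        train, test = tr.split_dataset(["a", "b"], 0.5, seed=0)
        assert len(train) == len(test) == 1

    def test_seed_changes_partition(self):
        ids = list(range(30))
        parts = {tuple(tr.split_dataset(ids, 0.8, seed=s)[1]) for s in range(6)}
        assert len(parts) > 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tr.split_dataset(["only"], 0.8, seed=0)
        with pytest.raises(ValueError):
            tr.split_dataset(["a", "b"], 0.99, seed=0)


class TestSamplePatch:
    def test_identity_crop(self, tiny_cohort):
        study, labels = tiny_cohort[0]
        masks = map_labels(labels)
        ps, pm = tr.sample_patch(study, masks, study.shape,
                                 np.random.default_rng(0))
        np.testing.assert_array_equal(ps.t1, study.t1)
        np.testing.assert_array_equal(pm.wt, masks.wt)

    def test_foreground_bias(self, phantom32):
        study, labels = phantom32
        masks = map_labels(labels)
        rng = np.random.default_rng(1)
        for _ in range(10):
            _, pm = tr.sample_patch(study, masks, (16, 16, 16), rng,
                                    p_foreground=1.0)
            assert pm.wt.sum() > 0  # every patch intersects WT

    def test_seeded_sequence_identical(self, phantom32):
        study, labels = phantom32
        masks = map_labels(labels)
        crops1 = [tr.sample_patch(study, masks, (16, 16, 16),
                                  np.random.default_rng(5))[0].t1 for _ in range(1)]
        crops2 = [tr.sample_patch(study, masks, (16, 16, 16),
                                  np.random.default_rng(5))[0].t1 for _ in range(1)]
        np.testing.assert_array_equal(crops1[0], crops2[0])

    def test_oversized_patch_rejected(self, tiny_cohort):
        study, labels = tiny_cohort[0]
        with pytest.raises(ValueError):
            tr.sample_patch(study, map_labels(labels), (64, 64, 64),
                            np.random.default_rng(0))


class TestTrain:
    def test_loss_decreases(self, tiny_cohort):
        cfg = tiny_config(steps=30)
        _, hist = tr.train(cfg, tiny_cohort)
        assert hist[-1]["l_total"] < hist[0]["l_total"]

    def test_zero_steps_equals_init(self, tiny_cohort):
        from comodseg import autograd as ag
        from comodseg.network import SegmentationNetwork
        cfg = tiny_config(steps=0)
        ckpt, hist = tr.train(cfg, tiny_cohort)
        assert hist == []
        with ag.use_dtype(np.float32):
            ref = SegmentationNetwork(dataclasses.replace(cfg.network))
            init = ref.state_dict()
        for k, v in ckpt.state.items():
            np.testing.assert_array_equal(v, init[k])

    def test_seed_determinism(self, tiny_cohort):
        _, h1 = tr.train(tiny_config(steps=3), tiny_cohort)
        _, h2 = tr.train(tiny_config(steps=3), tiny_cohort)
        assert [r["l_total"] for r in h1] == [r["l_total"] for r in h2]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            tr.train(tiny_config(), [])

    def test_divergence_guard(self, tiny_cohort, monkeypatch):
        import comodseg.training as trmod

        def bad_loss(*a, **k):
            class B:
                l_total = float("nan")
            return B()

        monkeypatch.setattr(trmod, "total_loss", bad_loss)
        with pytest.raises(FloatingPointError, match="diverged"):
            tr.train(tiny_config(steps=1), tiny_cohort)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            tiny_config(ablation_mode="bogus")
        with pytest.raises(ValueError):
            tr.TrainConfig(split_fraction=1.5).validate()
        with pytest.raises(ValueError):
            tr.TrainConfig(patch_size=(20, 20, 20)).validate()


class TestCheckpoint:
    def test_roundtrip(self, tiny_cohort, tmp_path):
        ckpt, _ = tr.train(tiny_config(steps=1), tiny_cohort)
        ckpt.save(tmp_path / "ck.npz")
        back = tr.Checkpoint.load(tmp_path / "ck.npz")
        assert back.network_config == ckpt.network_config
        for k in ckpt.state:
            np.testing.assert_array_equal(back.state[k], ckpt.state[k])

    def test_mismatched_state_rejected(self, tiny_cohort):
        from comodseg.network import SegmentationNetwork
        ckpt, _ = tr.train(tiny_config(steps=0), tiny_cohort)
        other = SegmentationNetwork(NetworkConfig(base_filters=4, seed=0))
        with pytest.raises(ValueError, match="mismatch"):
            other.load_state_dict(ckpt.state)


class TestPredict:
    def test_single_tile_equals_forward(self, tiny_cohort):
        ckpt, _ = tr.train(tiny_config(steps=2), tiny_cohort)
        study, labels = tiny_cohort[0]
        masks = tr.predict_study(ckpt, study)
        masks.validate()
        assert masks.wt.shape == study.shape

    def test_tiled_overlap_averaging_consistent(self, tiny_cohort, phantom32):
        # a 32^3 study predicted with 16^3 tiles: constant-free sanity + nesting
        ckpt, _ = tr.train(tiny_config(steps=2), tiny_cohort)
        study, _ = phantom32
        masks = tr.predict_study(ckpt, study, patch_size=(16, 16, 16))
        masks.validate()
        assert masks.wt.shape == study.shape

    def test_average_fusion_is_mean_of_probabilities(self, tiny_cohort):
        from comodseg import autograd as ag
        from comodseg.network import binarize_prediction
        ck1, _ = tr.train(tiny_config(steps=1, ablation_mode="g1_only"), tiny_cohort)
        ck2, _ = tr.train(tiny_config(steps=1, ablation_mode="g2_only"), tiny_cohort)
        study, _ = tiny_cohort[1]
        fused = tr.predict_average(ck1, ck2, study)
        norm = normalize_study(study)
        with ag.use_dtype(np.float32):
            pa = tr.predict_probabilities(ck1.build(), norm)
            pb = tr.predict_probabilities(ck2.build(), norm)
        manual = binarize_prediction(0.5 * (pa.astype(np.float64) + pb.astype(np.float64)))
        np.testing.assert_array_equal(fused.wt, manual.wt)
        np.testing.assert_array_equal(fused.et, manual.et)


class TestAblation:
    def test_modes_config_mapping(self):
        base = NetworkConfig(base_filters=2)
        assert tr._network_for_mode("g1_only", base).pairs == ("g1",)
        assert tr._network_for_mode("g2_only", base).pairs == ("g2",)
        assert not tr._network_for_mode("no_coattention", base).coattention
        assert tr._network_for_mode("saliency_attention", base).attention_mode == "saliency"
        with pytest.raises(ValueError):
            tr._network_for_mode("bogus", base)

    def test_no_coattention_degenerate_equality(self, tiny_cohort):
        # with identical per-pair inputs the per-pair maps coincide, so
        # independent reverse attention equals the co-attention average
        from comodseg.network import SegmentationNetwork
        study, _ = tiny_cohort[0]
        norm = normalize_study(study)
        stack = np.stack([norm.t1, norm.t1c])[None]
        full = SegmentationNetwork(NetworkConfig(base_filters=2, seed=4))
        noca = SegmentationNetwork(NetworkConfig(base_filters=2, seed=4,
                                                 coattention=False))
        same = {"g1": stack, "g2": stack.copy()}
        np.testing.assert_allclose(full(same).prediction.data,
                                   noca(same).prediction.data, atol=1e-10)

    def test_run_ablation_smoke(self, tiny_cohort):
        cfg = tiny_config(steps=2, split_fraction=0.5)
        res = tr.run_ablation(["g1_only", "average_fusion"], cfg, tiny_cohort)
        assert set(res) >= {"g1_only", "average_fusion"}
        for mode in ("g1_only", "average_fusion"):
            assert "average" in res[mode]["summary"]["dice"]
        assert set(res["__checkpoints__"]) == {"g1_only", "g2_only"}
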