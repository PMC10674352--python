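"""Model-zoo contracts: shapes, seeding, parameter counts, scene inference."""

import numpy as np
import pytest

from redtidenet.features import FeatureCube, stack_features
from redtidenet.networks import (
    ModelConfig,
    build_basic_unet,
    build_fcn8s,
    build_improved_unet,
    build_unet_eca,
    predict_scene,
    svm_pixel_baseline,
)
from redtidenet.persist import load_model, save_model
from redtidenet.raster_io import LabelMap

SMALL = ModelConfig(base_width=4)

BUILDERS = {
    "improved_unet": build_improved_unet,
    "unet": build_basic_unet,
    "unet_eca": build_unet_eca,
    "fcn8s": build_fcn8s,
}


@pytest.mark.parametrize("name", list(BUILDERS))
def test_models_map_patches_to_per_pixel_class_probabilities(rng, name):
    model = BUILDERS[name](SMALL, seed=0)
    x = rng.standard_normal((2, 7, 32, 32)).astype(np.float32)
    proba = model.predict_proba(x)
    assert proba.shape == (2, 2, 32, 32)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)
    assert np.all(proba >= 0)


def test_same_seed_and_config_give_identical_parameters():
    a = build_improved_unet(SMALL, seed=3)
    b = build_improved_unet(SMALL, seed=3)
    c = build_improved_unet(SMALL, seed=4)
    assert a.num_parameters() == b.num_parameters()
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
    assert any(
        not np.array_equal(pa.data, pc.data)
        for pa, pc in zip(a.parameters(), c.parameters())
    )


def test_improved_unet_has_more_parameters_than_basic():
    improved = build_improved_unet(SMALL, seed=0)
    basic = build_basic_unet(SMALL, seed=0)
    assert improved.num_parameters() > basic.num_parameters()


def test_ablation_ladder_configs():
    """Ladder: basic (no ECA, all conv) -> +ECA -> +ECA+ASPC."""
    basic = build_basic_unet(SMALL, seed=0)
    eca = build_unet_eca(SMALL, seed=0)
    improved = build_improved_unet(SMALL, seed=0)
    assert basic.config.encoder_block_types == ("conv",) * 4
    assert basic.config.eca_sites == ()
    assert eca.config.encoder_block_types == ("conv",) * 4
    assert eca.config.eca_sites != ()
    assert improved.config.encoder_block_types == ("aspc3", "aspc3", "aspc2", "conv")


def test_depth4_input_must_divide_by_16(rng):
    model = build_basic_unet(SMALL, seed=0)
    assert model.patch_size_multiple == 16  # 32x32 input -> 2x2 bottleneck
    with pytest.raises(ValueError, match="not divisible"):
        model.predict_proba(rng.standard_normal((1, 7, 40, 40)).astype(np.float32))


def test_channel_mismatch_rejected(rng):
    model = build_basic_unet(SMALL, seed=0)
    with pytest.raises(ValueError, match="channel mismatch"):
        model.predict_proba(rng.standard_normal((1, 5, 32, 32)).astype(np.float32))


class TestFCN8s:
    def test_small_input_rejected(self, rng):
        model = build_fcn8s(SMALL, seed=0)
        with pytest.raises(ValueError, match="multiples of 32"):
            model.predict_proba(rng.standard_normal((1, 7, 16, 16)).astype(np.float32))

    def test_fcn16s_toggle_changes_output(self, rng):
        x = rng.standard_normal((1, 7, 32, 32)).astype(np.float32)
        with_skip = build_fcn8s(SMALL, seed=0, use_pool3_skip=True).predict_proba(x)
        without = build_fcn8s(SMALL, seed=0, use_pool3_skip=False).predict_proba(x)
        assert with_skip.shape == without.shape == (1, 2, 32, 32)
        assert not np.allclose(with_skip, without)


class TestSVM:
    def test_linearly_separable_toy_is_learned_perfectly(self, rng):
        x = np.vstack([rng.normal(-2, 0.1, (50, 2)), rng.normal(2, 0.1, (50, 2))])
        y = np.repeat([0, 1], 50)
        clf = svm_pixel_baseline(x, y, seed=0)
        assert (clf.predict_pixels(x) == y).all()

    def test_same_seed_same_support_vectors(self, rng):
        x = rng.standard_normal((500, 3))
        y = (x[:, 0] + 0.3 * rng.standard_normal(500) > 0).astype(int)
        a = svm_pixel_baseline(x, y, max_train_pixels=200, seed=7)
        b = svm_pixel_baseline(x, y, max_train_pixels=200, seed=7)
        assert a.support_vector_count == b.support_vector_count

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            svm_pixel_baseline(rng.standard_normal((10, 2)), np.zeros(10))


class _ConstantModel:
    """Oracle stub predicting a constant class everywhere."""

    def __init__(self, value=0, in_channels=7):
        self.value = value
        self.in_channels = in_channels

    def predict_patches(self, patches, batch_size=32):
        return np.full(patches.shape[0:1] + patches.shape[2:], self.value, np.uint8)


class TestPredictScene:
    def make_inputs(self, small_scene):
        scene, labels = small_scene
        return stack_features(scene), labels

    def test_all_seawater_oracle_yields_zero_red_tide(self, small_scene):
        cube, labels = self.make_inputs(small_scene)
        out = predict_scene(_ConstantModel(0), cube, labels)
        assert (out.labels[out.valid] == 1).sum() == 0

    def test_masked_classes_forced_through(self, small_scene):
        cube, labels = self.make_inputs(small_scene)
        out = predict_scene(_ConstantModel(1), cube, labels)
        invalid = ~labels.valid
        np.testing.assert_array_equal(out.labels[invalid], labels.labels[invalid])
        assert (out.labels[labels.valid] == 1).all()

    def test_stitching_equals_per_patch_prediction(self, small_scene, rng):
        cube, labels = self.make_inputs(small_scene)
        model = build_basic_unet(SMALL, seed=1)
        out = predict_scene(model, cube, labels)
        assert out.labels.shape == labels.labels.shape
        r, c = 32, 0  # check one tile independently
        tile = cube.data[r : r + 32, c : c + 32].transpose(2, 0, 1)[None]
        expected = model.predict_patches(tile)[0]
        v = labels.valid[r : r + 32, c : c + 32]
        np.testing.assert_array_equal(out.labels[r : r + 32, c : c + 32][v], expected[v])

    def test_channel_mismatch_rejected(self, small_scene):
        cube, labels = self.make_inputs(small_scene)
        with pytest.raises(ValueError, match="channel mismatch"):
            predict_scene(_ConstantModel(0, in_channels=5), cube, labels)

    def test_non_tiling_scene_rejected(self, rng):
        cube = FeatureCube(rng.random((40, 64, 7)).astype(np.float32), [f"c{i}" for i in range(7)])
        labels = LabelMap.from_labels(np.zeros((40, 64), np.uint8))
        with pytest.raises(ValueError, match="tile"):
            predict_scene(_ConstantModel(0), cube, labels)


def test_model_save_load_round_trip(tmp_path, rng):
    model = build_improved_unet(SMALL, seed=5)
    x = rng.standard_normal((1, 7, 32, 32)).astype(np.float32)
    before = model.predict_proba(x)
    save_model(model, tmp_path / "m")
    back, stats = load_model(tmp_path / "m")
    assert stats is None
    np.testing.assert_array_equal(back.predict_proba(x), before)
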