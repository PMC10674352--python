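"""Contracts of the synthetic scene generator: determinism, class
contrasts, morphology, and the turbid-water confuser."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from redtidenet.features import compute_ndvi
from redtidenet.raster_io import CLASS_RED_TIDE, CLASS_SEAWATER
from redtidenet.synthetic import (
    SEAWATER_SPECTRUM,
    SyntheticSceneParams,
    generate_benchmark,
    generate_scene,
)


def test_same_seed_is_bit_identical():
    params = SyntheticSceneParams(height=64, width=64, seed=11)
    scene_a, labels_a = generate_scene(params)
    scene_b, labels_b = generate_scene(params)
    np.testing.assert_array_equal(scene_a.reflectance, scene_b.reflectance)
    np.testing.assert_array_equal(labels_a.labels, labels_b.labels)


def test_different_seeds_differ():
    a, _ = generate_scene(SyntheticSceneParams(height=64, width=64, seed=1))
    b, _ = generate_scene(SyntheticSceneParams(height=64, width=64, seed=2))
    assert not np.array_equal(a.reflectance, b.reflectance)


def test_realized_bloom_fraction_close_to_target():
    params = SyntheticSceneParams(height=256, width=256, red_tide_fraction=0.2, seed=3)
    _, labels = generate_scene(params)
    frac = (labels.labels[labels.valid] == CLASS_RED_TIDE).mean()
    assert abs(frac - 0.2) <= 0.03


def test_noiseless_ndvi_contrast_is_exact():
    params = SyntheticSceneParams(height=128, width=128, ndvi_contrast=0.3, noise_sd=0.0, seed=9)
    scene, labels = generate_scene(params)
    ndvi = compute_ndvi(scene.band(865.0), scene.band(660.0))
    diff = ndvi[labels.labels == CLASS_RED_TIDE].mean() - ndvi[labels.labels == CLASS_SEAWATER].mean()
    assert diff == pytest.approx(0.3, abs=1e-6)


def test_generated_scenes_satisfy_scene_invariants(small_scene):
    scene, labels = small_scene
    scene.validate()  # raises on violation
    assert scene.reflectance.min() >= 0
    np.testing.assert_array_equal(labels.valid, np.isin(labels.labels, (0, 1)))
    assert set(np.unique(labels.labels)) <= {0, 1, 2, 3, 4}


def test_concentrated_morphology_has_fewer_larger_components():
    base = SyntheticSceneParams(height=256, width=256, seed=21, noise_sd=0.0)
    counts = {}
    for morph in ("banded_dispersed", "concentrated"):
        _, labels = generate_scene(replace(base, morphology=morph))
        n = ndimage.label(labels.labels == CLASS_RED_TIDE)[1]
        counts[morph] = n
    assert counts["concentrated"] < counts["banded_dispersed"]


def test_turbid_pixels_bright_but_ndvi_neutral():
    """The confuser: broadband brightness up, NDVI within noise of seawater."""
    turbid_vals, clear_vals = [], []
    noise_sd = SyntheticSceneParams().noise_sd
    bright_ratio = []
    for seed in range(5):  # pool scenes: the class means need many pixels
        params = SyntheticSceneParams(height=384, width=384, seed=seed)
        scene, labels = generate_scene(params)
        # a noiseless twin shares all masks: identifies turbid pixels exactly
        clean, _ = generate_scene(replace(params, noise_sd=0.0))
        brightness = clean.reflectance.sum(axis=2)
        sea = labels.labels == CLASS_SEAWATER
        turbid = sea & np.isclose(brightness, 1.8 * SEAWATER_SPECTRUM.sum(), rtol=1e-3)
        clear = sea & ~turbid
        assert turbid.sum() > 1000
        noisy_brightness = scene.reflectance.sum(axis=2)
        bright_ratio.append(noisy_brightness[turbid].mean() / noisy_brightness[clear].mean())
        ndvi = compute_ndvi(scene.band(865.0), scene.band(660.0))
        turbid_vals.append(ndvi[turbid])
        clear_vals.append(ndvi[clear])
    assert min(bright_ratio) > 1.5  # clearly brighter ...
    gap = abs(np.concatenate(turbid_vals).mean() - np.concatenate(clear_vals).mean())
    assert gap < noise_sd  # ... yet spectrally indistinguishable


def test_infeasible_params_rejected():
    with pytest.raises(ValueError):
        SyntheticSceneParams(red_tide_fraction=1.5)
    with pytest.raises(ValueError):
        SyntheticSceneParams(ndvi_contrast=-0.1)
    with pytest.raises(ValueError):
        SyntheticSceneParams(morphology="spiral")
    with pytest.raises(ValueError, match="too large"):
        generate_scene(SyntheticSceneParams(height=32, width=32, ndvi_contrast=1.45))


class TestBenchmark:
    def test_tile_arithmetic(self, tiny_dataset):
        # 2 train + 1 test scenes of 96x96 -> at most 9 tiles each
        assert (tiny_dataset.split == "train").sum() <= 18
        assert (tiny_dataset.split == "test").sum() <= 9
        assert len(tiny_dataset) > 0

    def test_split_is_by_scene(self, tiny_dataset):
        scenes_by_split = {}
        for (scene_id, _, _), split in zip(tiny_dataset.provenance, tiny_dataset.split):
            scenes_by_split.setdefault(scene_id, set()).add(split)
        for splits in scenes_by_split.values():
            assert len(splits) == 1  # no scene contributes to both splits

    def test_same_master_seed_identical(self):
        params = SyntheticSceneParams(height=64, width=64)
        a = generate_benchmark(2, 1, params, seed=42)
        b = generate_benchmark(2, 1, params, seed=42)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.provenance == b.provenance

    def test_manifest_records_conditions(self, tiny_dataset):
        m = tiny_dataset.manifest
        assert m["generator_params"]["red_tide_fraction"] == 0.15
        assert m["n_train_scenes"] == 2 and m["n_test_scenes"] == 1
        assert m["normalization"]["method"] == "minmax"
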