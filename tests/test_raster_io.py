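"""Scene round trips, patch grids, and dataset persistence."""

import numpy as np
import pytest

from redtidenet.features import FeatureCube
from redtidenet.raster_io import (
    GOCI_BAND_CENTERS,
    LabelMap,
    PatchDataset,
    Scene,
    patchify,
    read_scene,
    write_scene,
)


def make_scene(rng, H=64, W=64, B=8):
    reflectance = rng.random((H, W, B)).astype(np.float32) * 0.05
    mask = np.zeros((H, W), dtype=np.uint8)
    mask[:8, :] = 2  # land strip
    mask[8, :] = 3  # coastline
    mask[20:30, 20:30] = 1  # a red-tide patch
    return Scene(reflectance, np.asarray(GOCI_BAND_CENTERS[:B]), mask,
                 crs_info={"proj": "lonlat"})


@pytest.mark.parametrize("format,ext", [("geotiff", "tif"), ("netcdf", "nc")])
def test_round_trip_is_bit_identical(tmp_path, rng, format, ext):
    scene = make_scene(rng)
    path = write_scene(scene, tmp_path / f"s.{ext}", format=format)
    back = read_scene(path, format=format)
    np.testing.assert_array_equal(back.reflectance, scene.reflectance)
    np.testing.assert_array_equal(back.class_mask, scene.class_mask)
    np.testing.assert_array_equal(back.band_centers, scene.band_centers)
    assert back.crs_info == {"proj": "lonlat"}
    assert back.reflectance.shape == (64, 64, 8)


def test_written_band_centers_are_goci_table(tmp_path, rng):
    scene = make_scene(rng)
    back = read_scene(write_scene(scene, tmp_path / "s.tif"))
    assert tuple(back.band_centers) == GOCI_BAND_CENTERS


def test_single_band_file_rejected(tmp_path, rng):
    import tifffile

    tifffile.imwrite(tmp_path / "one.tif", rng.random((2, 16, 16)).astype(np.float32))
    (tmp_path / "one.tif.json").write_text('{"band_centers": [555.0]}')
    with pytest.raises(ValueError, match="at least 2"):
        read_scene(tmp_path / "one.tif")


def test_missing_band_metadata_names_the_field(tmp_path, rng):
    import tifffile

    tifffile.imwrite(tmp_path / "s.tif", rng.random((9, 16, 16)).astype(np.float32))
    with pytest.raises(ValueError, match="band_centers"):
        read_scene(tmp_path / "s.tif")


def test_unknown_class_code_rejected(tmp_path, rng):
    scene = make_scene(rng)
    scene.class_mask[0, 0] = 7
    with pytest.raises(ValueError, match="unknown codes"):
        write_scene(scene, tmp_path / "s.tif")


def test_nonfinite_reflectance_on_valid_pixels_rejected(rng):
    scene = make_scene(rng)
    scene.reflectance[40, 40, 2] = np.nan  # a seawater pixel
    with pytest.raises(ValueError, match="non-finite"):
        scene.validate()


class TestPatchify:
    @staticmethod
    def cube_and_labels(rng, H, W, C=3):
        cube = FeatureCube(rng.random((H, W, C)).astype(np.float32), [f"c{i}" for i in range(C)])
        labels = np.zeros((H, W), dtype=np.uint8)
        return cube, labels

    def test_fully_valid_64x64_gives_four_patches(self, rng):
        cube, labels = self.cube_and_labels(rng, 64, 64)
        ds = patchify(cube, LabelMap.from_labels(labels), seed=0)
        assert len(ds) == 4
        assert sorted((r, c) for _, r, c in ds.provenance) == [(0, 0), (0, 32), (32, 0), (32, 32)]

    def test_all_invalid_tiles_dropped_against_brute_force(self, rng):
        cube, labels = self.cube_and_labels(rng, 96, 96)
        labels[0:32, 0:32] = 2  # one all-land quadrant tile
        lm = LabelMap.from_labels(labels)
        ds = patchify(cube, lm, seed=0)
        # brute-force tile enumeration oracle
        expected = sum(
            lm.valid[r : r + 32, c : c + 32].any()
            for r in range(0, 96, 32)
            for c in range(0, 96, 32)
        )
        assert expected == 8
        assert len(ds) == expected

    def test_partial_edge_tiles_dropped(self, rng):
        cube, labels = self.cube_and_labels(rng, 70, 100)
        ds = patchify(cube, LabelMap.from_labels(labels), seed=0)
        assert len(ds) == (70 // 32) * (100 // 32)

    def test_same_seed_same_order_different_seed_differs(self, rng):
        cube, labels = self.cube_and_labels(rng, 128, 128)
        a = patchify(cube, LabelMap.from_labels(labels), seed=3)
        b = patchify(cube, LabelMap.from_labels(labels), seed=3)
        c = patchify(cube, LabelMap.from_labels(labels), seed=4)
        assert a.provenance == b.provenance
        np.testing.assert_array_equal(a.features, b.features)
        assert a.provenance != c.provenance

    def test_tiles_do_not_overlap_and_origins_unique(self, rng):
        cube, labels = self.cube_and_labels(rng, 96, 64)
        ds = patchify(cube, LabelMap.from_labels(labels), seed=1)
        origins = [(r, c) for _, r, c in ds.provenance]
        assert len(set(origins)) == len(origins)
        for r, c in origins:
            assert r % 32 == 0 and c % 32 == 0

    def test_scene_smaller_than_patch_errors(self, rng):
        cube, labels = self.cube_and_labels(rng, 16, 64)
        with pytest.raises(ValueError, match="smaller than patch size"):
            patchify(cube, LabelMap.from_labels(labels))

    def test_patch_features_match_source_tiles(self, rng):
        cube, labels = self.cube_and_labels(rng, 64, 64)
        ds = patchify(cube, LabelMap.from_labels(labels), seed=0)
        for (_, r, c), feat in zip(ds.provenance, ds.features):
            np.testing.assert_array_equal(feat, cube.data[r : r + 32, c : c + 32])


def test_patch_dataset_save_load_round_trip(tmp_path, tiny_dataset):
    tiny_dataset.save(tmp_path / "ds")
    back = PatchDataset.load(tmp_path / "ds")
    np.testing.assert_array_equal(back.features, tiny_dataset.features)
    np.testing.assert_array_equal(back.labels, tiny_dataset.labels)
    np.testing.assert_array_equal(back.valid, tiny_dataset.valid)
    assert list(back.split) == list(tiny_dataset.split)
    assert back.provenance == tiny_dataset.provenance
    assert back.manifest["n_patches"] == len(tiny_dataset)
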