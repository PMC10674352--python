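"""Scene, label and patch-dataset containers plus file round trips.

Class codes are fixed package-wide: 0 seawater, 1 red tide, 2 land,
3 coastline, 4 unstudied. Only seawater and red tide are *valid* —
classified and scored; the other three are excluded from loss and metrics.

Scenes round-trip through two on-disk forms:

* multiband TIFF — bands 1..B hold reflectance, band B+1 the class mask;
  band centers and any georeferencing metadata live in a JSON sidecar
  (``<path>.json``);
* NetCDF — variables ``rrs(band, y, x)`` and ``class_mask(y, x)`` with a
  ``wavelength(band)`` coordinate (classic NetCDF3 via the scipy backend).

Coordinates are 0-based row-major; patch tiles are half-open intervals
[r, r+P) x [c, c+P) on a grid anchored at (0, 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import tifffile
import xarray as xr

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureCube

__all__ = [
    "CLASS_SEAWATER",
    "CLASS_RED_TIDE",
    "CLASS_LAND",
    "CLASS_COASTLINE",
    "CLASS_UNSTUDIED",
    "CLASS_CODES",
    "VALID_CLASSES",
    "GOCI_BAND_CENTERS",
    "Scene",
    "LabelMap",
    "PatchDataset",
    "read_scene",
    "write_scene",
    "patchify",
]

CLASS_SEAWATER = 0
CLASS_RED_TIDE = 1
CLASS_LAND = 2
CLASS_COASTLINE = 3
CLASS_UNSTUDIED = 4
CLASS_CODES = (0, 1, 2, 3, 4)
VALID_CLASSES = (CLASS_SEAWATER, CLASS_RED_TIDE)

#: GOCI band centers in nm (8 visible/NIR bands, 412-865).
GOCI_BAND_CENTERS = (412.0, 443.0, 490.0, 555.0, 660.0, 680.0, 745.0, 865.0)


def _valid_from_labels(labels: np.ndarray) -> np.ndarray:
    return np.isin(labels, VALID_CLASSES)


@dataclass
class Scene:
    """One multiband reflectance scene with its per-pixel class mask.

    reflectance: (H, W, B) remote-sensing reflectance, unitless, >= 0 on
    valid pixels; band_centers: B wavelengths in nm, strictly increasing;
    class_mask: (H, W) codes from CLASS_CODES; crs_info: opaque
    georeferencing metadata passed through file round trips.
    """

    reflectance: np.ndarray
    band_centers: np.ndarray
    class_mask: np.ndarray
    crs_info: dict | None = None
    scene_id: str = "scene"

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=np.float32)
        self.band_centers = np.asarray(self.band_centers, dtype=np.float64)
        self.class_mask = np.asarray(self.class_mask, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return _valid_from_labels(self.class_mask)

    def band(self, wavelength: float) -> np.ndarray:
        """Reflectance plane of the band centered at `wavelength` nm."""
        idx = np.nonzero(np.isclose(self.band_centers, wavelength))[0]
        if idx.size == 0:
            raise KeyError(f"scene has no band centered at {wavelength} nm")
        return self.reflectance[:, :, int(idx[0])]

    def label_map(self) -> "LabelMap":
        return LabelMap.from_labels(self.class_mask)

    def validate(self) -> None:
        H, W, B = self.reflectance.shape
        if self.band_centers.shape != (B,):
            raise ValueError("band_centers length must equal the band count")
        if B >= 2 and not np.all(np.diff(self.band_centers) > 0):
            raise ValueError("band_centers must be strictly increasing")
        if self.class_mask.shape != (H, W):
            raise ValueError("class_mask shape must match the scene")
        bad = set(np.unique(self.class_mask)) - set(CLASS_CODES)
        if bad:
            raise ValueError(f"class_mask contains unknown codes {sorted(bad)}")
        nonfinite = ~np.isfinite(self.reflectance[self.valid_mask])
        if nonfinite.any():
            raise ValueError(
                f"{int(nonfinite.sum())} non-finite reflectance values on valid pixels"
            )


@dataclass
class LabelMap:
    """(H, W) class labels plus the derived validity mask (codes 0/1)."""

    labels: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.labels.shape != self.valid.shape:
            raise ValueError("labels and valid mask must share a shape")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMap":
        labels = np.asarray(labels, dtype=np.uint8)
        return cls(labels=labels, valid=_valid_from_labels(labels))


@dataclass
class PatchDataset:
    """Aligned (feature, label, valid) patch triples with split tags.

    features: (N, P, P, C); labels: (N, P, P) binary, 1 = red tide;
    valid: (N, P, P) booleans; split: per-patch "train"/"test";
    provenance: (scene_id, row, col) tile origin per patch.
    """

    features: np.ndarray
    labels: np.ndarray
    valid: np.ndarray
    split: np.ndarray
    provenance: list[tuple[str, int, int]]
    channel_names: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.split = np.asarray(self.split, dtype=object)
        n = len(self.features)
        if not (len(self.labels) == len(self.valid) == len(self.split) == len(self.provenance) == n):
            raise ValueError("patch arrays must have equal leading dimension")
        if n and not self.valid.any(axis=(1, 2)).all():
            raise ValueError("every patch must contain at least one valid pixel")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def patch_size(self) -> int:
        return self.features.shape[1]

    @property
    def num_channels(self) -> int:
        return self.features.shape[3]

    def subset(self, split: str) -> "PatchDataset":
        sel = self.split == split
        return PatchDataset(
            self.features[sel], self.labels[sel], self.valid[sel], self.split[sel],
            [p for p, keep in zip(self.provenance, sel) if keep],
            self.channel_names, self.manifest,
        )

    @staticmethod
    def concatenate(parts: Sequence["PatchDataset"]) -> "PatchDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        return PatchDataset(
            np.concatenate([p.features for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.valid for p in parts]),
            np.concatenate([p.split for p in parts]),
            [t for p in parts for t in p.provenance],
            parts[0].channel_names,
            dict(parts[0].manifest),
        )

    def save(self, directory: str | Path) -> Path:
        """Persist as a compressed array archive plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            directory / "patches.npz",
            features=self.features,
            labels=self.labels,
            valid=self.valid,
            split=self.split.astype(str),
        )
        manifest = dict(self.manifest)
        manifest.update(
            {
                "n_patches": len(self),
                "patch_size": int(self.patch_size) if len(self) else 0,
                "channel_names": list(self.channel_names),
                "provenance": [[s, int(r), int(c)] for s, r, c in self.provenance],
                "split_counts": {
                    s: int((self.split == s).sum()) for s in np.unique(self.split.astype(str))
                },
                "red_tide_pixels": int((self.labels[self.valid] == 1).sum()),
                "seawater_pixels": int((self.labels[self.valid] == 0).sum()),
            }
        )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @staticmethod
    def load(directory: str | Path) -> "PatchDataset":
        directory = Path(directory)
        with np.load(directory / "patches.npz", allow_pickle=False) as z:
            features, labels, valid = z["features"], z["labels"], z["valid"]
            split = z["split"].astype(object)
        manifest = json.loads((directory / "manifest.json").read_text())
        provenance = [(s, int(r), int(c)) for s, r, c in manifest.pop("provenance")]
        return PatchDataset(
            features, labels, valid, split, provenance,
            manifest.get("channel_names", []), manifest,
        )


def write_scene(scene: Scene, path: str | Path, format: str = "geotiff") -> Path:
    """Write a scene losslessly; returns the written path."""
    scene.validate()
    path = Path(path)
    H, W, B = scene.shape
    if format == "geotiff":
        stack = np.concatenate(
            [np.moveaxis(scene.reflectance, 2, 0), scene.class_mask[None].astype(np.float32)]
        )
        tifffile.imwrite(path, stack)
        sidecar = {"band_centers": list(map(float, scene.band_centers))}
        if scene.crs_info is not None:
            sidecar["crs_info"] = scene.crs_info
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    elif format == "netcdf":
        ds = xr.Dataset(
            {
                "rrs": (("band", "y", "x"), np.moveaxis(scene.reflectance, 2, 0)),
                "class_mask": (("y", "x"), scene.class_mask.astype(np.int32)),
            },
            coords={"wavelength": ("band", scene.band_centers)},
        )
        if scene.crs_info is not None:
            ds.attrs["crs_info"] = json.dumps(scene.crs_info)
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown scene format {format!r}")
    return path


def read_scene(path: str | Path, format: str = "geotiff") -> Scene:
    """Read a scene written by `write_scene`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "geotiff":
        stack = tifffile.imread(path)
        if stack.ndim != 3 or stack.shape[0] < 3:  # >= 2 reflectance bands + mask
            raise ValueError("scene file must hold at least 2 reflectance bands plus a mask band")
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise ValueError("missing band metadata: no sidecar file with 'band_centers'")
        sidecar = json.loads(sidecar_path.read_text())
        if "band_centers" not in sidecar:
            raise ValueError("missing band metadata: sidecar lacks 'band_centers'")
        reflectance = np.moveaxis(stack[:-1], 0, 2)
        class_mask = stack[-1].astype(np.uint8)
        scene = Scene(reflectance, np.asarray(sidecar["band_centers"]), class_mask,
                      sidecar.get("crs_info"), scene_id=path.stem)
    elif format == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            if "rrs" not in ds or "class_mask" not in ds:
                raise ValueError("missing variable: NetCDF scene needs 'rrs' and 'class_mask'")
            if "wavelength" not in ds.coords:
                raise ValueError("missing band metadata: no 'wavelength' coordinate")
            rrs = ds["rrs"].values
            if rrs.shape[0] < 2:
                raise ValueError("scene file must hold at least 2 reflectance bands")
            crs_info = json.loads(ds.attrs["crs_info"]) if "crs_info" in ds.attrs else None
            scene = Scene(np.moveaxis(rrs, 0, 2), ds["wavelength"].values,
                          ds["class_mask"].values.astype(np.uint8), crs_info,
                          scene_id=path.stem)
    else:
        raise ValueError(f"unknown scene format {format!r}")
    scene.validate()
    return scene


def patchify(
    feature_cube: "FeatureCube | np.ndarray",
    label_map: LabelMap,
    patch_size: int = 32,
    seed: int = 0,
    scene_id: str = "scene",
    split: str = "train",
) -> PatchDataset:
    """Cut a feature cube into non-overlapping patch_size tiles.

    Tiles form a grid anchored at (0, 0); trailing partial tiles are dropped,
    as are tiles without a single valid pixel. The surviving tiles are
    shuffled with `seed`. Red tide (code 1) becomes label 1, everything else
    label 0; non-water pixels are excluded through the valid mask.
    """
    data = feature_cube if isinstance(feature_cube, np.ndarray) else feature_cube.data
    names = [] if isinstance(feature_cube, np.ndarray) else list(feature_cube.channel_names)
    H, W = data.shape[:2]
    if H < patch_size or W < patch_size:
        raise ValueError(f"scene {H}x{W} smaller than patch size {patch_size}")
    if label_map.labels.shape != (H, W):
        raise ValueError("label map shape must match the feature cube")

    feats, labels, valids, origins = [], [], [], []
    for r in range(0, H - patch_size + 1, patch_size):
        for c in range(0, W - patch_size + 1, patch_size):
            v = label_map.valid[r : r + patch_size, c : c + patch_size]
            if not v.any():
                continue
            feats.append(data[r : r + patch_size, c : c + patch_size])
            labels.append(
                (label_map.labels[r : r + patch_size, c : c + patch_size] == CLASS_RED_TIDE)
            )
            valids.append(v)
            origins.append((scene_id, r, c))
    if not feats:
        raise ValueError("no tile contains a valid pixel")
    order = np.random.default_rng(seed).permutation(len(feats))
    return PatchDataset(
        np.stack([feats[i] for i in order]),
        np.stack([labels[i] for i in order]).astype(np.uint8),
        np.stack([valids[i] for i in order]),
        np.array([split] * len(order), dtype=object),
        [origins[i] for i in order],
        channel_names=names,
        manifest={"patchify_seed": int(seed)},
    )
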