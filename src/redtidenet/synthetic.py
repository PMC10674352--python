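"""Seeded generator of GOCI-like 8-band scenes for the test bed.

Each scene emulates the radiometric structure that makes red-tide
detection hard in real ocean-color imagery:

* bloom pixels have elevated red/NIR reflectance, hence a positive NDVI
  contrast against seawater (the `ndvi_contrast` parameter is the exact
  class-mean NDVI difference in the noiseless limit);
* bloom pixels also shift the blue-green bands (443-555 nm) by the relative
  factor `bluegreen_shift` (negative: absorption by the bloom);
* turbid-water confusers are brighter across all bands by a constant
  factor, which leaves NDVI unchanged — bright but spectrally neutral,
  exactly the confusion that breaks brightness-threshold detectors;
* a land strip with a wavy coast, its one-pixel coastline rim, and an
  unstudied margin complete the class mask.

Bloom geometry comes from a Gaussian-filtered white-noise random field
thresholded at the quantile matching the requested bloom fraction:
`banded_dispersed` uses a short, anisotropic correlation length (many
elongated streaks), `concentrated` a long isotropic one (few compact
patches). Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage

from .features import (
    DEFAULT_BAND_SELECTION,
    FeatureCube,
    fit_norm_stats,
    normalize_features,
    stack_features,
)
from .raster_io import (
    CLASS_COASTLINE,
    CLASS_LAND,
    CLASS_RED_TIDE,
    CLASS_SEAWATER,
    CLASS_UNSTUDIED,
    GOCI_BAND_CENTERS,
    LabelMap,
    PatchDataset,
    Scene,
    patchify,
)

__all__ = ["SyntheticSceneParams", "generate_scene", "generate_benchmark", "SEAWATER_SPECTRUM"]

#: Baseline seawater remote-sensing reflectance per GOCI band (plausible
#: clear-water magnitudes; the generator's contracts are on class contrasts,
#: not on absolute values).
SEAWATER_SPECTRUM = np.array(
    [0.020, 0.022, 0.025, 0.023, 0.012, 0.010, 0.006, 0.005], dtype=np.float64
)

_BLUEGREEN = (443.0, 490.0, 555.0)
_TURBID_BRIGHTNESS = 1.8


@dataclass(frozen=True)
class SyntheticSceneParams:
    """Study conditions for one synthetic scene (defaults = benchmark)."""

    height: int = 256
    width: int = 256
    red_tide_fraction: float = 0.15
    morphology: str = "banded_dispersed"
    turbidity_fraction: float = 0.10
    land_fraction: float = 0.08
    ndvi_contrast: float = 0.25
    bluegreen_shift: float = -0.15
    noise_sd: float = 0.005
    boundary_roughness: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("red_tide_fraction", "turbidity_fraction", "land_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.land_fraction > 0.5:
            raise ValueError("land_fraction above 0.5 leaves too little water")
        if self.ndvi_contrast <= 0:
            raise ValueError("ndvi_contrast must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.morphology not in ("banded_dispersed", "concentrated"):
            raise ValueError("morphology must be 'banded_dispersed' or 'concentrated'")
        if self.height < 32 or self.width < 32:
            raise ValueError("scenes smaller than 32 pixels are not usable")


def _bloom_spectrum(contrast: float) -> np.ndarray:
    """Bloom per-band reflectance achieving the exact NDVI contrast.

    The 660/865 nm pair is solved so that bloom NDVI = seawater NDVI +
    contrast at twice the seawater red+NIR total (elevated red/NIR response);
    680 and 745 nm are raised accordingly and the blue-green shift is applied
    separately in `generate_scene`.
    """
    s = SEAWATER_SPECTRUM.copy()
    i660 = GOCI_BAND_CENTERS.index(660.0)
    i865 = GOCI_BAND_CENTERS.index(865.0)
    n0 = (s[i865] - s[i660]) / (s[i865] + s[i660])
    nt = n0 + contrast
    if nt >= 1.0:
        raise ValueError("ndvi_contrast too large for the seawater baseline")
    total = 2.0 * (s[i660] + s[i865])
    bloom = s.copy()
    bloom[i660] = total * (1.0 - nt) / 2.0
    bloom[i865] = total * (1.0 + nt) / 2.0
    bloom[GOCI_BAND_CENTERS.index(680.0)] = s[GOCI_BAND_CENTERS.index(680.0)] * 2.0
    bloom[GOCI_BAND_CENTERS.index(745.0)] = s[GOCI_BAND_CENTERS.index(745.0)] * 2.2
    return bloom


def _correlated_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    field = rng.standard_normal(shape)
    return ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")


def generate_scene(params: SyntheticSceneParams) -> tuple[Scene, LabelMap]:
    """Build one (Scene, LabelMap) pair; bit-identical for equal params."""
    H, W = params.height, params.width
    rng = np.random.default_rng(params.seed)

    # --- class-mask geometry -------------------------------------------------
    mask = np.full((H, W), CLASS_SEAWATER, dtype=np.uint8)
    lw = int(round(params.land_fraction * W))
    if lw > 0:
        wave = ndimage.gaussian_filter1d(rng.standard_normal(H), sigma=12, mode="reflect")
        amp = max(lw // 3, 1)
        wave = np.clip(np.round(wave / max(np.abs(wave).max(), 1e-9) * amp), -amp, amp)
        coast_col = np.clip(lw + wave.astype(int), 1, W - 8)
        cols = np.arange(W)[None, :]
        land = cols < coast_col[:, None]
        mask[land] = CLASS_LAND
        coastline = (cols == coast_col[:, None])
        mask[coastline] = CLASS_COASTLINE
    uw = max(3, W // 32)
    mask[:, W - uw :] = CLASS_UNSTUDIED

    water = mask == CLASS_SEAWATER

    # --- bloom and turbidity fields ------------------------------------------
    if params.boundary_roughness is not None:
        ell = params.boundary_roughness
    else:
        ell = 3.0 if params.morphology == "banded_dispersed" else 18.0
    sigma = (ell, 4.0 * ell) if params.morphology == "banded_dispersed" else (ell, ell)
    bloom_field = _correlated_field(rng, (H, W), sigma)
    turbid_field = _correlated_field(rng, (H, W), 8.0)
    noise = rng.standard_normal((H, W, len(GOCI_BAND_CENTERS))) if params.noise_sd > 0 else None

    bloom = np.zeros((H, W), dtype=bool)
    if params.red_tide_fraction > 0 and water.any():
        thr = np.quantile(bloom_field[water], 1.0 - params.red_tide_fraction)
        bloom = water & (bloom_field >= thr)
        mask[bloom] = CLASS_RED_TIDE
    turbid = np.zeros((H, W), dtype=bool)
    if params.turbidity_fraction > 0 and water.any():
        thr = np.quantile(turbid_field[water], 1.0 - params.turbidity_fraction)
        turbid = water & ~bloom & (turbid_field >= thr)

    # --- spectra --------------------------------------------------------------
    B = len(GOCI_BAND_CENTERS)
    bloom_spec = _bloom_spectrum(params.ndvi_contrast)
    for wl in _BLUEGREEN:
        i = GOCI_BAND_CENTERS.index(wl)
        bloom_spec[i] = SEAWATER_SPECTRUM[i] * (1.0 + params.bluegreen_shift)
    rrs = np.empty((H, W, B), dtype=np.float64)
    rrs[:] = SEAWATER_SPECTRUM
    rrs[turbid] = SEAWATER_SPECTRUM * _TURBID_BRIGHTNESS
    rrs[mask == CLASS_RED_TIDE] = bloom_spec
    rrs[mask == CLASS_LAND] = 0.08
    rrs[mask == CLASS_COASTLINE] = 0.05
    rrs[mask == CLASS_UNSTUDIED] = 0.0
    if noise is not None:
        # Turbid pixels carry proportionally scaled noise so that their NDVI
        # distribution is exactly that of clear seawater (scale invariance of
        # the index, which zero-clipping preserves): bright but spectrally
        # indistinguishable, as a confuser should be.
        sea_or_bloom = np.isin(mask, (CLASS_SEAWATER, CLASS_RED_TIDE))
        scale = np.where(turbid, _TURBID_BRIGHTNESS, 1.0)[:, :, None]
        rrs[sea_or_bloom] += (params.noise_sd * scale * noise)[sea_or_bloom]
        np.clip(rrs, 0.0, None, out=rrs)

    scene = Scene(
        reflectance=rrs.astype(np.float32),
        band_centers=np.asarray(GOCI_BAND_CENTERS),
        class_mask=mask,
        crs_info={"generator": "synthetic", "seed": int(params.seed)},
        scene_id=f"synthetic-{params.seed}",
    )
    scene.validate()
    return scene, LabelMap.from_labels(mask)


def _scene_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_benchmark(
    n_train_scenes: int = 4,
    n_test_scenes: int = 1,
    params: SyntheticSceneParams = SyntheticSceneParams(),
    seed: int = 0,
    band_selection: tuple[float, ...] = DEFAULT_BAND_SELECTION,
    include_ndvi: bool = True,
    normalization: str = "minmax",
) -> PatchDataset:
    """Multi-scene benchmark split by scene (time slot), never by patch.

    Scenes get per-scene seeds derived from the master seed; features are
    stacked (bands + NDVI), normalized with statistics fitted on the
    training scenes only, patchified into 32x32 tiles and concatenated. The
    manifest records every generation parameter.
    """
    if n_train_scenes < 1 or n_test_scenes < 1:
        raise ValueError("need at least one training and one test scene")
    n = n_train_scenes + n_test_scenes
    seeds = _scene_seeds(seed, 2 * n)
    scene_seeds, patch_seeds = seeds[:n], seeds[n:]

    cubes: list[FeatureCube] = []
    label_maps: list[LabelMap] = []
    for i in range(n):
        scene, label_map = generate_scene(replace(params, seed=scene_seeds[i]))
        cubes.append(stack_features(scene, band_selection, include_ndvi))
        label_maps.append(label_map)

    train_cubes = cubes[:n_train_scenes]
    train_masks = [lm.valid for lm in label_maps[:n_train_scenes]]
    stats = fit_norm_stats(train_cubes, method=normalization, valid_masks=train_masks)

    parts = []
    for i in range(n):
        split = "train" if i < n_train_scenes else "test"
        parts.append(
            patchify(
                normalize_features(cubes[i], stats),
                label_maps[i],
                seed=patch_seeds[i],
                scene_id=f"scene{i:02d}",
                split=split,
            )
        )
    dataset = PatchDataset.concatenate(parts)
    dataset.manifest.update(
        {
            "generator_params": asdict(params),
            "master_seed": int(seed),
            "scene_seeds": scene_seeds,
            "n_train_scenes": n_train_scenes,
            "n_test_scenes": n_test_scenes,
            "normalization": stats.to_dict(),
            "band_selection": list(band_selection),
            "include_ndvi": include_ndvi,
        }
    )
    return dataset
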