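"""Synthetic PlanetScope-like scene generation.

Generates 4-band (nir, red, green, blue) reflectance scenes of a fire-prone
forest landscape together with exact ground truth: a per-pixel class map
(vegetation / burnt / water / shadow / non-forest), a binary burnt mask and
a blocky forest mask emulating a coarser-resolution (nominally 10 m)
forest/non-forest product resampled onto the 3 m grid.

The landscape model is deliberately simple but reproduces the failure modes
that matter for burnt-area segmentation of real imagery:

* burnt surfaces are dark with strongly depressed NIR, spectrally close to
  water bodies and cloud shadow — the classic burn/water confusion;
* burns occur both as large contiguous patches (random-walk blob growth)
  and as small disconnected fragments (speckle), controlled by
  ``fragmentation``;
* per-pixel Gaussian class variability plus additive sensor noise, clipped
  to the valid reflectance range [0, 1].

All randomness flows from a single :class:`numpy.random.Generator` seeded
explicitly per call; identical parameters and seed give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import BAND_NAMES, Scene

# per-pixel class codes
NONFOREST, VEGETATION, BURNT, WATER, SHADOW = 0, 1, 2, 3, 4
CLASS_NAMES = {NONFOREST: "nonforest", VEGETATION: "vegetation", BURNT: "burnt",
               WATER: "water", SHADOW: "shadow"}

#: per-class per-band (mean, sd) reflectance. Vegetation is NIR-bright /
#: red-dark; burnt is NIR-dark and dark overall; water is near zero in all
#: four bands (the deliberate burn confuser); shadow is intermediate dark;
#: non-forest stands in for bright bare soil / built surfaces.
DEFAULT_CLASS_SPECTRA: dict[str, dict[str, tuple[float, float]]] = {
    "vegetation": {"nir": (0.45, 0.05), "red": (0.06, 0.015),
                   "green": (0.09, 0.015), "blue": (0.04, 0.010)},
    "burnt":      {"nir": (0.12, 0.025), "red": (0.07, 0.015),
                   "green": (0.06, 0.012), "blue": (0.04, 0.010)},
    "water":      {"nir": (0.02, 0.008), "red": (0.03, 0.008),
                   "green": (0.04, 0.008), "blue": (0.04, 0.008)},
    "shadow":     {"nir": (0.08, 0.015), "red": (0.04, 0.010),
                   "green": (0.04, 0.010), "blue": (0.03, 0.008)},
    "nonforest":  {"nir": (0.30, 0.04), "red": (0.25, 0.04),
                   "green": (0.22, 0.03), "blue": (0.18, 0.03)},
}

_CODE_TO_NAME = CLASS_NAMES


@dataclass
class SceneParams:
    """Parameters of one synthetic scene.

    ``burnt_fraction_target`` is the burnt proportion of *forest* pixels;
    the default 0.157 matches the burnt share of the landscape the package
    is designed around. ``fragmentation`` is the share of the burnt budget
    realized as small disconnected fragments rather than contiguous blobs.
    """

    height: int = 512
    width: int = 512
    burnt_fraction_target: float = 0.157
    n_burnt_patches: int = 5
    n_water_bodies: int = 1
    n_shadow_regions: int = 2
    patch_scale: float = 40.0      # linear blob scale, pixels
    fragmentation: float = 0.15
    class_spectra: dict = field(default_factory=lambda: DEFAULT_CLASS_SPECTRA)
    noise_sd: float = 0.01
    coarse_pixel_size_m: float = 10.0  # forest-mask grid
    pixel_size_m: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("zero-area scene")
        if not 0.0 <= self.burnt_fraction_target <= 1.0:
            raise ValueError("burnt_fraction_target must be in [0, 1]")
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ValueError("fragmentation must be in [0, 1]")
        if min(self.n_burnt_patches, self.n_water_bodies, self.n_shadow_regions) < 0:
            raise ValueError("object counts must be non-negative")
        for cls, bands in self.class_spectra.items():
            for b, (mu, sd) in bands.items():
                if not 0.0 <= mu <= 1.0:
                    raise ValueError(f"class {cls} band {b}: mean {mu} outside [0, 1]")
                if sd < 0:
                    raise ValueError("spectral sd must be non-negative")
        if self.class_spectra["burnt"]["nir"][0] >= self.class_spectra["vegetation"]["nir"][0]:
            raise ValueError("burnt class must have lower NIR mean than vegetation")
        if (self.burnt_fraction_target > 0 and self.n_burnt_patches == 0
                and self.fragmentation == 0.0):
            raise ValueError(
                "burnt_fraction_target > 0 is infeasible with no burnt patches "
                "and zero fragmentation")


@dataclass
class GroundTruth:
    """Exact per-pixel truth for one synthetic scene."""

    burnt: np.ndarray        # uint8 H x W
    class_map: np.ndarray    # uint8 H x W, codes above
    forest_mask: np.ndarray  # uint8 H x W


def _grow_blob(allowed: np.ndarray, occupied: np.ndarray, target_area: int,
               rng: np.random.Generator) -> np.ndarray:
    """Stochastic frontier growth: returns boolean mask of the new blob.

    Starts from a random allowed free pixel and repeatedly annexes a random
    subset of the blob's 4-connected frontier, producing compact patches
    with irregular boundaries. Stops at ``target_area`` (hit exactly when
    the geometry permits) or when the blob can no longer expand.
    """
    from scipy import ndimage

    h, w = allowed.shape
    free = allowed & ~occupied
    idx = np.flatnonzero(free)
    blob = np.zeros((h, w), dtype=bool)
    if idx.size == 0 or target_area <= 0:
        return blob
    start = idx[rng.integers(idx.size)]
    blob[np.unravel_index(start, (h, w))] = True
    size = 1
    struct = ndimage.generate_binary_structure(2, 1)
    while size < target_area:
        frontier = ndimage.binary_dilation(blob, struct) & free & ~blob
        fidx = np.flatnonzero(frontier)
        if fidx.size == 0:
            break
        # annex roughly half the frontier per round, capped by the deficit
        k = min(target_area - size, max(1, fidx.size // 2))
        chosen = rng.choice(fidx, size=k, replace=False)
        blob.flat[chosen] = True
        size += k
    return blob


def _coarse_block_index(n_fine: int, fine_size: float, coarse_size: float) -> np.ndarray:
    """Index of the coarse cell covering each fine pixel (floor mapping)."""
    return np.floor(np.arange(n_fine) * fine_size / coarse_size).astype(np.intp)


def generate_scene(params: SceneParams) -> tuple[Scene, GroundTruth]:
    """Generate one scene plus exact ground truth.

    The burnt budget is ``burnt_fraction_target`` times the forest pixel
    count, split between ``n_burnt_patches`` contiguous random-walk blobs
    and Bernoulli-like speckle fragments according to ``fragmentation``.
    The realized burnt fraction is within about +/-20 % relative of the
    target whenever the geometry permits.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width

    # --- forest base on the coarse grid (blocky non-forest margins) -------
    ri = _coarse_block_index(h, params.pixel_size_m, params.coarse_pixel_size_m)
    ci = _coarse_block_index(w, params.pixel_size_m, params.coarse_pixel_size_m)
    ch, cw = ri[-1] + 1, ci[-1] + 1
    coarse_forest = np.ones((ch, cw), dtype=bool)
    # a couple of non-forest blobs (clearings, settlements) on the coarse grid
    n_clearings = 2 if min(ch, cw) >= 4 else 0
    for _ in range(n_clearings):
        blob = _grow_blob(np.ones((ch, cw), dtype=bool), ~coarse_forest,
                          max(1, int(0.02 * ch * cw)), rng)
        coarse_forest &= ~blob
    forest = coarse_forest[np.ix_(ri, ci)]

    class_map = np.where(forest, VEGETATION, NONFOREST).astype(np.uint8)

    # --- water bodies (non-forest, spectral burn confuser) ----------------
    area_scale = params.patch_scale ** 2
    occupied = ~forest
    for _ in range(params.n_water_bodies):
        target = max(1, int(area_scale * rng.uniform(0.5, 1.5)))
        blob = _grow_blob(np.ones((h, w), dtype=bool), occupied, target, rng)
        class_map[blob] = WATER
        occupied |= blob
    forest = forest & (class_map != WATER)

    # --- shadow regions (inside forest, unburnt, dark) --------------------
    for _ in range(params.n_shadow_regions):
        target = max(1, int(0.5 * area_scale * rng.uniform(0.5, 1.5)))
        blob = _grow_blob(forest & (class_map == VEGETATION), np.zeros_like(forest),
                          target, rng)
        class_map[blob] = SHADOW

    # --- burnt patches + speckle ------------------------------------------
    n_forest = int(forest.sum())
    budget = int(round(params.burnt_fraction_target * n_forest))
    burnable = forest & (class_map == VEGETATION)
    if budget > int(burnable.sum()):
        raise ValueError(
            f"burnt_fraction_target {params.burnt_fraction_target} infeasible: "
            f"budget {budget} exceeds {int(burnable.sum())} burnable pixels")
    speckle_budget = int(round(params.fragmentation * budget))
    blob_budget = budget - speckle_budget
    burnt = np.zeros((h, w), dtype=bool)
    if params.n_burnt_patches > 0 and blob_budget > 0:
        per_patch = rng.dirichlet(np.full(params.n_burnt_patches, 4.0)) * blob_budget
        for target in per_patch:
            blob = _grow_blob(burnable, burnt, max(1, int(round(target))), rng)
            burnt |= blob
    if speckle_budget > 0:
        free = np.flatnonzero(burnable & ~burnt)
        take = min(speckle_budget, free.size)
        if take > 0:
            chosen = rng.choice(free, size=take, replace=False)
            burnt.flat[chosen] = True
    class_map[burnt] = BURNT

    # --- render spectra ----------------------------------------------------
    bands = np.zeros((h, w, 4), dtype=np.float64)
    for code, name in _CODE_TO_NAME.items():
        sel = class_map == code
        if not sel.any():
            continue
        n = int(sel.sum())
        for bi, bname in enumerate(BAND_NAMES):
            mu, sd = params.class_spectra[name][bname]
            bands[sel, bi] = mu + rng.normal(0.0, sd, size=n)
    if params.noise_sd > 0:
        bands += rng.normal(0.0, params.noise_sd, size=bands.shape)
    clipped = (bands < 0.0) | (bands > 1.0)
    clip_fraction = float(clipped.mean())
    bands = np.clip(bands, 0.0, 1.0)

    scene = Scene(bands=bands.astype(np.float32), pixel_size_m=params.pixel_size_m,
                  meta={"clip_fraction": clip_fraction, "seed": params.seed})
    truth = GroundTruth(burnt=burnt.astype(np.uint8), class_map=class_map,
                        forest_mask=forest.astype(np.uint8))
    assert not np.any(truth.burnt & ~truth.forest_mask), "burnt outside forest"
    return scene, truth


def make_forest_mask(scene: Scene, coarse_pixel_size_m: float = 10.0,
                     ndvi_threshold: float = 0.15) -> np.ndarray:
    """Derive a blocky forest mask from a scene at a coarser grid.

    Mimics applying a coarser-resolution forest product: a per-cell NDVI
    ((nir - red) / (nir + red)) is computed on the coarse grid from
    block-averaged reflectance, thresholded, then resampled back to the
    scene grid by nearest neighbour — so the result is constant within
    each coarse cell. Vegetation, burnt and shadow surfaces pass the
    threshold; water and bright bare surfaces do not.
    """
    if coarse_pixel_size_m <= 0 or scene.pixel_size_m <= 0:
        raise ValueError("pixel sizes must be positive")
    if coarse_pixel_size_m < scene.pixel_size_m:
        raise ValueError("coarse pixel size must be >= scene pixel size")
    h, w = scene.shape
    ri = _coarse_block_index(h, scene.pixel_size_m, coarse_pixel_size_m)
    ci = _coarse_block_index(w, scene.pixel_size_m, coarse_pixel_size_m)
    ch, cw = ri[-1] + 1, ci[-1] + 1
    flat_idx = (ri[:, None] * cw + ci[None, :]).ravel()
    counts = np.bincount(flat_idx, minlength=ch * cw).astype(np.float64)
    nir = np.bincount(flat_idx, weights=scene.band("nir").astype(np.float64).ravel(),
                      minlength=ch * cw) / counts
    red = np.bincount(flat_idx, weights=scene.band("red").astype(np.float64).ravel(),
                      minlength=ch * cw) / counts
    ndvi = (nir - red) / np.maximum(nir + red, 1e-9)
    coarse = (ndvi > ndvi_threshold).astype(np.uint8).reshape(ch, cw)
    return coarse[np.ix_(ri, ci)]
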