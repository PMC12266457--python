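"""Scene tiling, band selection, train/test/validation splitting.

Scenes are cut into fixed-size tiles (default 256 x 256) which are the
training currency: image stacks plus one-hot two-channel masks with
channel order (unburnt, burnt). Splitting operates on whole tiles so no
pixel appears in more than one set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import BAND_NAMES, Scene, _check_binary
from .evaluation import pixels_to_hectares

DEFAULT_BANDS = ("nir", "red", "green")


def select_bands(scene: Scene, band_names=DEFAULT_BANDS) -> np.ndarray:
    """Channel-ordered image stack from a scene.

    Default is the NIR-first false-colour triple (nir, red, green), which
    maximizes burn/vegetation contrast; all four bands may be requested.
    """
    band_names = tuple(band_names)
    if len(set(band_names)) != len(band_names):
        raise ValueError(f"duplicate band name in {band_names}")
    unknown = set(band_names) - set(BAND_NAMES)
    if unknown:
        raise ValueError(f"unknown band name(s) {sorted(unknown)}; bands are {BAND_NAMES}")
    idx = [BAND_NAMES.index(b) for b in band_names]
    return scene.bands[:, :, idx]


def one_hot_mask(mask: np.ndarray) -> np.ndarray:
    """Binary burnt mask -> (H, W, 2) one-hot with channels (unburnt, burnt)."""
    mask = _check_binary(mask)
    out = np.zeros(mask.shape + (2,), dtype=np.float32)
    out[..., 0] = mask == 0
    out[..., 1] = mask == 1
    return out


@dataclass
class PatchSet:
    """A batch of image/mask tiles with provenance.

    ``images``: (N, h, w, C) float32; ``masks``: (N, h, w, 2) one-hot;
    ``origins``: (N, 2) tile (row, col) origins in the source scene.
    """

    images: np.ndarray
    masks: np.ndarray
    origins: np.ndarray
    band_names: tuple = DEFAULT_BANDS
    pixel_size_m: float = 3.0
    tile_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.tile_ids is None:
            self.tile_ids = np.arange(len(self.images))
        sums = self.masks.sum(axis=-1)
        if not np.allclose(sums, 1.0):
            raise ValueError("mask channels must sum to exactly 1 per pixel")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "PatchSet":
        idx = np.asarray(idx)
        return PatchSet(self.images[idx], self.masks[idx], self.origins[idx],
                        self.band_names, self.pixel_size_m, self.tile_ids[idx])

    def binary_masks(self) -> np.ndarray:
        """(N, h, w) binary burnt masks (argmax of the one-hot channel)."""
        return self.masks[..., 1].astype(np.uint8)


def tile_origins(h: int, w: int, tile: int, stride: int) -> list[tuple[int, int]]:
    """Row-major tile origins of a regular grid; formula count
    floor((H-tile)/stride + 1) x floor((W-tile)/stride + 1)."""
    if tile < 1 or stride < 1:
        raise ValueError("tile and stride must be >= 1")
    if h < tile or w < tile:
        raise ValueError(f"scene {h}x{w} smaller than tile {tile}")
    rows = range(0, h - tile + 1, stride)
    cols = range(0, w - tile + 1, stride)
    return [(r, c) for r in rows for c in cols]


def tile_scene(scene: Scene, mask: np.ndarray, tile: int = 256, stride: int | None = None,
               band_names=DEFAULT_BANDS) -> PatchSet:
    """Cut a scene and aligned burnt mask into tiles."""
    if stride is None:
        stride = tile
    mask = _check_binary(mask)
    if mask.shape != scene.shape:
        raise ValueError("mask not aligned to scene")
    image = select_bands(scene, band_names)
    origins = tile_origins(*scene.shape, tile, stride)
    images = np.stack([image[r:r + tile, c:c + tile] for r, c in origins])
    masks = np.stack([one_hot_mask(mask[r:r + tile, c:c + tile]) for r, c in origins])
    return PatchSet(images, masks, np.array(origins), tuple(band_names),
                    scene.pixel_size_m)


def stitch_tiles(patches: PatchSet, shape: tuple[int, int]) -> np.ndarray:
    """Reassemble tile images onto a canvas (inverse of stride=tile tiling)."""
    h, w = shape
    t = patches.images.shape[1]
    out = np.zeros((h, w, patches.images.shape[3]), dtype=patches.images.dtype)
    for img, (r, c) in zip(patches.images, patches.origins):
        out[r:r + t, c:c + t] = img
    return out


@dataclass
class SplitSpec:
    """Tile-level train/test/validation fractions (must sum to 1)."""

    train: float = 0.7
    test: float = 0.15
    validation: float = 0.15
    seed: int = 0
    prefer_burnt_train: bool = False

    def __post_init__(self) -> None:
        fr = (self.train, self.test, self.validation)
        if any(not 0.0 < f < 1.0 for f in fr):
            raise ValueError("each split fraction must be in (0, 1)")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fr)}")


def _apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items over fractions."""
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([-(x - np.floor(x)) for x in raw])
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_tiles(patches: PatchSet, spec: SplitSpec) -> tuple[dict, pd.DataFrame]:
    """Split tiles into disjoint, exhaustive train/test/validation sets.

    Deterministic under ``spec.seed``. With ``prefer_burnt_train`` the
    train draw is weighted toward burnt-containing tiles (off by default).
    Returns the three PatchSets keyed ``train``/``test``/``validation``
    plus a per-set pixel-count and hectare report.
    """
    n = len(patches)
    if n < 3:
        raise ValueError("need at least 3 tiles to split three ways")
    sizes = _apportion(n, (spec.train, spec.test, spec.validation))
    if min(sizes) == 0:
        raise ValueError(f"split of {n} tiles leaves an empty set: sizes {sizes}")
    rng = np.random.default_rng(spec.seed)
    if spec.prefer_burnt_train:
        burnt_frac = patches.masks[..., 1].mean(axis=(1, 2))
        weights = 1.0 + 5.0 * (burnt_frac > 0)
        train_idx = rng.choice(n, size=sizes[0], replace=False, p=weights / weights.sum())
        rest = np.setdiff1d(np.arange(n), train_idx)
        rest = rng.permutation(rest)
        order = np.concatenate([train_idx, rest])
    else:
        order = rng.permutation(n)
    splits = {
        "train": patches.subset(np.sort(order[:sizes[0]])),
        "test": patches.subset(np.sort(order[sizes[0]:sizes[0] + sizes[1]])),
        "validation": patches.subset(np.sort(order[sizes[0] + sizes[1]:])),
    }
    report = split_report(splits, patches.pixel_size_m)
    return splits, report


def split_report(splits: dict, pixel_size_m: float) -> pd.DataFrame:
    """Per-set burnt/unburnt pixel counts and hectares."""
    rows = []
    for name in ("train", "test", "validation"):
        ps = splits[name]
        burnt_px = int(ps.masks[..., 1].sum())
        unburnt_px = int(ps.masks[..., 0].sum())
        rows.append({
            "category": name.capitalize(),
            "burnt_pixels": burnt_px,
            "burnt_ha": pixels_to_hectares(burnt_px, pixel_size_m),
            "unburnt_pixels": unburnt_px,
            "unburnt_ha": pixels_to_hectares(unburnt_px, pixel_size_m),
        })
    return pd.DataFrame(rows)
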