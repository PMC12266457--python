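"""Geometric data augmentation applied identically to image and mask.

The operator set mirrors the standard image-generator parameters used for
this task: horizontal/vertical flips, rotation within +/-30 degrees, width
and height shifts within +/-10 % of the tile size, zoom within +/-20 %,
with reflect fill at the borders. One random transform is sampled per call
and applied to the image (bilinear resampling) and to the mask (nearest
neighbour on the class-index map, then re-one-hot), so the mask stays
exactly one-hot. A configuration with all flips off and all ranges zero is
the identity, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class AugmentationConfig:
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_range_deg: float = 30.0
    width_shift_range: float = 0.1
    height_shift_range: float = 0.1
    zoom_range: float = 0.2
    fill_mode: str = "reflect"

    def __post_init__(self) -> None:
        if min(self.rotation_range_deg, self.width_shift_range,
               self.height_shift_range, self.zoom_range) < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.fill_mode != "reflect":
            raise ValueError("only fill_mode='reflect' is supported")

    @property
    def is_identity(self) -> bool:
        return (not self.horizontal_flip and not self.vertical_flip
                and self.rotation_range_deg == 0 and self.width_shift_range == 0
                and self.height_shift_range == 0 and self.zoom_range == 0)


def hflip(image: np.ndarray, mask_onehot: np.ndarray):
    """Deterministic horizontal flip of an image/mask pair (an involution)."""
    return image[:, ::-1].copy(), mask_onehot[:, ::-1].copy()


def vflip(image: np.ndarray, mask_onehot: np.ndarray):
    """Deterministic vertical flip of an image/mask pair (an involution)."""
    return image[::-1, :].copy(), mask_onehot[::-1, :].copy()


def _sample_transform(shape: tuple[int, int], config: AugmentationConfig,
                      rng: np.random.Generator):
    """Draw (flip_h, flip_v, matrix, offset) for scipy inverse mapping."""
    h, w = shape
    flip_h = config.horizontal_flip and bool(rng.integers(2))
    flip_v = config.vertical_flip and bool(rng.integers(2))
    angle = np.deg2rad(rng.uniform(-config.rotation_range_deg, config.rotation_range_deg))
    zoom = rng.uniform(1.0 - config.zoom_range, 1.0 + config.zoom_range)
    shift_r = rng.uniform(-config.height_shift_range, config.height_shift_range) * h
    shift_c = rng.uniform(-config.width_shift_range, config.width_shift_range) * w
    # inverse map: output (r, c) -> input coordinates, about the tile centre
    cos, sin = np.cos(angle), np.sin(angle)
    inv = np.array([[cos, -sin], [sin, cos]]) / zoom
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - inv @ (centre + np.array([shift_r, shift_c]))
    return flip_h, flip_v, inv, offset


def augment(image: np.ndarray, mask_onehot: np.ndarray, config: AugmentationConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled transform to an image tile and its one-hot mask."""
    if config.is_identity:
        return image.copy(), mask_onehot.copy()
    flip_h, flip_v, inv, offset = _sample_transform(image.shape[:2], config, rng)
    img = image
    cls = np.argmax(mask_onehot, axis=-1).astype(np.float64)
    if flip_h:
        img = img[:, ::-1]
        cls = cls[:, ::-1]
    if flip_v:
        img = img[::-1, :]
        cls = cls[::-1, :]
    out_img = np.empty_like(img)
    for ch in range(img.shape[2]):
        out_img[:, :, ch] = ndimage.affine_transform(
            img[:, :, ch].astype(np.float64), inv, offset=offset, order=1,
            mode="reflect").astype(img.dtype)
    out_cls = ndimage.affine_transform(cls, inv, offset=offset, order=0, mode="reflect")
    out_mask = np.zeros_like(mask_onehot)
    out_mask[..., 0] = out_cls < 0.5
    out_mask[..., 1] = out_cls >= 0.5
    return out_img, out_mask
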