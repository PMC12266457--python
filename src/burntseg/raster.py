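"""Raster containers and TIFF I/O.

A :class:`Scene` is a 4-band surface-reflectance raster ordered
``(nir, red, green, blue)`` with values in [0, 1], a square pixel size in
metres (3 m for PlanetScope-class imagery) and an affine georeference.
Masks are single-band uint8 rasters aligned to a scene.

Rasters are stored as plain TIFF (via :mod:`tifffile`); georeferencing
metadata (pixel size, affine transform, band order, nodata) travels as a
JSON document in the ImageDescription tag so that a write/read round trip
preserves both arrays and metadata exactly.

Coordinate convention: 0-based ``(row, col)``, origin at the top-left,
row-major. All module boundaries use this convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

BAND_NAMES = ("nir", "red", "green", "blue")

#: identity georeference: (a, b, c, d, e, f) of x' = a*col + b*row + c,
#: y' = d*col + e*row + f — the standard 6-parameter affine.
IDENTITY_TRANSFORM = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass
class Scene:
    """4-band reflectance raster, bands last, order (nir, red, green, blue)."""

    bands: np.ndarray  # H x W x 4 float
    pixel_size_m: float = 3.0
    transform: tuple = IDENTITY_TRANSFORM
    nodata: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        if self.bands.ndim != 3 or self.bands.shape[2] != len(BAND_NAMES):
            raise ValueError(
                f"Scene.bands must be H x W x {len(BAND_NAMES)}, got {self.bands.shape}"
            )
        if self.bands.shape[0] < 1 or self.bands.shape[1] < 1:
            raise ValueError("zero-area scene")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        valid = self.valid_mask()
        vals = self.bands[valid]
        if vals.size and (not np.all(np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1):
            raise ValueError("reflectance must be finite and within [0, 1] where not nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    def valid_mask(self) -> np.ndarray:
        """Boolean H x W mask of pixels that are not nodata (in any band)."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return ~np.any(self.bands == self.nodata, axis=2)

    def band(self, name: str) -> np.ndarray:
        """Single band by canonical name."""
        try:
            return self.bands[:, :, BAND_NAMES.index(name)]
        except ValueError:
            raise KeyError(f"unknown band {name!r}; bands are {BAND_NAMES}") from None


def _check_binary(mask: np.ndarray, what: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{what} must be binary (0/1)")
    return mask.astype(np.uint8)


def write_scene(path, scene: Scene) -> None:
    meta = {
        "kind": "scene",
        "band_order": list(BAND_NAMES),
        "pixel_size_m": scene.pixel_size_m,
        "transform": list(scene.transform),
        "nodata": scene.nodata,
    }
    tifffile.imwrite(
        path,
        np.moveaxis(scene.bands.astype(np.float32), 2, 0),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def write_mask(path, mask: np.ndarray, pixel_size_m: float = 3.0,
               transform: tuple = IDENTITY_TRANSFORM) -> None:
    meta = {"kind": "mask", "pixel_size_m": pixel_size_m, "transform": list(transform)}
    tifffile.imwrite(path, _check_binary(mask), description=json.dumps(meta),
                     photometric="minisblack")


def _read_meta(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description
    try:
        return json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        return {}


def read_raster(path) -> Scene | np.ndarray:
    """Read a raster written by this package (or any 1/4-band TIFF).

    Returns a :class:`Scene` for 4-band files and a uint8 array for
    single-band masks. Files without georeference metadata get the
    identity transform and a warning in ``meta``.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta = _read_meta(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] not in (1, 4) and arr.shape[-1] in (1, 4):
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] == 4:
        scene_meta = {}
        if "pixel_size_m" not in meta:  # not written by this package
            scene_meta["warning"] = "no georeference metadata; assuming identity transform"
        return Scene(
            bands=np.moveaxis(arr, 0, 2),
            pixel_size_m=float(meta.get("pixel_size_m", 3.0)),
            transform=tuple(meta.get("transform", IDENTITY_TRANSFORM)),
            nodata=meta.get("nodata"),
            meta=scene_meta,
        )
    if arr.shape[0] == 1:
        return arr[0].astype(np.uint8)
    raise ValueError(f"expected a 1- or 4-band raster, got {arr.shape[0]} bands")
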