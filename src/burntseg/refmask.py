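"""Threshold-based reference burnt-area mask generation.

Reproduces, programmatically, the analyst workflow used to label burnt
areas on a single post-fire image: sample band values at chosen burnt /
unburnt locations, record each band's minimum and maximum over the burnt
samples, then mark as burnt every pixel whose four band values all lie
inside those ranges, restricted to the forest mask.

The band test is inclusive on both ends (the ranges are derived from data,
so they must re-select their own pixels) and conjunctive across all four
bands — the conservative reading of "thresholding with these values".
Pixel coordinates are 0-based (row, col).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as _sk_polygon

from .raster import BAND_NAMES, Scene, _check_binary

BURNT_LABEL = "burnt"
UNBURNT_LABEL = "unburnt"


@dataclass
class SampleSet:
    """Analyst sample locations: labelled points and optional polygons.

    ``points`` is a list of ``(row, col, label)``; ``polygons`` a list of
    ``(ring, label)`` where ``ring`` is a sequence of (row, col) vertices.
    """

    points: list = field(default_factory=list)
    polygons: list = field(default_factory=list)

    @classmethod
    def from_geojson(cls, path) -> "SampleSet":
        """Read samples from a GeoJSON FeatureCollection.

        Point coordinates are interpreted as (col, row) pairs (x, y order)
        in pixel space; each feature needs a ``class`` property equal to
        ``burnt`` or ``unburnt``.
        """
        with open(path) as fh:
            doc = json.load(fh)
        ss = cls()
        for feat in doc.get("features", []):
            label = feat.get("properties", {}).get("class")
            geom = feat.get("geometry", {})
            if label not in (BURNT_LABEL, UNBURNT_LABEL):
                raise ValueError(f"feature missing a burnt/unburnt 'class' property: {feat}")
            if geom.get("type") == "Point":
                x, y = geom["coordinates"]
                ss.points.append((int(y), int(x), label))
            elif geom.get("type") == "Polygon":
                ring = [(int(y), int(x)) for x, y in geom["coordinates"][0]]
                ss.polygons.append((ring, label))
            else:
                raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
        return ss


@dataclass
class BandRange:
    """Per-band inclusive (min, max) reflectance, in canonical band order."""

    ranges: dict  # band name -> (lo, hi)

    def __post_init__(self) -> None:
        if set(self.ranges) != set(BAND_NAMES):
            raise ValueError(f"ranges must cover exactly the bands {BAND_NAMES}")
        for b, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"band {b}: min {lo} > max {hi}")


def sample_raster_values(scene: Scene, samples: SampleSet) -> pd.DataFrame:
    """One record per sampled pixel: row, col, label and the 4 band values.

    Polygons are rasterized to the pixels they cover (a degenerate polygon
    covering a single pixel behaves like a point sample).
    """
    h, w = scene.shape
    rows, cols, labels = [], [], []
    for i, (r, c, label) in enumerate(samples.points):
        if not (0 <= r < h and 0 <= c < w):
            raise IndexError(f"point sample #{i} at (row={r}, col={c}) is outside "
                             f"the {h}x{w} raster")
        rows.append(r)
        cols.append(c)
        labels.append(label)
    for i, (ring, label) in enumerate(samples.polygons):
        rr = np.array([p[0] for p in ring], dtype=float)
        cc = np.array([p[1] for p in ring], dtype=float)
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
            raise IndexError(f"polygon sample #{i} has vertices outside the raster")
        pr, pc = _sk_polygon(rr, cc, shape=(h, w))
        if pr.size == 0:  # degenerate ring: fall back to its vertices' pixels
            pr, pc = rr.astype(int), cc.astype(int)
        for r, c in zip(pr, pc):
            rows.append(int(r))
            cols.append(int(c))
            labels.append(label)
    if not rows:
        raise ValueError("sample set is empty")
    vals = scene.bands[np.array(rows), np.array(cols), :]
    out = pd.DataFrame({"row": rows, "col": cols, "label": labels})
    for bi, b in enumerate(BAND_NAMES):
        out[b] = vals[:, bi]
    return out


def extract_band_ranges(sample_table: pd.DataFrame, label: str = BURNT_LABEL) -> BandRange:
    """Per-band min/max over the samples carrying ``label``."""
    sel = sample_table[sample_table["label"] == label]
    if len(sel) == 0:
        raise ValueError(f"no samples labelled {label!r}")
    return BandRange({b: (float(sel[b].min()), float(sel[b].max())) for b in BAND_NAMES})


def threshold_mask(scene: Scene, ranges: BandRange, forest_mask: np.ndarray) -> np.ndarray:
    """Binary burnt mask: all four bands within range AND inside the forest."""
    forest_mask = _check_binary(forest_mask, "forest_mask")
    if forest_mask.shape != scene.shape:
        raise ValueError(f"forest mask shape {forest_mask.shape} != scene {scene.shape}")
    inside = np.ones(scene.shape, dtype=bool)
    for bi, b in enumerate(BAND_NAMES):
        lo, hi = ranges.ranges[b]
        band = scene.bands[:, :, bi]
        inside &= (band >= lo) & (band <= hi)
    return (inside & (forest_mask == 1)).astype(np.uint8)
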