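"""End-to-end pipeline: simulate scenes, derive the threshold reference
mask, tile and split, train both architectures, evaluate, and compare.

Every stage draws from a named substream of the single run seed
(scene_i, samples, split, model builds, training), so re-running an
identical configuration reproduces every artifact. A ``manifest.json``
records the configuration, its hash, the seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import compare_models, tilewise_auc
from .config import RunConfig, config_to_dict
from .evaluation import (area_stats, burnt_fraction, confusion, error_mask,
                         metrics, normalized_confusion, probabilities_to_mask,
                         roc_auc)
from .nn.unet import ModelSpec, build_model
from .raster import write_mask, write_scene
from .refmask import SampleSet, extract_band_ranges, sample_raster_values, threshold_mask
from .synthetic import SceneParams, generate_scene
from .tiling import PatchSet, SplitSpec, split_tiles, tile_scene
from .training import train

_SUBSTREAMS = ("scene", "samples", "split", "model_unet", "model_gru", "train")


def _substream_seed(seed: int, name: str, index: int = 0) -> int:
    """Stable per-stage seed below 2^31 derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{name}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def draw_samples(truth, n_burnt: int, n_unburnt: int, rng: np.random.Generator) -> SampleSet:
    """Programmatic stand-in for analyst point picking: random burnt points
    and random unburnt forest points from the ground truth."""
    burnt_idx = np.flatnonzero(truth.burnt.astype(bool))
    unburnt_idx = np.flatnonzero(truth.forest_mask.astype(bool) & ~truth.burnt.astype(bool))
    if burnt_idx.size == 0:
        raise ValueError("ground truth has no burnt pixels to sample")
    w = truth.burnt.shape[1]
    pts = []
    for idx_pool, n, label in ((burnt_idx, n_burnt, "burnt"),
                               (unburnt_idx, n_unburnt, "unburnt")):
        take = rng.choice(idx_pool, size=min(n, idx_pool.size), replace=False)
        pts.extend((int(i) // w, int(i) % w, label) for i in take)
    return SampleSet(points=pts)


def make_reference_mask(scene, truth, section, rng) -> np.ndarray:
    """Sample -> band ranges -> threshold -> forest constraint."""
    samples = draw_samples(truth, section.n_burnt_samples, section.n_unburnt_samples, rng)
    table = sample_raster_values(scene, samples)
    ranges = extract_band_ranges(table, "burnt")
    return threshold_mask(scene, ranges, truth.forest_mask)


def concat_patchsets(sets: list[PatchSet]) -> PatchSet:
    offset = 0
    ids = []
    for ps in sets:
        ids.append(ps.tile_ids + offset)
        offset += len(ps)
    return PatchSet(
        np.concatenate([ps.images for ps in sets]),
        np.concatenate([ps.masks for ps in sets]),
        np.concatenate([ps.origins for ps in sets]),
        sets[0].band_names, sets[0].pixel_size_m, np.concatenate(ids))


def predict_patchset(model, patches: PatchSet, batch_size: int = 4) -> np.ndarray:
    """Burnt-probability maps (N, h, w) for every tile."""
    out = []
    for i in range(0, len(patches), batch_size):
        probs = model.forward(patches.images[i:i + batch_size], train=False)
        out.append(probs[..., 1])
    return np.concatenate(out)


def evaluate_model(probs: np.ndarray, patches: PatchSet) -> dict:
    """Pooled-pixel evaluation of probability maps against tile masks."""
    ref = patches.binary_masks()
    pred = (probs > 0.5).astype(np.uint8)
    conf = confusion(pred, ref)
    rep = metrics(conf)
    rep.update({f"norm_{k}": v for k, v in normalized_confusion(conf).items()})
    rep["burnt_pct_reference"] = burnt_fraction(conf, "reference")
    rep["burnt_pct_predicted"] = burnt_fraction(conf, "predicted")
    rep["auc_pooled"] = roc_auc(probs.ravel(), ref.ravel())
    rep["confusion"] = conf
    return rep


def run_pipeline(config: RunConfig, write_rasters: bool = True) -> dict:
    """Execute every stage; artifacts land under ``config.out_dir``.

    Returns a dict with the in-memory results (metrics per model, epoch
    logs, comparison result, split report).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate + reference masks --------------------------------------
    sample_rng = np.random.default_rng(_substream_seed(config.seed, "samples"))
    tilesets = []
    for i in range(config.n_scenes):
        params = SceneParams(**{**config.scene.__dict__, "seed":
                                _substream_seed(config.seed, "scene", i)})
        scene, truth = generate_scene(params)
        ref_mask = make_reference_mask(scene, truth, config.reference_mask, sample_rng)
        if write_rasters:
            write_scene(out / f"scene_{i}.tif", scene)
            write_mask(out / f"reference_mask_{i}.tif", ref_mask,
                       scene.pixel_size_m, scene.transform)
            write_mask(out / f"truth_mask_{i}.tif", truth.burnt,
                       scene.pixel_size_m, scene.transform)
        tilesets.append(tile_scene(scene, ref_mask, tile=config.tile,
                                   band_names=config.bands))
    patches = concat_patchsets(tilesets)

    # --- split ------------------------------------------------------------
    split_spec = SplitSpec(**{**config.split.__dict__,
                              "seed": _substream_seed(config.seed, "split")})
    splits, split_report = split_tiles(patches, split_spec)
    split_report.to_csv(out / "split_report.csv", index=False)

    # --- train both architectures -----------------------------------------
    results = {"split_report": split_report, "models": {}}
    logs = {}
    archs = {"unet": "custom_unet", "unet_gru": "unet_gru"}
    for name, arch in archs.items():
        spec = ModelSpec(
            architecture=arch, input_hw=(config.tile, config.tile),
            in_channels=len(config.bands), base_filters=config.model.base_filters,
            depth=config.model.depth, gru_units=config.model.gru_units,
            dropout=config.model.dropout, kernel=config.model.kernel,
            seed=_substream_seed(config.seed, f"model_{name}"))
        model = build_model(spec)
        tcfg_kwargs = dict(config.training.__dict__)
        tcfg_kwargs["seed"] = _substream_seed(config.seed, "train", hash(name) % 1000)
        from .training import TrainingConfig
        _, log = train(model, splits["train"], splits["validation"],
                       TrainingConfig(**tcfg_kwargs), config.augmentation)
        model.save_weights(out / f"weights_{name}.npz")
        logs[name] = log
        log.to_csv(out / f"epoch_log_{name}.csv", index=False)

        probs = predict_patchset(model, splits["test"])
        rep = evaluate_model(probs, splits["test"])
        results["models"][name] = {"report": rep, "log": log, "model": model,
                                   "test_probs": probs}

    # --- evaluation tables (S3/S5-shaped) ----------------------------------
    mrows, crows = [], []
    for name in archs:
        rep = results["models"][name]["report"]
        conf = rep["confusion"]
        mrows.append({"model": name, **{k: rep[k] for k in
                                        ("precision", "recall", "f1", "accuracy",
                                         "iou_burnt", "iou_macro", "dice", "auc_pooled")}})
        crows.append({"model": name, "tn": conf.tn, "fp": conf.fp,
                      "fn": conf.fn, "tp": conf.tp})
    pd.DataFrame(mrows).to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(crows).to_csv(out / "confusion.csv", index=False)

    # error mask for the first test tile of each model
    if write_rasters and len(splits["test"]):
        ref0 = splits["test"].binary_masks()[0]
        for name in archs:
            p0 = (results["models"][name]["test_probs"][0] > 0.5).astype(np.uint8)
            em = error_mask(p0, ref0)
            import tifffile
            tifffile.imwrite(out / f"error_mask_{name}_tile0.tif", em)

    # --- tile-wise AUC comparison ------------------------------------------
    masks = splits["test"].binary_masks()
    # retention depends only on the reference masks, so both models keep
    # exactly the same tiles
    auc_a, kept = tilewise_auc(results["models"]["unet"]["test_probs"], masks)
    auc_b, _ = tilewise_auc(results["models"]["unet_gru"]["test_probs"], masks)
    table = pd.DataFrame({
        "tile_id": splits["test"].tile_ids[kept],
        "auc_unet": auc_a,
        "auc_unet_gru": auc_b,
    })
    table.to_csv(out / "tile_auc.csv", index=False)
    comparison = compare_models(table, "auc_unet", "auc_unet_gru")
    with open(out / "comparison.json", "w") as fh:
        json.dump(comparison.as_dict(), fh, indent=1)
    results["comparison"] = comparison
    results["tile_auc"] = table

    # --- manifest -----------------------------------------------------------
    cfg_dict = config_to_dict(config)
    # hash the study conditions only, not where the artifacts land
    hashed = {k: v for k, v in cfg_dict.items() if k != "out_dir"}
    cfg_json = json.dumps(hashed, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"burntseg": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
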