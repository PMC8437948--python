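"""End-to-end pipeline orchestration and manifest validation.

``run_pipeline`` chains simulate -> segment -> patchify -> augment ->
extract -> select -> train-eval under one YAML-style config and a single
global seed.  Each stage writes into its own subdirectory of the run root
with a manifest-in/manifest-out contract; a stage whose output manifest
already exists is skipped, which makes runs resumable per stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment as _augment
from . import classify as _classify
from . import features as _features
from . import patches as _patches
from . import segmentation as _segmentation
from . import selection as _selection
from . import similarity as _similarity
from . import synthetic as _synthetic
from .colorspace import read_image, read_mask
from .severity import SEVERITY_GROUPS

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "validate_manifest"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "run",
    "simulate": {"n_per_group": 4, "image_size": [256, 256]},
    "segment": {"method": "slic", "n_superpixels": 700, "compactness": 10.0,
                "n_centers": 3, "kmeans_iters": 500, "rule": "max_a",
                "min_area": 25},
    "patchify": {"k": 3},
    "augment": {"mode": "B", "include_patches": False,
                "min_lesion_fraction": 0.01},
    "extract": {"groups": ["texture", "color"]},
    "select": {"enabled": True, "fraction": 2 / 3},
    "train_eval": {"classifiers": ["rf", "knn"], "k_folds": 5, "repeats": 10},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise ValueError(f"unknown config key {path + k!r}")
        if isinstance(base[k], dict):
            out[k] = _merge(base[k], v or {}, path=f"{path}{k}.")
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config merged over the defaults; unknown keys rejected."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def validate_manifest(path: str | Path) -> list[str]:
    """Check manifest rows for missing files, bad labels, shape mismatches."""
    path = Path(path)
    violations: list[str] = []
    df = pd.read_csv(path)
    root = path.parent
    for i, row in df.iterrows():
        f = root / row["filename"]
        if not f.exists():
            violations.append(f"row {i}: missing file {row['filename']}")
            continue
        label = row.get("group", row.get("label"))
        if label not in SEVERITY_GROUPS:
            violations.append(f"row {i}: invalid label {label!r}")
        mask_file = root / f"{f.stem}_lesion.png"
        if mask_file.exists():
            img = read_image(f)
            mask = read_mask(mask_file)
            if mask.shape != img.shape[:2]:
                violations.append(f"row {i}: mask/image shape mismatch")
    return violations


def run_pipeline(config: dict) -> dict:
    """Run every stage; returns the machine-readable run summary."""
    cfg = _merge(DEFAULT_CONFIG, config)
    root = Path(cfg["out_dir"])
    root.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"stages": {}}

    # --- simulate ---------------------------------------------------------
    sim_dir = root / "scenes"
    if not (sim_dir / "manifest.csv").exists():
        _synthetic.generate_dataset(
            cfg["simulate"]["n_per_group"], sim_dir, seed=seed,
            image_size=tuple(cfg["simulate"]["image_size"]))
    manifest = pd.read_csv(sim_dir / "manifest.csv")
    summary["stages"]["simulate"] = {"n_scenes": len(manifest)}

    # --- segment ----------------------------------------------------------
    seg_dir = root / "segmentation"
    seg_done = seg_dir / "similarity.csv"
    if not seg_done.exists():
        seg_dir.mkdir(exist_ok=True)
        sp = cfg["segment"]
        params = _segmentation.SLICParams(
            n_superpixels=sp["n_superpixels"], compactness=sp["compactness"],
            n_centers=sp["n_centers"], kmeans_iters=sp["kmeans_iters"],
            rule=sp["rule"], min_area=sp["min_area"], seed=seed)
        rows = []
        for _, row in manifest.iterrows():
            stem = Path(row["filename"]).stem
            img = read_image(sim_dir / row["filename"])
            gt = read_mask(sim_dir / f"{stem}_lesion.png")
            res = _segmentation.segment_slic(img, params)
            from .colorspace import write_mask
            write_mask(seg_dir / f"{stem}_pred.png", res.mask)
            rec = {"filename": row["filename"]}
            if gt.any() and res.mask.any():
                rep = _similarity.evaluate(res.mask, gt)
                rec.update(dice=rep.dice, gce=rep.gce, voi=rep.voi,
                           hd=rep.hd, ri=rep.ri)
            rows.append(rec)
        pd.DataFrame(rows).to_csv(seg_done, index=False)
    seg_df = pd.read_csv(seg_done)
    if "dice" in seg_df:
        summary["stages"]["segment"] = {
            "mean_dice": float(np.nanmean(seg_df["dice"]))}

    # --- patchify ---------------------------------------------------------
    patch_dir = root / "patches"
    if not (patch_dir / "patches.csv").exists():
        scenes = []
        for _, row in manifest.iterrows():
            stem = Path(row["filename"]).stem
            img = read_image(sim_dir / row["filename"])
            mask = read_mask(sim_dir / f"{stem}_lesion.png")
            scenes.append((stem, img, mask, row["erythema"], row["scale"],
                           row["group"]))
        _patches.patch_manifest(scenes, patch_dir, k=cfg["patchify"]["k"],
                                seed=seed)
    patch_df = pd.read_csv(patch_dir / "patches.csv")
    summary["stages"]["patchify"] = {"n_patches": len(patch_df)}

    # --- augment ----------------------------------------------------------
    ds_dir = root / "dataset"
    if not (ds_dir / "dataset.csv").exists():
        spec = _augment.DatasetSpec(
            mode=cfg["augment"]["mode"],
            include_patches=cfg["augment"]["include_patches"],
            min_lesion_fraction=cfg["augment"]["min_lesion_fraction"],
            seed=seed)
        _augment.assemble_dataset(manifest, spec, sim_dir, ds_dir,
                                  patches_manifest=patch_df,
                                  patches_dir=patch_dir,
                                  mask_suffix="_lesion")
    ds_df = pd.read_csv(ds_dir / "dataset.csv")
    summary["stages"]["augment"] = {"n_rows": len(ds_df)}

    # --- extract ----------------------------------------------------------
    feat_file = root / "features.csv"
    if not feat_file.exists():
        groups = tuple(cfg["extract"]["groups"])
        feats = _features.extract_matrix(ds_df, ds_dir, groups)
        feats.to_csv(feat_file, index=False)
    feats = pd.read_csv(feat_file)
    summary["stages"]["extract"] = {"n_rows": len(feats),
                                    "n_features": feats.shape[1] - 3}

    # --- select -----------------------------------------------------------
    feat_cols = [c for c in feats.columns
                 if c not in ("filename", "label", "is_patch")]
    X = feats[feat_cols]
    y = feats["label"].to_numpy()
    if cfg["select"]["enabled"]:
        sel = _selection.select_features(X, y,
                                         fraction=cfg["select"]["fraction"])
        X = X[sel.selected]
        (root / "selected_features.txt").write_text("\n".join(sel.selected))
        summary["stages"]["select"] = {"n_selected": len(sel.selected)}

    # --- train-eval -------------------------------------------------------
    cvcfg = _classify.CVConfig(k_folds=cfg["train_eval"]["k_folds"],
                               repeats=cfg["train_eval"]["repeats"], seed=seed)
    results = {}
    for kind in cfg["train_eval"]["classifiers"]:
        rep = _classify.cross_validate(
            _classify.ClassifierSpec(kind=kind, seed=seed), X, y, cvcfg)
        rep.summary.to_csv(root / f"eval_{kind}.csv")
        results[kind] = {m: float(rep.summary.loc[m, "mean"])
                         for m in rep.summary.index}
    summary["stages"]["train_eval"] = results

    with open(root / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
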