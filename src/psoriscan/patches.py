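"""Erythema/scale patch decomposition of a segmented lesion.

Within the lesion mask the pixels are clustered in CIE-Lab by seeded
k-means (k=3 by default) and the clusters are mapped to symptoms by their
color statistics: the cluster with the highest mean a* is erythema (redness),
the highest mean L* among the rest is scale (white flaking), any remainder
is transitional.  Each symptom yields a "patch image" — the original RGB
with every non-component pixel zeroed — mirroring how masked symptom patches
are used to build a classification dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .colorspace import rgb_to_lab, write_image

logger = logging.getLogger(__name__)

__all__ = ["PatchSet", "decompose", "patch_manifest"]


@dataclass
class PatchSet:
    erythema_image: np.ndarray
    scale_image: np.ndarray
    erythema_mask: np.ndarray
    scale_mask: np.ndarray
    cluster_map: np.ndarray  # -1 outside the lesion, 0..k-1 inside


def decompose(img: np.ndarray, lesion: np.ndarray, k: int = 3,
              seed: int = 0) -> PatchSet:
    """Cluster lesion pixels in Lab and split them into symptom components."""
    lesion = np.asarray(lesion, dtype=bool)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    n_px = int(lesion.sum())
    if n_px < k:
        raise ValueError(f"lesion has {n_px} pixels; need at least k={k}")
    lab = rgb_to_lab(img)
    pts = lab[lesion]
    if np.allclose(pts, pts[0]):
        raise ValueError("all lesion pixels identical; clustering degenerate "
                         "— lower k or check the mask")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                random_state=seed)
    labels = km.fit_predict(pts)

    cluster_map = np.full(lesion.shape, -1, dtype=np.int32)
    cluster_map[lesion] = labels

    mean_a = np.array([pts[labels == i, 1].mean() if (labels == i).any() else -np.inf
                       for i in range(k)])
    mean_l = np.array([pts[labels == i, 0].mean() if (labels == i).any() else -np.inf
                       for i in range(k)])
    ery_id = int(np.argmax(mean_a))
    mean_l[ery_id] = -np.inf
    scale_id = int(np.argmax(mean_l))

    ery_mask = cluster_map == ery_id
    scale_mask = cluster_map == scale_id

    def _patch(mask: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(img))
        out[mask] = np.asarray(img)[mask]
        return out

    return PatchSet(
        erythema_image=_patch(ery_mask),
        scale_image=_patch(scale_mask),
        erythema_mask=ery_mask,
        scale_mask=scale_mask,
        cluster_map=cluster_map,
    )


def patch_manifest(scenes, out_dir: str | Path, k: int = 3,
                   seed: int = 0) -> pd.DataFrame:
    """Decompose scenes and write symptom patch PNGs plus manifest rows.

    ``scenes`` is an iterable of (stem, image, lesion_mask, erythema_score,
    scale_score, group).  Healthy scenes (empty mask) contribute nothing;
    a failed decomposition skips the scene with a logged warning.  Patch
    rows carry the parent image's severity scores and ``is_patch=1``; no
    augmentation is ever applied to them downstream.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for stem, img, mask, e_score, s_score, group in scenes:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        try:
            ps = decompose(img, mask, k=k, seed=seed)
        except ValueError as exc:
            logger.warning("patch decomposition failed for %s: %s", stem, exc)
            continue
        for kind, patch in (("erythema", ps.erythema_image),
                            ("scale", ps.scale_image)):
            fname = f"{stem}_{kind}.png"
            write_image(out / fname, patch)
            rows.append({"filename": fname, "erythema": e_score,
                         "scale": s_score, "group": group, "is_patch": 1})
    df = pd.DataFrame(rows, columns=["filename", "erythema", "scale", "group",
                                     "is_patch"])
    df.to_csv(out / "patches.csv", index=False)
    return df
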