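"""Dataset assembly by cropping and geometric augmentation.

Two dataset modes mirror the two augmentation regimes used for severity
classification: dataset A holds grid crops of each scene only; dataset B
adds eleven geometric variants per kept crop (rotations by 90/180/270,
horizontal flips of the identity and of each rotation, and four scalings:
uniform expansion, uniform reduction, horizontal stretch, vertical stretch).
Crops whose lesion content is too small are discarded, except for crops of
healthy scenes.  Symptom patch images may be appended to either mode but are
never transformed.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .colorspace import read_image, read_mask, write_image, write_mask

__all__ = ["DatasetSpec", "crop_image", "affine_set", "filter_lesion_content",
           "assemble_dataset"]


@dataclass
class DatasetSpec:
    mode: str = "A"
    include_patches: bool = False
    min_lesion_fraction: float = 0.01
    crop_aspect_threshold: float = 1.4
    scaling_factors: tuple[float, float, float, float] = (1.25, 0.8, 1.25, 1.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("A", "B"):
            raise ValueError("mode must be 'A' or 'B'")
        if any(f <= 0 for f in self.scaling_factors):
            raise ValueError("scaling factors must be positive")


def crop_image(img: np.ndarray, mask: np.ndarray,
               aspect_threshold: float = 1.4) -> list[tuple[np.ndarray, np.ndarray]]:
    """Tile the image into 6 (elongated) or 4 (near-square) exact parts.

    If max(H,W)/min(H,W) >= ``aspect_threshold`` the long axis is split in 3
    and the short axis in 2 (six parts); otherwise a 2x2 grid.  Integer
    remainders go to the last row/column, so the parts tile exactly.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    h, w = img.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("image too small to crop")
    if max(h, w) / min(h, w) >= aspect_threshold:
        ny, nx = (3, 2) if h >= w else (2, 3)
    else:
        ny, nx = 2, 2

    def _edges(size: int, n: int) -> list[int]:
        return [i * (size // n) for i in range(n)] + [size]

    ye, xe = _edges(h, ny), _edges(w, nx)
    out = []
    for i in range(ny):
        for j in range(nx):
            sl = (slice(ye[i], ye[i + 1]), slice(xe[j], xe[j + 1]))
            out.append((img[sl], mask[sl]))
    return out


def _rescale(img: np.ndarray, mask: np.ndarray, fy: float, fx: float):
    h, w = img.shape[:2]
    shape = (max(int(round(h * fy)), 1), max(int(round(w * fx)), 1))
    im = resize(img, shape + img.shape[2:], order=1, preserve_range=True,
                anti_aliasing=False).astype(img.dtype)
    mk = resize(mask.astype(float), shape, order=0, preserve_range=True,
                anti_aliasing=False) > 0.5
    return im, mk


def affine_set(img: np.ndarray, mask: np.ndarray,
               factors: tuple[float, float, float, float] = (1.25, 0.8, 1.25, 1.25),
               ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """The eleven geometric variants of one crop (identity excluded).

    3 rotations + 4 horizontal flips (of identity and each rotation) +
    4 scalings (uniform x``factors[0]``, uniform x``factors[1]``,
    x-stretch x``factors[2]``, y-stretch x``factors[3]``).  Masks use
    nearest-neighbor interpolation, images bilinear.
    """
    if any(f <= 0 for f in factors):
        raise ValueError("scaling factors must be positive")
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    out = []
    rots = {"rot90": 1, "rot180": 2, "rot270": 3}
    for tag, kk in rots.items():
        out.append((tag, np.rot90(img, kk), np.rot90(mask, kk)))
    out.append(("flip", np.fliplr(img), np.fliplr(mask)))
    for tag, kk in rots.items():
        out.append((f"flip_{tag}", np.fliplr(np.rot90(img, kk)),
                    np.fliplr(np.rot90(mask, kk))))
    expand, reduce_, sx, sy = factors
    for tag, (fy, fx) in (("scale_up", (expand, expand)),
                          ("scale_down", (reduce_, reduce_)),
                          ("stretch_x", (1.0, sx)),
                          ("stretch_y", (sy, 1.0))):
        im, mk = _rescale(img, mask, fy, fx)
        out.append((tag, im, mk))
    return out


def filter_lesion_content(pairs, min_fraction: float = 0.01):
    """Keep (crop, mask, label) triples with enough lesion; healthy exempt.

    ``pairs`` is an iterable of dicts with keys ``mask`` and ``label``;
    returns the kept subset in order.
    """
    kept = []
    for rec in pairs:
        mask = np.asarray(rec["mask"], dtype=bool)
        if rec["label"] == "healthy" or mask.mean() >= min_fraction:
            kept.append(rec)
    return kept


def assemble_dataset(manifest: pd.DataFrame, spec: DatasetSpec,
                     images_dir: str | Path, out_dir: str | Path,
                     patches_manifest: pd.DataFrame | None = None,
                     patches_dir: str | Path | None = None,
                     mask_suffix: str = "_lesion") -> pd.DataFrame:
    """Build a classification dataset directory plus its manifest.

    Scene images and masks are read from ``images_dir`` (mask files named
    ``<stem><mask_suffix>.png``); crops, variants and their masks are written
    to ``out_dir``.  The returned manifest has columns
    ``filename,label,source,transform,is_patch``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images_dir = Path(images_dir)
    rows = []
    for _, mrow in manifest.iterrows():
        stem = Path(mrow["filename"]).stem
        img = read_image(images_dir / mrow["filename"])
        mask = read_mask(images_dir / f"{stem}{mask_suffix}.png")
        label = mrow["group"]
        crops = crop_image(img, mask, spec.crop_aspect_threshold)
        recs = [{"img": ci, "mask": cm, "label": label,
                 "tag": "orig", "crop": i}
                for i, (ci, cm) in enumerate(crops)]
        kept = filter_lesion_content(recs, spec.min_lesion_fraction)
        if spec.mode == "B":
            variants = []
            for rec in kept:
                for tag, vi, vm in affine_set(rec["img"], rec["mask"],
                                              spec.scaling_factors):
                    variants.append({"img": vi, "mask": vm, "label": label,
                                     "tag": tag, "crop": rec["crop"]})
            kept = kept + filter_lesion_content(variants,
                                                spec.min_lesion_fraction)
        for rec in kept:
            fname = f"{stem}_c{rec['crop']}_{rec['tag']}.png"
            write_image(out / fname, rec["img"])
            write_mask(out / f"{Path(fname).stem}_mask.png", rec["mask"])
            rows.append({"filename": fname, "label": rec["label"],
                         "source": mrow["filename"], "transform": rec["tag"],
                         "is_patch": 0})
    if spec.include_patches:
        if patches_manifest is None or patches_dir is None:
            raise ValueError("include_patches requires patches_manifest and "
                             "patches_dir")
        for _, prow in patches_manifest.iterrows():
            shutil.copy(Path(patches_dir) / prow["filename"],
                        out / prow["filename"])
            rows.append({"filename": prow["filename"], "label": prow["group"],
                         "source": prow["filename"], "transform": "",
                         "is_patch": 1})
    df = pd.DataFrame(rows, columns=["filename", "label", "source",
                                     "transform", "is_patch"])
    df.to_csv(out / "dataset.csv", index=False)
    return df
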