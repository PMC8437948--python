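"""Synthetic psoriasis-like scene generator with ground truth.

Clinical photographs of localized plaques are not publicly available, so the
pipeline is exercised on generated scenes that emulate their salient
structure: a skin-tone background with a smooth shading gradient and dark
hair-like strokes, one to four irregular plaque blobs whose interior redness
(CIE-Lab a* shift) scales with an erythema grade of 0-4, and white
low-chroma speckle ("scale") whose coverage of the plaque scales with a
scaling grade of 0-4.  Every scene carries exact lesion / erythema / scale
masks and the 5-level severity group derived from the grade sum, so
segmentation, patch decomposition and classification can all be scored
against known truth.

Plaque boundaries are produced by thresholding a smoothed random field, and
the redness ramps down over an edge band whose width grows as the erythema
grade decreases — mimicking the boundary ambiguity of mild disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import color as _skcolor
from skimage import measure

from .colorspace import write_image, write_mask
from .severity import severity_group

__all__ = ["LesionSceneParams", "LesionScene", "generate_scene", "generate_dataset"]


@dataclass
class LesionSceneParams:
    """Parameters of one synthetic lesion scene.

    ``erythema_a_gain`` is the a* shift per erythema grade unit;
    ``scale_coverage_gain`` the fraction of plaque area covered by scale per
    scaling grade unit; ``shadow_amplitude`` the peak-to-peak L* amplitude of
    the global shading ramp.
    """

    image_size: tuple[int, int] = (512, 512)
    skin_base_lab: tuple[float, float, float] = (70.0, 12.0, 18.0)
    n_lesions: int | None = None
    erythema_score: int = 0
    scale_score: int = 0
    erythema_a_gain: float = 8.0
    scale_coverage_gain: float = 0.12
    shadow_amplitude: float = 6.0
    n_hairs: int = 12
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("erythema_score", "scale_score"):
            v = getattr(self, name)
            if not (0 <= int(v) <= 4):
                raise ValueError(f"{name} must be in 0..4, got {v}")
        healthy = self.erythema_score == 0 and self.scale_score == 0
        if self.n_lesions is None:
            self.n_lesions = 0 if healthy else 2
        if healthy and self.n_lesions != 0:
            raise ValueError("healthy scenes (both scores 0) must have n_lesions=0")
        if not healthy and self.n_lesions == 0:
            raise ValueError("non-zero scores require at least one lesion")
        if not (0 <= self.n_lesions <= 4):
            raise ValueError("n_lesions must be in 0..4")


@dataclass
class LesionScene:
    """A scene image plus its ground-truth masks and severity grading."""

    image: np.ndarray
    lesion_mask: np.ndarray
    erythema_mask: np.ndarray
    scale_mask: np.ndarray
    erythema_score: int
    scale_score: int
    severity_group: str = field(init=False)

    def __post_init__(self) -> None:
        self.severity_group = severity_group(self.erythema_score, self.scale_score).group


def _blob(shape: tuple[int, int], center: np.ndarray, radius: float,
          rng: np.random.Generator) -> np.ndarray:
    """One irregular plaque blob: radial bump distorted by smoothed noise."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - center[0], xx - center[1]) / radius
    noise = ndi.gaussian_filter(rng.standard_normal(shape), sigma=max(radius / 3.0, 2.0))
    noise /= noise.std() + 1e-12
    mask = (dist + 0.35 * noise) < 1.0
    # thresholding can leave satellites: keep the component nearest the center
    lab, n = measure.label(mask, return_num=True)
    if n > 1:
        cy, cx = int(round(center[0])), int(round(center[1]))
        keep = lab[np.clip(cy, 0, h - 1), np.clip(cx, 0, w - 1)]
        if keep == 0:
            sizes = np.bincount(lab.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
        mask = lab == keep
    return mask


def generate_scene(params: LesionSceneParams) -> LesionScene:
    """Render one scene; fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    base_l, base_a, base_b = params.skin_base_lab

    # global shading: smooth multiplicative ramp along a random direction
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    proj = (np.cos(theta) * xx / max(w - 1, 1) + np.sin(theta) * yy / max(h - 1, 1))
    proj = (proj - proj.min()) / (np.ptp(proj) + 1e-12) - 0.5
    lum = base_l * (1.0 + (params.shadow_amplitude / base_l) * proj)
    a_ch = np.full((h, w), base_a, dtype=np.float64)
    b_ch = np.full((h, w), base_b, dtype=np.float64)

    # plaque blobs (random draws happen unconditionally in a fixed order so
    # that a fixed seed yields identical geometry across score settings)
    lesion = np.zeros((h, w), dtype=bool)
    margin = 0.18 * min(h, w)
    for _ in range(int(params.n_lesions)):
        center = rng.uniform([margin, margin], [h - margin, w - margin])
        radius = rng.uniform(0.10, 0.18) * min(h, w)
        lesion |= _blob((h, w), center, radius, rng)
    # correlation length ~2.5 px: flake-scale islands rather than pixel noise
    speck_field = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=2.5)

    erythema_mask = np.zeros((h, w), dtype=bool)
    scale_mask = np.zeros((h, w), dtype=bool)
    if lesion.any():
        # redness with radial falloff; edge band widens as the grade drops
        edge_width = max(1.0, 1.5 * (5 - params.erythema_score))
        falloff = np.clip(ndi.distance_transform_edt(lesion) / edge_width, 0.0, 1.0)
        shift = params.erythema_score * params.erythema_a_gain * falloff
        a_ch += shift
        lum -= 0.25 * shift

        coverage = params.scale_score * params.scale_coverage_gain
        if coverage > 1.0:
            warnings.warn("requested scale coverage exceeds 1; clipping", stacklevel=2)
            coverage = 1.0
        if coverage > 0:
            interior = lesion & (falloff >= 0.25)
            n_target = min(int(round(coverage * lesion.sum())), int(interior.sum()))
            if n_target > 0:
                vals = speck_field[interior]
                thr = np.partition(vals, len(vals) - n_target)[len(vals) - n_target]
                scale_mask = interior & (speck_field >= thr)
                # render scale near-white: high L*, low chroma
                lum[scale_mask] = 0.2 * lum[scale_mask] + 0.8 * 93.0
                a_ch[scale_mask] = 0.2 * a_ch[scale_mask] + 0.8 * 4.0
                b_ch[scale_mask] = 0.2 * b_ch[scale_mask] + 0.8 * 8.0
        # planted erythema GT is defined on the rendered redness field (the
        # same blurred signal an annotator sees): pixels retaining at least
        # half the full a* shift after the lens blur, excluding scale flakes
        a_rendered = (ndi.gaussian_filter(a_ch, params.blur_sigma)
                      if params.blur_sigma > 0 else a_ch)
        half_shift = 0.5 * params.erythema_score * params.erythema_a_gain
        if half_shift > 0:
            erythema_mask = lesion & (a_rendered - base_a >= half_shift) & ~scale_mask

    # hair-like strokes: thin dark quadratic Bezier curves
    t = np.linspace(0.0, 1.0, 4 * max(h, w) // 2)
    for _ in range(int(params.n_hairs)):
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        p1 = p0 + rng.uniform(-0.4, 0.4, size=2) * min(h, w)
        p2 = p1 + rng.uniform(-0.4, 0.4, size=2) * min(h, w)
        pts = ((1 - t)[:, None] ** 2 * p0 + 2 * ((1 - t) * t)[:, None] * p1
               + (t[:, None] ** 2) * p2)
        rr = np.round(pts[:, 0]).astype(int)
        cc = np.round(pts[:, 1]).astype(int)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        lum[rr[ok], cc[ok]] -= 22.0

    lab = np.stack([lum, a_ch, b_ch], axis=-1)
    if params.blur_sigma > 0:
        lab = ndi.gaussian_filter(lab, sigma=(params.blur_sigma, params.blur_sigma, 0))
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    rgb = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
    img = np.round(rgb * 255.0).astype(np.uint8)

    return LesionScene(
        image=img,
        lesion_mask=lesion,
        erythema_mask=erythema_mask,
        scale_mask=scale_mask,
        erythema_score=int(params.erythema_score),
        scale_score=int(params.scale_score),
    )


# severity group -> admissible (erythema, scale) grade pairs
_GROUP_BANDS = {
    "healthy": (0, 0),
    "mild": (1, 2),
    "moderate": (3, 4),
    "severe": (5, 6),
    "very_severe": (7, 8),
}


def _score_pairs(group: str) -> list[tuple[int, int]]:
    lo, hi = _GROUP_BANDS[group]
    return [(e, s) for e in range(5) for s in range(5) if lo <= e + s <= hi]


def generate_dataset(n_per_group: int, out_dir: str | Path, seed: int = 0,
                     image_size: tuple[int, int] = (512, 512),
                     **scene_kwargs) -> pd.DataFrame:
    """Write a balanced 5-group scene dataset and its CSV manifest.

    Produces ``scene_####.png`` plus ``_lesion/_erythema/_scale`` mask PNGs
    per scene and ``manifest.csv`` with header ``filename,erythema,scale,group``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group in _GROUP_BANDS:
        pairs = _score_pairs(group)
        for _ in range(n_per_group):
            e, s = pairs[rng.integers(len(pairs))]
            scene = generate_scene(LesionSceneParams(
                image_size=image_size, erythema_score=e, scale_score=s,
                seed=int(rng.integers(2**31)), **scene_kwargs))
            stem = f"scene_{idx:04d}"
            write_image(out / f"{stem}.png", scene.image)
            write_mask(out / f"{stem}_lesion.png", scene.lesion_mask)
            write_mask(out / f"{stem}_erythema.png", scene.erythema_mask)
            write_mask(out / f"{stem}_scale.png", scene.scale_mask)
            rows.append({"filename": f"{stem}.png", "erythema": e, "scale": s,
                         "group": scene.severity_group})
            idx += 1
    manifest = pd.DataFrame(rows, columns=["filename", "erythema", "scale", "group"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
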