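"""Texture, color and spectrum descriptors of a masked lesion or patch.

Three feature groups, mirroring the descriptor families used for severity
classification:

* ``texture`` — angle-averaged gray-level co-occurrence statistics (32
  levels, distance 1, four angles), gray-level run-length statistics over
  four directions, intensity-histogram moments, semi-variogram values at
  lags {1, 2, 4, 8} with a log-lag slope, and the uniform LBP histogram
  (P=8, R=1).
* ``color`` — mean and standard deviation of all 12 channels across RGB,
  HSV, CIE-Lab and YCbCr, plus skewness of a* and L* and an erythema index
  (mean a* − mean b*).
* ``spectrum`` — mean/std of the magnitude response of a zero-mean Gabor
  bank (4 orientations × 3 frequencies) and the 25 Zernike moment
  magnitudes up to radial order 8 on the mask's bounding circle.

All statistics are computed over the mask only (pixel pairs, runs and LBP
neighborhoods must lie entirely inside it).  An empty mask falls back to the
whole image — the convention for healthy images, where no lesion exists and
the skin itself is the region of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as _sstats
from scipy.signal import fftconvolve
from skimage import color as _skcolor
from skimage.feature import local_binary_pattern
from skimage.filters import gabor_kernel

from .colorspace import read_image, read_mask, rgb_to_hsv, rgb_to_lab, rgb_to_ycbcr

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector", "FeatureError",
    "glcm_matrix", "glcm_features", "glrlm_matrix", "glrlm_features",
    "intensity_histogram_features", "semivariogram_features", "lbp_features",
    "color_features", "gabor_features", "zernike_features",
    "extract_all", "extract_matrix", "GROUPS",
]

GROUPS = ("texture", "color", "spectrum")

# (dy, dx) offsets for the four standard angles 0, 45, 90, 135 degrees
_ANGLE_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


class FeatureError(ValueError):
    """A feature could not be computed for this image/mask."""


@dataclass
class FeatureVector:
    names: list[str]
    values: np.ndarray
    group_index: dict[str, list[str]]


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        return np.round(_skcolor.rgb2gray(img.astype(np.float64) / 255.0) * 255.0)
    return img.astype(np.float64)


def _quantize(gray: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = gray[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return np.zeros_like(gray, dtype=np.int64)
    q = np.floor((gray - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


# ---------------------------------------------------------------- GLCM

def glcm_matrix(q: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
                levels: int) -> np.ndarray:
    """Unnormalized symmetric co-occurrence counts for one offset, masked."""
    dy, dx = offset
    h, w = q.shape
    src = (slice(max(0, -dy), h - max(0, dy)), slice(max(0, -dx), w - max(0, dx)))
    dst = (slice(max(0, dy), h - max(0, -dy)), slice(max(0, dx), w - max(0, -dx)))
    a = q[src]
    b = q[dst]
    valid = mask[src] & mask[dst]
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    return counts + counts.T


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    contrast = float((p * (i - j) ** 2).sum())
    pi = p.sum(axis=1)
    mu_i = float((np.arange(levels) * pi).sum())
    sd_i = float(np.sqrt(((np.arange(levels) - mu_i) ** 2 * pi).sum()))
    if sd_i > 1e-12:
        corr = float(((i - mu_i) * (j - mu_i) * p).sum() / sd_i ** 2)
    else:
        corr = 1.0  # constant region: perfect (degenerate) correlation
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"contrast": contrast, "correlation": corr, "energy": energy,
            "homogeneity": homogeneity, "entropy": entropy}


def glcm_features(gray: np.ndarray, mask: np.ndarray, levels: int = 32,
                  distances: tuple[int, ...] = (1,)) -> dict[str, float]:
    """Haralick-style statistics averaged over four angles."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise FeatureError("GLCM needs at least 2 masked pixels")
    q = _quantize(np.asarray(gray, dtype=np.float64), mask, levels)
    acc: dict[str, float] = {}
    n_used = 0
    for d in distances:
        for dy, dx in _ANGLE_OFFSETS:
            counts = glcm_matrix(q, mask, (dy * d, dx * d), levels)
            tot = counts.sum()
            if tot == 0:
                continue
            stats = _glcm_stats(counts / tot)
            for k, v in stats.items():
                acc[k] = acc.get(k, 0.0) + v
            n_used += 1
    if n_used == 0:
        raise FeatureError("no co-occurring pixel pairs inside the mask")
    return {f"glcm_{k}": v / n_used for k, v in acc.items()}


# ---------------------------------------------------------------- GLRLM

def _lines(arr: np.ndarray, direction: int):
    """Yield the 1-D scan lines of a 2-D array along one of 4 directions."""
    if direction == 0:      # horizontal
        yield from arr
    elif direction == 90:   # vertical
        yield from arr.T
    elif direction == 45:
        f = np.fliplr(arr)
        for off in range(-arr.shape[0] + 1, arr.shape[1]):
            yield np.diagonal(f, offset=off)
    elif direction == 135:
        for off in range(-arr.shape[0] + 1, arr.shape[1]):
            yield np.diagonal(arr, offset=off)
    else:  # pragma: no cover
        raise ValueError(direction)


def glrlm_matrix(q: np.ndarray, mask: np.ndarray, direction: int,
                 levels: int) -> np.ndarray:
    """Run-length counts R[gray, length-1] along one direction; runs break
    at mask boundaries."""
    max_len = max(q.shape)
    R = np.zeros((levels, max_len), dtype=np.float64)
    for line, mline in zip(_lines(q, direction), _lines(mask, direction)):
        line = np.asarray(line)
        mline = np.asarray(mline, dtype=bool)
        if not mline.any():
            continue
        # encode invalid pixels as a sentinel so runs break there
        coded = np.where(mline, line, -1)
        change = np.flatnonzero(np.diff(coded) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(coded)]))
        for s, e in zip(starts, ends):
            if coded[s] >= 0:
                R[coded[s], e - s - 1] += 1
    return R


def glrlm_features(gray: np.ndarray, mask: np.ndarray,
                   levels: int = 32) -> dict[str, float]:
    """Run-length statistics averaged over the four scan directions."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("GLRLM needs a non-empty mask")
    q = _quantize(np.asarray(gray, dtype=np.float64), mask, levels)
    n_p = float(mask.sum())
    acc = {k: 0.0 for k in ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre")}
    for direction in (0, 45, 90, 135):
        R = glrlm_matrix(q, mask, direction, levels)
        n_r = R.sum()
        if n_r == 0:
            continue
        lens = np.arange(1, R.shape[1] + 1, dtype=np.float64)
        glv = np.arange(1, levels + 1, dtype=np.float64)  # 1-based gray level
        rl = R.sum(axis=0)
        rg = R.sum(axis=1)
        acc["sre"] += (rl / lens ** 2).sum() / n_r
        acc["lre"] += (rl * lens ** 2).sum() / n_r
        acc["gln"] += (rg ** 2).sum() / n_r
        acc["rln"] += (rl ** 2).sum() / n_r
        acc["rp"] += n_r / n_p
        acc["lgre"] += (rg / glv ** 2).sum() / n_r
        acc["hgre"] += (rg * glv ** 2).sum() / n_r
    return {f"glrlm_{k}": v / 4.0 for k, v in acc.items()}


# ------------------------------------------------------- histogram moments

def intensity_histogram_features(gray: np.ndarray, mask: np.ndarray,
                                 bins: int = 64) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(gray, dtype=np.float64)[mask]
    if vals.size == 0:
        raise FeatureError("histogram features need a non-empty mask")
    var = float(vals.var())
    if var > 0:
        skew = float(_sstats.skew(vals))
        kurt = float(_sstats.kurtosis(vals))
    else:
        skew = kurt = 0.0
    hist, _ = np.histogram(vals, bins=bins, range=(0.0, 256.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    return {
        "hist_mean": float(vals.mean()),
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_energy": float((p ** 2).sum()),
        "hist_entropy": float(-(nz * np.log2(nz)).sum()),
    }


# ----------------------------------------------------------- semivariogram

def semivariogram_features(gray: np.ndarray, mask: np.ndarray,
                           lags: tuple[int, ...] = (1, 2, 4, 8)) -> dict[str, float]:
    """Empirical semi-variance over masked horizontal+vertical pairs.

    A lag with no valid pair contributes gamma = 0 (and is excluded from the
    log-lag slope fit).
    """
    mask = np.asarray(mask, dtype=bool)
    z = np.asarray(gray, dtype=np.float64)
    if not mask.any():
        raise FeatureError("semivariogram needs a non-empty mask")
    out: dict[str, float] = {}
    pts = []
    for h in lags:
        total, count = 0.0, 0
        for (sl_a, sl_b) in (((slice(None), slice(None, -h)),
                              (slice(None), slice(h, None))),
                             ((slice(None, -h), slice(None)),
                              (slice(h, None), slice(None)))):
            if h >= z.shape[1] and sl_a[1] != slice(None):
                continue
            valid = mask[sl_a] & mask[sl_b]
            diff = z[sl_a][valid] - z[sl_b][valid]
            total += float((diff ** 2).sum())
            count += int(valid.sum())
        gamma = total / (2.0 * count) if count else 0.0
        out[f"semivar_lag{h}"] = gamma
        if count:
            pts.append((np.log2(h) if h > 1 else 0.0, gamma))
    if len(pts) >= 2:
        xs, ys = zip(*pts)
        slope = float(np.polyfit(xs, ys, 1)[0])
    else:
        slope = 0.0
    out["semivar_slope"] = slope
    return out


# --------------------------------------------------------------------- LBP

def lbp_features(gray: np.ndarray, mask: np.ndarray, P: int = 8,
                 R: float = 1.0) -> dict[str, float]:
    """Normalized uniform-LBP histogram (P+2 bins) over interior pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("LBP needs a non-empty mask")
    codes = local_binary_pattern(np.round(gray).astype(np.int32), P, R,
                                 method="uniform")
    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3)))
    if not interior.any():  # mask too thin to have interior pixels
        interior = mask
    hist = np.bincount(codes[interior].astype(int), minlength=P + 2)
    p = hist / hist.sum()
    return {f"lbp_u{i}": float(p[i]) for i in range(P + 2)}


# ------------------------------------------------------------------- color

_COLOR_CHANNELS = ("R", "G", "B", "H", "S", "V", "L", "a", "b", "Y", "Cb", "Cr")


def color_features(img: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean/std of the 12 channels plus a*/L* skewness and erythema index."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("color features need a non-empty mask")
    img = np.asarray(img)
    stacks = np.concatenate([
        img.astype(np.float64), rgb_to_hsv(img), rgb_to_lab(img),
        rgb_to_ycbcr(img)], axis=-1)
    out: dict[str, float] = {}
    sel = stacks[mask]
    for idx, ch in enumerate(_COLOR_CHANNELS):
        out[f"{ch}_mean"] = float(sel[:, idx].mean())
        out[f"{ch}_std"] = float(sel[:, idx].std())
    a_vals, l_vals = sel[:, 7], sel[:, 6]
    out["a_skew"] = float(_sstats.skew(a_vals)) if a_vals.std() > 0 else 0.0
    out["L_skew"] = float(_sstats.skew(l_vals)) if l_vals.std() > 0 else 0.0
    out["erythema_index"] = float(sel[:, 7].mean() - sel[:, 8].mean())
    return out


# ------------------------------------------------------------------- gabor

def _reflect_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size convolution with reflected boundaries via FFT."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(img, ((ph, kernel.shape[0] - 1 - ph),
                          (pw, kernel.shape[1] - 1 - pw)), mode="reflect")
    return fftconvolve(padded, kernel, mode="valid")


def gabor_features(gray: np.ndarray, mask: np.ndarray,
                   orientations: int = 4,
                   frequencies: tuple[float, ...] = (0.1, 0.2, 0.4)) -> dict[str, float]:
    """Mean/std of zero-mean Gabor magnitude responses per (theta, f)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("Gabor features need a non-empty mask")
    g = np.asarray(gray, dtype=np.float64)
    out: dict[str, float] = {}
    for oi in range(orientations):
        theta = oi * np.pi / orientations
        for f in frequencies:
            kern = gabor_kernel(frequency=f, theta=theta)
            kern = kern - kern.mean()  # strictly DC-free
            resp = np.abs(_reflect_convolve(g, kern.real)
                          + 1j * _reflect_convolve(g, kern.imag))
            tag = f"gabor_t{oi * 180 // orientations}_f{f:g}"
            out[f"{tag}_mean"] = float(resp[mask].mean())
            out[f"{tag}_std"] = float(resp[mask].std())
    return out


# ----------------------------------------------------------------- zernike

def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    from math import factorial
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * factorial(n - s)
             / (factorial(s) * factorial((n + m) // 2 - s)
                * factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike_features(gray: np.ndarray, mask: np.ndarray,
                     order: int = 8) -> dict[str, float]:
    """Zernike moment magnitudes |Z_nm| up to radial order ``order``.

    Computed on the mask's bounding circle (center = mask centroid); the
    masked intensities are normalized to unit sum first, so the magnitudes
    are invariant to intensity scaling and, being magnitudes, to rotation.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("Zernike moments need a non-empty mask")
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    r = np.hypot(dy, dx)
    radius = r.max() + 0.5 if r.max() > 0 else 1.0
    rho = r / radius
    theta = np.arctan2(dy, dx)
    f = np.asarray(gray, dtype=np.float64)[mask]
    s = f.sum()
    f = f / s if s > 0 else f
    out: dict[str, float] = {}
    for n in range(order + 1):
        for m in range(n % 2, n + 1, 2):
            rad = _radial_poly(n, m, rho)
            z = (n + 1) / np.pi * np.sum(f * rad * np.exp(-1j * m * theta))
            out[f"zernike_{n}_{m}"] = float(np.abs(z))
    return out


# ------------------------------------------------------------- composition

def _texture(gray, mask):
    out = {}
    out.update(glcm_features(gray, mask))
    out.update(glrlm_features(gray, mask))
    out.update(intensity_histogram_features(gray, mask))
    out.update(semivariogram_features(gray, mask))
    out.update(lbp_features(gray, mask))
    return out


def extract_all(img: np.ndarray, mask: np.ndarray | None = None,
                groups: tuple[str, ...] = GROUPS) -> FeatureVector:
    """Concatenate the requested feature groups in fixed order."""
    for gname in groups:
        if gname not in GROUPS:
            raise ValueError(f"unknown feature group {gname!r}")
    img = np.asarray(img)
    if mask is None or not np.asarray(mask, dtype=bool).any():
        mask = np.ones(img.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    gray = _to_gray(img)
    names: list[str] = []
    values: list[float] = []
    group_index: dict[str, list[str]] = {}
    for gname in GROUPS:
        if gname not in groups:
            continue
        if gname == "texture":
            feats = _texture(gray, mask)
        elif gname == "color":
            feats = color_features(img, mask)
        else:
            feats = dict(**gabor_features(gray, mask),
                         **zernike_features(gray, mask))
        prefix = {"texture": "tex", "color": "col", "spectrum": "spec"}[gname]
        gnames = []
        for k, v in feats.items():
            if not np.isfinite(v):
                raise FeatureError(f"non-finite value for feature {k}")
            names.append(f"{prefix}.{k}")
            gnames.append(f"{prefix}.{k}")
            values.append(v)
        group_index[gname] = gnames
    return FeatureVector(names=names, values=np.asarray(values),
                         group_index=group_index)


def extract_matrix(manifest: pd.DataFrame, root: str | Path,
                   groups: tuple[str, ...] = GROUPS) -> pd.DataFrame:
    """Feature matrix over a dataset manifest.

    Scene/crop rows read their mask from ``<stem>_mask.png``; patch rows
    (``is_patch == 1``) use the nonzero pixels of the patch image itself.
    Rows whose extraction fails are skipped with a logged reason.
    """
    root = Path(root)
    records = []
    for _, row in manifest.iterrows():
        try:
            img = read_image(root / row["filename"])
            if int(row.get("is_patch", 0)) == 1:
                mask = img.any(axis=-1)
            else:
                mask = read_mask(root / f"{Path(row['filename']).stem}_mask.png")
            fv = extract_all(img, mask, groups)
        except (FeatureError, FileNotFoundError, ValueError) as exc:
            logger.warning("skipping %s: %s", row["filename"], exc)
            continue
        rec = {"filename": row["filename"], "label": row["label"],
               "is_patch": int(row.get("is_patch", 0))}
        rec.update(dict(zip(fv.names, fv.values)))
        records.append(rec)
    return pd.DataFrame(records)
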