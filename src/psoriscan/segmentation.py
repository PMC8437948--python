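"""Lesion segmentation: SLIC superpixels + local k-means (automatic route)
and a reaction-diffusion level-set method (semi-automatic alternative).

The automatic route over-segments the image into ~700 superpixels in the
5-D [L*, a*, b*, x, y] space, clusters the superpixel mean colors into three
centers with seeded k-means (500 iterations), and selects the lesion
cluster(s) by a redness rule — by default the cluster with the highest mean
a*.  The level-set route evolves a signed function from a user-supplied
initial mask with an edge-stopped region force (time step ``dt1``) followed
by a small diffusion sub-step (time step ``dt2``) each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as _skcolor
from skimage import morphology, segmentation as _skseg
from sklearn.cluster import KMeans

from .colorspace import rgb_to_lab

__all__ = [
    "SLICParams", "LSMParams", "SegmentationResult",
    "slic_superpixels", "cluster_superpixels", "select_lesion_clusters",
    "segment_slic", "segment_lsm",
]


@dataclass
class SLICParams:
    n_superpixels: int = 700
    compactness: float = 10.0
    n_centers: int = 3
    kmeans_iters: int = 500
    slic_iters: int = 10
    rule: str = "max_a"
    min_area: int = 25
    redness_margin: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_superpixels >= self.n_centers >= 2):
            raise ValueError("need n_superpixels >= n_centers >= 2")
        if self.kmeans_iters < 1 or self.slic_iters < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class LSMParams:
    init_mask: np.ndarray
    dt1: float = 1.0
    dt2: float = 0.001
    iterations: int = 15
    smoothing_sigma: float = 1.5
    curvature_weight: float = 0.2

    def __post_init__(self) -> None:
        if self.dt1 <= 0 or self.dt2 < 0:
            raise ValueError("time steps must be positive (dt2 may be 0)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        self.init_mask = np.asarray(self.init_mask, dtype=bool)
        if not self.init_mask.any():
            raise ValueError("init_mask must be non-empty")


@dataclass
class SegmentationResult:
    mask: np.ndarray
    method: str
    superpixels: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None


def slic_superpixels(img: np.ndarray, params: SLICParams | None = None) -> np.ndarray:
    """Partition the image into superpixels by local k-means in [L,a,b,x,y].

    Returns an integer label image with labels compacted to 0..n-1; every
    pixel carries exactly one label and connectivity is enforced.
    """
    params = params or SLICParams()
    img = np.asarray(img)
    if params.n_superpixels > img.shape[0] * img.shape[1]:
        raise ValueError("more superpixels requested than pixels")
    labels = _skseg.slic(
        img,
        n_segments=params.n_superpixels,
        compactness=params.compactness,
        max_num_iter=params.slic_iters,
        start_label=0,
        enforce_connectivity=True,
        convert2lab=True,
    )
    # compact to a contiguous 0..n-1 range
    _, labels = np.unique(labels, return_inverse=True)
    return labels.reshape(img.shape[:2])


def _superpixel_means(spx: np.ndarray, lab: np.ndarray) -> np.ndarray:
    n = int(spx.max()) + 1
    counts = np.bincount(spx.ravel(), minlength=n).astype(np.float64)
    means = np.empty((n, 3))
    for c in range(3):
        means[:, c] = np.bincount(spx.ravel(), weights=lab[..., c].ravel(),
                                  minlength=n) / counts
    return means


def cluster_superpixels(spx: np.ndarray, lab: np.ndarray, n_centers: int = 3,
                        iters: int = 500, seed: int = 0) -> np.ndarray:
    """k-means over per-superpixel mean (L*, a*, b*); per-pixel cluster ids."""
    spx = np.asarray(spx)
    if spx.shape != lab.shape[:2]:
        raise ValueError("superpixel map must cover the Lab image")
    n_spx = int(spx.max()) + 1
    if n_centers > n_spx:
        raise ValueError("more centers than superpixels")
    means = _superpixel_means(spx, lab)
    km = KMeans(n_clusters=n_centers, init="k-means++", n_init=1,
                max_iter=iters, random_state=seed)
    spx_cluster = km.fit_predict(means)
    return spx_cluster[spx]


def select_lesion_clusters(clusters: np.ndarray, lab: np.ndarray,
                           rule: str = "max_a",
                           manual_ids: list[int] | None = None) -> np.ndarray:
    """Pick the lesion cluster(s) from a cluster map by a redness rule.

    ``max_a``: the single cluster with maximum mean a*.
    ``a_above_median``: every cluster whose mean a* exceeds the image median a*.
    ``manual``: explicit cluster ids.
    """
    clusters = np.asarray(clusters)
    ids = np.unique(clusters)
    if ids.size < 2:
        raise ValueError("need at least 2 clusters to select a lesion")
    a_ch = lab[..., 1]
    mean_a = np.array([a_ch[clusters == i].mean() for i in ids])
    if rule == "max_a":
        chosen = [ids[int(np.argmax(mean_a))]]
    elif rule == "a_above_median":
        med = float(np.median(a_ch))
        chosen = [i for i, m in zip(ids, mean_a) if m > med]
    elif rule == "manual":
        if manual_ids is None:
            raise ValueError("manual rule requires manual_ids")
        chosen = list(manual_ids)
    else:
        raise ValueError(f"unknown lesion-selection rule: {rule!r}")
    return np.isin(clusters, chosen)


def _cleanup(mask: np.ndarray, min_area: int) -> np.ndarray:
    mask = ndi.binary_fill_holes(mask)
    if min_area > 1:
        # drop connected components with fewer than min_area pixels
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    return mask


def segment_slic(img: np.ndarray, params: SLICParams | None = None) -> SegmentationResult:
    """Full automatic segmentation: superpixels -> color k-means -> lesion rule
    -> morphological cleanup (fill holes, drop components < min_area)."""
    params = params or SLICParams()
    spx = slic_superpixels(img, params)
    lab = rgb_to_lab(img)
    clusters = cluster_superpixels(spx, lab, params.n_centers,
                                   params.kmeans_iters, params.seed)
    mask = select_lesion_clusters(clusters, lab, rule=params.rule)
    # redness guard: a lesion-free image has no cluster meaningfully redder
    # than the skin itself, so the argmax pick must clear a margin
    if mask.any():
        a_ch = lab[..., 1]
        if a_ch[mask].mean() - np.median(a_ch) < params.redness_margin:
            mask = np.zeros_like(mask)
    mask = _cleanup(mask, params.min_area)
    return SegmentationResult(mask=mask, method="slic",
                              superpixels=spx, cluster_labels=clusters)


def segment_lsm(img: np.ndarray, params: LSMParams) -> SegmentationResult:
    """Two-phase reaction-diffusion level set from an initial mask.

    phi starts as the signed distance of ``init_mask``.  Each iteration takes
    one explicit step of the edge-stopped region force (Chan-Vese style means
    contrast, normalized to unit magnitude) plus a weak curvature term with
    step ``dt1``, then a diffusion sub-step ``phi += dt2 * laplace(phi)``.
    The final mask is {phi > 0}.  On a constant image the region force
    vanishes and the mask stays at the initialization.
    """
    img = np.asarray(img)
    if img.ndim == 3:
        gray = _skcolor.rgb2gray(img.astype(np.float64) / 255.0)
    else:
        gray = img.astype(np.float64)
        if gray.max() > 1.5:
            gray = gray / 255.0
    if not np.isfinite(gray).all():
        raise ValueError("image contains non-finite values")
    if params.init_mask.shape != gray.shape:
        raise ValueError("init_mask shape must match the image")

    smooth = ndi.gaussian_filter(gray, params.smoothing_sigma)
    gy, gx = np.gradient(smooth)
    g = 1.0 / (1.0 + (gx ** 2 + gy ** 2) / (np.mean(gx ** 2 + gy ** 2) + 1e-12))

    inside = params.init_mask
    phi = ndi.distance_transform_edt(inside) - ndi.distance_transform_edt(~inside)
    phi = phi.astype(np.float64)

    for _ in range(params.iterations):
        fg = phi > 0
        if fg.any() and (~fg).any():
            c1 = smooth[fg].mean()
            c2 = smooth[~fg].mean()
        else:  # front left the domain; nothing to contrast against
            c1 = c2 = smooth.mean()
        force = (smooth - c2) ** 2 - (smooth - c1) ** 2
        fmax = np.abs(force).max()
        if fmax > 0:
            force = force / fmax
        py, px = np.gradient(phi)
        grad_mag = np.hypot(py, px)
        norm = grad_mag + 1e-12
        curv = (np.gradient(py / norm)[0] + np.gradient(px / norm)[1])
        phi = phi + params.dt1 * (g * force * grad_mag
                                  + params.curvature_weight * g * curv * grad_mag)
        if params.dt2 > 0:
            phi = phi + params.dt2 * ndi.laplace(phi)

    return SegmentationResult(mask=phi > 0, method="lsm")
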