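"""Five-indicator similarity evaluation between binary segmentation masks.

DICE (overlap), GCE (Martin's global consistency error), VoI (variation of
information, bits), HD (Hausdorff distance, pixels) and RI (Rand index) are
all computed on the two-region partition {foreground, background} induced by
each mask.  Conventions for two empty masks: DICE=1, GCE=0, VoI=0, RI=1; HD
is undefined for an empty mask and raises.

Direction of similarity: DICE and RI increase and GCE, VoI, HD decrease as
the masks become more similar (VoI = 0 for identical partitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

__all__ = ["SimilarityReport", "dice", "gce", "voi", "hausdorff",
           "rand_index", "evaluate"]


@dataclass(frozen=True)
class SimilarityReport:
    dice: float
    gce: float
    voi: float
    hd: float
    ri: float


def _as_masks(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2 pixel-count table over the {bg, fg} partitions of a and b."""
    n11 = np.count_nonzero(a & b)
    n10 = np.count_nonzero(a & ~b)
    n01 = np.count_nonzero(~a & b)
    n00 = a.size - n11 - n10 - n01
    return np.array([[n00, n01], [n10, n11]], dtype=np.float64)


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1 when both masks are empty."""
    a, b = _as_masks(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / float(denom)


def gce(a, b) -> float:
    """Martin's global consistency error between the two 2-region partitions.

    The local refinement error at pixel x is |R(a,x) \\ R(b,x)| / |R(a,x)|;
    GCE is the smaller of the two one-directional sums, divided by n.
    """
    a, b = _as_masks(a, b)
    n = a.size
    tab = _contingency(a, b)
    ra = tab.sum(axis=1)  # region sizes in a
    rb = tab.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_ab = np.where(ra[:, None] > 0, tab * (ra[:, None] - tab) / ra[:, None], 0.0)
        e_ba = np.where(rb[None, :] > 0, tab * (rb[None, :] - tab) / rb[None, :], 0.0)
    return min(e_ab.sum(), e_ba.sum()) / n


def voi(a, b) -> float:
    """Variation of information H(A) + H(B) - 2 I(A;B), in bits."""
    a, b = _as_masks(a, b)
    tab = _contingency(a, b) / a.size
    pa = tab.sum(axis=1)
    pb = tab.sum(axis=0)

    def _h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    h_ab = _h(tab.ravel())  # joint entropy
    # VI = 2 H(A,B) - H(A) - H(B)
    return max(2.0 * h_ab - _h(pa) - _h(pb), 0.0)


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance between foreground point sets, pixels."""
    a, b = _as_masks(a, b)
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    pa = np.argwhere(a).astype(np.float64)
    pb = np.argwhere(b).astype(np.float64)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def rand_index(a, b) -> float:
    """Fraction of unordered pixel pairs classified consistently (together
    or apart) by the two partitions; computed from the contingency table."""
    a, b = _as_masks(a, b)
    n = a.size
    if n < 2:
        raise ValueError("Rand index needs at least two pixels")
    tab = _contingency(a, b)
    sum_sq = (tab ** 2).sum()
    sum_a = (tab.sum(axis=1) ** 2).sum()
    sum_b = (tab.sum(axis=0) ** 2).sum()
    # agreements = C(n,2) - [pairs split by exactly one partition]
    disagree = 0.5 * (sum_a + sum_b) - sum_sq
    total = n * (n - 1) / 2.0
    return float((total - disagree) / total)


def evaluate(pred, gt) -> SimilarityReport:
    """All five indicators of a predicted mask against ground truth."""
    return SimilarityReport(
        dice=dice(pred, gt),
        gce=gce(pred, gt),
        voi=voi(pred, gt),
        hd=hausdorff(pred, gt),
        ri=rand_index(pred, gt),
    )
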