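"""Three-filter consensus feature selection.

Features are ranked independently by greedy mRMR (mutual-information
relevance minus mean redundancy), the chi-square statistic of the binned
feature x class table, and ReliefF weights.  The top 2/3 of each ranking is
kept and the final feature set is the intersection of the three subsets.
Mutual information and chi-square use a 10-bin equal-width discretization of
each feature over its observed range; ties in any score are broken by the
original feature order (stable).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.metrics import mutual_info_score

__all__ = ["RankedFeatures", "ConsensusResult", "mrmr_rank", "chi2_rank",
           "relieff_rank", "consensus_select", "select_features"]


@dataclass
class RankedFeatures:
    method: str
    order: list[str]   # best first
    scores: dict[str, float]


@dataclass
class ConsensusResult:
    selected: list[str]          # in original feature order
    per_method_top: dict[str, list[str]]
    fraction: float


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least two classes")
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    return y


def _discretize(col: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi <= lo:
        return np.zeros(len(col), dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(col, edges[1:-1]), 0, bins - 1)


def _stable_rank(names: list[str], scores: np.ndarray) -> list[str]:
    order = np.argsort(-scores, kind="stable")
    return [names[i] for i in order]


def mrmr_rank(X: pd.DataFrame, y, bins: int = 10) -> RankedFeatures:
    """Greedy mRMR with the MID (difference) criterion.

    First pick maximizes I(f; y); each subsequent pick maximizes
    I(f; y) - mean over selected s of I(f; s).
    """
    y = _check_xy(X, y)
    names = list(X.columns)
    disc = np.column_stack([_discretize(X[c].to_numpy(float), bins)
                            for c in names])
    p = len(names)
    relevance = np.array([mutual_info_score(disc[:, j], y) for j in range(p)])
    pair_mi = np.full((p, p), np.nan)
    selected: list[int] = []
    remaining = list(range(p))
    redundancy = np.zeros(p)
    scores: dict[str, float] = {}
    while remaining:
        if not selected:
            crit = relevance[remaining]
        else:
            crit = np.array([relevance[j] - redundancy[j] / len(selected)
                             for j in remaining])
        # stable argmax: first index attaining the maximum
        best_pos = int(np.flatnonzero(crit == crit.max())[0])
        j = remaining.pop(best_pos)
        scores[names[j]] = float(crit[best_pos])
        selected.append(j)
        for r in remaining:
            if np.isnan(pair_mi[j, r]):
                pair_mi[j, r] = pair_mi[r, j] = mutual_info_score(
                    disc[:, j], disc[:, r])
            redundancy[r] += pair_mi[j, r]
    return RankedFeatures(method="mrmr", order=[names[j] for j in selected],
                          scores=scores)


def chi2_rank(X: pd.DataFrame, y, bins: int = 10) -> RankedFeatures:
    """Per-feature chi-square statistic of the binned-feature x class table."""
    y = _check_xy(X, y)
    names = list(X.columns)
    stats = []
    for c in names:
        d = _discretize(X[c].to_numpy(float), bins)
        tab = pd.crosstab(d, y).to_numpy()
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            stats.append(0.0)  # single effective bin: no association
            continue
        stats.append(float(chi2_contingency(tab, correction=False)[0]))
    stats = np.asarray(stats)
    return RankedFeatures(method="chi2", order=_stable_rank(names, stats),
                          scores=dict(zip(names, stats)))


def relieff_rank(X: pd.DataFrame, y, k_neighbors: int = 10) -> RankedFeatures:
    """ReliefF weights with k nearest hits/misses, every sample an anchor.

    Features are range-normalized; miss contributions are weighted by class
    priors P(C)/(1 - P(class(anchor))).  If some class has fewer than
    k_neighbors + 1 members, k shrinks to fit.
    """
    y = _check_xy(X, y)
    names = list(X.columns)
    Xv = X.to_numpy(float)
    n, p = Xv.shape
    span = Xv.max(axis=0) - Xv.min(axis=0)
    span[span == 0] = 1.0
    Xn = (Xv - Xv.min(axis=0)) / span
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    k = min(k_neighbors, counts.min() - 1)
    if k < 1:
        raise ValueError("every class needs at least 2 samples for ReliefF")
    # pairwise manhattan distances, chunked to bound memory at ~n*chunk*p
    dist = np.empty((n, n))
    chunk = max(1, int(2e7 // (n * p)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        dist[s:e] = np.abs(Xn[s:e, None, :] - Xn[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    w = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        hits = same[np.argsort(dist[i, same], kind="stable")[:k]]
        w -= np.abs(Xn[hits] - Xn[i]).sum(axis=0) / (n * k)
        for c in classes:
            if c == y[i]:
                continue
            other = np.flatnonzero(y == c)
            kk = min(k, len(other))
            misses = other[np.argsort(dist[i, other], kind="stable")[:kk]]
            wgt = priors[c] / (1.0 - priors[y[i]])
            w += wgt * np.abs(Xn[misses] - Xn[i]).sum(axis=0) / (n * kk)
    return RankedFeatures(method="relieff", order=_stable_rank(names, w),
                          scores=dict(zip(names, w)))


def consensus_select(rankings: list[RankedFeatures],
                     fraction: float = 2 / 3) -> ConsensusResult:
    """Intersect the top-⌈fraction·p⌉ feature sets of the three rankings."""
    universes = [set(r.order) for r in rankings]
    if any(u != universes[0] for u in universes):
        raise ValueError("rankings cover different feature sets")
    p = len(universes[0])
    n_top = ceil(fraction * p)
    tops = {r.method: r.order[:n_top] for r in rankings}
    common = set.intersection(*(set(t) for t in tops.values()))
    if not common:
        raise ValueError("consensus selection is empty; raise the fraction")
    reference = rankings[0].order  # keep deterministic output order
    first = [n for n in reference if n in common]
    return ConsensusResult(selected=first, per_method_top=tops,
                           fraction=fraction)


def select_features(X: pd.DataFrame, y, fraction: float = 2 / 3,
                    bins: int = 10, k_neighbors: int = 10) -> ConsensusResult:
    """Run all three filters and return their consensus."""
    rankings = [mrmr_rank(X, y, bins=bins), chi2_rank(X, y, bins=bins),
                relieff_rank(X, y, k_neighbors=k_neighbors)]
    return consensus_select(rankings, fraction=fraction)
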