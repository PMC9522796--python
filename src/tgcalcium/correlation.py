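"""All-pairs correlation and distance analysis of firing neurons.

Traces are first thresholded (frames below the mean + SD firing
threshold are zeroed, so only supra-threshold transients contribute),
then the Pearson correlation coefficient is computed for every unordered
ROI pair. Pairs with r > 0.5 (strictly) are classified as correlated;
pairs at exactly 0.5 are not. Inter-ROI distance is the Euclidean
distance between centroids in micrometres. The distance distributions of
correlated vs non-correlated pairs are compared with a two-tailed
Mann-Whitney U test (exact enumeration for small groups, tie-corrected
normal approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .events import DffTrace
from .roi import RoiSet

__all__ = [
    "PairRecord",
    "CorrelationMatrix",
    "thresholded_signal",
    "pairwise_correlation",
    "pair_distances",
    "classify_pairs",
    "mann_whitney_u",
    "compare_distance_distributions",
    "cluster_matrix",
]

CORRELATED_R = 0.5  # strict: r > 0.5 is correlated, r == 0.5 is not


@dataclass
class PairRecord:
    """One unordered ROI pair (roi_i < roi_j)."""

    roi_i: int
    roi_j: int
    pearson_r: float
    distance_um: float = np.nan
    zero_variance: bool = False

    @property
    def correlated(self) -> bool:
        return self.pearson_r > CORRELATED_R


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray
    roi_ids: list[int]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.roi_ids):
            raise ValueError("matrix shape inconsistent with roi_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.roi_ids, columns=self.roi_ids)


def thresholded_signal(dff: DffTrace) -> np.ndarray:
    """Zero sub-threshold frames; supra-threshold frames keep their dF/F0.

    This keeps amplitude information from the transients while removing
    baseline noise, which is what the correlation is computed from.
    """
    out = dff.dff.copy()
    out[out < dff.threshold] = 0.0
    return out


def pairwise_correlation(signals: dict[int, np.ndarray],
                         exclude_zero_variance: bool = True
                         ) -> tuple[CorrelationMatrix, list[PairRecord]]:
    """Pearson r for every unordered ROI pair.

    ``signals`` maps roi_id -> equal-length 1-D signal. A zero-variance
    (never-firing) signal has undefined correlation; its r is recorded as
    0 with ``zero_variance=True``, and such pairs are excluded from the
    record list by default since the pair analysis concerns firing
    neurons only. The matrix always covers all ROIs (unit diagonal).
    """
    ids = sorted(signals)
    if len(ids) < 2:
        raise ValueError("need at least 2 ROIs")
    lengths = {len(signals[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("signals must have equal length")
    arr = np.vstack([np.asarray(signals[i], dtype=float) for i in ids])
    sd = arr.std(axis=1)
    ok = sd > 0
    mat = np.eye(len(ids))
    if ok.sum() >= 2:
        sub = np.corrcoef(arr[ok])
        mat[np.ix_(ok, ok)] = sub
        np.fill_diagonal(mat, 1.0)
    records = []
    for a, b in combinations(range(len(ids)), 2):
        zv = not (ok[a] and ok[b])
        r = 0.0 if zv else float(mat[a, b])
        if zv and exclude_zero_variance:
            continue
        records.append(PairRecord(roi_i=ids[a], roi_j=ids[b], pearson_r=r,
                                  zero_variance=zv))
    return CorrelationMatrix(matrix=mat, roi_ids=ids), records


def pair_distances(rois: RoiSet) -> dict[tuple[int, int], float]:
    """Euclidean centroid distance (um) for every unordered ROI pair:
    sqrt((x2 - x1)^2 + (y2 - y1)^2)."""
    out = {}
    for a, b in combinations(rois.rois, 2):
        i, j = sorted((a.id, b.id))
        xa, ya = a.centroid_xy_um
        xb, yb = b.centroid_xy_um
        out[(i, j)] = float(np.hypot(xb - xa, yb - ya))
    return out


def attach_distances(records: list[PairRecord],
                     distances: dict[tuple[int, int], float]) -> list[PairRecord]:
    for rec in records:
        rec.distance_um = distances[(min(rec.roi_i, rec.roi_j),
                                     max(rec.roi_i, rec.roi_j))]
    return records


def classify_pairs(records: list[PairRecord]
                   ) -> tuple[list[PairRecord], list[PairRecord], float]:
    """Split pair records at r > 0.5 and report the correlated percentage.

    Returns (correlated, non_correlated, fraction_correlated_pct) where
    the fraction is ``100 * n_correlated / n_total``.
    """
    if not records:
        raise ValueError("no pair records to classify")
    correlated = [r for r in records if r.correlated]
    non_correlated = [r for r in records if not r.correlated]
    frac = 100.0 * len(correlated) / len(records)
    return correlated, non_correlated, frac


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For groups of at most 8 observations each the null distribution is
    enumerated exactly over all ways of assigning the pooled (tied) ranks
    to the two groups; the two-sided p-value is the fraction of
    assignments whose U deviates from nm/2 by at least as much as the
    observed U. Larger groups use the tie-corrected normal approximation
    with continuity correction.

    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if max(n, m) <= 8:
        center = n * m / 2.0
        dev = abs(u_x - center)
        total = comb(n + m, n)
        count = 0
        rank_sum_const = n * (n + 1) / 2.0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - rank_sum_const
            if abs(u - center) >= dev - 1e-12:
                count += 1
        return u_x, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_distance_distributions(correlated_dists, non_correlated_dists
                                   ) -> dict:
    """Compare inter-ROI distance distributions of correlated vs
    non-correlated pairs (two-tailed Mann-Whitney).

    Returns a dict with both medians, the U statistic and the two-sided
    p-value.
    """
    c = np.asarray(correlated_dists, dtype=float)
    nc = np.asarray(non_correlated_dists, dtype=float)
    if len(c) < 1 or len(nc) < 1:
        raise ValueError("both groups must be nonempty")
    u, p = mann_whitney_u(c, nc)
    return {
        "median_correlated_um": float(np.median(c)),
        "median_non_correlated_um": float(np.median(nc)),
        "u_statistic": u,
        "p_value": p,
        "n_correlated": len(c),
        "n_non_correlated": len(nc),
    }


def cluster_matrix(cmat: CorrelationMatrix, method: str = "average"
                   ) -> tuple[list[int], CorrelationMatrix]:
    """Agglomerative clustering of the correlation matrix on distance 1 - r.

    Returns the dendrogram leaf order (as roi ids) and the reordered
    matrix for plotting.
    """
    if method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    m = cmat.matrix
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    dist = 1.0 - m
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    order = list(leaves_list(z))
    reordered = m[np.ix_(order, order)]
    ids = [cmat.roi_ids[i] for i in order]
    return ids, CorrelationMatrix(matrix=reordered, roi_ids=ids)
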