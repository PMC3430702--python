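"""Sample-level cohort statistics.

Whole-genome copy-number tracks are compared with correlation distance
(1 - Pearson r on the log2(c/psi) tracks) and clustered agglomeratively with
average linkage; trait associations use Pearson's r with the two-sided
t-distribution p-value; windowed means support probe-level vs expression
comparisons on a common genomic binning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .cn_estimation import CopyNumberProfile


@dataclass
class Dendrogram:
    """Agglomerative merge history over labelled leaves.

    ``merges`` lists (cluster_a, cluster_b, height) with scipy's convention:
    clusters 0..n-1 are leaves, merge k creates cluster n+k.
    """

    merges: List[Tuple[int, int, float]]
    labels: List[str]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.labels) - 1:
            raise ValueError("need exactly n-1 merges for n leaves")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def to_linkage(self) -> np.ndarray:
        n = len(self.labels)
        sizes = {i: 1 for i in range(n)}
        rows = []
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            rows.append([a, b, h, size])
        return np.asarray(rows, dtype=float)

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.to_linkage(), self.labels)
        return str(tree).strip()


def _common_tracks(a: CopyNumberProfile, b: CopyNumberProfile):
    ga = a.probes[["chromosome", "start"]]
    gb = b.probes[["chromosome", "start"]]
    if len(ga) != len(gb) or not ga.reset_index(drop=True).equals(
            gb.reset_index(drop=True)):
        raise ValueError(f"{a.sample_id} and {b.sample_id} are on different probe grids")
    return a.track, b.track


def track_distance(x, y) -> float:
    """Correlation distance 1 - r between two equal-length tracks; in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant track: correlation distance undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return 1.0 - r


def profile_distance(a: CopyNumberProfile, b: CopyNumberProfile) -> float:
    """Correlation distance between two samples' log2(c/psi) tracks."""
    x, y = _common_tracks(a, b)
    return track_distance(x, y)


def cluster_tracks(labels: Sequence[str], tracks: Sequence[np.ndarray],
                   linkage: str = "average") -> Dendrogram:
    """Average-linkage agglomeration on pairwise correlation distances."""
    if len(labels) != len(tracks) or len(labels) < 2:
        raise ValueError("need at least two labelled tracks to cluster")
    n = len(tracks)
    condensed = np.array([track_distance(tracks[i], tracks[j])
                          for i in range(n) for j in range(i + 1, n)])
    Z = hierarchy.linkage(condensed, method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(merges=merges, labels=list(labels))


def hierarchical_cluster(profiles: Sequence[CopyNumberProfile],
                         linkage: str = "average") -> Dendrogram:
    """Cluster whole-genome copy-number profiles on a shared probe grid."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    for other in profiles[1:]:
        _common_tracks(profiles[0], other)
    return cluster_tracks([p.sample_id for p in profiles],
                          [p.track for p in profiles], linkage=linkage)


def pearson_with_p(x, y) -> Tuple[float, float]:
    """Pearson r and its two-sided p-value (t-distribution, n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def window_mean(positions, values, window_size: int = 2_000_000) -> pd.DataFrame:
    """Means over non-overlapping windows tiled from position 0.

    Returns one row per window up to the last populated one; empty windows
    carry NaN. Positions must be sorted and on a single chromosome.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if len(positions) != len(values) or len(positions) == 0:
        raise ValueError("positions and values must be equal-length and non-empty")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    idx = positions // window_size
    n_windows = int(idx[-1]) + 1
    sums = np.bincount(idx, weights=values, minlength=n_windows)
    counts = np.bincount(idx, minlength=n_windows)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    w = np.arange(n_windows)
    return pd.DataFrame({
        "window_start": w * window_size,
        "window_end": (w + 1) * window_size,
        "n": counts.astype(int),
        "mean": means,
    })
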