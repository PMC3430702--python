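"""Circular binary segmentation (CBS) of log2-ratio profiles.

The per-chromosome probe series is split recursively at the arc [i, j) that
maximizes a two-sample t-like contrast between the arc and its complement
(the two flanks pooled, i.e. the circular formulation on a linearized
chromosome). A candidate split is accepted when a permutation test on the
current piece gives p <= alpha; the published analysis this package follows
used alpha = 0.0001. Permutations stop early once the significance level can
no longer be reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from ._util import child_rng
from .io import RatioProfile


@dataclass(frozen=True)
class SegmentationConfig:
    alpha: float = 1e-4
    n_permutations: int = 10_000
    min_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass(frozen=True)
class Segment:
    chromosome: str
    start_probe: int  # probe index within the chromosome, half-open
    end_probe: int
    genomic_start: int
    genomic_end: int
    mean: float
    n_probes: int

    def __post_init__(self) -> None:
        if self.n_probes != self.end_probe - self.start_probe or self.n_probes < 1:
            raise ValueError("segment probe bounds inconsistent with n_probes")


@dataclass
class SegmentedProfile:
    sample_id: str
    segments: List[Segment] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample": self.sample_id,
            "chromosome": s.chromosome,
            "genomic_start": s.genomic_start,
            "genomic_end": s.genomic_end,
            "n_probes": s.n_probes,
            "mean": s.mean,
            "start_probe": s.start_probe,
            "end_probe": s.end_probe,
        } for s in self.segments])

    @property
    def n_probes(self) -> int:
        return sum(s.n_probes for s in self.segments)


def cbs_statistic(values: np.ndarray, i: int, j: int) -> float:
    """Two-sample contrast between the arc values[i:j] and its complement.

    |mean(arc) - mean(comp)| / (s * sqrt(1/n_arc + 1/n_comp)) with s the
    pooled standard deviation. Degenerate spread (s = 0) yields 0 when the
    means agree and +inf otherwise.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not (0 <= i < j <= n):
        raise ValueError("need 0 <= i < j <= n")
    if j - i == n:
        raise ValueError("complement must be non-empty")
    arc = values[i:j]
    comp = np.concatenate([values[:i], values[j:]])
    diff = abs(arc.mean() - comp.mean())
    ss = float(np.sum((arc - arc.mean()) ** 2) + np.sum((comp - comp.mean()) ** 2))
    dof = max(n - 2, 1)
    denom = np.sqrt(ss / dof * (1.0 / len(arc) + 1.0 / len(comp)))
    if denom == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return float(diff / denom)


def _valid_start_mask(n: int, L: int, min_width: int) -> Optional[np.ndarray]:
    """Starts i for arcs of length L leaving every resulting piece >= min_width."""
    if L < min_width or L > n - 1:
        return None
    i = np.arange(n - L + 1)
    j = i + L
    left_ok = (i == 0) | (i >= min_width)
    right_ok = (j == n) | (n - j >= min_width)
    mask = left_ok & right_ok
    return mask if mask.any() else None

_EQ_TOL = 1e-12


def _stat_from_sums(a, q, L, n, tot, sqtot):
    """Vectorized statistic for arcs given arc sums/square-sums (see cbs_statistic)."""
    nc = n - L
    mean_a = a / L
    mean_c = (tot - a) / nc
    ss = (q - a * a / L) + (sqtot - q - (tot - a) ** 2 / nc)
    ss = np.maximum(ss, 0.0)
    denom = np.sqrt(ss / max(n - 2, 1) * (1.0 / L + 1.0 / nc))
    diff = np.abs(mean_a - mean_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    # s == 0: infinite contrast unless the means agree too
    t = np.where(denom > 0, t, np.where(diff > _EQ_TOL, np.inf, 0.0))
    return t


def max_arc(values: np.ndarray, min_width: int = 2):
    """Best-scoring arc of one vector: (statistic, i, j).

    Ties are broken toward smaller i, then smaller j. Returns (0.0, 0, n)
    when no arc satisfies the width constraints.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        return 0.0, 0, n
    S = np.concatenate([[0.0], np.cumsum(v)])
    Q = np.concatenate([[0.0], np.cumsum(v * v)])
    # full (i, j) scan in C order so argmax tie-breaks (smaller i, then j)
    i_idx, j_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    L = j_idx - i_idx
    valid = (L >= max(min_width, 1)) & (L <= n - 1)
    valid &= ((i_idx == 0) | (i_idx >= min_width)) & ((j_idx == n) | (n - j_idx >= min_width))
    if not valid.any():
        return 0.0, 0, n
    with np.errstate(divide="ignore", invalid="ignore"):
        a = S[j_idx] - S[i_idx]
        q = Q[j_idx] - Q[i_idx]
        nc = n - L
        mean_a = np.where(L > 0, a / np.maximum(L, 1), 0.0)
        mean_c = np.where(nc > 0, (S[n] - a) / np.maximum(nc, 1), 0.0)
        ss = np.maximum((q - a * mean_a) + (Q[n] - q - (S[n] - a) * mean_c), 0.0)
        denom = np.sqrt(ss / max(n - 2, 1) * (1.0 / np.maximum(L, 1) + 1.0 / np.maximum(nc, 1)))
        diff = np.abs(mean_a - mean_c)
        t = np.where(denom > 0, diff / denom,
                     np.where(diff > _EQ_TOL, np.inf, 0.0))
    t = np.where(valid, t, -np.inf)
    m = float(np.max(t))
    if m < 0:
        return 0.0, 0, n
    # an arc and its complement score identically in exact arithmetic but can
    # differ by an ulp here; treat near-maxima as ties and take the first in
    # (i, j) order
    if np.isinf(m):
        tied = np.isinf(t) & (t > 0)
    else:
        tied = t >= m - 1e-9 * max(1.0, abs(m))
    flat = int(np.argmax(tied))
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), int(i), int(j)


def _permutation_maxima(batch: np.ndarray, min_width: int) -> np.ndarray:
    """Per-row maximum arc statistic for a batch of permuted vectors."""
    B, n = batch.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(batch, axis=1)], axis=1)
    Q = np.concatenate([np.zeros((B, 1)), np.cumsum(batch * batch, axis=1)], axis=1)
    tot = S[:, [n]]
    sqtot = Q[:, [n]]
    best = np.zeros(B)
    for L in range(1, n):
        mask = _valid_start_mask(n, L, min_width)
        if mask is None:
            continue
        a = (S[:, L:] - S[:, :-L])[:, mask]
        q = (Q[:, L:] - Q[:, :-L])[:, mask]
        t = _stat_from_sums(a, q, L, n, tot, sqtot)
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _split_is_significant(values: np.ndarray, observed: float,
                          config: SegmentationConfig,
                          rng: np.random.Generator) -> bool:
    """Permutation test with early stopping.

    p is the fraction of value permutations whose maximal arc statistic
    reaches the observed one; permuting stops as soon as the exceedance
    count already forces p > alpha.
    """
    n_perm = config.n_permutations
    stop_at = int(np.floor(config.alpha * n_perm)) + 1
    exceed = 0
    done = 0
    chunk = 128
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(values, (b, 1)), axis=1)
        maxima = _permutation_maxima(perms, config.min_width)
        exceed += int(np.sum(maxima >= observed))
        done += b
        if exceed >= stop_at:
            return False
        chunk = min(chunk * 2, 2048)
    return exceed / n_perm <= config.alpha


def segment_chromosome(values: np.ndarray, config: SegmentationConfig,
                       rng: Optional[np.random.Generator] = None) -> List[int]:
    """Recursive CBS on one chromosome; returns sorted interior breakpoints.

    Breakpoints are probe indices in (0, n); an arc touching the boundary
    contributes a single breakpoint (plain binary split).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if rng is None:
        rng = child_rng(config.seed, 7)
    breakpoints: List[int] = []
    queue = [(0, n)]
    while queue:
        lo, hi = queue.pop(0)
        piece = v[lo:hi]
        stat, i, j = max_arc(piece, config.min_width)
        if stat <= 0:
            continue
        if not _split_is_significant(piece, stat, config, rng):
            continue
        cuts = [c for c in (i, j) if 0 < c < hi - lo]
        if not cuts:
            continue
        breakpoints.extend(lo + c for c in cuts)
        edges = [0, *cuts, hi - lo]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a >= 2 * config.min_width:
                queue.append((lo + a, lo + b))
    return sorted(set(breakpoints))


def segment_profile(profile: RatioProfile,
                    config: Optional[SegmentationConfig] = None) -> SegmentedProfile:
    """CBS independently on every chromosome of a ratio profile."""
    if config is None:
        config = SegmentationConfig()
    out = SegmentedProfile(sample_id=profile.sample_id)
    for ci, chrom in enumerate(profile.chrom_order):
        sub = profile.data[profile.data["chromosome"] == chrom]
        if sub.empty:
            continue
        vals = sub["log2"].to_numpy(float)
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        rng = child_rng(config.seed, 7, ci)
        bps = segment_chromosome(vals, config, rng)
        edges = [0, *bps, len(vals)]
        for a, b in zip(edges[:-1], edges[1:]):
            out.segments.append(Segment(
                chromosome=chrom, start_probe=a, end_probe=b,
                genomic_start=int(starts[a]), genomic_end=int(ends[b - 1]),
                mean=float(np.mean(vals[a:b])), n_probes=b - a,
            ))
    _assert_tiling(profile, out)
    return out


def _assert_tiling(profile: RatioProfile, seg: SegmentedProfile) -> None:
    counts = profile.data.groupby("chromosome", sort=False).size().to_dict()
    for chrom, total in counts.items():
        spans = sorted((s.start_probe, s.end_probe) for s in seg.segments
                       if s.chromosome == chrom)
        cursor = 0
        for a, b in spans:
            if a != cursor:
                raise AssertionError(f"{chrom}: segments do not tile probes")
            cursor = b
        if cursor != total:
            raise AssertionError(f"{chrom}: segments do not cover all probes")


SEGMENT_COLUMNS = ["sample", "chromosome", "genomic_start", "genomic_end",
                   "n_probes", "mean", "start_probe", "end_probe"]


def write_segments(seg: SegmentedProfile, path) -> None:
    seg.frame().to_csv(path, sep="\t", index=False, columns=SEGMENT_COLUMNS)


def read_segments(path) -> SegmentedProfile:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no segments")
    prof = SegmentedProfile(sample_id=str(df["sample"].iloc[0]))
    for _, r in df.iterrows():
        prof.segments.append(Segment(
            chromosome=str(r["chromosome"]),
            start_probe=int(r["start_probe"]), end_probe=int(r["end_probe"]),
            genomic_start=int(r["genomic_start"]), genomic_end=int(r["genomic_end"]),
            mean=float(r["mean"]), n_probes=int(r["n_probes"]),
        ))
    return prof
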