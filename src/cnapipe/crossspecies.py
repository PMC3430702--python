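"""Cross-species projection of copy-number tracks and profile similarity.

A copy-number profile from one species is compared with profiles from
another by rewriting its coordinates through synteny blocks: paired source /
target intervals with an orientation. A target-genome probe position falling
inside a block's target interval maps linearly (proportionally, since paired
blocks may differ in length) to a source position, where the value of the
covering source segment -- log2(estimated copy number over inferred ploidy)
-- is read off. Two projected profiles are then scored with the similarity
index

    s = sign(r) * sqrt(|r|) * 1000,

r being the Pearson correlation over positions where both profiles have
values; s is bounded in [-1000, 1000] with self-similarity 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cn_estimation import CopyNumberProfile

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class SyntenyBlock:
    """A pair of homologous intervals (0-based half-open) with orientation."""

    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.src_start >= self.src_end or self.tgt_start >= self.tgt_end:
            raise ValueError("synteny block intervals must be non-empty")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    @property
    def src_length(self) -> int:
        return self.src_end - self.src_start

    @property
    def tgt_length(self) -> int:
        return self.tgt_end - self.tgt_start


@dataclass
class ProjectedProfile:
    """A copy-number track resampled onto a target-genome position grid."""

    sample_id: str
    grid: pd.DataFrame  # chromosome, position (sorted)
    values: np.ndarray  # NaN where no block / no segment covers the position
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values length mismatch")


def resolve_blocks(blocks: Sequence[SyntenyBlock]) -> List[SyntenyBlock]:
    """Drop target-overlapping blocks, keeping the longer target interval."""
    kept: List[SyntenyBlock] = []
    for blk in sorted(blocks, key=lambda b: (b.tgt_chrom, b.tgt_start, -b.tgt_length)):
        clash = next((k for k in kept if k.tgt_chrom == blk.tgt_chrom
                      and k.tgt_start < blk.tgt_end and blk.tgt_start < k.tgt_end), None)
        if clash is None:
            kept.append(blk)
        elif blk.tgt_length > clash.tgt_length:
            warnings.warn(f"dropping target-overlapping synteny block {clash}", stacklevel=2)
            kept.remove(clash)
            kept.append(blk)
        else:
            warnings.warn(f"dropping target-overlapping synteny block {blk}", stacklevel=2)
    return sorted(kept, key=lambda b: (b.tgt_chrom, b.tgt_start))


def map_position(tgt_chrom: str, pos: int,
                 blocks: Sequence[SyntenyBlock]) -> Optional[tuple]:
    """Map one target-genome position to (src_chrom, src_pos), or None.

    The fractional offset within the target interval is carried over
    proportionally; reverse-oriented blocks reflect it.
    """
    for blk in blocks:
        if blk.tgt_chrom == tgt_chrom and blk.tgt_start <= pos < blk.tgt_end:
            f = (pos - blk.tgt_start) / blk.tgt_length
            if blk.orientation == FORWARD:
                src = blk.src_start + int(np.floor(f * blk.src_length))
            else:
                src = blk.src_end - 1 - int(np.floor(f * blk.src_length))
            return blk.src_chrom, src
    return None


def project_profile(cn: CopyNumberProfile, blocks: Sequence[SyntenyBlock],
                    target_grid: pd.DataFrame, group: str = "") -> ProjectedProfile:
    """Resample a copy-number track onto a target genome's probe positions.

    Each target position maps through the (resolved) blocks; the value is the
    log2(c/psi) of the source segment containing the mapped position. The
    segmented track, not the raw probe value, is what gets compared.
    """
    blocks = resolve_blocks(blocks)
    grid = target_grid.sort_values(["chromosome", "position"]).reset_index(drop=True)
    seg = cn.segments
    by_chrom = {
        chrom: (sub["genomic_start"].to_numpy(), sub["genomic_end"].to_numpy(),
                sub["log2_cn_over_ploidy"].to_numpy())
        for chrom, sub in seg.sort_values(["chromosome", "genomic_start"])
                              .groupby("chromosome", sort=False)
    }
    values = np.full(len(grid), np.nan)
    for k, (chrom, pos) in enumerate(zip(grid["chromosome"], grid["position"])):
        hit = map_position(chrom, int(pos), blocks)
        if hit is None:
            continue
        src_chrom, src_pos = hit
        if src_chrom not in by_chrom:
            continue
        starts, ends, vals = by_chrom[src_chrom]
        idx = np.searchsorted(starts, src_pos, side="right") - 1
        if idx >= 0 and src_pos < ends[idx]:
            values[k] = vals[idx]
    return ProjectedProfile(sample_id=cn.sample_id, grid=grid, values=values,
                            group=group)


def similarity_index(a: ProjectedProfile, b: ProjectedProfile,
                     min_overlap: int = 10) -> float:
    """sign(r) * sqrt(|r|) * 1000 over the common non-missing positions."""
    if len(a.values) != len(b.values):
        raise ValueError("profiles must share the target grid")
    mask = np.isfinite(a.values) & np.isfinite(b.values)
    n = int(mask.sum())
    if n < min_overlap:
        raise ValueError(f"only {n} overlapping positions (< {min_overlap})")
    x, y = a.values[mask], b.values[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on the overlap; similarity undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return float(np.sign(r) * np.sqrt(abs(r)) * 1000.0)


def similarity_matrix(profiles: Sequence[ProjectedProfile],
                      min_overlap: int = 10):
    """All pairwise similarity indices plus group-average summaries.

    Returns (matrix, group_summary): ``matrix`` is a symmetric DataFrame with
    the diagonal fixed at 1000; pairs whose index is undefined become NaN
    with a warning and are excluded from group means. ``group_summary`` holds
    the mean index for every ordered group pair, self-pairs excluded within
    a group.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    labels = [p.sample_id for p in profiles]
    n = len(profiles)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1000.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = similarity_index(profiles[i], profiles[j], min_overlap=min_overlap)
            except ValueError as exc:
                warnings.warn(f"{labels[i]} vs {labels[j]}: {exc}", stacklevel=2)
                s = np.nan
            mat[i, j] = mat[j, i] = s
    matrix = pd.DataFrame(mat, index=labels, columns=labels)

    groups = [p.group or p.sample_id for p in profiles]
    rows = []
    for g1 in dict.fromkeys(groups):
        for g2 in dict.fromkeys(groups):
            vals = [mat[i, j] for i in range(n) for j in range(n)
                    if groups[i] == g1 and groups[j] == g2 and i != j]
            if not vals:
                continue
            vals = np.asarray(vals, float)
            rows.append({"group_a": g1, "group_b": g2,
                         "mean_similarity": float(np.nanmean(vals)),
                         "n_pairs": int(np.isfinite(vals).sum())})
    return matrix, pd.DataFrame(rows)


SYNTENY_COLUMNS = ["src_chrom", "src_start", "src_end",
                   "tgt_chrom", "tgt_start", "tgt_end", "orientation"]


def read_synteny_blocks(path) -> List[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:7]) != SYNTENY_COLUMNS:
        raise ValueError(f"{path}: header must be {SYNTENY_COLUMNS}")
    out = []
    for _, r in df.iterrows():
        orient = {"+": FORWARD, "-": REVERSE}.get(str(r["orientation"]),
                                                  str(r["orientation"]))
        out.append(SyntenyBlock(str(r["src_chrom"]), int(r["src_start"]),
                                int(r["src_end"]), str(r["tgt_chrom"]),
                                int(r["tgt_start"]), int(r["tgt_end"]), orient))
    return out


def write_synteny_blocks(blocks: Sequence[SyntenyBlock], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SYNTENY_COLUMNS) + "\n")
        for b in blocks:
            sign = "+" if b.orientation == FORWARD else "-"
            fh.write(f"{b.src_chrom}\t{b.src_start}\t{b.src_end}\t"
                     f"{b.tgt_chrom}\t{b.tgt_start}\t{b.tgt_end}\t{sign}\n")


def write_projected(prof: ProjectedProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_id={prof.sample_id}\n")
        fh.write(f"# group={prof.group}\n")
        out = prof.grid.copy()
        out["value"] = prof.values
        out.to_csv(fh, sep="\t", index=False)


def read_projected(path) -> ProjectedProfile:
    header = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return ProjectedProfile(sample_id=header.get("sample_id", "sample"),
                            grid=df[["chromosome", "position"]],
                            values=df["value"].to_numpy(float),
                            group=header.get("group", ""))


def read_target_grid(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["chromosome", "position"]:
        raise ValueError(f"{path}: header must be chromosome, position")
    return df[["chromosome", "position"]]


def write_target_grid(grid: pd.DataFrame, path) -> None:
    grid.to_csv(path, sep="\t", index=False, columns=["chromosome", "position"])
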