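"""Tumor purity/ploidy inference and integer copy-number assignment.

Comparing aCGH profiles across samples requires undoing two sample-specific
distortions: contamination by normal (diploid) cells, which compresses log2
ratios toward 0, and tumor polyploidy, which shifts the normalization
center. A segment at integer tumor copy number c in a sample of purity rho
and tumor ploidy psi has expected log2 ratio

    log2( (rho*c + 2*(1-rho)) / (rho*psi + 2*(1-rho)) ).

Both parameters are recovered by an exhaustive grid search that scores every
(rho, psi) pair by the probe-weighted squared mismatch between observed
segment means and the nearest integer-copy-number expectation, plus a small
ploidy penalty that resolves the inherent (psi, 2*psi) doubling degeneracy
toward the more parsimonious genome. The per-probe comparison track used by
all downstream analyses is log2(c_hat / psi_hat), which is purity-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .segmentation import SegmentedProfile
from .synthetic import DEFAULT_C_MAX, DEFAULT_LOG2_FLOOR, mixture_log2

DEFAULT_RHO_GRID = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
DEFAULT_PSI_GRID = np.round(np.arange(1.0, 6.0 + 1e-9, 0.05), 2)


@dataclass(frozen=True)
class TumorModel:
    """Fitted sample composition: purity rho, tumor ploidy psi."""

    purity: float
    ploidy: float
    fit_error: float = float("nan")
    c_max: int = DEFAULT_C_MAX
    floor: float = DEFAULT_LOG2_FLOOR

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not 1 <= self.ploidy <= self.c_max:
            raise ValueError(f"ploidy must be in [1, c_max={self.c_max}]")


@dataclass
class CopyNumberProfile:
    """Integer copy numbers per segment plus the per-probe log2(c/psi) track.

    ``probes`` may be None when only segment-level information was loaded
    (e.g. from a segment TSV); probe-level operations then raise.
    """

    sample_id: str
    model: TumorModel
    segments: pd.DataFrame  # segment table with copy_number, log2_cn_over_ploidy, hd
    probes: Optional[pd.DataFrame] = None  # chromosome, start, end, probe_id, cn, track, hd

    @property
    def track(self) -> np.ndarray:
        """Per-probe log2(estimated copy number over inferred ploidy)."""
        if self.probes is None:
            raise ValueError(f"{self.sample_id}: no probe-level track loaded")
        return self.probes["log2_cn_over_ploidy"].to_numpy(float)

    @property
    def chrom_order(self) -> list:
        source = self.probes if self.probes is not None else self.segments
        return list(dict.fromkeys(source["chromosome"]))


def expected_log2(c, model: TumorModel) -> np.ndarray:
    """Expected mixture log2 ratio at integer copy number c under the model."""
    return mixture_log2(c, model.purity, model.ploidy, floor=model.floor)


def _expectation_table(rho: float, psi: float, c_max: int, floor: float) -> np.ndarray:
    return mixture_log2(np.arange(c_max + 1), rho, psi, floor=floor)


def _nearest_copy_number(means: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Nearest integer copy number under a strictly increasing expectation table.

    Equidistant means resolve to the smaller copy number.
    """
    mids = 0.5 * (table[:-1] + table[1:])
    return np.searchsorted(mids, means, side="left")


def fit_tumor_model(profile: SegmentedProfile,
                    rho_grid: Optional[np.ndarray] = None,
                    psi_grid: Optional[np.ndarray] = None,
                    c_max: int = DEFAULT_C_MAX,
                    lam: Optional[float] = None,
                    floor: float = DEFAULT_LOG2_FLOOR) -> TumorModel:
    """Exhaustive (rho, psi) grid search over a segmented profile.

    Objective: sum over segments of n_probes * (mean - expected_log2(c_hat))^2
    plus lam * psi, with c_hat the nearest integer copy number for each
    segment. Ties break toward smaller psi, then larger purity, so the fit is
    deterministic. lam defaults to 1e-3 per probe.
    """
    rho_grid = DEFAULT_RHO_GRID if rho_grid is None else np.asarray(rho_grid, float)
    psi_grid = DEFAULT_PSI_GRID if psi_grid is None else np.asarray(psi_grid, float)
    if rho_grid.size == 0 or psi_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if not profile.segments:
        raise ValueError("cannot fit an empty profile")
    means = np.array([s.mean for s in profile.segments])
    weights = np.array([s.n_probes for s in profile.segments], dtype=float)
    total = float(weights.sum())
    if total < 10:
        raise ValueError("need at least 10 probes to fit a tumor model")
    if lam is None:
        lam = 1e-3 * total

    best_obj = np.inf
    best = None
    for psi in np.sort(psi_grid):
        if not 1 <= psi <= c_max:
            continue
        penalty = lam * psi
        for rho in np.sort(rho_grid)[::-1]:
            table = _expectation_table(rho, psi, c_max, floor)
            c_hat = _nearest_copy_number(means, table)
            resid = means - table[c_hat]
            obj = float(np.sum(weights * resid * resid)) + penalty
            if obj < best_obj:
                best_obj = obj
                best = (float(rho), float(psi))
    return TumorModel(purity=best[0], ploidy=best[1], fit_error=best_obj,
                      c_max=c_max, floor=floor)


def assign_copy_numbers(profile: SegmentedProfile, model: TumorModel,
                        probes: pd.DataFrame) -> CopyNumberProfile:
    """Assign the nearest integer copy number to every segment and expand the
    purity-free log2(c/psi) track onto the probe grid.

    ``probes`` is the probe table the profile was segmented from
    (chromosome, start, end, probe_id in profile order).
    """
    table = _expectation_table(model.purity, model.ploidy, model.c_max, model.floor)
    seg = profile.frame()
    means = seg["mean"].to_numpy(float)
    c_hat = _nearest_copy_number(means, table)
    if np.any(means > table[-1]):
        warnings.warn(
            f"{int(np.sum(means > table[-1]))} segment(s) exceed the expectation at "
            f"c_max={model.c_max}; copy numbers clamped", stacklevel=2)
    with np.errstate(divide="ignore"):
        track = np.log2(c_hat / model.ploidy)
    track = np.where(c_hat == 0, model.floor, np.maximum(track, model.floor))
    seg["copy_number"] = c_hat.astype(int)
    seg["log2_cn_over_ploidy"] = track
    seg["hd"] = c_hat == 0

    # expand to probes chromosome by chromosome via the probe-index spans
    probe_parts = []
    for chrom, grp in probes.groupby("chromosome", sort=False):
        sub = seg[seg["chromosome"] == chrom]
        n = len(grp)
        cn = np.empty(n, dtype=int)
        tr = np.empty(n, dtype=float)
        hd = np.zeros(n, dtype=bool)
        covered = 0
        for _, row in sub.iterrows():
            a, b = int(row["start_probe"]), int(row["end_probe"])
            cn[a:b] = row["copy_number"]
            tr[a:b] = row["log2_cn_over_ploidy"]
            hd[a:b] = row["hd"]
            covered += b - a
        if covered != n:
            raise ValueError(f"{chrom}: segments do not tile the probe grid")
        part = grp.reset_index(drop=True).copy()
        part["copy_number"] = cn
        part["log2_cn_over_ploidy"] = tr
        part["hd"] = hd
        probe_parts.append(part)
    probe_frame = pd.concat(probe_parts, ignore_index=True)
    return CopyNumberProfile(sample_id=profile.sample_id, model=model,
                             segments=seg, probes=probe_frame)


CN_COLUMNS = ["sample", "chromosome", "genomic_start", "genomic_end", "n_probes",
              "segment_mean", "copy_number", "log2_cn_over_ploidy", "hd_flag",
              "start_probe", "end_probe"]


def write_cn_profile(cn: CopyNumberProfile, path) -> None:
    df = cn.segments.rename(columns={"mean": "segment_mean", "hd": "hd_flag"})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_id={cn.sample_id}\n")
        fh.write(f"# purity={cn.model.purity}\n")
        fh.write(f"# ploidy={cn.model.ploidy}\n")
        fh.write(f"# fit_error={cn.model.fit_error}\n")
        df.to_csv(fh, sep="\t", index=False, columns=CN_COLUMNS)


def read_cn_profile(path, probes: Optional[pd.DataFrame] = None) -> CopyNumberProfile:
    """Load a copy-number segment TSV written by write_cn_profile.

    Supplying the matching probe table (chromosome, start, end, probe_id in
    segmentation order) rebuilds the per-probe track as well.
    """
    header = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    df = df.rename(columns={"segment_mean": "mean", "hd_flag": "hd"})
    model = TumorModel(purity=float(header["purity"]), ploidy=float(header["ploidy"]),
                       fit_error=float(header.get("fit_error", "nan")))
    cn = CopyNumberProfile(sample_id=header.get("sample_id", Path(path).stem),
                           model=model, segments=df)
    if probes is not None:
        # re-expand the probe track from the segment spans
        parts = []
        for chrom, grp in probes.groupby("chromosome", sort=False):
            sub = df[df["chromosome"] == chrom]
            n = len(grp)
            c = np.empty(n, dtype=int)
            t = np.empty(n, dtype=float)
            h = np.zeros(n, dtype=bool)
            for _, r in sub.iterrows():
                a, b = int(r["start_probe"]), int(r["end_probe"])
                c[a:b], t[a:b], h[a:b] = int(r["copy_number"]), \
                    float(r["log2_cn_over_ploidy"]), bool(r["hd"])
            part = grp.reset_index(drop=True).copy()
            part["copy_number"], part["log2_cn_over_ploidy"], part["hd"] = c, t, h
            parts.append(part)
        cn.probes = pd.concat(parts, ignore_index=True)
    return cn
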